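import numpy as np
import pytest

from vasoreact import StimulusParadigm, TrapezoidParams


@pytest.fixture
def paradigm() -> StimulusParadigm:
    return StimulusParadigm()


@pytest.fixture
def planted() -> TrapezoidParams:
    return TrapezoidParams(baseline=0.0, amplitude=1.0, t_peak=6.0, t_return=28.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
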