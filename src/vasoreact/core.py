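"""Shared domain types and analytic primitives.

The central object is the trapezoidal model of the stimulus-locked BOLD
response: the percent-signal-change trace of a stimulation block is described
by a baseline, a linear rise from block onset to a plateau, a plateau lasting
until stimulus offset, and a linear descent back to baseline. Three derived
metrics summarize vascular reactivity:

* time-to-peak — from block onset (t = 0) to the start of the plateau,
* time-to-baseline — from stimulus offset to the return to baseline,
* amplitude — plateau height above baseline, in percent signal change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusParadigm",
    "BoldSeries",
    "Volume4D",
    "ZStatMap",
    "BlockMatrix",
    "TrapezoidParams",
    "TrapezoidFit",
    "trapezoid_value",
    "sigma_to_fwhm",
    "fwhm_to_sigma",
    "design_time_grid",
]

#: FWHM of a Gaussian with unit standard deviation.
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class StimulusParadigm:
    """Block-design visual stimulation timing.

    Defaults describe seven repetitions of a 20 s flickering-checkerboard
    stimulus each followed by 28 s of rest, sampled every 3 s (one fMRI
    volume per TR). ``flicker_rate`` is carried as metadata only; the
    flicker itself is never modeled.
    """

    n_blocks: int = 7
    stim_duration: float = 20.0
    rest_duration: float = 28.0
    tr: float = 3.0
    flicker_rate: float = 8.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be > 0")
        if self.rest_duration < 0:
            raise ValueError("rest_duration must be >= 0")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        ratio = self.block_length / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"block length {self.block_length} s is not an integer "
                f"multiple of tr {self.tr} s"
            )

    @property
    def block_length(self) -> float:
        """Duration of one stimulus + rest block in seconds."""
        return self.stim_duration + self.rest_duration

    @property
    def samples_per_block(self) -> int:
        return round(self.block_length / self.tr)

    @property
    def n_samples(self) -> int:
        """Total design length in volumes."""
        return self.n_blocks * self.samples_per_block

    @property
    def run_duration(self) -> float:
        return self.n_blocks * self.block_length


@dataclass(frozen=True)
class BoldSeries:
    """A single sampled signal (raw units or percent change)."""

    values: np.ndarray
    tr: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("BoldSeries needs a 1-D array of >= 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("BoldSeries must not contain missing values")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, first sample at ``t0``."""
        return self.t0 + self.tr * np.arange(self.values.size)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Volume4D:
    """A 4-D BOLD run (x, y, z, time) with its in-brain mask."""

    data: np.ndarray
    mask: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        if data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, time)")
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match spatial shape "
                f"{data.shape[:3]}"
            )
        if not mask.any():
            raise ValueError("mask selects no voxels")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class ZStatMap:
    """Voxelwise Z statistics; out-of-mask voxels carry NaN."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        if values.shape != mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("Z values inside the mask must be finite")


@dataclass(frozen=True)
class BlockMatrix:
    """Per-block percent-change traces plus retention flags.

    ``normalization_mean`` is the grand mean over all blocks that served as
    the percent-change denominator; it is computed once, before any block
    rejection, and never updated afterwards.
    """

    blocks: np.ndarray
    tr: float
    retained: np.ndarray
    normalization_mean: float

    def __post_init__(self) -> None:
        blocks = np.asarray(self.blocks, dtype=float)
        retained = np.asarray(self.retained, dtype=bool)
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "retained", retained)
        if blocks.ndim != 2:
            raise ValueError("blocks must be 2-D (block x sample)")
        if retained.shape != (blocks.shape[0],):
            raise ValueError("retained needs one flag per block")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def discarded_indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(~self.retained)]


@dataclass(frozen=True)
class TrapezoidParams:
    """Parameters of the trapezoidal response model.

    All times are in seconds from block onset (t = 0). The descending edge
    starts at ``t_fall_start`` (fixed at stimulus offset during fitting) and
    regains baseline at ``t_return``.
    """

    baseline: float
    amplitude: float
    t_peak: float
    t_return: float
    t_fall_start: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.t_peak <= self.t_fall_start):
            raise ValueError("require 0 < t_peak <= t_fall_start")
        if self.t_return < self.t_fall_start:
            raise ValueError("t_return must be >= t_fall_start")


@dataclass(frozen=True)
class TrapezoidFit:
    """A fitted trapezoid with the derived reactivity metrics."""

    params: TrapezoidParams
    time_to_peak: float
    time_to_baseline: float
    amplitude: float
    sse: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.time_to_peak < 0 or self.time_to_baseline < 0:
            raise ValueError("derived times must be non-negative")
        if self.sse < -1e-12:
            raise ValueError("sse must be >= 0")
        object.__setattr__(self, "sse", max(self.sse, 0.0))


def trapezoid_value(t, params: TrapezoidParams):
    """Evaluate the trapezoid at time(s) ``t`` (seconds from block onset).

    Piecewise linear: baseline before onset, linear rise on [0, t_peak],
    plateau at baseline + amplitude on [t_peak, t_fall_start], linear descent
    on [t_fall_start, t_return], baseline afterwards. Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    shape = _trapezoid_shape(t, params.t_peak, params.t_fall_start, params.t_return)
    out = params.baseline + params.amplitude * shape
    return out if out.ndim else float(out)


def _trapezoid_shape(t: np.ndarray, t_peak: float, t_fall: float, t_return: float) -> np.ndarray:
    """Unit-amplitude, zero-baseline trapezoid profile at times ``t``."""
    shape = np.zeros_like(t, dtype=float)
    rising = (t >= 0) & (t < t_peak)
    shape[rising] = t[rising] / t_peak
    plateau = (t >= t_peak) & (t <= t_fall)
    shape[plateau] = 1.0
    if t_return > t_fall:
        falling = (t > t_fall) & (t < t_return)
        shape[falling] = (t_return - t[falling]) / (t_return - t_fall)
    return shape


def sigma_to_fwhm(sigma: float) -> float:
    """Convert a Gaussian kernel's sigma (mm) to its full width at half maximum.

    FWHM = sigma * 2*sqrt(2*ln 2); e.g. sigma = 3 mm gives ~7.06 mm, the
    kernel conventionally reported as "7 mm FWHM".
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return sigma * _FWHM_PER_SIGMA


def fwhm_to_sigma(fwhm: float) -> float:
    """Inverse of :func:`sigma_to_fwhm`."""
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    return fwhm / _FWHM_PER_SIGMA


def design_time_grid(paradigm: StimulusParadigm) -> np.ndarray:
    """Sample times (s) of the full design; sample k sits at t = k * tr.

    The first sample of each block coincides with block onset, matching the
    convention that response timing is measured from the beginning of the
    block at t = 0.
    """
    return paradigm.tr * np.arange(paradigm.n_samples, dtype=float)
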