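"""Synthetic data generators.

Two families of inputs are simulated:

* subject-level 4-D BOLD runs with a trapezoidal response planted in a known
  "active" voxel set, plus i.i.d. Gaussian noise and a single low-frequency
  cosine drift per run (the component a 48-s high-pass filter would remove);
* cohort tables with the statistical structure the group analyses assume:
  three groups (healthy controls, premanifest and manifest Huntington's
  disease gene carriers), demographic covariates, per-region cortical
  thickness drawn from group-specific means, and cognitive test scores linked
  to thickness through a configurable slope.

Every generator is a pure function of its spec and seed: the same inputs
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BoldSeries,
    StimulusParadigm,
    TrapezoidParams,
    Volume4D,
    design_time_grid,
    trapezoid_value,
)

__all__ = [
    "SubjectTruth",
    "GroupSpec",
    "CohortSpec",
    "CognitiveTest",
    "simulate_subject_run",
    "simulate_cohort",
    "simulate_block_response",
    "DEFAULT_REGION_MEANS",
    "DEFAULT_TESTS",
]


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one simulated subject run.

    ``active_voxels`` marks where the trapezoidal response is planted; it must
    lie inside the in-brain mask. ``baseline_level`` is the raw signal level
    (arbitrary scanner units, conventionally ~1000); the planted response
    modulates it multiplicatively by ``trapezoid/100`` so that percent-change
    extraction recovers the planted trapezoid.
    """

    params: TrapezoidParams
    active_voxels: np.ndarray
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    baseline_level: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "active_voxels", np.asarray(self.active_voxels, dtype=bool)
        )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be > 0")


def simulate_subject_run(
    paradigm: StimulusParadigm,
    truth: SubjectTruth,
    grid_shape: tuple[int, int, int],
    mask: np.ndarray | None = None,
    n_discard_initial_volumes: int = 0,
) -> Volume4D:
    """Simulate a block-design BOLD run with a planted trapezoid response.

    Active voxels carry ``baseline_level * (1 + trapezoid(t mod block)/100)``;
    every voxel additionally receives Gaussian noise (sd ``noise_sd``) and a
    run-length cosine drift of amplitude ``drift_amplitude``. An empty active
    set yields a null subject. ``n_discard_initial_volumes`` prepends and then
    drops dummy volumes, shifting acquisition relative to the paradigm
    (models runs whose recorded duration falls short of n_blocks x block).
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 4:
        raise ValueError("grid_shape must be 3-D with every extent >= 4")
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid_shape:
        raise ValueError("mask shape does not match grid_shape")
    active = np.asarray(truth.active_voxels, dtype=bool)
    if active.shape != grid_shape:
        raise ValueError("active_voxels shape does not match grid_shape")
    if np.any(active & ~mask):
        raise ValueError("active voxels must lie inside the in-brain mask")

    times = design_time_grid(paradigm)
    block_times = np.mod(times, paradigm.block_length)
    response = truth.baseline_level * (
        1.0 + trapezoid_value(block_times, truth.params) / 100.0
    )
    n_t = times.size

    rng = np.random.default_rng(truth.seed)
    data = np.full(grid_shape + (n_t,), truth.baseline_level, dtype=float)
    data[active] = response
    if truth.drift_amplitude != 0.0:
        drift = truth.drift_amplitude * np.cos(
            2.0 * np.pi * times / paradigm.run_duration
        )
        data += drift
    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd, size=data.shape)
    if n_discard_initial_volumes > 0:
        data = data[..., n_discard_initial_volumes:]
    return Volume4D(data=data, mask=mask, tr=paradigm.tr)


def simulate_block_response(
    params: TrapezoidParams,
    paradigm: StimulusParadigm,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BoldSeries:
    """One block-length percent-change series: trapezoid plus Gaussian noise."""
    if params.t_return > paradigm.block_length:
        raise ValueError("t_return exceeds the block length")
    times = paradigm.tr * np.arange(paradigm.samples_per_block, dtype=float)
    values = trapezoid_value(times, params)
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return BoldSeries(values=values, tr=paradigm.tr, t0=0.0)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Per-region cortical thickness (mm): {region: {group: (mean, sd)}}.
#: Means/SDs are typical visual-cortex values for healthy adults and early
#: Huntington's disease, with thinning confined to the manifest group.
DEFAULT_REGION_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "cuneus": {"control": (1.95, 0.14), "premanifest": (1.93, 0.13), "manifest": (1.82, 0.15)},
    "fusiform": {"control": (2.71, 0.16), "premanifest": (2.72, 0.11), "manifest": (2.55, 0.21)},
    "inferior_temporal": {"control": (2.70, 0.13), "premanifest": (2.73, 0.13), "manifest": (2.58, 0.18)},
    "lateral_occipital": {"control": (2.11, 0.13), "premanifest": (2.17, 0.11), "manifest": (1.99, 0.22)},
    "lingual": {"control": (2.10, 0.16), "premanifest": (2.08, 0.09), "manifest": (1.96, 0.18)},
    "pericalcarine": {"control": (1.74, 0.16), "premanifest": (1.71, 0.13), "manifest": (1.67, 0.16)},
    "superior_parietal": {"control": (2.21, 0.16), "premanifest": (2.19, 0.10), "manifest": (2.02, 0.19)},
    "temporal_pole": {"control": (3.60, 0.36), "premanifest": (3.77, 0.21), "manifest": (3.59, 0.40)},
}

GROUPS = ("control", "premanifest", "manifest")
GENE_CARRIER_GROUPS = ("premanifest", "manifest")


@dataclass(frozen=True)
class CognitiveTest:
    """One cognitive assessment feeding a compound domain score.

    ``higher_is_better`` is False for timed tests (e.g. trail making), whose
    raw scores grow with impairment; the compound-Z construction flips them.
    ``mean``/``sd`` give the raw-score scale in the control population.
    """

    name: str
    domain: str
    mean: float
    sd: float
    higher_is_better: bool = True


#: Two visual cognitive domains: object perception and scanning/attention.
DEFAULT_TESTS: tuple[CognitiveTest, ...] = (
    CognitiveTest("vosp_object", "visual_perception", 18.0, 1.6),
    CognitiveTest("git_perception", "visual_perception", 15.0, 2.5),
    CognitiveTest("sdmt", "visual_scanning", 50.0, 9.0),
    CognitiveTest("stroop_word", "visual_scanning", 95.0, 14.0),
    CognitiveTest("tmt_a_seconds", "visual_scanning", 28.0, 8.0, higher_is_better=False),
)


@dataclass(frozen=True)
class GroupSpec:
    """Covariate distributions for one group."""

    n: int
    age_mean: float
    age_sd: float
    male_fraction: float = 0.5
    education_mean: float = 17.0
    education_sd: float = 2.5
    cag_mean: float | None = None
    cag_sd: float | None = None
    #: additive deficit (in domain-Z units) applied to every cognitive domain
    domain_deficit: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        for sd in (self.age_sd, self.education_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")


def _default_groups() -> dict[str, GroupSpec]:
    return {
        "control": GroupSpec(n=18, age_mean=46.2, age_sd=10.7, male_fraction=7 / 18),
        "premanifest": GroupSpec(
            n=21, age_mean=37.4, age_sd=9.0, male_fraction=11 / 21,
            education_mean=16.8, cag_mean=41.8, cag_sd=2.2,
        ),
        "manifest": GroupSpec(
            n=20, age_mean=52.1, age_sd=10.8, male_fraction=11 / 20,
            education_mean=16.4, cag_mean=42.8, cag_sd=2.4,
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Data-generating assumptions for a simulated cohort table.

    ``thickness_per_z`` (mm per domain-Z point) links the cognition-anchor
    region's thickness to the latent domain score: a subject whose anchor
    region is ``d`` mm thinner than the control mean scores ``d /
    thickness_per_z`` Z lower, before covariate effects and residual noise.
    ``age_slope_thickness`` models cortical thinning with age (mm/year),
    which makes the covariate-adjusted group difference the difference of
    the group thickness means by construction.
    """

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    region_means: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEANS)
    )
    tests: tuple[CognitiveTest, ...] = DEFAULT_TESTS
    thickness_per_z: float = 0.13
    cognition_residual_sd: float = 1.5
    test_noise_sd: float = 0.25
    anchor_region: str = "lateral_occipital"
    age_slope_thickness: float = -0.004
    age_slope_cognition: float = -0.015
    education_slope_cognition: float = 0.03
    education_min: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness_per_z == 0:
            raise ValueError("thickness_per_z must be nonzero")
        if self.cognition_residual_sd < 0 or self.test_noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        for g, gs in self.groups.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if g in GENE_CARRIER_GROUPS and gs.cag_mean is None:
                raise ValueError(f"gene-carrier group {g!r} needs a CAG distribution")
            if g == "control" and gs.cag_mean is not None:
                raise ValueError("CAG is defined only for gene-carrier groups")
        if self.anchor_region not in self.region_means:
            raise ValueError(f"anchor region {self.anchor_region!r} has no thickness model")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort table (one row per subject).

    Columns: ``subject``, ``group``, ``age`` (years), ``gender`` (1 = male),
    ``education`` (years, truncated at ``education_min``), ``cag`` (repeat
    count, NaN for controls), ``thick_<region>`` (mm) and one raw-score
    column per cognitive test. Deterministic given ``spec`` (incl. its seed).
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    # Fixed group iteration order keeps the table reproducible.
    for group in GROUPS:
        if group not in spec.groups:
            continue
        gs = spec.groups[group]
        ref_age = spec.groups["control"].age_mean if "control" in spec.groups else 45.0
        for i in range(gs.n):
            row: dict = {"subject": f"{group[:3]}{i:03d}", "group": group}
            row["age"] = rng.normal(gs.age_mean, gs.age_sd)
            row["gender"] = int(rng.random() < gs.male_fraction)
            edu = rng.normal(gs.education_mean, gs.education_sd)
            row["education"] = max(edu, spec.education_min)
            if gs.cag_mean is not None:
                row["cag"] = rng.normal(gs.cag_mean, gs.cag_sd or 0.0)
            else:
                row["cag"] = np.nan

            age_dev = row["age"] - ref_age
            for region, by_group in spec.region_means.items():
                mean, sd = by_group[group]
                row[f"thick_{region}"] = (
                    mean + spec.age_slope_thickness * age_dev + rng.normal(0.0, sd)
                )

            # Latent domain score: anchored to the cognition-anchor region's
            # thickness, plus group deficit, covariate effects and residual.
            anchor_mean = spec.region_means[spec.anchor_region]["control"][0]
            thick_dev = row[f"thick_{spec.anchor_region}"] - anchor_mean
            latent = (
                thick_dev / spec.thickness_per_z
                + gs.domain_deficit
                + spec.age_slope_cognition * age_dev
                + spec.education_slope_cognition
                * (row["education"] - spec.groups["control"].education_mean)
                + rng.normal(0.0, spec.cognition_residual_sd)
            )
            for test in spec.tests:
                z = latent + rng.normal(0.0, spec.test_noise_sd)
                if not test.higher_is_better:
                    z = -z
                row[test.name] = test.mean + test.sd * z
            rows.append(row)
    return pd.DataFrame(rows)
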