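"""End-to-end orchestration: simulate -> GLM -> reactivity -> group stats.

A pipeline run is fully described by a configuration mapping plus a seed;
identical configuration and seed reproduce byte-identical numeric outputs
(the manifest additionally records a timestamp, excluded from that
guarantee).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import StimulusParadigm, TrapezoidParams
from .glm import build_design_matrix, fit_glm
from .io import atomic_write_text, paradigm_from_config, write_json
from .reactivity import fit_subject
from .stats import ancova_contrast, association_regression, bonferroni_alpha, compound_zscore
from .synth import CohortSpec, SubjectTruth, simulate_cohort, simulate_subject_run

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

DEFAULT_DOMAINS = {
    "visual_perception": ["vosp_object", "git_perception"],
    "visual_scanning": ["sdmt", "stroop_word", "tmt_a_seconds"],
}
DEFAULT_DIRECTIONS = {"tmt_a_seconds": False}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    ``raw`` keeps the original mapping for hashing into the manifest. A seed
    is mandatory: every stochastic stage derives its own stream from it.
    """

    paradigm: StimulusParadigm
    seed: int
    out_dir: Path
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 3, "premanifest": 3, "manifest": 3}
    )
    grid_shape: tuple[int, int, int] = (10, 10, 6)
    active_fraction: float = 0.2
    noise_sd: float = 2.0
    drift_amplitude: float = 0.0
    baseline_level: float = 1000.0
    planted: TrapezoidParams = field(
        default_factory=lambda: TrapezoidParams(
            baseline=0.0, amplitude=1.0, t_peak=6.0, t_return=28.0
        )
    )
    roi_fraction: float = 0.2
    artifact_threshold: float = 3.0
    grid_resolution: float = 0.25
    highpass_cutoff_s: float | None = None
    ancova_covariates: tuple[str, ...] = ("age", "gender", "education")
    regression_covariates: tuple[str, ...] = ("age", "gender", "education", "cag")
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, cfg: dict, out_dir: str | Path) -> "PipelineConfig":
        if "seed" not in cfg:
            raise ValueError("config must provide a seed for stochastic synthesis")
        paradigm = paradigm_from_config(cfg.get("paradigm", {}))
        synth = cfg.get("synthesis", {})
        react = cfg.get("reactivity", {})
        glm = cfg.get("glm", {})
        stats_cfg = cfg.get("stats", {})
        planted = synth.get("planted", {})
        kwargs = dict(
            paradigm=paradigm,
            seed=int(cfg["seed"]),
            out_dir=Path(out_dir),
            raw=cfg,
        )
        if "n_per_group" in synth:
            kwargs["n_per_group"] = dict(synth["n_per_group"])
        if "grid_shape" in synth:
            kwargs["grid_shape"] = tuple(synth["grid_shape"])
        for k in ("active_fraction", "noise_sd", "drift_amplitude", "baseline_level"):
            if k in synth:
                kwargs[k] = synth[k]
        if planted:
            kwargs["planted"] = TrapezoidParams(
                baseline=planted.get("baseline_pct", 0.0),
                amplitude=planted.get("amplitude_pct", 1.0),
                t_peak=planted.get("t_peak_s", 6.0),
                t_return=planted.get("t_return_s", 28.0),
                t_fall_start=planted.get("t_fall_start_s", paradigm.stim_duration),
            )
        if "fraction" in react:
            kwargs["roi_fraction"] = react["fraction"]
        if "threshold" in react:
            kwargs["artifact_threshold"] = react["threshold"]
        if "grid_resolution" in react:
            kwargs["grid_resolution"] = react["grid_resolution"]
        if glm.get("highpass", False):
            kwargs["highpass_cutoff_s"] = glm.get("highpass_cutoff_s", 48.0)
        if "ancova_covariates" in stats_cfg:
            kwargs["ancova_covariates"] = tuple(stats_cfg["ancova_covariates"])
        if "regression_covariates" in stats_cfg:
            kwargs["regression_covariates"] = tuple(stats_cfg["regression_covariates"])
        return cls(**kwargs)


def demo_config(seed: int = 7) -> dict:
    """A small complete configuration (3 subjects/group, 10x10x6 grid)."""
    return {
        "seed": seed,
        "paradigm": {
            "n_blocks": 7,
            "stim_duration_s": 20.0,
            "rest_duration_s": 28.0,
            "tr_s": 3.0,
            "flicker_hz": 8.0,
        },
        "synthesis": {
            "n_per_group": {"control": 3, "premanifest": 3, "manifest": 3},
            "grid_shape": [10, 10, 6],
            "active_fraction": 0.2,
            "noise_sd": 2.0,
            "drift_amplitude": 0.0,
            "baseline_level": 1000.0,
            "planted": {
                "baseline_pct": 0.0,
                "amplitude_pct": 1.0,
                "t_peak_s": 6.0,
                "t_return_s": 28.0,
            },
        },
        "glm": {"highpass": False},
        "reactivity": {"fraction": 0.2, "threshold": 3.0, "grid_resolution": 0.25},
        "stats": {
            "ancova_covariates": ["age", "gender"],
            # at 3 subjects/group only two covariates leave residual df
            "regression_covariates": ["age", "gender"],
        },
    }


def _active_mask(grid_shape: tuple[int, int, int], fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    n = int(np.prod(grid_shape))
    k = max(1, round(fraction * n))
    idx = rng.choice(n, size=k, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask.reshape(grid_shape)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline and write all outputs + a manifest.

    Stages: per-subject BOLD simulation and reactivity fitting, cohort table
    simulation, compound Z-scores, ANCOVA contrasts per thickness region and
    reactivity metric, and thickness-cognition association regressions. Any
    stage failure is re-raised with stage and subject attribution.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True).encode()
        ).hexdigest(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "warnings": captured,
    }

    ss = np.random.SeedSequence(config.seed)
    subject_seeds, cohort_seed_seq = ss.spawn(2)

    # --- stage 1: cohort table -------------------------------------------
    cohort_seed = int(cohort_seed_seq.generate_state(1)[0] % (2**31))
    n_groups = config.n_per_group
    spec = CohortSpec(seed=cohort_seed)
    spec = CohortSpec(
        groups={
            g: type(gs)(**{**gs.__dict__, "n": n_groups.get(g, gs.n)})
            for g, gs in spec.groups.items()
        },
        seed=cohort_seed,
    )
    try:
        cohort = simulate_cohort(spec)
    except Exception as exc:  # pragma: no cover - attribution plumbing
        raise RuntimeError(f"stage=simulate_cohort failed: {exc}") from exc
    zscores = compound_zscore(cohort, DEFAULT_DOMAINS, DEFAULT_DIRECTIONS)
    cohort = pd.concat([cohort, zscores], axis=1)

    # --- stage 2: per-subject BOLD runs + reactivity fits ----------------
    reports = {}
    subj_rng_seeds = subject_seeds.spawn(len(cohort))
    design = build_design_matrix(
        config.paradigm, config.paradigm.n_samples, config.highpass_cutoff_s
    )
    rows = []
    for (idx, row), sseq in zip(cohort.iterrows(), subj_rng_seeds):
        subject = row["subject"]
        seed_pair = sseq.generate_state(2) % (2**31)
        rng = np.random.default_rng(int(seed_pair[0]))
        truth = SubjectTruth(
            params=config.planted,
            active_voxels=_active_mask(config.grid_shape, config.active_fraction, rng),
            noise_sd=config.noise_sd,
            drift_amplitude=config.drift_amplitude,
            baseline_level=config.baseline_level,
            seed=int(seed_pair[1]),
        )
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                run = simulate_subject_run(config.paradigm, truth, config.grid_shape)
                zmap, _ = fit_glm(run, design)
                report = fit_subject(
                    run,
                    zmap,
                    config.paradigm,
                    fraction=config.roi_fraction,
                    threshold=config.artifact_threshold,
                    grid_resolution=config.grid_resolution,
                )
            for w in wlist:
                captured.append(f"subject={subject}: {w.message}")
        except Exception as exc:
            raise RuntimeError(f"stage=fit_subject subject={subject}: {exc}") from exc
        for di in report.discarded_indices:
            captured.append(f"subject={subject}: discarded block {di}")
        reports[subject] = report.to_dict()
        rows.append(
            {
                "subject": subject,
                "time_to_peak_s": report.fit.time_to_peak,
                "time_to_baseline_s": report.fit.time_to_baseline,
                "amplitude_pct": report.fit.amplitude,
            }
        )
    metrics = pd.DataFrame(rows).set_index("subject")
    cohort = cohort.join(metrics, on="subject")

    # --- stage 3: group statistics ---------------------------------------
    regions = [c for c in cohort.columns if c.startswith("thick_")]
    reactivity_outcomes = ["time_to_peak_s", "time_to_baseline_s", "amplitude_pct"]
    domain_cols = [c for c in cohort.columns if c.startswith("z_")]
    contrasts = {}
    try:
        for outcome in regions + reactivity_outcomes + domain_cols:
            contrasts[outcome] = [
                res.__dict__ for res in ancova_contrast(
                    cohort, outcome, covariates=config.ancova_covariates
                )
            ]
        associations = {}
        for region in regions:
            associations[region] = {
                dom: association_regression(
                    cohort, region, dom, covariates=config.regression_covariates
                ).__dict__
                for dom in domain_cols
            }
    except Exception as exc:
        raise RuntimeError(f"stage=group_stats failed: {exc}") from exc
    m = len(regions) * len(domain_cols)
    stats_bundle = {
        "ancova_contrasts": contrasts,
        "associations": associations,
        "bonferroni_alpha": bonferroni_alpha(0.05, max(m, 1)),
        "n_comparisons": m,
    }

    # --- outputs ----------------------------------------------------------
    cohort_path = out / "cohort.csv"
    atomic_write_text(cohort.to_csv(index=False), cohort_path)
    write_json(reports, out / "fit_reports.json")
    write_json(stats_bundle, out / "group_stats.json")
    manifest["stages"] = {
        "simulate_cohort": {"n_subjects": int(len(cohort))},
        "fit_subject": {"n_reports": len(reports)},
        "group_stats": {"n_outcomes": len(contrasts), "n_comparisons": m},
    }
    manifest["outputs"] = ["cohort.csv", "fit_reports.json", "group_stats.json"]
    write_json(manifest, out / "manifest.json")
    return manifest
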