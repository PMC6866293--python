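"""Vascular reactivity extraction and trapezoid fitting.

The subject-level pipeline:

1. build a functional ROI from the top fraction (default 20%) of the
   subject's Z-statistic activation map;
2. average the BOLD series over the ROI;
3. cut the series into stimulation blocks (stimulus + following rest);
4. express every block in percent BOLD change relative to the grand mean of
   all blocks (computed once, before any rejection);
5. discard blocks whose absolute percent change exceeds 3% (non-physiological
   spikes); the normalization denominator is deliberately NOT recomputed;
6. average the retained blocks and fit the trapezoid model by profiled
   breakpoint search: for each candidate (t_peak, t_return) pair on a grid,
   baseline and amplitude are solved in closed form (linear least squares),
   and the grid optimum is refined by a local continuous search.

The fitted parameters yield time-to-peak (block onset to plateau onset),
time-to-baseline (stimulus offset to baseline return) and amplitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    BlockMatrix,
    BoldSeries,
    StimulusParadigm,
    TrapezoidFit,
    TrapezoidParams,
    Volume4D,
    ZStatMap,
    _trapezoid_shape,
)

__all__ = [
    "RoiMask",
    "FitReport",
    "top_fraction_mask",
    "roi_mean_timeseries",
    "segment_blocks",
    "to_percent_change",
    "reject_artifact_blocks",
    "average_block",
    "fit_trapezoid",
    "extract_metrics",
    "fit_subject",
]


@dataclass(frozen=True)
class RoiMask:
    """Functional ROI: the most task-responsive voxels of one subject."""

    voxels: np.ndarray
    fraction: float
    n_source_voxels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class FitReport:
    """Full diagnostics of one subject's reactivity fit."""

    fit: TrapezoidFit
    n_blocks_total: int
    n_blocks_retained: int
    discarded_indices: tuple[int, ...]
    normalization_mean: float
    roi_n_voxels: int = 0

    def to_dict(self) -> dict:
        return {
            "time_to_peak_s": self.fit.time_to_peak,
            "time_to_baseline_s": self.fit.time_to_baseline,
            "amplitude_pct": self.fit.amplitude,
            "baseline_pct": self.fit.params.baseline,
            "t_peak_s": self.fit.params.t_peak,
            "t_return_s": self.fit.params.t_return,
            "t_fall_start_s": self.fit.params.t_fall_start,
            "sse": self.fit.sse,
            "n_samples": self.fit.n_samples,
            "n_blocks_total": self.n_blocks_total,
            "n_blocks_retained": self.n_blocks_retained,
            "discarded_indices": list(self.discarded_indices),
            "normalization_mean": self.normalization_mean,
            "roi_n_voxels": self.roi_n_voxels,
        }


def top_fraction_mask(zmap: ZStatMap, fraction: float = 0.2) -> RoiMask:
    """Select the ceil(fraction * N) most activated in-mask voxels.

    Ties at the cut are broken by ascending linear voxel index, so the
    selection is deterministic. An all-equal Z map still returns exactly k
    voxels (pure tie-break) with a warning.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    mask = zmap.mask
    n = int(mask.sum())
    if n < 1:
        raise ValueError("no in-mask voxels")
    k = math.ceil(fraction * n)

    flat_idx = np.flatnonzero(mask.ravel())
    z = zmap.values.ravel()[flat_idx]
    if np.ptp(z) == 0:
        warnings.warn(
            "all Z values equal; ROI selection is a pure index tie-break",
            RuntimeWarning,
            stacklevel=2,
        )
    # Sort by descending Z, ties by ascending linear index (stable).
    order = np.lexsort((flat_idx, -z))
    chosen = flat_idx[order[:k]]
    voxels = np.zeros(mask.size, dtype=bool)
    voxels[chosen] = True
    return RoiMask(voxels=voxels.reshape(mask.shape), fraction=fraction, n_source_voxels=n)


def roi_mean_timeseries(run: Volume4D, roi: RoiMask) -> BoldSeries:
    """Unweighted mean BOLD series over the ROI voxels."""
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    if roi.voxels.shape != run.data.shape[:3]:
        raise ValueError("ROI shape does not match run")
    series = run.data[roi.voxels].mean(axis=0)
    return BoldSeries(values=series, tr=run.tr, t0=0.0)


def segment_blocks(series: BoldSeries, paradigm: StimulusParadigm) -> np.ndarray:
    """Reshape a run-length series into an (n_blocks x samples/block) matrix.

    Trailing samples beyond the last full design block are dropped with a
    warning; a series shorter than the design is an error.
    """
    L = paradigm.samples_per_block
    needed = paradigm.n_blocks * L
    n = len(series)
    if n < needed:
        raise ValueError(
            f"series has {n} samples; paradigm needs {needed}"
        )
    if n > needed:
        warnings.warn(
            f"dropping {n - needed} trailing sample(s) beyond the design",
            RuntimeWarning,
            stacklevel=2,
        )
    return series.values[:needed].reshape(paradigm.n_blocks, L).copy()


def to_percent_change(raw_blocks: np.ndarray, tr: float) -> BlockMatrix:
    """Express blocks as percent BOLD change about the grand mean of all blocks.

    Each sample x becomes 100 * (x - m) / m with m the grand mean over every
    block (pre-rejection, recorded as ``normalization_mean``).
    """
    raw_blocks = np.asarray(raw_blocks, dtype=float)
    m = raw_blocks.mean()
    if m <= 0:
        raise ValueError(f"non-positive grand mean ({m}); non-physiological input")
    pct = 100.0 * (raw_blocks - m) / m
    return BlockMatrix(
        blocks=pct,
        tr=tr,
        retained=np.ones(raw_blocks.shape[0], dtype=bool),
        normalization_mean=float(m),
    )


def reject_artifact_blocks(blocks: BlockMatrix, threshold: float = 3.0,
                           statistic: str = "max_abs") -> BlockMatrix:
    """Flag non-physiological blocks for discard.

    A block is discarded iff its percent-change statistic strictly exceeds
    ``threshold`` (a block peaking exactly at the threshold is retained).
    ``statistic`` is ``"max_abs"`` (default spike detector) or ``"mean_abs"``.
    The normalization mean is never recomputed after rejection.
    """
    if statistic == "max_abs":
        stat = np.abs(blocks.blocks).max(axis=1)
    elif statistic == "mean_abs":
        stat = np.abs(blocks.blocks).mean(axis=1)
    else:
        raise ValueError(f"unknown rejection statistic {statistic!r}")
    retained = blocks.retained & ~(stat > threshold)
    if not retained.any():
        raise ValueError(
            "all blocks exceed the artifact threshold; subject is unfittable"
        )
    return BlockMatrix(
        blocks=blocks.blocks,
        tr=blocks.tr,
        retained=retained,
        normalization_mean=blocks.normalization_mean,
    )


def average_block(blocks: BlockMatrix) -> BoldSeries:
    """Sample-wise mean over the retained blocks only."""
    if blocks.n_retained < 1:
        raise ValueError("no retained blocks to average")
    avg = blocks.blocks[blocks.retained].mean(axis=0)
    return BoldSeries(values=avg, tr=blocks.tr, t0=0.0)


# ---------------------------------------------------------------------------
# Trapezoid fitting
# ---------------------------------------------------------------------------

def _profiled_sse(
    y: np.ndarray, t: np.ndarray, t_peak: np.ndarray, t_fall: float, t_return: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (baseline, amplitude) and SSE for breakpoint candidates.

    For each candidate shape s(t; t_peak, t_return), solves
    min_{b,a} ||y - b - a s||^2. Vectorized over candidates.
    """
    n = y.size
    # shapes: (candidate, sample)
    tp = np.atleast_1d(t_peak)[:, None]
    trt = np.atleast_1d(t_return)[:, None]
    tt = t[None, :]
    s = np.zeros((tp.shape[0], n))
    rising = (tt >= 0) & (tt < tp)
    s = np.where(rising, tt / tp, s)
    plateau = (tt >= tp) & (tt <= t_fall)
    s = np.where(plateau, 1.0, s)
    width = trt - t_fall
    falling = (tt > t_fall) & (tt < trt) & (width > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        desc = (trt - tt) / np.where(width > 0, width, 1.0)
    s = np.where(falling, desc, s)

    s1 = s.sum(axis=1)
    s2 = (s * s).sum(axis=1)
    sy = s @ y
    ysum = y.sum()
    denom = n * s2 - s1 * s1
    flat = denom <= 1e-12 * max(n, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(flat, 0.0, (n * sy - s1 * ysum) / np.where(flat, 1.0, denom))
    b = (ysum - a * s1) / n
    resid = y[None, :] - b[:, None] - a[:, None] * s
    sse = np.einsum("ij,ij->i", resid, resid)
    return b, a, sse


def fit_trapezoid(
    avg: BoldSeries,
    paradigm: StimulusParadigm,
    grid_resolution: float = 0.25,
    refine: bool = True,
) -> TrapezoidFit:
    """Least-squares trapezoid fit to the average percent-change block.

    Profiled breakpoint search: t_peak ranges over (0, stim_duration] and
    t_return over [stim_duration, block_length] on a grid of step
    ``grid_resolution``; for each pair, baseline and amplitude have a
    closed-form solution. The grid optimum is optionally refined by a local
    Nelder-Mead search over the breakpoints (still profiling baseline and
    amplitude), constrained to the parameter box; the returned SSE is never
    worse than the best grid point. Ties (e.g. flat input) resolve to the
    smallest grid t_peak, then smallest t_return.
    """
    y = avg.values
    if y.size < 6:
        raise ValueError("need at least 6 samples to fit the trapezoid")
    t = avg.times
    t_fall = paradigm.stim_duration
    block_len = paradigm.block_length

    tp_grid = np.arange(grid_resolution, t_fall + 1e-9, grid_resolution)
    tr_grid = np.arange(t_fall, block_len + 1e-9, grid_resolution)
    TP, TRt = np.meshgrid(tp_grid, tr_grid, indexing="ij")
    b, a, sse = _profiled_sse(y, t, TP.ravel(), t_fall, TRt.ravel())
    best = int(np.argmin(sse))  # argmin takes the first minimum: smallest
    # t_peak then smallest t_return by grid construction
    best_tp, best_tr = TP.ravel()[best], TRt.ravel()[best]
    best_b, best_a, best_sse = b[best], a[best], sse[best]

    if refine:
        # Deterministic hierarchical zoom: around each of the best coarse
        # cells, rescan a local 21x21 grid at geometrically shrinking steps
        # (clipped to the parameter box). Derivative-free and immune to the
        # plateau stalls a simplex search hits at the box boundary.
        for s_idx in np.argsort(sse, kind="stable")[:3]:
            tp0, tr0 = TP.ravel()[s_idx], TRt.ravel()[s_idx]
            step = grid_resolution
            local_best = (sse[s_idx], tp0, tr0, b[s_idx], a[s_idx])
            for _ in range(8):
                offs = step * np.arange(-10, 11) / 10.0
                tp_loc = np.clip(local_best[1] + offs, 1e-6, t_fall)
                tr_loc = np.clip(local_best[2] + offs, t_fall, block_len)
                P, R = np.meshgrid(np.unique(tp_loc), np.unique(tr_loc), indexing="ij")
                bb, aa, ss = _profiled_sse(y, t, P.ravel(), t_fall, R.ravel())
                j = int(np.argmin(ss))
                if ss[j] < local_best[0]:
                    local_best = (ss[j], P.ravel()[j], R.ravel()[j], bb[j], aa[j])
                step /= 8.0
            if local_best[0] < best_sse:
                best_sse, best_tp, best_tr, best_b, best_a = local_best

    # Flat-profile candidates collapse amplitude to 0; report the documented
    # tie-break (smallest grid t_peak, t_return at stimulus offset).
    if best_a == 0.0 and np.allclose(y, y.mean()):
        best_tp, best_tr = tp_grid[0], t_fall
        best_b, best_sse = float(y.mean()), 0.0

    params = TrapezoidParams(
        baseline=float(best_b),
        amplitude=float(best_a),
        t_peak=float(best_tp),
        t_return=float(best_tr),
        t_fall_start=float(t_fall),
    )
    return TrapezoidFit(
        params=params,
        time_to_peak=float(best_tp),
        time_to_baseline=float(best_tr - t_fall),
        amplitude=float(best_a),
        sse=float(best_sse),
        n_samples=int(y.size),
    )


def extract_metrics(fit: TrapezoidFit, paradigm: StimulusParadigm) -> tuple[float, float, float]:
    """(time_to_peak, time_to_baseline, amplitude) from a fitted trapezoid.

    time_to_peak is measured from block onset; time_to_baseline from the end
    of the stimulus (t = stim_duration) to the return to baseline.
    """
    return (
        fit.params.t_peak,
        fit.params.t_return - paradigm.stim_duration,
        fit.params.amplitude,
    )


def fit_subject(
    run: Volume4D,
    zmap: ZStatMap,
    paradigm: StimulusParadigm,
    fraction: float = 0.2,
    threshold: float = 3.0,
    grid_resolution: float = 0.25,
    refine: bool = True,
    rejection_statistic: str = "max_abs",
) -> FitReport:
    """Full subject-level reactivity pipeline from run + Z map to FitReport."""
    roi = top_fraction_mask(zmap, fraction)
    series = roi_mean_timeseries(run, roi)
    raw = segment_blocks(series, paradigm)
    blocks = to_percent_change(raw, paradigm.tr)
    blocks = reject_artifact_blocks(blocks, threshold, rejection_statistic)
    avg = average_block(blocks)
    fit = fit_trapezoid(avg, paradigm, grid_resolution, refine)
    return FitReport(
        fit=fit,
        n_blocks_total=blocks.n_blocks,
        n_blocks_retained=blocks.n_retained,
        discarded_indices=tuple(blocks.discarded_indices),
        normalization_mean=blocks.normalization_mean,
        roi_n_voxels=roi.n_voxels,
    )
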