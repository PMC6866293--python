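"""Cohort-level statistics.

Implements the tabular analyses of the study design:

* compound cognitive Z-scores — each test standardized against the control
  group, timed tests sign-flipped so higher always means better, then
  averaged within a domain;
* ANCOVA group contrasts — outcome regressed on group indicators (control as
  reference) plus covariates; the group coefficient is the covariate-adjusted
  difference vs controls, with a t-based 95% CI and two-sided p;
* thickness-cognition association regressions in gene carriers, reporting the
  unstandardized slope B, its SE, and partial eta squared from Type-III
  (drop-one) sums of squares;
* Bonferroni-style alpha adjustment for a comparison family.

Model fitting is ordinary least squares via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ContrastResult",
    "AssociationResult",
    "compound_zscore",
    "ancova_contrast",
    "association_regression",
    "bonferroni_alpha",
]

GENE_CARRIER_GROUPS = ("premanifest", "manifest")


@dataclass(frozen=True)
class ContrastResult:
    """Covariate-adjusted difference of one group vs the reference."""

    group: str
    reference: str
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    p: float


@dataclass(frozen=True)
class AssociationResult:
    """Slope of outcome on predictor, adjusted for covariates."""

    predictor: str
    B: float
    SE: float
    partial_eta_sq: float
    p: float
    n: int


def compound_zscore(
    table: pd.DataFrame,
    domains: dict[str, list[str]],
    higher_is_better: dict[str, bool] | None = None,
    reference_group: str = "control",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-domain compound Z-scores standardized against the reference group.

    For each test, Z = (x - mean_ref) / sd_ref using the reference (control)
    group's mean and SD. Tests whose raw score grows with impairment (timed
    tests; ``higher_is_better[test] = False``) are sign-flipped so that a
    higher Z is better in every domain. The domain score is the mean of its
    tests' Z-scores. Returns a DataFrame with one ``z_<domain>`` column per
    domain, indexed like ``table``.
    """
    higher_is_better = higher_is_better or {}
    ref = table[table[group_col] == reference_group]
    if ref.empty:
        raise ValueError(f"no rows in reference group {reference_group!r}")
    out = pd.DataFrame(index=table.index)
    for domain, tests in domains.items():
        zs = []
        for test in tests:
            mu = ref[test].mean()
            sd = ref[test].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(
                    f"test {test!r} has zero variance in the reference group"
                )
            z = (table[test] - mu) / sd
            if not higher_is_better.get(test, True):
                z = -z
            zs.append(z)
        out[f"z_{domain}"] = pd.concat(zs, axis=1).mean(axis=1)
    return out


def _design(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in columns])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design: " + ", ".join(["intercept"] + columns))
    return X


def ancova_contrast(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "gender", "education"),
    reference_group: str = "control",
    group_col: str = "group",
) -> list[ContrastResult]:
    """ANCOVA with group as factor and simple contrasts vs the reference.

    Fits OLS of ``outcome`` on non-reference group indicators plus the
    covariates; each indicator's coefficient is the covariate-adjusted group
    difference vs the reference, reported with a 95% CI and two-sided p from
    the t distribution.
    """
    groups = [g for g in table[group_col].unique() if g != reference_group]
    groups.sort()
    if reference_group not in set(table[group_col]):
        raise ValueError(f"reference group {reference_group!r} absent from table")
    work = table.copy()
    indicator_cols = []
    for g in groups:
        col = f"_grp_{g}"
        work[col] = (work[group_col] == g).astype(float)
        indicator_cols.append(col)
    X = _design(work, indicator_cols + list(covariates))
    model = sm.OLS(work[outcome].to_numpy(float), X).fit()
    results = []
    ci = model.conf_int(alpha=0.05)
    for j, g in enumerate(groups, start=1):
        results.append(
            ContrastResult(
                group=g,
                reference=reference_group,
                estimate=float(model.params[j]),
                ci_low=float(ci[j][0]),
                ci_high=float(ci[j][1]),
                se=float(model.bse[j]),
                p=float(model.pvalues[j]),
            )
        )
    return results


def association_regression(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = ("age", "gender", "education", "cag"),
    group_col: str = "group",
    carrier_groups: tuple[str, ...] = GENE_CARRIER_GROUPS,
) -> AssociationResult:
    """Multiple linear regression of outcome on predictor + covariates.

    Restricted to gene-carrier rows. All terms enter in one block; the
    predictor's partial eta squared is SS_predictor / (SS_predictor +
    SS_residual) with SS_predictor the Type-III (drop-one) sum of squares,
    which for a single-df term equals t^2 / (t^2 + df_resid).
    """
    if predictor in covariates:
        raise ValueError("predictor duplicated among covariates")
    carriers = table[table[group_col].isin(carrier_groups)]
    if carriers.empty:
        raise ValueError("no gene-carrier rows in table")
    X = _design(carriers, [predictor] + list(covariates))
    if len(carriers) <= X.shape[1]:
        raise ValueError(
            f"{len(carriers)} gene-carrier rows cannot support "
            f"{X.shape[1]} model terms (no residual degrees of freedom)"
        )
    y = carriers[outcome].to_numpy(float)
    model = sm.OLS(y, X).fit()
    t = float(model.tvalues[1])
    df_resid = float(model.df_resid)
    partial_eta_sq = t * t / (t * t + df_resid)
    return AssociationResult(
        predictor=predictor,
        B=float(model.params[1]),
        SE=float(model.bse[1]),
        partial_eta_sq=float(partial_eta_sq),
        p=float(model.pvalues[1]),
        n=len(carriers),
    )


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise adjusted significance level alpha / m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m
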