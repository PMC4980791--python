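"""Group comparisons, covariate models and meta-analysis.

Bar-plot style group tests (one-way ANOVA or Kruskal-Wallis with midrank
tie correction), Stouffer combination of per-study Z-scores, inverse-
variance fixed-effects pooling of mean differences, and the two covariate
model families used for age-acceleration outcomes: OLS of an acceleration
measure on participant characteristics, and logistic regression of a
binary outcome on acceleration plus covariates. Raw two-sided p-values
throughout; no multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    test: str  # "anova" | "kruskal"
    statistic: float
    p_value: float
    groups: pd.DataFrame  # index = label; columns n, mean, se

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def group_test(values, groups, method: str = "anova") -> GroupComparison:
    """One-way group comparison with per-group mean and standard error."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    chunks = [values[inv == i] for i in range(len(labels))]
    if any(len(c) < 2 for c in chunks):
        raise ValueError("every group needs n >= 2")

    if method == "anova":
        if all(np.ptp(c) == 0 for c in chunks):
            raise ValueError("zero within-group variance; ANOVA undefined")
        stat, p = sps.f_oneway(*chunks)
    elif method == "kruskal":
        stat, p = sps.kruskal(*chunks)  # midrank ties + correction divisor
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(
        {
            "n": [len(c) for c in chunks],
            "mean": [c.mean() for c in chunks],
            "se": [c.std(ddof=1) / np.sqrt(len(c)) for c in chunks],
        },
        index=pd.Index(labels, name="group"),
    )
    return GroupComparison(test=method, statistic=float(stat), p_value=float(p), groups=table)


@dataclass
class MetaResult:
    method: str  # "stouffer" | "fixed_effects"
    estimate: float  # combined Z, or pooled mean difference
    se: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float
    studies: pd.DataFrame

    def forest_table(self) -> str:
        """Plain-text forest-style rendering of the per-study inputs."""
        lines = [f"meta-analysis ({self.method})"]
        for name, row in self.studies.iterrows():
            lines.append("  " + name + ": " + ", ".join(f"{k}={v:.4g}" for k, v in row.items()))
        if self.method == "stouffer":
            lines.append(f"  combined Z = {self.estimate:.4f}, p = {self.p_value:.3g}")
        else:
            lines.append(
                f"  pooled = {self.estimate:.4f} (SE {self.se:.4f}, "
                f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}]), p = {self.p_value:.3g}"
            )
        return "\n".join(lines)


def stouffer_meta(z_scores, weights=None, study_names=None) -> MetaResult:
    """Stouffer combination: Z = sum(w_i Z_i) / sqrt(sum(w_i^2)).

    Default weights are sqrt(n_i) when sample sizes are supplied as
    weights; pass ``weights=None`` for equal weights.
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("no studies")
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    z_meta = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p = float(2.0 * sps.norm.sf(abs(z_meta)))
    studies = pd.DataFrame(
        {"z": z, "weight": w},
        index=pd.Index(study_names if study_names is not None else
                       [f"study{i+1}" for i in range(z.size)], name="study"),
    )
    return MetaResult("stouffer", z_meta, None, None, None, p, studies)


def fixed_effects_meta(diffs, ses, study_names=None) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-study mean differences."""
    d = np.asarray(diffs, dtype=float)
    se = np.asarray(ses, dtype=float)
    if d.size == 0:
        raise ValueError("no studies")
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    w = 1.0 / se**2
    pooled = float(np.sum(w * d) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    ci = (pooled - 1.96 * pooled_se, pooled + 1.96 * pooled_se)
    p = float(2.0 * sps.norm.sf(abs(pooled / pooled_se)))
    studies = pd.DataFrame(
        {"diff": d, "se": se, "weight": w},
        index=pd.Index(study_names if study_names is not None else
                       [f"study{i+1}" for i in range(d.size)], name="study"),
    )
    return MetaResult("fixed_effects", pooled, pooled_se, ci[0], ci[1], p, studies)


def group_mean_diff_z(values, groups, order: tuple[str, str]) -> tuple[float, float, float]:
    """Two-group mean difference (order[1] - order[0]), its SE, and Welch Z.

    The fixed group ordering defines the sign convention for study Z-scores
    entering a Stouffer combination.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == order[0]]
    b = values[groups == order[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    diff = b.mean() - a.mean()
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    return float(diff), se, float(diff / se)


def _expand_covariates(
    covariates: pd.DataFrame, reference_levels: dict | None = None
) -> pd.DataFrame:
    """Dummy-code categoricals; the reference level is the first sorted
    level unless overridden via ``reference_levels`` (column -> level)."""
    reference_levels = reference_levels or {}
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            ref = reference_levels.get(name, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {name!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _drop_degenerate(X: pd.DataFrame) -> pd.DataFrame:
    keep = []
    for c in X.columns:
        v = X[c].to_numpy()
        if np.ptp(v) == 0:
            logger.warning("dropping constant covariate %r", c)
            continue
        sub = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), sub])) < len(keep) + 2:
            logger.warning("dropping exactly collinear covariate %r", c)
            continue
        keep.append(c)
    return X[keep]


def fit_accel_covariate_model(
    accel, covariates: pd.DataFrame, reference_levels: dict | None = None
) -> pd.DataFrame:
    """OLS of an acceleration measure on participant characteristics.

    Categorical covariates are expanded against their first sorted level
    unless ``reference_levels`` names another (the convention is visible in
    the term names: a level that appears as ``col[level]`` is a contrast
    against the reference). Returns the coefficient table with the model
    R-squared attached as ``.attrs['r_squared']``.
    """
    y = np.asarray(accel, dtype=float)
    X = _drop_degenerate(_expand_covariates(covariates, reference_levels))
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few samples for the covariate model")
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    table = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    table.attrs["r_squared"] = float(fit.rsquared)
    return table


def fit_outcome_model(outcome, accel, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Logistic regression of a binary outcome on acceleration (+ covariates).

    Returns estimates, SEs, Wald Z and p per term. Complete separation is
    detected and raised as an error.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame({"accel": np.asarray(accel, dtype=float)})
    if covariates is not None:
        X = pd.concat([X, _expand_covariates(covariates).reset_index(drop=True)], axis=1)
    X = sm.add_constant(_drop_degenerate(X), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as err:  # statsmodels raises PerfectSeparationError
        raise ValueError(f"logistic fit failed (separation?): {err}") from err
    if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e4):
        raise ValueError("complete separation detected: unbounded estimates")
    return pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "z": fit.tvalues, "p": fit.pvalues}
    )
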