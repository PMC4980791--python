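"""Intrinsic and extrinsic epigenetic age acceleration.

IEAA (intrinsic) is the residual of DNAm age regressed on chronological
age together with seven blood immune-cell abundances (naive CD8+ T,
exhausted CD8+ T, plasmablasts, CD4+ T, NK, monocytes, granulocytes), so
it is orthogonal to blood composition by construction.

EEAA (extrinsic) is built in two steps. First, a Klemera-Doubal composite
biological age is formed from a blood-trained DNAm age plus three
composition markers that change with age (naive CD8+ T, exhausted CD8+ T,
plasmablasts): each marker ``x_j`` is regressed on age (``x_j = q_j +
k_j * age``, residual SD ``s_j``) and the composite is the precision-
weighted average of the per-marker inverse estimates,

    BA = [ sum_j (x_j - q_j) k_j / s_j^2 ] / [ sum_j k_j^2 / s_j^2 ].

Second, EEAA is the residual of BA on age. Both residual measures have
mean zero and zero correlation with age on their fitting cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

IEAA_CELL_COVARIATES = ("naiveCD8T", "exhCD8T", "plasmablast", "CD4T", "NK", "mono", "gran")
EEAA_MARKERS = ("blood_dnam_age", "naiveCD8T", "exhCD8T", "plasmablast")


def _ols_residuals(y: np.ndarray, X: pd.DataFrame):
    """OLS with intercept; constant columns are dropped with a warning,
    exact collinearity is handled by the pseudo-inverse."""
    keep = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) > 0]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        logger.warning("dropping constant regressors: %s", dropped)
    design = sm.add_constant(X[keep].astype(float), has_constant="add")
    fit = sm.OLS(y, design).fit()
    return fit, design


def compute_ieaa(
    dnam_age: pd.Series, age, cells: pd.DataFrame, covariates=IEAA_CELL_COVARIATES
) -> tuple[pd.Series, pd.DataFrame]:
    """IEAA: residual of DNAm age on age + blood cell abundances.

    ``cells`` must contain one column per requested covariate (advanced
    subset scores and/or broad NNLS coefficients). Returns the residual
    vector and the fitted coefficient table.
    """
    cells = cells.loc[dnam_age.index]
    missing = [c for c in covariates if c not in cells.columns]
    if missing:
        raise KeyError(f"cell covariates missing from table: {missing}")
    X = cells[list(covariates)].copy()
    X.insert(0, "age", np.asarray(age, dtype=float))
    if len(dnam_age) <= X.shape[1] + 2:
        raise ValueError("too few samples for the IEAA regression")
    fit, design = _ols_residuals(dnam_age.to_numpy(dtype=float), X)
    table = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    return pd.Series(fit.resid, index=dnam_age.index, name="ieaa"), table


@dataclass
class KDModel:
    """Klemera-Doubal calibration: per-marker slope, intercept, residual SD."""

    params: pd.DataFrame  # index = marker, columns = k, q, s
    excluded: list[str]
    meta: dict

    def save(self, path) -> None:
        out = self.params.copy()
        out.index.name = "marker"
        out.to_csv(path, sep="\t")

    @classmethod
    def load(cls, path) -> "KDModel":
        return cls(pd.read_csv(path, sep="\t", index_col="marker"), excluded=[], meta={})


def fit_kd_model(
    markers: pd.DataFrame, age, t_threshold: float = 2.0, s_floor_rel: float = 1e-6
) -> KDModel:
    """Calibrate each marker against age by simple OLS.

    Markers whose age slope is not distinguishable from zero (|t| below
    ``t_threshold``) are excluded with a warning: a marker that does not
    move with age carries no biological-age information and its near-zero
    slope would only add noise. The residual SD is floored at
    ``s_floor_rel * |k|`` so an exactly age-determined marker does not get
    infinite weight.
    """
    age = np.asarray(age, dtype=float)
    if len(markers) < 20:
        raise ValueError("need >= 20 samples to calibrate markers")
    if np.ptp(age) == 0:
        raise ValueError("age is constant")

    rows, excluded = {}, []
    X = sm.add_constant(age)
    for name in markers.columns:
        y = markers[name].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"marker {name!r} is constant")
        fit = sm.OLS(y, X).fit()
        q, k = fit.params
        t = fit.tvalues[1]
        if abs(t) < t_threshold:
            logger.warning("excluding marker %r: age slope t=%.2f", name, t)
            excluded.append(name)
            continue
        s = float(np.sqrt(fit.ssr / (len(y) - 2)))
        s = max(s, s_floor_rel * abs(k))
        rows[name] = {"k": float(k), "q": float(q), "s": s}
    if not rows:
        raise ValueError("no marker passed the age-slope screen")
    return KDModel(
        params=pd.DataFrame.from_dict(rows, orient="index")[["k", "q", "s"]],
        excluded=excluded,
        meta={"n": len(markers), "t_threshold": t_threshold},
    )


def kd_composite_age(model: KDModel, markers: pd.DataFrame) -> pd.Series:
    """Precision-weighted composite biological age (years)."""
    names = model.params.index
    missing = names.difference(markers.columns)
    if len(missing) > 0:
        raise ValueError(f"markers missing from data: {list(missing)}")
    if len(names) == 0:
        raise ValueError("empty marker set")
    k = model.params["k"].to_numpy()
    q = model.params["q"].to_numpy()
    s = model.params["s"].to_numpy()
    X = markers[list(names)].to_numpy(dtype=float)
    num = (X - q) @ (k / s**2)
    den = float(np.sum(k**2 / s**2))
    return pd.Series(num / den, index=markers.index, name="kd_age")


def compute_eeaa(composite: pd.Series, age) -> pd.Series:
    """EEAA: residual of the composite biological age on chronological age."""
    age = np.asarray(age, dtype=float)
    if len(composite) < 10:
        raise ValueError("need >= 10 samples")
    if np.ptp(age) == 0:
        raise ValueError("age is constant")
    fit = sm.OLS(composite.to_numpy(dtype=float), sm.add_constant(age)).fit()
    return pd.Series(fit.resid, index=composite.index, name="eeaa")


@dataclass
class AccelResult:
    """Bundle of the three acceleration measures and their auxiliary fits."""

    age_accel: pd.Series
    ieaa: pd.Series
    eeaa: pd.Series
    ieaa_table: pd.DataFrame
    kd_model: KDModel

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_accel": self.age_accel, "ieaa": self.ieaa, "eeaa": self.eeaa}
        )


def compute_acceleration(
    dnam_age: pd.Series,
    blood_dnam_age: pd.Series,
    age,
    cells: pd.DataFrame,
    annotation: pd.DataFrame,
    reference_group: str,
    spline_df: int = 4,
) -> AccelResult:
    """All three acceleration measures for one cohort.

    ``cells`` must carry the IEAA covariates and the three EEAA cell
    markers; ``blood_dnam_age`` is the composition-sensitive blood clock's
    prediction used as the fourth EEAA marker.
    """
    from .clock import universal_age_accel

    age = pd.Series(np.asarray(age, dtype=float), index=dnam_age.index)
    age_accel, _ = universal_age_accel(dnam_age, age, annotation, reference_group, df=spline_df)
    ieaa, table = compute_ieaa(dnam_age, age, cells)

    markers = cells[["naiveCD8T", "exhCD8T", "plasmablast"]].copy()
    markers.insert(0, "blood_dnam_age", blood_dnam_age)
    kd = fit_kd_model(markers, age)
    eeaa = compute_eeaa(kd_composite_age(kd, markers), age)
    return AccelResult(age_accel=age_accel, ieaa=ieaa, eeaa=eeaa, ieaa_table=table, kd_model=kd)
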