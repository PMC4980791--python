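"""Penalized-regression DNA-methylation age and the universal AgeAccel residual.

A clock is an elastic-net regression of a calibrated age transform
``F(age)`` on CpG beta values. ``F`` is logarithmic below an adult-age
knot ``A`` (default 20 years) and linear above it:

    F(age) = log(age + 1) - log(A + 1)   for age <= A
    F(age) = (age - A) / (A + 1)         for age >  A

Predicted transformed values are mapped back through the exact inverse to
give DNAm age in years. The *universal* age-acceleration measure is the
residual of DNAm age around a natural-cubic-spline regression of DNAm age
on chronological age fitted in a designated reference group, so the
reference group has mean acceleration zero by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

DEFAULT_ADULT_AGE = 20.0


def transform_age(age, adult_age: float = DEFAULT_ADULT_AGE):
    """Calibrated age transform ``F``: log below ``adult_age``, linear above.

    Continuous and strictly increasing on (-1, inf); ``F(adult_age) = 0``.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1):
        raise ValueError("age must be > -1")
    out = np.where(
        a <= adult_age,
        np.log1p(a) - np.log1p(adult_age),
        (a - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def inverse_transform_age(t, adult_age: float = DEFAULT_ADULT_AGE):
    """Exact inverse of :func:`transform_age`."""
    x = np.asarray(t, dtype=float)
    out = np.where(
        x <= 0,
        np.expm1(x + np.log1p(adult_age)),
        adult_age + x * (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


@dataclass
class ClockModel:
    """Trained DNAm-age predictor.

    ``coefficients`` spans the full training probe universe (zeros where
    the elastic net dropped a probe); ``clock_probes`` are the probes with
    nonzero weight — the analogue of a published clock's CpG list.
    ``training_means`` (per-probe training beta means) double as the
    constant-imputation values and the gold-standard profile for sample
    normalization.
    """

    coefficients: pd.Series
    intercept: float
    adult_age: float
    training_means: pd.Series
    seed: int = 0
    penalty: dict = field(default_factory=dict)

    @property
    def clock_probes(self) -> pd.Index:
        return self.coefficients.index[self.coefficients != 0.0]

    def save(self, coef_path, header_path) -> None:
        df = pd.DataFrame(
            {"coefficient": self.coefficients, "training_mean": self.training_means}
        )
        df.index.name = "probe_id"
        df.to_csv(coef_path, sep="\t")
        pd.Series(
            {"intercept": self.intercept, "adult_age": self.adult_age, "seed": self.seed}
        ).to_csv(header_path, sep="\t", header=False)

    @classmethod
    def load(cls, coef_path, header_path) -> "ClockModel":
        df = pd.read_csv(coef_path, sep="\t", index_col="probe_id")
        hdr = pd.read_csv(header_path, sep="\t", header=None, index_col=0).iloc[:, 0]
        return cls(
            coefficients=df["coefficient"],
            intercept=float(hdr["intercept"]),
            adult_age=float(hdr["adult_age"]),
            training_means=df["training_mean"],
            seed=int(hdr["seed"]),
        )


def train_clock(
    train: pd.DataFrame,
    ages,
    l1_ratio: float = 0.5,
    n_folds: int = 10,
    adult_age: float = DEFAULT_ADULT_AGE,
    seed: int = 0,
) -> ClockModel:
    """Fit an elastic-net clock: F(age) on betas, penalty by cross-validation.

    Parameters
    ----------
    train
        probe-by-sample beta matrix.
    ages
        chronological ages (years), aligned with the columns of ``train``.
    """
    ages = np.asarray(ages, dtype=float)
    if train.shape[1] != len(ages):
        raise ValueError("ages must align with the sample columns of train")
    if train.shape[1] < 50:
        raise ValueError("need at least 50 training samples")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; the clock is unidentifiable")
    if train.shape[1] < n_folds:
        raise ValueError("fewer samples than cross-validation folds")

    y = transform_age(ages, adult_age)
    X = train.to_numpy().T
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, alphas=60, eps=1e-2, tol=1e-3, max_iter=10_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny alphas
        model.fit(X, y)

    return ClockModel(
        coefficients=pd.Series(model.coef_, index=train.index, name="coefficient"),
        intercept=float(model.intercept_),
        adult_age=adult_age,
        training_means=train.mean(axis=1).rename("training_mean"),
        seed=seed,
        penalty={"l1_ratio": l1_ratio, "alpha": float(model.alpha_), "n_folds": n_folds},
    )


def predict_dnam_age(model: ClockModel, data: pd.DataFrame) -> pd.Series:
    """DNAm age (years) = inverse-F(intercept + sum of weighted clock betas)."""
    probes = model.clock_probes
    missing = probes.difference(data.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} clock probes absent from data (e.g. {missing[0]}); "
            "impute them first (impute_missing_clock_probes)"
        )
    sub = data.loc[probes]
    if sub.isna().any().any():
        raise ValueError("clock probes contain missing values; impute them first")
    lin = model.intercept + sub.to_numpy().T @ model.coefficients.loc[probes].to_numpy()
    return pd.Series(
        inverse_transform_age(lin, model.adult_age), index=data.columns, name="dnam_age"
    )


def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots), no intercept.

    Standard truncated-power construction with the natural constraints; with
    K knots it yields K-1 columns (the linear term plus K-2 curvature terms).
    """
    x = np.asarray(x, dtype=float)
    K = len(knots)

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


@dataclass
class SplineFit:
    """Reference-group regression of DNAm age on age (spline or linear)."""

    knots: np.ndarray | None
    coef: np.ndarray
    reference_group: str
    df: int

    def predict(self, age) -> np.ndarray:
        x = np.asarray(age, dtype=float)
        if self.knots is None:
            X = np.column_stack([np.ones_like(x), x])
        else:
            X = np.column_stack([np.ones_like(x), _natural_cubic_basis(x, self.knots)])
        return X @ self.coef


def universal_age_accel(
    dnam_age: pd.Series,
    age,
    annotation: pd.DataFrame,
    reference_group: str,
    df: int = 4,
    min_spline_n: int = 30,
) -> tuple[pd.Series, SplineFit]:
    """Universal age acceleration: residual to the reference-group spline.

    Fits a natural cubic spline (``df`` basis functions; simple linear fit
    when the reference group has fewer than ``min_spline_n`` samples) of
    DNAm age on chronological age using reference-group samples only, and
    returns each sample's vertical distance from that curve. The reference
    group's mean acceleration is zero by least-squares construction.
    """
    age = pd.Series(np.asarray(age, dtype=float), index=dnam_age.index)
    if reference_group not in set(annotation["group"]):
        raise ValueError(f"reference group {reference_group!r} absent from annotation")
    ref = annotation.index[annotation["group"] == reference_group]
    ref = ref.intersection(dnam_age.index)
    if len(ref) < 10:
        raise ValueError("need >= 10 reference-group samples")

    xr, yr = age.loc[ref].to_numpy(), dnam_age.loc[ref].to_numpy()
    if len(ref) < min_spline_n or np.unique(xr).size <= df + 1:
        X = np.column_stack([np.ones_like(xr), xr])
        fit = SplineFit(None, np.linalg.lstsq(X, yr, rcond=None)[0], reference_group, 1)
    else:
        # K = df + 1 knots: boundary at the reference age range, interior at
        # equally spaced quantiles.
        qs = np.linspace(0, 1, df + 1)
        knots = np.unique(np.quantile(xr, qs))
        X = np.column_stack([np.ones_like(xr), _natural_cubic_basis(xr, knots)])
        fit = SplineFit(knots, np.linalg.lstsq(X, yr, rcond=None)[0], reference_group, df)

    accel = dnam_age - fit.predict(age.to_numpy())
    return accel.rename("age_accel"), fit
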