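"""Reference-based blood-cell deconvolution and learned subset estimators.

Broad leukocyte abundances are estimated per sample by non-negative least
squares: the sample's methylation profile over signature probes is
projected onto purified cell-type reference profiles, minimizing
``||x - R w||^2`` subject to ``w >= 0``. No sum-to-one constraint is
imposed; raw coefficients are kept as interpretable cell "counts" and a
sum-normalized version is reported alongside.

Abundances of specialized subsets (naive CD8+ T, exhausted CD8+ T,
plasmablasts, naive CD4+ T) are produced by penalized linear predictors
trained on cohorts with known subset abundances — a functional stand-in
for the advanced estimators shipped with epigenetic-clock software, whose
coefficients are not public.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

#: collapse map from fine simulation cell types to the six broad types the
#: reference-based method reports
BROAD_MAP = {
    "naiveCD8T": "CD8T",
    "exhCD8T": "CD8T",
    "CD4T": "CD4T",
    "NK": "NK",
    "B": "B",
    "plasmablast": "B",
    "mono": "mono",
    "gran": "gran",
}
BROAD_TYPES = ("CD8T", "CD4T", "NK", "B", "mono", "gran")


@dataclass
class CellCounts:
    """Per-sample deconvolution output.

    ``raw`` holds the unnormalized NNLS coefficients per reference cell
    type; ``proportions`` the sum-normalized simplex version; ``broad`` the
    raw coefficients collapsed to the six broad types; ``advanced`` the
    learned subset scores (may be absent until estimators are applied).
    """

    raw: pd.DataFrame
    proportions: pd.DataFrame
    broad: pd.DataFrame
    advanced: pd.DataFrame | None = None


def estimate_cell_proportions(data: pd.DataFrame, ref: pd.DataFrame) -> CellCounts:
    """Houseman-style constrained projection onto a cell-type reference.

    ``ref`` is a signature-probe-by-cell-type matrix of pure beta levels.
    Only probes shared between ``data`` and ``ref`` are used; the solve is
    deterministic. A rank-deficient reference on the shared probes is
    reported but a (non-unique) solution is still returned.
    """
    shared = data.index.intersection(ref.index)
    if len(shared) < ref.shape[1]:
        raise ValueError(
            f"{len(shared)} shared signature probes for {ref.shape[1]} cell types"
        )
    R = ref.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < ref.shape[1]:
        logger.warning("reference matrix is rank-deficient on shared probes")
    X = data.loc[shared].to_numpy(dtype=float)

    W = np.empty((data.shape[1], ref.shape[1]))
    for j in range(data.shape[1]):
        W[j], _ = nnls(R, X[:, j])

    raw = pd.DataFrame(W, index=data.columns, columns=ref.columns)
    totals = raw.sum(axis=1)
    props = raw.div(totals.where(totals > 0, 1.0), axis=0)
    broad = raw.T.groupby([BROAD_MAP.get(c, c) for c in raw.columns]).sum().T
    broad = broad.reindex(columns=[b for b in BROAD_TYPES if b in broad.columns])
    return CellCounts(raw=raw, proportions=props, broad=broad)


@dataclass
class SubsetModel:
    """Penalized linear predictor of one cell subset's abundance from betas."""

    subset: str
    coefficients: pd.Series
    intercept: float
    seed: int = 0
    penalty: dict = field(default_factory=dict)

    def predict(self, data: pd.DataFrame) -> pd.Series:
        probes = self.coefficients.index
        missing = probes.difference(data.index)
        if len(missing) > 0:
            raise ValueError(f"{len(missing)} model probes absent from data")
        vals = self.intercept + data.loc[probes].to_numpy().T @ self.coefficients.to_numpy()
        return pd.Series(vals, index=data.columns, name=self.subset)

    def save(self, path) -> None:
        out = self.coefficients.rename("coefficient").to_frame()
        out.index.name = "probe_id"
        out.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# subset={self.subset}\tintercept={self.intercept!r}"
                     f"\tseed={self.seed}\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def load(cls, path) -> "SubsetModel":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
            meta = dict(kv.split("=", 1) for kv in header.split("\t"))
            coef = pd.read_csv(fh, sep="\t", index_col="probe_id")["coefficient"]
        return cls(subset=meta["subset"], coefficients=coef,
                   intercept=float(meta["intercept"]), seed=int(meta["seed"]))


def train_subset_estimator(
    train: pd.DataFrame,
    truth_values,
    subset: str = "subset",
    l1_ratio: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
) -> SubsetModel:
    """Fit an elastic-net predictor of a subset abundance from beta values."""
    y = np.asarray(truth_values, dtype=float)
    if train.shape[1] != len(y):
        raise ValueError("truth values must align with the sample columns of train")
    if train.shape[1] < 50:
        raise ValueError("need at least 50 training samples")
    if np.ptp(y) == 0:
        raise ValueError("truth values are constant; nothing to learn")

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, alphas=60, eps=1e-2, tol=1e-3, max_iter=10_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(train.to_numpy().T, y)
    keep = model.coef_ != 0.0
    return SubsetModel(
        subset=subset,
        coefficients=pd.Series(model.coef_[keep], index=train.index[keep]),
        intercept=float(model.intercept_),
        seed=seed,
        penalty={"l1_ratio": l1_ratio, "alpha": float(model.alpha_)},
    )


def estimate_advanced_subsets(
    models: dict[str, SubsetModel], data: pd.DataFrame, subsets=None
) -> pd.DataFrame:
    """Apply trained subset estimators; one score column per subset."""
    subsets = list(subsets) if subsets is not None else list(models)
    missing = [s for s in subsets if s not in models]
    if missing:
        raise KeyError(f"no trained model for subsets: {missing}")
    return pd.DataFrame({s: models[s].predict(data) for s in subsets})
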