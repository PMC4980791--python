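"""Beta-value computation, gold-standard calibration, probe filters, imputation.

Matrices are pandas DataFrames, probes in rows and samples in columns.
Missing values are NaN. Beta values derive from methylated (M) and
unmethylated (U) fluorescence intensities as

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + offset),    offset = 100,

so beta lies in [0, 1) and zero/negative signal maps to 0. Before clock
prediction each sample can be calibrated to a stored gold-standard beta
distribution (the clock's training-mean profile) by a monotone quantile
map, standing in for reference-anchored normalization of array data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def compute_beta(M: pd.DataFrame, U: pd.DataFrame, offset: float = 100.0) -> pd.DataFrame:
    """Beta values from methylated/unmethylated intensities (clamped at 0)."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if isinstance(M, pd.DataFrame) and isinstance(U, pd.DataFrame):
        if M.shape != U.shape or not M.index.equals(U.index) or not M.columns.equals(U.columns):
            raise ValueError("M and U must share probe and sample index sets")
    m = np.maximum(np.asarray(M, dtype=float), 0.0)
    u = np.maximum(np.asarray(U, dtype=float), 0.0)
    beta = m / (m + u + offset)
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(beta, index=M.index, columns=M.columns)
    return beta


def normalize_to_gold_standard(data: pd.DataFrame, gold: pd.Series) -> pd.DataFrame:
    """Calibrate every sample's beta distribution to a gold-standard profile.

    For each sample, a monotone piecewise-linear transfer function is built
    from the sample's empirical distribution over the probes shared with
    ``gold`` onto the gold distribution (sorted sample values -> sorted gold
    values) and then applied to all of the sample's probes. The map is the
    identity for a sample already distributed like the gold standard, and
    the operation is idempotent.
    """
    shared = data.index.intersection(gold.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} probes shared with the gold standard (need >= 10)")
    gold_sorted = np.sort(gold.loc[shared].to_numpy(dtype=float))

    out = np.empty(data.shape)
    values = data.to_numpy(dtype=float)
    shared_pos = data.index.get_indexer(shared)
    for j in range(data.shape[1]):
        col = values[:, j]
        x_knots = np.sort(col[shared_pos])
        # np.interp requires increasing x; ties collapse to the same knot,
        # keeping the transfer monotone (non-decreasing).
        out[:, j] = np.interp(col, x_knots, gold_sorted)
    out = np.clip(out, 0.0, 1.0)
    out[np.isnan(values)] = np.nan
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def drop_probes(data: pd.DataFrame, blacklist) -> pd.DataFrame:
    """Remove blacklisted probes (e.g. SNP-adjacent CpGs); order preserved."""
    blacklist = pd.Index(blacklist)
    absent = blacklist.difference(data.index)
    if len(absent) > 0:
        logger.warning("%d blacklisted probes not present in the matrix", len(absent))
    return data.loc[~data.index.isin(blacklist)]


def impute_missing_clock_probes(data: pd.DataFrame, model) -> pd.DataFrame:
    """Fill absent/missing clock probes with the clock's training means.

    Every clock probe that is absent from ``data`` (or NaN for some sample)
    is set, for the affected samples, to the constant mean beta observed in
    the clock's training set. Present values are untouched.
    """
    if model.training_means is None or len(model.training_means) == 0:
        raise ValueError("clock model lacks training means")
    probes = model.clock_probes
    out = data.reindex(data.index.union(probes.difference(data.index), sort=False))
    means = model.training_means.reindex(probes)
    if means.isna().any():
        raise ValueError("clock model lacks training means for some clock probes")
    block = out.loc[probes]
    out.loc[probes] = block.where(block.notna(), means, axis=0)
    return out


def read_blacklist(path) -> pd.Index:
    """Probe blacklist file: one probe ID per line, '#' comments allowed."""
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return pd.Index(ids)
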