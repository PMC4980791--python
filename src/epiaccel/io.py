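"""TSV readers/writers for the pipeline's tabular interchange formats.

Everything is tab-delimited UTF-8 with a header row. Beta matrices have
probe IDs in the first column and one column per sample; sample sheets
are keyed by ``sample_id``; reference matrices by ``probe_id`` with one
column per cell type. Missing beta values are written as ``NA``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    out = beta.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_beta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["NA"])


def write_sample_sheet(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])


def write_reference_tsv(ref: pd.DataFrame, path) -> None:
    out = ref.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_reference_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def file_digest(path) -> str:
    """SHA-256 content digest, for run-report provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def digest_tree(paths) -> dict[str, str]:
    return {str(Path(p)): file_digest(p) for p in paths}
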