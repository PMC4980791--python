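"""Deconvolve blood composition and predict DNAm age on the analysis cohort.

Applies the NNLS reference projection, the trained subset estimators and
both clocks; reports accuracy against the simulation truth and writes the
per-sample estimates under results/analysis/results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from epiaccel import ClockModel, estimate_cell_proportions, predict_dnam_age
from epiaccel import io as eio
from epiaccel.deconvolution import SubsetModel, estimate_advanced_subsets
from epiaccel.experiments import ADVANCED_SUBSETS

DATA = Path("scratch/analysis/data")
MODELS = Path("results/analysis/models")
OUT = Path("results/analysis/results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    beta = eio.read_beta_tsv(DATA / "cohort_beta.tsv")
    ann = eio.read_sample_sheet(DATA / "cohort_samples.tsv")
    ref = eio.read_reference_tsv(DATA / "reference.tsv")
    cell_truth = eio.read_sample_sheet(DATA / "cohort_cell_truth.tsv")

    counts = estimate_cell_proportions(beta, ref)
    models = {s: SubsetModel.load(MODELS / f"subset_{s}.tsv") for s in ADVANCED_SUBSETS}
    counts.advanced = estimate_advanced_subsets(models, beta)
    print("deconvolution accuracy (r vs truth):")
    for c in ("naiveCD8T", "exhCD8T", "CD4T", "gran"):
        est = counts.advanced[c] if c in counts.advanced.columns else counts.proportions[c]
        truth_col = cell_truth[c]
        print(f"  {c}: r = {np.corrcoef(est, truth_col)[0, 1]:.3f}")

    clock = ClockModel.load(MODELS / "clock.tsv", MODELS / "clock_header.tsv")
    blood = ClockModel.load(MODELS / "blood_clock.tsv", MODELS / "blood_clock_header.tsv")
    dnam = predict_dnam_age(clock, beta)
    blood_age = predict_dnam_age(blood, beta)
    print(f"intrinsic clock: r(DNAm age, age) = {np.corrcoef(dnam, ann['age'])[0,1]:.3f}, "
          f"median |error| = {np.median(np.abs(dnam - ann['age'])):.2f} yr")
    print(f"blood clock:     r(DNAm age, age) = {np.corrcoef(blood_age, ann['age'])[0,1]:.3f}")

    cells_out = pd.concat([counts.broad, counts.advanced], axis=1)
    eio.write_sample_sheet(cells_out, OUT / "cell_counts.tsv")
    sheet = ann.copy()
    sheet["dnam_age"] = dnam
    sheet["blood_dnam_age"] = blood_age
    eio.write_sample_sheet(sheet, OUT / "samples_predicted.tsv")
    print(f"wrote {OUT/'cell_counts.tsv'} and {OUT/'samples_predicted.tsv'}")


if __name__ == "__main__":
    main()
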