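"""Train the two epigenetic clocks and the cell-subset estimators.

The intrinsic clock sees one half of the cell-shared probes (plus the
inert probes); the blood clock sees the other half plus the composition
signature panel, so it partially tracks cell composition. Subset
estimators are calibrated on the composition-diverse panel restricted to
signature probes. Models are written under results/analysis/models/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from epiaccel import io as eio
from epiaccel import train_clock, train_subset_estimator
from epiaccel.experiments import ADVANCED_SUBSETS, child_seeds

DATA = Path("scratch/analysis/data")
OUT = Path("results/analysis/models")
FIT_SEED = child_seeds(20260930, 5)[4]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    beta = eio.read_beta_tsv(DATA / "train_beta.tsv")
    ann = eio.read_sample_sheet(DATA / "train_samples.tsv")
    probes = pd.read_csv(DATA / "probes.tsv", sep="\t", index_col="probe_id")
    adv_truth = eio.read_sample_sheet(DATA / "train_advanced_truth.tsv")

    sig = probes.index[probes["class"] == "signature"]
    clockp = probes.index[probes["class"] == "clock"]
    noise = probes.index[probes["class"] == "noise"]
    perm = np.random.default_rng(FIT_SEED).permutation(len(clockp))
    half_a = clockp[np.sort(perm[: len(clockp) // 2])]
    half_b = clockp[np.sort(perm[len(clockp) // 2:])]

    clock = train_clock(beta.loc[half_a.union(noise, sort=False)], ann["age"],
                        seed=FIT_SEED)
    blood = train_clock(beta.loc[half_b.union(sig, sort=False)], ann["age"],
                        seed=FIT_SEED)
    clock.save(OUT / "clock.tsv", OUT / "clock_header.tsv")
    blood.save(OUT / "blood_clock.tsv", OUT / "blood_clock_header.tsv")
    print(f"intrinsic clock: {len(clock.clock_probes)} CpGs "
          f"(alpha={clock.penalty['alpha']:.2e})")
    print(f"blood clock:     {len(blood.clock_probes)} CpGs, "
          f"{len(blood.clock_probes.intersection(sig))} from the signature panel")

    panel_beta = eio.read_beta_tsv(DATA / "panel_beta.tsv")
    panel_truth = eio.read_sample_sheet(DATA / "panel_advanced_truth.tsv")
    for s in ADVANCED_SUBSETS:
        model = train_subset_estimator(panel_beta.loc[sig], panel_truth[s],
                                       subset=s, seed=FIT_SEED)
        model.save(OUT / f"subset_{s}.tsv")
        print(f"subset estimator {s}: {len(model.coefficients)} probes")


if __name__ == "__main__":
    main()
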