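"""Simulate the study cohorts: a broad-age training cohort, a
composition-diverse calibration panel, and a 3-group, 2-dataset analysis
cohort (one group with an intrinsic +2-year offset, one with an extrinsic
naive-CD8 deficit), all sharing one probe universe.

Writes beta matrices, sample sheets, truth tables and the cell-type
reference under results/analysis/data/.
"""

import json
from dataclasses import replace
from pathlib import Path

from epiaccel import GroupSpec, SimConfig, make_reference_matrix, simulate_cohort
from epiaccel import io as eio
from epiaccel.experiments import child_seeds

MASTER_SEED = 20260930
OUT = Path("scratch/analysis/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    s_probe, s_train, s_panel, s_cohort = child_seeds(MASTER_SEED, 4)

    train_cfg = SimConfig(n_samples=400, age_range=(40.0, 90.0),
                          groups=(GroupSpec("train", 1.0),),
                          seed=s_train, probe_seed=s_probe)
    panel_cfg = replace(train_cfg, dirichlet_concentration=30.0, seed=s_panel)
    cohort_cfg = SimConfig(
        n_samples=600, n_datasets=2,
        groups=(
            GroupSpec("ref", 0.5),
            GroupSpec("grpB", 0.3, intrinsic_offset_years=2.0),
            GroupSpec("grpC", 0.2, extrinsic_shift_logits={"naiveCD8T": -0.4}),
        ),
        seed=s_cohort, probe_seed=s_probe,
    )

    for tag, cfg in (("train", train_cfg), ("panel", panel_cfg), ("cohort", cohort_cfg)):
        beta, ann, truth = simulate_cohort(cfg)
        eio.write_beta_tsv(beta, OUT / f"{tag}_beta.tsv")
        eio.write_sample_sheet(ann, OUT / f"{tag}_samples.tsv")
        eio.write_sample_sheet(truth.advanced_truth, OUT / f"{tag}_advanced_truth.tsv")
        eio.write_sample_sheet(truth.cell_proportions, OUT / f"{tag}_cell_truth.tsv")
        truth.samples.to_csv(OUT / f"{tag}_latent_truth.tsv", sep="\t")
        if tag == "train":
            eio.write_reference_tsv(make_reference_matrix(truth), OUT / "reference.tsv")
            truth.probes.to_csv(OUT / "probes.tsv", sep="\t")
        print(f"{tag}: {beta.shape[0]} probes x {beta.shape[1]} samples, "
              f"groups {sorted(set(ann['group']))}, datasets {sorted(set(ann['dataset']))}")

    (OUT / "manifest.json").write_text(json.dumps(
        {"master_seed": MASTER_SEED, "probe_seed": s_probe,
         "seeds": {"train": s_train, "panel": s_panel, "cohort": s_cohort}}, indent=2))
    print(f"wrote cohorts under {OUT}")


if __name__ == "__main__":
    main()
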