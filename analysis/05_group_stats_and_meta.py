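"""Group comparisons of the acceleration measures and cross-dataset
meta-analysis.

Per dataset: one-way ANOVA and Kruskal-Wallis of each measure across the
three groups (bar-plot style group means +/- 1 SE). Across datasets: the
ref-vs-grpB contrast is combined by Stouffer's method (sqrt-n weights)
and by inverse-variance fixed-effects pooling. A covariate model regresses
each measure on sex and group. Tables land in results/analysis/results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from epiaccel import (
    fit_accel_covariate_model,
    fixed_effects_meta,
    group_mean_diff_z,
    group_test,
    stouffer_meta,
)
from epiaccel import io as eio

OUT = Path("results/analysis/results")
CONTRAST = ("ref", "grpB")


def main() -> None:
    sheet = eio.read_sample_sheet(OUT / "samples_augmented.tsv")
    rows, meta_rows = [], []
    for measure in ("age_accel", "ieaa", "eeaa"):
        per_study = []
        for ds, sub in sheet.groupby("dataset"):
            for method in ("anova", "kruskal"):
                comp = group_test(sub[measure], sub["group"], method=method)
                for lab, row in comp.groups.iterrows():
                    rows.append({"dataset": ds, "measure": measure, "test": method,
                                 "group": lab, "n": int(row["n"]), "mean": row["mean"],
                                 "se": row["se"], "p": comp.p_value})
            d, se, z = group_mean_diff_z(sub[measure], sub["group"], CONTRAST)
            per_study.append({"ds": ds, "d": d, "se": se, "z": z, "n": len(sub)})
        st = stouffer_meta([s["z"] for s in per_study],
                           [np.sqrt(s["n"]) for s in per_study],
                           [s["ds"] for s in per_study])
        fe = fixed_effects_meta([s["d"] for s in per_study],
                                [s["se"] for s in per_study],
                                [s["ds"] for s in per_study])
        meta_rows.append({"measure": measure, "contrast": "grpB-ref",
                          "stouffer_z": st.estimate, "stouffer_p": st.p_value,
                          "pooled_diff": fe.estimate, "pooled_se": fe.se,
                          "ci_low": fe.ci_low, "ci_high": fe.ci_high,
                          "p": fe.p_value})
        print(f"{measure}: grpB-ref pooled diff = {fe.estimate:+.2f} yr "
              f"[{fe.ci_low:+.2f}, {fe.ci_high:+.2f}], Stouffer Z = {st.estimate:.2f} "
              f"(p = {st.p_value:.2g})")
        print(fe.forest_table())

    pd.DataFrame(rows).to_csv(OUT / "group_tests.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(OUT / "meta_analysis.tsv", sep="\t", index=False)

    tabs = []
    for measure in ("age_accel", "ieaa", "eeaa"):
        tab = fit_accel_covariate_model(sheet[measure], sheet[["sex", "group"]],
                                        reference_levels={"group": "ref"})
        tab = tab.reset_index(names="term")
        tab.insert(0, "measure", measure)
        tabs.append(tab)
        for term, label in (("group[grpB]", "grpB (intrinsic +2 yr)"),
                            ("group[grpC]", "grpC (extrinsic naive-CD8 deficit)")):
            row = tab.loc[tab["term"] == term]
            if not row.empty:
                est, p = row.iloc[0][["estimate", "p"]]
                print(f"{measure} ~ sex + group: {label} vs ref: "
                      f"{est:+.2f} yr, p = {p:.2g}")
    pd.concat(tabs).to_csv(OUT / "covariate_models.tsv", sep="\t", index=False)
    print(f"wrote group_tests.tsv, meta_analysis.tsv, covariate_models.tsv under {OUT}")


if __name__ == "__main__":
    main()
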