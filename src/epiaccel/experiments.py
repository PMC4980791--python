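"""Reusable simulation experiments: train-on-one-cohort, analyze-another.

These helpers mirror how the acceleration statistics are used in practice:
the clocks and subset estimators are calibrated on an independent training
cohort (sharing the probe universe, i.e. the array design) and then
applied unchanged to an analysis cohort carrying the group contrast of
interest. They back both the analysis scripts and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .acceleration import compute_acceleration
from .clock import predict_dnam_age, train_clock
from .deconvolution import estimate_advanced_subsets, estimate_cell_proportions, train_subset_estimator
from .simulate import GroupSpec, SimConfig, make_reference_matrix, simulate_cohort
from .stats import group_test

ADVANCED_SUBSETS = ("naiveCD8T", "exhCD8T", "plasmablast", "naiveCD4T")


def child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit integer seeds derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class TrainedModels:
    """Clocks and subset estimators calibrated on a training cohort."""

    clock: object  # intrinsic clock: cell-shared probes only
    blood_clock: object  # composition-sensitive clock: all probes
    subset_models: dict
    reference: pd.DataFrame
    probe_seed: int


def train_models(
    seed: int,
    n_train: int = 400,
    base_cfg: SimConfig | None = None,
    train_age_range: tuple[float, float] = (40.0, 90.0),
) -> TrainedModels:
    """Simulate a plain training cohort and calibrate all predictors on it.

    The intrinsic clock is trained on the cell-shared (clock + noise)
    probes, so it tracks the latent epigenetic age; the blood clock is
    trained on all probes including the composition signatures, so —
    like a blood-trained clock — it partially tracks cell composition.
    """
    base_cfg = base_cfg or SimConfig()
    s_probe, s_cohort, s_fit, s_panel = child_seeds(seed, 4)
    # Training spans a broader age range than a typical application cohort,
    # as published clocks do; this keeps the calibration slope near 1 so
    # group offsets in epigenetic age pass through unattenuated.
    cfg = replace(
        base_cfg,
        n_samples=n_train,
        age_range=train_age_range,
        groups=(GroupSpec("train", 1.0),),
        n_datasets=1,
        dataset_mean_shifts=None,
        seed=s_cohort,
        probe_seed=s_probe,
    )
    beta, annotation, truth = simulate_cohort(cfg)
    ages = annotation["age"]

    sig = truth.probes.index[truth.probes["class"] == "signature"]
    clock_probes = truth.probes.index[truth.probes["class"] == "clock"]
    noise_probes = truth.probes.index[truth.probes["class"] == "noise"]
    # The two clocks see disjoint halves of the cell-shared probes — like
    # published multi-tissue and blood clocks, whose CpG sets barely
    # overlap — so their idiosyncratic errors are independent. The blood
    # clock additionally sees the composition signatures.
    half = len(clock_probes) // 2
    perm = np.random.default_rng(s_fit).permutation(len(clock_probes))
    half_a = clock_probes[np.sort(perm[:half])]
    half_b = clock_probes[np.sort(perm[half:])]
    clock = train_clock(beta.loc[half_a.union(noise_probes, sort=False)], ages,
                        seed=s_fit, adult_age=cfg.adult_age)
    blood_clock = train_clock(beta.loc[half_b.union(sig, sort=False)], ages,
                              seed=s_fit, adult_age=cfg.adult_age)

    # Subset estimators are calibrated on a composition-diverse panel (low
    # Dirichlet concentration) and restricted to the signature probes: like
    # predictors built against purified or reconstituted mixtures, they must
    # identify each subset's own composition direction rather than proxy it
    # through the cohort's age-composition gradient or cell-intrinsic probes.
    panel_cfg = replace(cfg, dirichlet_concentration=30.0, seed=s_panel)
    panel_beta, _, panel_truth = simulate_cohort(panel_cfg)
    subset_models = {
        s: train_subset_estimator(
            panel_beta.loc[sig], panel_truth.advanced_truth[s], subset=s, seed=s_fit
        )
        for s in ADVANCED_SUBSETS
    }
    return TrainedModels(
        clock=clock,
        blood_clock=blood_clock,
        subset_models=subset_models,
        reference=make_reference_matrix(truth),
        probe_seed=s_probe,
    )


def analyze_cohort(models: TrainedModels, beta, annotation, reference_group: str):
    """Deconvolve, predict both clocks, and compute all acceleration measures."""
    counts = estimate_cell_proportions(beta, models.reference)
    counts.advanced = estimate_advanced_subsets(models.subset_models, beta)
    cells = pd.concat(
        [counts.advanced[["naiveCD8T", "exhCD8T", "plasmablast"]],
         counts.broad[["CD4T", "NK", "mono", "gran"]]],
        axis=1,
    )
    dnam_age = predict_dnam_age(models.clock, beta)
    blood_age = predict_dnam_age(models.blood_clock, beta)
    accel = compute_acceleration(
        dnam_age, blood_age, annotation["age"], cells, annotation, reference_group
    )
    return accel, counts, dnam_age, blood_age


def run_contrast_experiment(
    analysis_cfg: SimConfig, seed: int, models: TrainedModels | None = None
) -> dict:
    """Two-group contrast: simulate, analyze, compare 'case' vs 'control'.

    Returns group mean differences (case - control) and ANOVA p-values for
    IEAA and EEAA, plus the per-sample results for further inspection.
    """
    if models is None:
        models = train_models(seed, base_cfg=analysis_cfg)
    cfg = replace(analysis_cfg, probe_seed=models.probe_seed, seed=child_seeds(seed, 4)[3])
    beta, annotation, truth = simulate_cohort(cfg)
    accel, counts, _, _ = analyze_cohort(models, beta, annotation, reference_group="control")

    out = {"truth": truth, "accel": accel, "counts": counts, "annotation": annotation}
    for name, series in (("ieaa", accel.ieaa), ("eeaa", accel.eeaa)):
        comp = group_test(series, annotation["group"], method="anova")
        means = comp.groups["mean"]
        out[f"{name}_diff"] = float(means["case"] - means["control"])
        out[f"{name}_p"] = comp.p_value
    # Age-adjusted composition contrast: does the deconvolved naive-CD8
    # marker itself differ between groups? (should be null for a purely
    # intrinsic contrast, strongly non-null for an extrinsic one)
    from .acceleration import compute_eeaa

    naive_adj = compute_eeaa(counts.advanced["naiveCD8T"], annotation["age"])
    comp = group_test(naive_adj, annotation["group"], method="anova")
    out["naive_cd8_adj_diff"] = float(
        comp.groups["mean"]["case"] - comp.groups["mean"]["control"]
    )
    out["naive_cd8_adj_p"] = comp.p_value
    return out
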