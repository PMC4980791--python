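"""Config-driven end-to-end orchestration.

A run executes: simulate (or load) -> preprocess -> deconvolve -> clock ->
acceleration -> group statistics / meta-analysis -> report. Every stage's
outputs are TSV files under a fixed directory layout (data/, models/,
results/, report/), and the run report records parameters, seeds and
SHA-256 digests of every file written, so a run is a pure function of
(config, seed).

Within a run the clocks and subset estimators are fitted on a random
training split of the cohort (stratified nothing — plain seeded
permutation) and applied to the held-out analysis split; acceleration
measures and group statistics are computed per dataset on the analysis
split, then combined across datasets by Stouffer and inverse-variance
meta-analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .acceleration import compute_acceleration
from .clock import ClockModel, predict_dnam_age, train_clock
from .deconvolution import (
    estimate_advanced_subsets,
    estimate_cell_proportions,
    train_subset_estimator,
)
from .experiments import ADVANCED_SUBSETS, child_seeds
from .preprocess import drop_probes, impute_missing_clock_probes, normalize_to_gold_standard, read_blacklist
from .simulate import GroupSpec, SimConfig, make_reference_matrix, simulate_cohort
from .stats import fit_accel_covariate_model, fixed_effects_meta, group_mean_diff_z, group_test, stouffer_meta

logger = logging.getLogger(__name__)

ACCEL_MEASURES = ("age_accel", "ieaa", "eeaa")


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" | "load"
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_samples=600,
        n_datasets=2,
        groups=(
            GroupSpec("ref", 0.5),
            GroupSpec("grpB", 0.3, intrinsic_offset_years=2.0),
            GroupSpec("grpC", 0.2, extrinsic_shift_logits={"naiveCD8T": -0.4}),
        ),
    ))
    # load-mode inputs
    beta_path: str | None = None
    annotation_path: str | None = None
    reference_path: str | None = None
    # clock / acceleration settings
    adult_age: float = 20.0
    l1_ratio: float = 0.5
    n_folds: int = 10
    spline_df: int = 4
    reference_group: str = "ref"
    train_fraction: float = 0.4
    normalize: bool = True
    # stats plan
    contrast: tuple[str, str] | None = ("ref", "grpB")  # Stouffer sign order
    covariates: tuple[str, ...] = ("sex", "group")
    # robustness plan
    blacklist_path: str | None = None
    blacklist_fraction: float = 0.13  # used when no explicit blacklist file
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["groups"] = [dataclasses.asdict(g) for g in self.sim.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if sim:
            groups = tuple(
                GroupSpec(**g) if isinstance(g, dict) else g for g in sim.pop("groups", [])
            )
            for key in ("age_range", "cell_types", "probe_slope_range", "base_logits",
                        "age_slopes_logit_per_year", "dataset_mean_shifts"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(groups=groups or (GroupSpec("A", 1.0),), **sim)
        if d.get("contrast") is not None:
            d["contrast"] = tuple(d["contrast"])
        if d.get("covariates") is not None:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def dump_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunReport:
    config: dict
    stages: list[dict]
    digests: dict[str, str]
    tables: dict[str, str]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "stages": self.stages,
                 "digests": self.digests, "tables": self.tables},
                fh, indent=2, default=str,
            )


def _stage(stages: list, name: str, t0: float, **info) -> None:
    stages.append({"stage": name, "seconds": round(time.time() - t0, 3), **info})
    logger.info("stage %s done (%.2fs)", name, stages[-1]["seconds"])


def _split_train(annotation: pd.DataFrame, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    ids = annotation.index.to_numpy()
    n_train = max(50, int(round(fraction * len(ids))))
    perm = rng.permutation(len(ids))
    return pd.Index(ids[perm[:n_train]]), pd.Index(ids[perm[n_train:]])


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute all stages; write data/, models/, results/, report/."""
    outdir = Path(outdir)
    for sub in ("data", "models", "results", "report"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    written: list[Path] = []
    tables: dict[str, str] = {}
    seeds = child_seeds(config.seed, 4)

    # --- acquire data -----------------------------------------------------
    t0 = time.time()
    if config.mode == "simulate":
        cfg = dataclasses.replace(config.sim, seed=seeds[0], adult_age=config.adult_age)
        beta, annotation, truth = simulate_cohort(cfg)
        reference = make_reference_matrix(truth)
        eio.write_beta_tsv(beta, outdir / "data" / "beta.tsv")
        eio.write_sample_sheet(annotation, outdir / "data" / "sample_sheet.tsv")
        eio.write_reference_tsv(reference, outdir / "data" / "reference.tsv")
        eio.write_sample_sheet(truth.samples, outdir / "data" / "truth_samples.tsv")
        eio.write_sample_sheet(truth.cell_proportions, outdir / "data" / "truth_cells.tsv")
        written += [outdir / "data" / f for f in
                    ("beta.tsv", "sample_sheet.tsv", "reference.tsv",
                     "truth_samples.tsv", "truth_cells.tsv")]
        truth_probes = truth.probes
    elif config.mode == "load":
        for p in (config.beta_path, config.annotation_path, config.reference_path):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"load mode requires existing input path, got {p!r}")
        beta = eio.read_beta_tsv(config.beta_path)
        annotation = eio.read_sample_sheet(config.annotation_path)
        reference = eio.read_reference_tsv(config.reference_path)
        truth_probes = None
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    if config.reference_group not in set(annotation["group"]):
        raise ValueError(f"reference group {config.reference_group!r} absent from annotation")
    _stage(stages, "acquire", t0, n_samples=len(annotation), n_probes=len(beta))

    # --- train clocks & subset estimators on the training split -----------
    t0 = time.time()
    train_ids, analysis_ids = _split_train(annotation, config.train_fraction, seeds[1])
    train_beta = beta[train_ids]
    ages_train = annotation.loc[train_ids, "age"]
    sig_probes = reference.index.intersection(beta.index)
    non_sig = beta.index.difference(sig_probes, sort=False)
    # disjoint probe halves for the two clocks (published clocks barely
    # share CpGs); the blood clock additionally sees signature probes
    perm = np.random.default_rng(seeds[2]).permutation(len(non_sig))
    half_a = non_sig[np.sort(perm[: len(non_sig) // 2])]
    half_b = non_sig[np.sort(perm[len(non_sig) // 2:])]
    clock = train_clock(train_beta.loc[half_a], ages_train,
                        l1_ratio=config.l1_ratio, n_folds=config.n_folds,
                        adult_age=config.adult_age, seed=seeds[2])
    blood_clock = train_clock(train_beta.loc[half_b.union(sig_probes, sort=False)],
                              ages_train,
                              l1_ratio=config.l1_ratio, n_folds=config.n_folds,
                              adult_age=config.adult_age, seed=seeds[2])
    clock.save(outdir / "models" / "clock.tsv", outdir / "models" / "clock_header.tsv")
    blood_clock.save(outdir / "models" / "blood_clock.tsv",
                     outdir / "models" / "blood_clock_header.tsv")
    written += [outdir / "models" / f for f in
                ("clock.tsv", "clock_header.tsv", "blood_clock.tsv", "blood_clock_header.tsv")]

    subset_models = None
    if config.mode == "simulate":
        # signature panel only: composition estimators must not proxy age
        # through cell-intrinsic probes
        subset_models = {
            s: train_subset_estimator(train_beta.loc[sig_probes],
                                      truth.advanced_truth.loc[train_ids, s],
                                      subset=s, seed=seeds[2])
            for s in ADVANCED_SUBSETS
        }
    _stage(stages, "train", t0, n_train=len(train_ids), n_clock_probes=len(clock.clock_probes))

    # --- preprocess + predict + deconvolve the analysis split --------------
    t0 = time.time()
    analysis_beta = beta[analysis_ids]
    if config.normalize:
        analysis_beta = normalize_to_gold_standard(
            analysis_beta, clock.training_means.loc[clock.clock_probes]
        )
    counts = estimate_cell_proportions(analysis_beta, reference)
    if subset_models is not None:
        counts.advanced = estimate_advanced_subsets(subset_models, analysis_beta)
        cells = pd.concat(
            [counts.advanced[["naiveCD8T", "exhCD8T", "plasmablast"]],
             counts.broad[["CD4T", "NK", "mono", "gran"]]], axis=1)
    else:
        # without subset estimators, fall back to deconvolved fine types
        cells = counts.raw.rename(columns=str)
    dnam_age = predict_dnam_age(clock, analysis_beta)
    blood_age = predict_dnam_age(blood_clock, analysis_beta)
    _stage(stages, "deconvolve_predict", t0)

    # --- acceleration, per dataset ----------------------------------------
    t0 = time.time()
    ann = annotation.loc[analysis_ids]
    results = ann.copy()
    results["dnam_age"] = dnam_age
    results["blood_dnam_age"] = blood_age
    for m in ACCEL_MEASURES:
        results[m] = np.nan
    for ds, ids in ann.groupby("dataset").groups.items():
        ids = pd.Index(ids)
        accel = compute_acceleration(
            dnam_age.loc[ids], blood_age.loc[ids], ann.loc[ids, "age"],
            cells.loc[ids], ann.loc[ids], config.reference_group,
            spline_df=config.spline_df,
        )
        for m in ACCEL_MEASURES:
            results.loc[ids, m] = getattr(accel, m)
        accel.kd_model.save(outdir / "models" / f"kd_{ds}.tsv")
        written.append(outdir / "models" / f"kd_{ds}.tsv")
    counts_out = pd.concat([counts.broad, counts.advanced], axis=1) \
        if counts.advanced is not None else counts.broad
    eio.write_sample_sheet(counts_out, outdir / "results" / "cell_counts.tsv")
    eio.write_sample_sheet(results, outdir / "results" / "samples_augmented.tsv")
    written += [outdir / "results" / "cell_counts.tsv",
                outdir / "results" / "samples_augmented.tsv"]
    _stage(stages, "acceleration", t0)

    # --- group statistics and meta-analysis --------------------------------
    t0 = time.time()
    stat_rows, meta_rows = [], []
    for measure in ACCEL_MEASURES:
        per_study = []
        for ds, sub in results.groupby("dataset"):
            for method in ("anova", "kruskal"):
                comp = group_test(sub[measure], sub["group"], method=method)
                for lab, row in comp.groups.iterrows():
                    stat_rows.append({"dataset": ds, "measure": measure, "test": method,
                                      "group": lab, "n": int(row["n"]),
                                      "mean": row["mean"], "se": row["se"],
                                      "statistic": comp.statistic, "p": comp.p_value})
            if config.contrast is not None and \
                    set(config.contrast) <= set(sub["group"]):
                d, se, z = group_mean_diff_z(sub[measure], sub["group"], config.contrast)
                per_study.append({"dataset": ds, "diff": d, "se": se, "z": z,
                                  "n": len(sub)})
        if per_study:
            zs = [s["z"] for s in per_study]
            ws = [np.sqrt(s["n"]) for s in per_study]
            st = stouffer_meta(zs, ws, [s["dataset"] for s in per_study])
            fe = fixed_effects_meta([s["diff"] for s in per_study],
                                    [s["se"] for s in per_study],
                                    [s["dataset"] for s in per_study])
            meta_rows.append({"measure": measure, "contrast": "-".join(config.contrast),
                              "stouffer_z": st.estimate, "stouffer_p": st.p_value,
                              "pooled_diff": fe.estimate, "pooled_se": fe.se,
                              "ci_low": fe.ci_low, "ci_high": fe.ci_high,
                              "fixed_effects_p": fe.p_value})
            tables[f"forest_{measure}"] = fe.forest_table()

    cov_tabs = []
    for measure in ACCEL_MEASURES:
        tab = fit_accel_covariate_model(results[measure],
                                        results[list(config.covariates)])
        tab = tab.reset_index(names="term")
        tab.insert(0, "measure", measure)
        cov_tabs.append(tab)
    pd.DataFrame(stat_rows).to_csv(outdir / "results" / "group_tests.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(outdir / "results" / "meta_analysis.tsv", sep="\t", index=False)
    pd.concat(cov_tabs).to_csv(outdir / "results" / "covariate_models.tsv", sep="\t", index=False)
    written += [outdir / "results" / f for f in
                ("group_tests.tsv", "meta_analysis.tsv", "covariate_models.tsv")]
    _stage(stages, "stats", t0)

    report = RunReport(config=config.to_dict(), stages=stages,
                       digests=eio.digest_tree(written), tables=tables)
    report.save(outdir / "report" / "run_report.json")
    (outdir / "report" / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False))
    return report


def run_robustness(config: PipelineConfig, outdir) -> RunReport:
    """Probe-removal robustness re-analysis.

    Repeats clock prediction and acceleration after dropping a blacklist
    of clock probes (an explicit file, or a seeded random fraction of the
    fitted clock's probes — the 47-of-353 analogue) and imputing them with
    training means; reports the rank correlation between base and robust
    IEAA/EEAA per dataset.
    """
    outdir = Path(outdir)
    base = outdir / "results" / "samples_augmented.tsv"
    if not base.exists():
        raise FileNotFoundError("base run not found; run the pipeline first")
    base_results = eio.read_sample_sheet(base)
    beta = eio.read_beta_tsv(outdir / "data" / "beta.tsv")
    reference = eio.read_reference_tsv(outdir / "data" / "reference.tsv")
    clock = ClockModel.load(outdir / "models" / "clock.tsv",
                            outdir / "models" / "clock_header.tsv")
    blood_clock = ClockModel.load(outdir / "models" / "blood_clock.tsv",
                                  outdir / "models" / "blood_clock_header.tsv")

    if config.blacklist_path:
        blacklist = read_blacklist(config.blacklist_path)
    else:
        rng = np.random.default_rng(child_seeds(config.seed, 5)[4])
        probes = clock.clock_probes.union(blood_clock.clock_probes).to_numpy()
        k = max(1, int(round(config.blacklist_fraction * len(probes))))
        blacklist = pd.Index(rng.choice(probes, size=k, replace=False))
    if len(pd.Index(clock.clock_probes).difference(blacklist)) == 0:
        raise ValueError("blacklist removes every clock probe")

    analysis_ids = base_results.index
    analysis_beta = beta[analysis_ids]
    if config.normalize:
        analysis_beta = normalize_to_gold_standard(
            analysis_beta, clock.training_means.loc[clock.clock_probes])
    reduced = drop_probes(analysis_beta, blacklist)
    imputed = impute_missing_clock_probes(reduced, clock)
    imputed = impute_missing_clock_probes(imputed, blood_clock)

    counts = estimate_cell_proportions(imputed, reference)
    # Advanced subset scores are reused from the base run: their estimators
    # may weight probes outside the two clocks' nonzero sets, which the
    # constant imputation does not restore.
    base_cells = eio.read_sample_sheet(outdir / "results" / "cell_counts.tsv")
    cells = pd.concat(
        [base_cells[["naiveCD8T", "exhCD8T", "plasmablast"]],
         counts.broad[["CD4T", "NK", "mono", "gran"]]], axis=1).loc[analysis_ids]

    dnam_age = predict_dnam_age(clock, imputed)
    blood_age = predict_dnam_age(blood_clock, imputed)

    rows = []
    robust = base_results.copy()
    for ds, sub in base_results.groupby("dataset"):
        ids = sub.index
        accel = compute_acceleration(
            dnam_age.loc[ids], blood_age.loc[ids], sub["age"], cells.loc[ids],
            sub, config.reference_group, spline_df=config.spline_df)
        for m in ACCEL_MEASURES:
            robust.loc[ids, m] = getattr(accel, m)
        for m in ("ieaa", "eeaa"):
            rho = pd.Series(base_results.loc[ids, m]).corr(
                pd.Series(robust.loc[ids, m]), method="spearman")
            rows.append({"dataset": ds, "measure": m, "spearman_rho": float(rho),
                         "n_dropped": int(len(blacklist))})

    eio.write_sample_sheet(robust, outdir / "results" / "samples_robust.tsv")
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "results" / "robustness.tsv", sep="\t", index=False)
    report = RunReport(
        config=config.to_dict(),
        stages=[{"stage": "robustness", "n_dropped": int(len(blacklist))}],
        digests=eio.digest_tree([outdir / "results" / "samples_robust.tsv",
                                 outdir / "results" / "robustness.tsv"]),
        tables={"robustness": summary.to_string(index=False)},
    )
    report.save(outdir / "report" / "robustness_report.json")
    return report
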