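"""Synthetic 450K-style methylation cohorts with known ground truth.

The generator emulates the statistical structure that the age-acceleration
analysis assumes about whole blood:

* each sample has a latent *intrinsic epigenetic age* ``e`` equal to
  chronological age plus group/sex offsets and Gaussian noise;
* blood is a mixture of leukocyte types whose expected composition drifts
  with age on the logit scale (naive CD8+ T cells fall, exhausted CD8+ T
  cells and plasmablasts rise), with Dirichlet person-to-person variability;
* *clock probes* share one methylation level across cell types that moves
  linearly in the transformed intrinsic age, so they carry cell-intrinsic
  aging signal only;
* *signature probes* have cell-type-specific constant levels (one "on"
  cell type well separated from the rest), so they carry composition signal
  only;
* *noise probes* are constant;
* the observed beta value is the composition-weighted mixture of pure
  levels plus Gaussian measurement noise, clamped to [0, 1].

Intrinsic effects therefore enter only through ``e`` and extrinsic effects
only through the composition logits — which is exactly the separation the
intrinsic/extrinsic age-acceleration statistics are meant to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clock import transform_age

CELL_TYPES = ("naiveCD8T", "exhCD8T", "CD4T", "NK", "B", "plasmablast", "mono", "gran")

# Blood-like mean composition (granulocyte-dominated) expressed as logits.
_BASE_PROPORTIONS = {
    "naiveCD8T": 0.06,
    "exhCD8T": 0.02,
    "CD4T": 0.15,
    "NK": 0.07,
    "B": 0.06,
    "plasmablast": 0.01,
    "mono": 0.08,
    "gran": 0.55,
}

# Immunosenescence trajectories, logit units per year of age.
_AGE_SLOPES = {
    "naiveCD8T": -0.03,
    "exhCD8T": +0.04,
    "CD4T": 0.0,
    "NK": 0.0,
    "B": 0.0,
    "plasmablast": +0.015,
    "mono": 0.0,
    "gran": 0.0,
}


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: its share of samples and its aging offsets.

    ``intrinsic_offset_years`` shifts the latent epigenetic age ``e`` only;
    ``extrinsic_shift_logits`` shifts composition logits only (cell type ->
    logit shift).
    """

    label: str
    fraction: float
    intrinsic_offset_years: float = 0.0
    extrinsic_shift_logits: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 600
    age_range: tuple[float, float] = (50.0, 80.0)
    groups: tuple[GroupSpec, ...] = (GroupSpec("A", 1.0),)
    sex_effect_years: float = 1.0
    intrinsic_sd_years: float = 4.0
    cell_types: tuple[str, ...] = CELL_TYPES
    base_logits: tuple[float, ...] | None = None
    age_slopes_logit_per_year: tuple[float, ...] | None = None
    dirichlet_concentration: float = 100.0
    #: age at which base_logits describe the mean composition; trajectories
    #: pivot around this age so mid-cohort blood stays blood-like
    composition_anchor_age: float = 65.0
    n_clock_probes: int = 120
    n_signature_probes: int = 160
    n_noise_probes: int = 60
    probe_slope_range: tuple[float, float] = (0.04, 0.12)
    signature_on_level: float = 0.85
    signature_off_level: float = 0.15
    measurement_sd: float = 0.02
    adult_age: float = 20.0
    n_datasets: int = 1
    dataset_mean_shifts: tuple[float, ...] | None = None
    seed: int = 0
    #: optional fixed seed for the probe universe (the "array design");
    #: cohorts simulated with the same probe_seed share probes, so a clock
    #: trained on one cohort can be applied to another. None -> derived
    #: from the master seed.
    probe_seed: int | None = None

    def __post_init__(self) -> None:
        fracs = [g.fraction for g in self.groups]
        if not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ValueError(f"group fractions must sum to 1, got {sum(fracs)}")
        if self.age_range[0] < 0 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be a nonempty interval with low >= 0")
        if self.measurement_sd < 0:
            raise ValueError("measurement_sd must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.signature_on_level - self.signature_off_level < 0.6:
            raise ValueError("signature on/off separation must be >= 0.6 beta units")
        if self.n_clock_probes < 1 or self.n_signature_probes < len(self.cell_types):
            raise ValueError("need >= 1 clock probe and >= 1 signature probe per cell type")

    def resolved_base_logits(self) -> np.ndarray:
        if self.base_logits is not None:
            return np.asarray(self.base_logits, dtype=float)
        return np.log([_BASE_PROPORTIONS[c] for c in self.cell_types])

    def resolved_age_slopes(self) -> np.ndarray:
        if self.age_slopes_logit_per_year is not None:
            return np.asarray(self.age_slopes_logit_per_year, dtype=float)
        return np.array([_AGE_SLOPES[c] for c in self.cell_types])


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort.

    samples
        per-sample table: age, sex, group, dataset and the latent intrinsic
        age ``e_true`` (years).
    cell_proportions
        sample-by-cell-type true mixing weights, each row on the simplex.
    probes
        per-probe table: class (clock | signature | noise), generative
        intercept/slope, and the "on" cell type for signature probes.
    pure_levels
        signature-probe-by-cell-type pure (unmixed, noise-free) beta levels.
    advanced_truth
        per-sample true abundances of the advanced subsets used by the
        extrinsic-aging markers: naiveCD8T / plasmablast (proportion),
        exhCD8T (percent), naiveCD4T (age-declining naive fraction of CD4).
    """

    samples: pd.DataFrame
    cell_proportions: pd.DataFrame
    probes: pd.DataFrame
    pure_levels: pd.DataFrame
    advanced_truth: pd.DataFrame
    config: SimConfig


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def _probe_ids(n: int, start: int = 0) -> list[str]:
    return [f"cg{j:06d}" for j in range(start, start + n)]


def _simulate_samples(
    cfg: SimConfig, n: int, dataset: str, id_offset: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ages, group/sex labels, intrinsic ages and true compositions."""
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    labels = [g.label for g in cfg.groups]
    fracs = np.array([g.fraction for g in cfg.groups])
    # Exact largest-remainder allocation so group sizes match the fractions.
    quota = fracs / fracs.sum() * n
    counts = np.floor(quota).astype(int)
    counts[np.argsort(quota - counts)[::-1][: n - counts.sum()]] += 1
    group = rng.permutation(np.repeat(labels, counts))
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    offsets = {g.label: g.intrinsic_offset_years for g in cfg.groups}
    e = (
        ages
        + np.array([offsets[g] for g in group])
        + cfg.sex_effect_years * (sex == "M")
        + rng.normal(0.0, cfg.intrinsic_sd_years, size=n)
    )

    base = cfg.resolved_base_logits()
    slopes = cfg.resolved_age_slopes()
    shift_by_group = {
        g.label: np.array([g.extrinsic_shift_logits.get(c, 0.0) for c in cfg.cell_types])
        for g in cfg.groups
    }
    logits = base[None, :] + slopes[None, :] * (ages[:, None] - cfg.composition_anchor_age)
    logits += np.stack([shift_by_group[g] for g in group])
    m = _softmax(logits)
    # Dirichlet with sample-specific mean composition: standard-gamma trick.
    g = rng.standard_gamma(cfg.dirichlet_concentration * m)
    w = g / g.sum(axis=1, keepdims=True)

    ids = [f"s{j:05d}" for j in range(id_offset, id_offset + n)]
    samples = pd.DataFrame(
        {"age": ages, "sex": sex, "group": group, "dataset": dataset, "e_true": e},
        index=pd.Index(ids, name="sample_id"),
    )
    props = pd.DataFrame(w, index=samples.index, columns=list(cfg.cell_types))
    return samples, props


def _make_probe_table(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the shared probe universe: classes, intercepts, slopes, pure levels."""
    n_total = cfg.n_clock_probes + cfg.n_signature_probes + cfg.n_noise_probes
    ids = _probe_ids(n_total)
    classes = (
        ["clock"] * cfg.n_clock_probes
        + ["signature"] * cfg.n_signature_probes
        + ["noise"] * cfg.n_noise_probes
    )

    lo, hi = cfg.probe_slope_range
    sign = rng.choice([-1.0, 1.0], size=cfg.n_clock_probes)
    slope = sign * rng.uniform(lo, hi, size=cfg.n_clock_probes)
    # Anchor each clock probe's level at mid-range age so clamping is rare.
    f_mid = transform_age((cfg.age_range[0] + cfg.age_range[1]) / 2.0, cfg.adult_age)
    intercept_clock = rng.uniform(0.3, 0.7, size=cfg.n_clock_probes) - slope * f_mid

    on_cells = [cfg.cell_types[j % len(cfg.cell_types)] for j in range(cfg.n_signature_probes)]
    intercept_noise = rng.uniform(0.05, 0.95, size=cfg.n_noise_probes)

    probes = pd.DataFrame(
        {
            "class": classes,
            "intercept": np.concatenate(
                [intercept_clock, np.full(cfg.n_signature_probes, np.nan), intercept_noise]
            ),
            "slope": np.concatenate(
                [slope, np.zeros(cfg.n_signature_probes), np.zeros(cfg.n_noise_probes)]
            ),
            "on_cell": [""] * cfg.n_clock_probes + on_cells + [""] * cfg.n_noise_probes,
        },
        index=pd.Index(ids, name="probe_id"),
    )

    sig_ids = probes.index[probes["class"] == "signature"]
    pure = pd.DataFrame(
        cfg.signature_off_level,
        index=sig_ids,
        columns=list(cfg.cell_types),
    )
    for pid, cell in zip(sig_ids, on_cells):
        pure.loc[pid, cell] = cfg.signature_on_level
    return probes, pure


def _mix_betas(
    cfg: SimConfig,
    samples: pd.DataFrame,
    props: pd.DataFrame,
    probes: pd.DataFrame,
    pure: pd.DataFrame,
    mean_shift: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Composition-weighted mixture of pure levels + measurement noise."""
    f_e = transform_age(samples["e_true"].to_numpy(), cfg.adult_age)

    is_clock = (probes["class"] == "clock").to_numpy()
    is_sig = (probes["class"] == "signature").to_numpy()
    is_noise = (probes["class"] == "noise").to_numpy()

    n_probes, n = len(probes), len(samples)
    beta = np.empty((n_probes, n))
    a = probes["intercept"].to_numpy()
    b = probes["slope"].to_numpy()
    # Clock probes: one cell-shared level per sample, linear in F(e), clamped.
    beta[is_clock] = np.clip(a[is_clock, None] + b[is_clock, None] * f_e[None, :], 0.0, 1.0)
    beta[is_sig] = pure.to_numpy() @ props.to_numpy().T
    beta[is_noise] = np.repeat(a[is_noise, None], n, axis=1)

    beta += mean_shift
    if cfg.measurement_sd > 0:
        beta += rng.normal(0.0, cfg.measurement_sd, size=beta.shape)
    np.clip(beta, 0.0, 1.0, out=beta)
    return pd.DataFrame(beta, index=probes.index, columns=samples.index)


def _advanced_truth(samples: pd.DataFrame, props: pd.DataFrame) -> pd.DataFrame:
    from scipy.special import expit

    age = samples["age"].to_numpy()
    naive_cd4_frac = expit(2.0 - 0.05 * (age - 40.0))
    return pd.DataFrame(
        {
            "naiveCD8T": props["naiveCD8T"],
            "exhCD8T": 100.0 * props["exhCD8T"],
            "plasmablast": props["plasmablast"],
            "naiveCD4T": props["CD4T"].to_numpy() * naive_cd4_frac,
        },
        index=samples.index,
    )


def simulate_cohort(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a cohort (optionally multi-dataset) under ``cfg``.

    Returns ``(beta, annotation, truth)`` where ``beta`` is the
    probe-by-sample beta matrix, ``annotation`` the sample sheet
    (age, sex, group, dataset) and ``truth`` the full generative record.

    Deterministic given ``cfg.seed``: the master seed is split into named
    substreams (probes; then per-dataset samples and measurement noise), so
    the probe universe is shared across datasets and a partial rerun of one
    dataset reproduces bit-identically.
    """
    ss = np.random.SeedSequence(cfg.seed)
    probe_ss, *dataset_seeds = ss.spawn(1 + cfg.n_datasets)
    if cfg.probe_seed is not None:
        probe_ss = np.random.SeedSequence(cfg.probe_seed)
    probes, pure = _make_probe_table(cfg, np.random.default_rng(probe_ss))

    shifts = cfg.dataset_mean_shifts or tuple(0.0 for _ in range(cfg.n_datasets))
    if len(shifts) != cfg.n_datasets:
        raise ValueError("dataset_mean_shifts length must equal n_datasets")

    per = np.full(cfg.n_datasets, cfg.n_samples // cfg.n_datasets)
    per[: cfg.n_samples % cfg.n_datasets] += 1

    all_samples, all_props, all_beta = [], [], []
    offset = 0
    for d in range(cfg.n_datasets):
        sample_rng, noise_rng = (np.random.default_rng(s) for s in dataset_seeds[d].spawn(2))
        name = f"ds{d + 1}"
        samples, props = _simulate_samples(cfg, int(per[d]), name, offset, sample_rng)
        beta = _mix_betas(cfg, samples, props, probes, pure, shifts[d], noise_rng)
        all_samples.append(samples)
        all_props.append(props)
        all_beta.append(beta)
        offset += int(per[d])

    samples = pd.concat(all_samples)
    props = pd.concat(all_props)
    beta = pd.concat(all_beta, axis=1)
    truth = SyntheticTruth(
        samples=samples,
        cell_proportions=props,
        probes=probes,
        pure_levels=pure,
        advanced_truth=_advanced_truth(samples, props),
        config=cfg,
    )
    annotation = samples[["age", "sex", "group", "dataset"]].copy()
    return beta, annotation, truth


def make_reference_matrix(truth: SyntheticTruth) -> pd.DataFrame:
    """Signature-probe-by-cell-type matrix of pure (unmixed) beta levels.

    This plays the role of a purified-leukocyte methylation signature panel
    for reference-based deconvolution.
    """
    if truth.pure_levels.empty:
        raise ValueError("no signature probes configured")
    return truth.pure_levels.copy()


def betas_to_intensities(
    beta: pd.DataFrame, total_intensity: float, offset: float = 100.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct (methylated, unmethylated) intensities realizing ``beta``.

    With total signal ``S = M + U`` and the beta definition
    ``b = M / (M + U + offset)``, setting ``M = b * (S + offset)`` and
    ``U = S - M`` reproduces ``b`` exactly. Feasible only for
    ``b <= S / (S + offset)`` (``U`` must stay nonnegative).
    """
    s = float(total_intensity)
    if s <= 0:
        raise ValueError("total_intensity must be positive")
    b = beta.to_numpy() if isinstance(beta, pd.DataFrame) else np.asarray(beta, dtype=float)
    bound = s / (s + offset)
    if np.any(b > bound + 1e-15):
        raise ValueError(
            f"beta values above {bound:.6f} are infeasible at total intensity {s:g}"
        )
    m = b * (s + offset)
    u = s - m
    if isinstance(beta, pd.DataFrame):
        m = pd.DataFrame(m, index=beta.index, columns=beta.columns)
        u = pd.DataFrame(u, index=beta.index, columns=beta.columns)
    return m, u


def intrinsic_contrast_config(
    offset_years: float = 3.0, n_per_group: int = 300, seed: int = 0, **kw
) -> SimConfig:
    """Two-group design differing only in the intrinsic epigenetic-age offset."""
    return SimConfig(
        n_samples=2 * n_per_group,
        groups=(GroupSpec("control", 0.5), GroupSpec("case", 0.5, intrinsic_offset_years=offset_years)),
        seed=seed,
        **kw,
    )


def extrinsic_contrast_config(
    naive_cd8_logit_shift: float = -0.5, n_per_group: int = 300, seed: int = 0, **kw
) -> SimConfig:
    """Two-group design differing only in composition (naive CD8 logit shift)."""
    return SimConfig(
        n_samples=2 * n_per_group,
        groups=(
            GroupSpec("control", 0.5),
            GroupSpec("case", 0.5, extrinsic_shift_logits={"naiveCD8T": naive_cd8_logit_shift}),
        ),
        seed=seed,
        **kw,
    )
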