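# Methods

## Overview

`epiaccel` implements the blood epigenetic-aging toolkit — beta-value
preprocessing, elastic-net DNAm-age clocks, reference-based cell
deconvolution, and the universal/intrinsic/extrinsic age-acceleration
statistics with group tests and meta-analysis — together with a synthetic
methylation-cohort generator that provides ground truth for every stage.
This note records the model, the parameter choices that matter, the
numerical decisions, and what the synthetic validation does and does not
establish about real data.

## Generative model of the synthetic cohorts

Each sample carries a latent *intrinsic epigenetic age*

    e_i = age_i + δ_g(i) + γ·1[male_i] + ε_i,   ε_i ~ N(0, σ_int²),

and a true blood composition drawn from a Dirichlet distribution whose
mean follows age on the logit scale:

    m_i = softmax(base + slopes·(age_i − a₀) + shift_g(i)),
    w_i ~ Dirichlet(κ·m_i).

Probes come in three classes. *Clock probes* have one cell-shared level
`clamp01(α_p + β_p·F(e_i))`, linear in the transformed intrinsic age, so
they carry cell-autonomous aging signal only. *Signature probes* have
cell-type-specific constant levels (one "on" type at 0.85, all others at
0.15, a 0.7 beta-unit separation), so they carry composition signal only.
*Noise probes* are constant. The observed beta value is the
composition-weighted mixture of pure levels plus Gaussian measurement
noise, clamped to [0, 1]. Group effects therefore enter through exactly
one channel each: intrinsic offsets through `e` and extrinsic shifts
through the composition logits — the separation the IEAA/EEAA dichotomy
is designed to detect, here made literal so that specificity is testable.

Randomness is organized as named substreams of one master seed (probe
universe; per-dataset sample draws; per-dataset measurement noise), so a
multi-dataset cohort shares one probe universe, any single dataset can be
re-simulated bit-identically, and two cohorts simulated with the same
`probe_seed` share an "array design" — which is what lets a clock trained
on one cohort be applied to another.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| base composition (age 65) | gran .55, CD4 .15, mono .08, NK .07, B .06, naive CD8 .06, exh CD8 .02, plasmablast .01 | leukocyte differential of older-adult blood |
| composition anchor a₀ | 65 yr | base logits describe mid-cohort blood; trajectories pivot here so the mixture stays blood-like across the study ages |
| age slopes (logit/yr) | naive CD8 −0.03, exh CD8 +0.04, plasmablast +0.015, others 0 | immunosenescence: naive CD8 falls, exhausted CD8 and plasmablasts rise; magnitudes give age–naive-CD8 correlations near −0.6, comparable to flow-cytometry aging studies |
| Dirichlet κ | 100 | person-to-person composition scatter around the age trend |
| intrinsic SD σ_int | 4 yr | typical deviation of epigenetic from chronological age |
| sex effect γ | +1 yr (male) | males run epigenetically older |
| measurement SD | 0.02 beta units | typical 450K technical noise |
| probes | 120 clock, 160 signature (20/type), 60 noise | signature panel sized like published deconvolution libraries (hundreds of CpGs); clock panel large enough for a few dozen selected CpGs |
| clock probe slopes | |β_p| ∈ [0.04, 0.12] per transformed-age unit | keeps levels inside [0,1] over the age range with rare clamping |
| analysis age range | 50–80 yr | older-adult cohorts, the setting where these measures are usually applied |
| adult-age knot A | 20 yr | the published clock's calibration constant; configurable |

These values were fixed at design time by a power analysis of the study
conditions the package is meant to exercise (group offsets of a few years
at a few hundred samples per group) and are not tuned per experiment.

## Clock training and application

A clock is `ElasticNetCV` (mixing 0.5, 60-step penalty path, penalty-path
floor `eps = 1e-2`, 10-fold CV with a fixed fold seed) regressing
`F(age)` on betas, where `F(age) = log(age+1) − log(A+1)` below the
adult-age knot and `(age − A)/(A+1)` above — continuous, strictly
increasing, exactly invertible. The form is adopted from the published
clock literature; `A` is configurable.

Two clocks are trained on disjoint halves of the cell-shared probes: the
*intrinsic* clock (half A plus the inert probes) and the *blood* clock
(half B plus the signature panel). Published multi-tissue and blood
clocks share almost no CpGs, and the disjoint split reproduces the
consequence: their idiosyncratic errors are independent, and the blood
clock — free to weight composition signatures that covary with age —
partially tracks cell composition, which is precisely why the extrinsic
measure built on it is composition-sensitive.

Clocks are trained on a cohort spanning 40–90 years, wider than the
50–80-year application cohorts, as published clocks are. This keeps the
calibration slope near one, so a group offset in epigenetic age passes
into DNAm age essentially unattenuated instead of being shrunk by
regression toward the training mean.

The per-probe training means stored in the model serve two roles: the
constant-imputation values for missing clock CpGs, and the gold-standard
profile for per-sample quantile calibration. The calibration builds a
monotone piecewise-linear transfer from the sample's empirical beta
distribution over the shared probes onto the stored profile and applies
it to all probes; it is the identity for a sample already matching the
profile and is idempotent. The real preprocessing this stands in for is
reference-anchored normalization of Infinium arrays; the synthetic data
have no type I/II probe chemistry, so the probe-type-stratified variant
is an extension point, and the choice of the training-mean profile as the
gold standard is a stand-in the original method leaves unspecified.

## Deconvolution and subset estimators

Broad cell abundances solve `min‖x − Rw‖²  s.t. w ≥ 0` per sample
(scipy NNLS) over the probes shared with the reference. No sum-to-one
constraint is imposed — raw coefficients remain interpretable as cell
"counts", and IEAA uses them; sum-normalized proportions are reported
alongside. Granulocytes are one compartment. The fine 8-type solution is
collapsed to the six broad types (naive+exhausted → CD8T, B+plasmablast →
B) after solving, which is exact for mixtures.

The advanced-subset estimators (naive CD8+, exhausted CD8+, plasmablast,
naive CD4+) are elastic-net predictors trained against known subset
abundances — a functional stand-in for the proprietary estimators shipped
with epigenetic-clock software, whose coefficients are not public. Two
training restrictions matter and were adopted after their absence proved
structurally misleading:

1. **Signature probes only.** Trained on all probes, the estimators
   proxy the subsets through age-correlated clock probes, leaking
   cell-intrinsic signal into the IEAA covariates and blinding EEAA to
   genuine composition shifts.
2. **Composition-diverse calibration panel.** Trained on an age-structured
   cohort, the estimators learn the cohort's age-composition gradient
   rather than each subset's own direction: a case-only composition shift
   then passes through at ~0.2 of its true size. Training on a
   high-diversity Dirichlet panel (κ = 30 — the analogue of purified or
   reconstituted mixtures used to build real references) raises the
   pass-through to ~0.85.

The exhausted-CD8 truth is expressed in percent and the others as
proportions/scores; the original "count" units are unspecified, so scores
here are unitless and documented as such.

## Acceleration measures

*AgeAccel*: residual of DNAm age to a natural cubic spline (df 4, knots at
reference-group age quantiles, linear beyond the boundary knots, plain
linear fit when the reference group has under 30 samples) fitted in the
designated reference group only. Its reference-group mean is zero by
least-squares construction.

*IEAA*: OLS residual of DNAm age on age and the seven cell covariates
(advanced scores for naive CD8, exhausted CD8, plasmablast; NNLS
coefficients for CD4T, NK, mono, gran). Constant covariates are dropped
with a warning; exact collinearity falls back to the pseudo-inverse.

*EEAA*: each marker (blood-clock DNAm age plus the three cell scores) is
regressed on age (`x_j = q_j + k_j·age`, residual SD `s_j` with the n−2
denominator); markers whose slope fails |t| ≥ 2 are excluded with a
warning — a marker that does not move with age carries no biological-age
information, and on 30-year age windows the weak plasmablast trend is
regularly screened out, leaving a three-marker composite. The composite
is the precision-weighted average of the per-marker inverse estimates
(the Klemera–Doubal BA_E form, without the chronological-age
augmentation term: the construction is a weighted average of the four
markers only). Markers enter unstandardized — `s_j` provides the scaling
— and `s_j` is floored at `1e−6·|k_j|` so an exactly age-determined
marker cannot take infinite weight. Calibration is refit on the analysis
cohort per dataset; a frozen model can be serialized and reused. EEAA is
the age-residual of the composite.

Both residual measures have mean zero and are exactly uncorrelated with
age (and IEAA with every covariate) on their fitting cohort — these are
identities of least squares and are asserted at 1e−6 in the tests.

## Group statistics and meta-analysis

One-way ANOVA and Kruskal–Wallis (midrank ties with the standard
correction divisor, via scipy) with per-group mean ± 1 SE; Stouffer
combination `Z = Σw_iZ_i / √Σw_i²` with √n weights by default (equal
weights available — the original weighting is unstated); fixed-effects
inverse-variance pooling with a normal-approximation 95% CI; OLS
covariate models with dummy coding against a stated reference level; and
maximum-likelihood logistic outcome models with Wald tests, where
complete separation is detected (unbounded standard errors) and raised.
Raw two-sided p-values throughout; no multiplicity correction, matching
the presentation style of the analyses this reproduces. Study Z signs
follow a fixed group ordering declared in the configuration.

## Pipeline

`run_pipeline` executes simulate/load → train (40% split) → normalize →
deconvolve → predict → acceleration per dataset → group stats and
meta-analysis, writing TSVs under `data/`, `models/`, `results/` and a
JSON run report with parameters, seeds, stage timings and SHA-256 digests
of every file written; the run is a pure function of (config, seed). The
robustness mode re-predicts after dropping a blacklist of clock CpGs
(a file, or a seeded ~13% of the two clocks' CpG union) with
constant-mean imputation, and reports Spearman correlations between base
and robust IEAA/EEAA per dataset. Advanced subset scores are carried over
from the base run there, because their estimators may weight probes that
the clocks' imputation does not restore. Configuration is one YAML file;
all defaults are embedded and echoed into the report.

## Numerical choices

- Elastic-net: `eps = 1e-2`, `tol = 1e-3`, `max_iter = 10⁴`. The penalty
  path floor matters: CV on small-variance targets otherwise descends to
  tiny penalties where coordinate descent converges slowly, with no
  measurable gain in held-out accuracy.
- NNLS is deterministic; a rank-deficient reference is reported, and the
  (non-unique) solution still returned.
- Quantile calibration uses `np.interp` on sorted knots; ties collapse to
  one knot, keeping the transfer monotone non-decreasing.
- Beta clamping: `max(·, 0)` before the ratio; the +100 offset guarantees
  outputs in [0, 1).
- Spline knots are deduplicated before basis construction; degenerate age
  sets fall back to the linear fit.
- Derived seeds are 31-bit integers from `SeedSequence.generate_state`.

## What the synthetic validation shows — and does not

Passing tests establish that the statistics do what their definitions
promise under the generative model above: the clock recovers a latent
epigenetic age measured through noisy linear probes; IEAA responds to
intrinsic offsets (a +3-year offset is recovered within [2, 4] years at
n = 300/group) and not to composition shifts; EEAA detects a naive-CD8
logit deficit of 0.5 at p < 0.01 at the same size while IEAA stays within
±1 year. The generator deliberately omits: Infinium type I/II chemistry
and dye bias, batch and chip effects, SNPs under probes, nonlinear
probe–age trajectories, cell-type-by-age interaction in methylation,
tissue panels beyond blood-like mixtures, and non-Gaussian (logit-normal)
beta noise — additive Gaussian noise with clamping was chosen for
transparency of moments. Real-data behavior of these measures depends on
exactly those omitted features, so the tests validate the machinery, not
cohort-level effect sizes.

Known limitations: the IEAA–EEAA correlation on the default cohort runs
~0.8–0.9, higher than the moderate correlation seen in real blood,
because both synthetic clocks read the same latent aging process through
clean probes; real clocks disagree more. The EEAA composite's sensitivity
to composition rests on composition being strongly age-informative (the
operating premise of the extrinsic measure); under much larger residual
composition variance (small κ) the Klemera–Doubal weighting rightly
down-weights the cell markers and EEAA degenerates toward the blood
clock's residual.
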