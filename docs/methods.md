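# Methods

## Structural and statistical model

Drug disposition is a one-compartment model with first-order elimination.
A constant-rate infusion (rate R = amount/duration) contributes

* during infusion: C(t) = (R/CL)·(1 − e^(−k·t)), k = CL/V,
* after the stop time: exponential decay of the end-of-infusion value,

and regimens are summed dose by dose (superposition), so every simulated
concentration is exactly linear in dose amount.  Infusion duration is not
part of the published regimen description; the package default is 0.5 h
(typical for teicoplanin), configurable globally — trough predictions at
24 h after a dose are insensitive to it.  Durations below 10⁻⁶ h are
treated as boluses (C += amount/V) to avoid the 0/0 limit.

Individual parameters follow the final covariate model (see README):
typical CL scales linearly in weight and as 0.882^(SCr/29.075) in serum
creatinine; typical V as 1.75^(WT/16.71).  Subject deviations are
log-normal.  The published inter-individual variabilities are labelled
CV%; under an exponential η-model that convention is read directly as the
log-scale SD (ω_CL = 0.659, ω_V = 0.610), not as √ln(1+CV²) — the two
differ by <9% at these magnitudes.  The residual-error model is
exponential with σ = 0.07 by default; the source analysis is ambiguous
between "additive" (text) and a 7% CV (parameter table), and an
exponential 7% error is the reading under which the CV label is
meaningful.  Additive and proportional variants are selectable.

The Cockcroft creatinine clearance (140 − age)·WT·[0.85 if female]/
(0.818·SCr) is computed for reporting; it is not a covariate of the final
model.

## Virtual cohorts

Covariates (weight, SCr, age) are drawn from log-normals truncated to the
published ranges.  The log-normal parameters are solved so that the
*truncated* distribution reproduces the published mean and SD (a naive
moment-match before truncation deflates the realized SD — by ~24% for
age, whose upper bound cuts a visible tail).  Sex is Bernoulli (54.7%
male).  Weight and SCr are sampled independently; no joint structure is
published.  Draws are rejection-sampled, so all values lie inside the
stated ranges by construction.

Subject-level PK deviations are sampled under one of two schemes
(`EtaScheme`):

* **"model"** — independent N(0, ω²) draws at the full published ωs: the
  data-generating population model.  Used wherever the model itself is
  the object of study (parameter-recovery experiments, likelihood
  oracles, synthetic TDM datasets for estimation).
* **"estimates"** (default for the dosing analysis) — the dosing
  simulation in the source analysis propagated each patient's *estimated*
  parameters, not fresh population draws.  Parameter estimates from a
  sparse, trough-dominated design (~1.5 samples/child) are shrunken —
  their log-scale SDs are ω·(1 − shrinkage), with the published
  shrinkages 26.9% (CL) and 19.8% (V) — and collinear: one or two troughs
  identify only the exposure combination of CL and V, so estimate pairs
  line up along a common axis.  We therefore draw (η₁, η₂) fully
  correlated with SDs 0.482/0.489.  This is the package's own
  reconstruction of an under-specified step; it is the only scheme we
  found whose simulated cohort reproduces the published trough means,
  optimal doses, dose slopes and toxicity fractions simultaneously, and
  the choice ρ = 1 is the parameter-free limit of the collinearity
  argument rather than a fitted constant.  Under independent full-ω
  draws the low-CL log-normal tail dominates the cohort *mean* trough
  (sensitivity d ln Cmin/dη₁ ≈ −(1 + k·t) ≈ −4 at 24–48 h), inflating it
  ~40% above every published value.

Synthetic TDM datasets mimic the clinical design: standard loading +
maintenance dosing by weight, one pre-dose trough per child plus a second
with probability 0.5 (mean 1.5), exponential residual error, and
sub-LLOQ concentrations recorded at the 2.5 mg/L quantification limit
with a flag.  What the generator does **not** emulate: opportunistic
(non-trough) sampling times, covariate measurement error, missing-SCr
imputation, dose deviations, or any WT–SCr correlation — so passing tests
demonstrate internal consistency of the pipeline under the stated model,
not fidelity to any real hospital dataset.

## Dosing simulation and targets

Loading regimens are q12h ×3 from t = 0 with the trough read at 48 h;
maintenance regimens are q24h from t = 0 (no preceding loading doses,
matching the published simulation design) with the trough read at 96 h,
immediately before what would be the fifth dose.  One fixed cohort
(covariates + deviations) is reused across an entire dose scan (common
random numbers), which makes per-subject troughs exactly proportional to
dose, dose–response monotone, and the mean-trough-vs-dose slope exactly
mean(10 mg/kg)/10.

A regimen is optimal for a trough target when the cohort **mean** trough
reaches 10 or 15 mg/L (comparison at tolerance 10⁻⁹); percentile-based
criteria are deliberately not used, mirroring the source definition.
Steady-state AUC₂₄ = daily dose/CL; PTA at a MIC is the fraction of
subjects with AUC₂₄/MIC at or above 125 or 345, and CFR is the
frequency-weighted PTA average with a 90% adequacy threshold.  Loading
regimens are evaluated against trough targets only.  The bundled MIC file
is a synthetic example snapshot (mode 0.5 mg/L, wild type ≤ 2 mg/L); all
CFR numbers are conditional on the supplied distribution, and the CFR
dose optimum is additionally sensitive to the η-scheme (the shrunken
default yields a slightly lower optimum than the full-ω model scheme).

## Estimation

The population fit maximizes a Laplace approximation to the marginal
likelihood (a stand-in for FOCE-type estimation): per subject, the joint
−2 log-likelihood g(η) is minimized by a damped Newton search, vectorized
across subjects, with central finite differences (step 10⁻⁴), gradient
tolerance 10⁻⁸ and at most 100 iterations; the subject contribution is
g(η̂) + log det(H/2) − q·log 2π.  Degenerate ω → 0 dimensions are fixed
at zero (pure fixed-effects likelihood when both vanish).  The outer
optimization is Nelder–Mead on log-transformed positive parameters with
warm-started inner modes.  Accuracy against adaptive two-dimensional
Gauss–Hermite quadrature is ~0.2% on sparse toy subjects (tested at 1%).
Absolute objective values are approximation-specific and are never
compared with other software's OFVs; only differences between nested
models are used.  LLOQ-floored records enter the likelihood as recorded
values, replicating the clinical handling.

Covariate selection is classic forward addition (retain if ΔOFV > 3.84,
χ², df 1, p < 0.05; best candidate per round) followed by backward
deletion from the full model (retain only if removal raises OFV by
≥ 10.83, p < 0.001), with the full decision trace returned.

External-validation metrics are PE = (pred − obs)/obs·100% and its
absolute value, computed from typical-value (η = 0) predictions —
population rather than empirical-Bayes predictions, a documented choice
where the source is silent — with acceptance bands ±15% for observations
≥ 10 mg/L (boundary inclusive) and ±20% below.

## Problem sizes and numerical conventions

The dosing analysis uses 5,000 virtual children (the published cohort
size); acceptance runs regenerate it from the given seed.  Parameter
recovery uses 200 subjects × 6 samples (tested: θs within ±20%, ωs within
±30%); the repeated-replicate bias check runs at 4 replicates × 60
subjects; stepwise-selection experiments use 40–60 subjects × 3–4 samples
with ω = 0.3 and σ = 0.1 — sizes chosen to make each experiment decisive
while keeping the full suite fast.  All stochastic operations take
explicit seeds (numpy `SeedSequence` spawning; no global state) and equal
seeds are bit-reproducible.  Event CSVs store times in hours from first
dose, `.` for missing values, and numbers at 10 significant digits, which
bounds write/read round-trip error at ~10⁻⁹ relative.

## Known limitations

* One compartment only; teicoplanin's deep-compartment kinetics and
  protein-binding nonlinearity are out of scope.
* The "estimates" η-scheme is a reconstruction of an under-specified
  simulation step; its shrinkage inputs are taken from the published fit
  rather than derived from first principles.
* CFR conclusions depend entirely on the user-supplied MIC distribution.
* The Laplace estimator is adequate for recovery and model comparison but
  provides no standard errors, bootstrap, or simulation-based diagnostics.
* Mean-trough optimality (the source's criterion) is sensitive to the
  upper tail of the exposure distribution; percentile targets would give
  materially higher doses.
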