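# Methods

## The model

`reactnorm` quantifies genotype-by-environment interaction (G×E) caused by
heat stress in dairy-heifer fertility. The environment is summarised per
heifer by a heat-load gradient x computed from hourly weather over a
*critical period* anchored on her first-service day, and each record is
modelled with a linear reaction norm:

    y_i = x_f(i)' b + a0_j(i) + x_i · a1_j(i) + e_i

* `b` — fixed effects: herd-year-month of first service, service
  technician, semen type (conventional/sexed), plus (by default) a fixed
  linear regression on x that absorbs the mean environmental trend. The
  source material is not explicit about an environmental main effect in Xb;
  both configurations are supported (`include_eg_fixed`), and the default
  includes it so the random slope captures only genetic deviations from the
  average trend.
* `(a0, a1)` — correlated random intercept and slope per animal,
  `[a0; a1] ~ N(0, Σ ⊗ K)` with `Σ = [[σ²a0, σa0a1], [σa0a1, σ²a1]]` and
  K either the pedigree numerator relationship matrix **A** or the
  single-step matrix **H** combining A with a genomic relationship matrix.
* `e ~ N(0, I σ²e)` — residuals homogeneous across the gradient (a
  diagnostic for this assumption is provided, see below).

An animal's genomic estimated breeding value is a function of the
gradient, `gEBV(x) = a0 + x·a1`; genetic variance along the gradient is
`v(x) = σ²a0 + 2x σa0a1 + x² σ²a1`, heritability `h²(x) = v(x)/(v(x)+σ²e)`,
and the genetic correlation between two gradient levels follows from the
same quadratic form. The binary conception-rate trait is analysed with the
same linear model (linear-score analysis of 0/1 fertility outcomes; no
threshold model is provided).

## Environmental gradients

Hourly THI = Tdb + 0.36·Tdp + 41.2 (temperatures in °C). A *heat-stress
day* has hourly THI strictly above 72 for at least six continuous hours; a
missing hour breaks the run (conservative), and a day is usable if at
least 18 hourly records exist. Two gradients over an inclusive day window
(s, e) relative to first service (day 0 belongs to the "after" side):

* **prop** — fraction of heat-stress days in the window, in [0, 1];
* **mthi** — window mean of the daily minimum hourly THI, clipped to
  [15, 75] (the conventional plotting axis; the clip almost never binds on
  realistic data).

The candidate-window scan fits the reaction norm model once per window and
ranks windows by AIC = −2 logL + 2k, where k counts only the estimated
(co)variance parameters (4 for the RNM, 2 for the animal model), the REML
convention. The default grid is the Cartesian product of start offsets
{−90, −60, −30, −10, 0} days with window lengths {30, 40, 60, 70} days,
keeping windows ending by +60 — 19 windows including the (−30, 30)
reference. The grid is a package default, fully configurable.

## Kinship

* **A** and its inverse are built pedigree-only: inbreeding by the
  Meuwissen–Luo ancestor-tracing algorithm, A⁻¹ by Henderson's rules with
  Mendelian-sampling variances, log|A| = Σ log dᵢ for the REML
  determinant. A22 blocks are extracted without forming A (Colleau's
  indirect method: two sparse triangular solves per column).
* **G** is VanRaden method 1, `G0 = MM'/(2Σp(1−p))` with M centred by
  2p and missing genotypes imputed at the mean; allele frequencies come
  from the current genotyped sample (base-population frequencies are not
  observable). G0 is first tuned (`α + βG0` matching the mean diagonal and
  mean off-diagonal of A22 — the two-moment adjustment) and then blended,
  `G = (1−ω)G* + ωA22` with ω = 0.05 by default.
* **H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]**. Some sources print the second
  block with A22 rather than A22⁻¹; the A22⁻¹ form is the standard
  single-step construction and is what this package uses (the other
  variant is available behind a flag for comparison). log|H| =
  log|A| + log|G| − log|A22| feeds the REML likelihood.
* Genotype QC applies, in order: individual call rate ≥ 0.90, SNP missing
  rate ≤ 0.10, minor allele frequency ≥ 0.05, Hardy-Weinberg chi-square
  (1 df) p > 1e-5, autosomes only. The chi-square test (not an exact test)
  keeps QC O(m).

## Estimation

REML maximises the exact restricted log-likelihood evaluated through the
mixed-model equations: one sparse (or dense, for small/fully genomic
systems) factorisation per evaluation, with

    −2 logL = n log σ²e + log|Σ ⊗ K| + log|C| + y'Py + (n−p) log 2π,

which matches a direct dense REML likelihood to machine precision (tested
against that oracle). Sparse factorisation uses SuperLU with the
minimum-degree-on-A+A' column ordering; the default COLAMD ordering
produces catastrophic fill on animal-model equations.

Updates are Newton steps using the **exact average-information matrix**
as curvature (AI_ij = ½ fᵢ' P fⱼ with fᵢ = ∂V/∂θᵢ · Py, computed by
solves against the current factorisation). The score vector is obtained
by central finite differences of the exact logL with parameter-relative
steps (1e-4), avoiding sparse-inverse trace computation for which no
suitable primitive exists in the scientific Python stack. Each round
evaluates both the AI-Newton candidate and a diagonally preconditioned
gradient candidate and keeps whichever climbs higher — far from the
optimum the Newton direction can descend into a low-genetic-variance
side valley of the reaction norm surface. A step that leaves the
parameter space (Σ not positive definite, σ²e ≤ 0) or fails to improve
the likelihood is halved, up to 40 times; two consecutive failed rounds
terminate as converged-at-noise-floor. Convergence otherwise requires a
relative parameter change below 1e-8 or a log-likelihood change below
1e-9. Standard errors of the (co)variance components are from the
inverse AI matrix at the optimum; standard errors of heritabilities and
correlations use first-order (Taylor/delta) propagation with the AI
parameter covariance.

Two further numerical safeguards matter in practice. First, the
optimiser works internally with the gradient **centred at its mean** —
an exact reparametrisation (Σ* = BΣB', B = [[1, c], [0, 1]]): on raw
scales such as mTHI (x ∈ [15, 75]) the intercept is an extrapolation to
x = 0 and the raw-scale surface has a badly conditioned curved ridge in
(σ²a0, σa0a1). All reported parameters, solutions, PEVs and covariances
are transformed back to the raw scale, so σ²a0 keeps its published
meaning as the genetic variance at x = 0. Second, starting values come
from a **hierarchical warm start**: a plain animal-model fit splits
phenotypic variance into genetic and residual parts, and the genetic
variance is then divided evenly between the centred intercept and the
slope term. Reaction norm surfaces can be multimodal, with a spurious
low-genetic-variance mode; starting with a too-small slope variance is
what steers the iteration into it.

Prediction-error variances come from MME-inverse columns solved on demand
for the animals requested; accuracy is `sqrt(1 − PEV(x)/v(x))` clipped at
zero. The one-tailed G×E test is z = σ̂²a1 / SE(σ̂²a1) against the normal
upper tail at α = 0.05; because the REML estimate is constrained to the
positive-definite cone, the test is mildly conservative near the null
(empirical size ≈ 2–5% in the calibration experiment below).

The residual-homogeneity diagnostic splits records at the 10th and 30th
percentile ranks of the realized gradient and re-estimates the residual
variance per subset by *profile* REML — the genetic covariance is held at
the full-data estimate, and only σ²e is re-optimised per subset (a free
per-subset refit trades genetic against residual variance and is far
noisier). The max/min variance ratio summarises departures from
homogeneity.

## G×E diagnostics

Sire re-ranking: eligible sires (≥ 20 phenotyped daughters) are ranked by
gEBV(x) in the trait's favorable direction (lower is better for AFC and
IFL, higher for CR) at paired quantiles of the realized gradient
distribution (1/99, 5/95, 10/90, 25/75%), and the top-50 intersections
are counted. Climate-resilient and -sensitive sires are found by first
screening on preferential intercepts (beyond mean ∓ 2 SD in the favorable
direction) and then taking the k flattest and k steepest slopes.
Top-heifer overlap between the two gradient definitions selects heifers
with EBV accuracy above 0.4, takes the top 1% under each gradient at
*equivalent* levels, and reports the intersection fraction; equivalence
pairs (e.g. prop = 1 ↔ the mean minimum THI of all-hot windows) are
estimated from the data, not hard-coded.

## ssGWAS and SNP clusters

Marker effects for the intercept and slope are back-solved from the
genotyped animals' EBVs in a single pass with identity SNP weights:
`u_t = M' G⁻¹ ĝ_t / (2Σp(1−p))`. Two properties matter for interpreting
recovery: the back-solved vector lives in the row space of M, so faithful
per-SNP recovery requires fewer markers than genotyped animals; and
recovery quality is bounded by the EBV accuracy. The marker-sum identity
`M u_t ≈ ĝ_t` holds to r > 0.99 at the default blend ω = 0.05.

Sliding windows of 20 adjacent SNPs (step 1, never spanning chromosomes)
are scored as `100 · Var(M_w u_w) / σ²_t`, with the REML estimate of the
term's variance as denominator by default (the realized variance
`Var(M u)` is available behind a flag). The number of flagged windows per
term is the top fraction (default 0.5%) of the SNP count — the
convention under which a 111,068-SNP panel yields 555 selections.
Overlapping or abutting flagged windows merge into regions whose
coordinates are the bp of the first and last SNP (1-based, inclusive).

SNP trajectories `e(x) = u0 + x·u1` are clustered by slope: C1 = top
fraction changing in the trait-favorable direction, C2 = opposite, C3 =
|slope| nearest zero, with C3 further split by the sign of the mean
effect; boundary ties break deterministically by map order. Mapping
cluster SNPs to genes requires a user-supplied BED-like interval table
(half-open [start, end)); no genome annotation ships with the package.

## The synthetic herd generator

The generator emulates the study system: 15 herds, a multi-year hourly
weather series, a multi-generation pedigree whose final cohort of heifers
is phenotyped with a configurable number of daughters per sire, SNP
genotypes gene-dropped through the pedigree from founder frequencies
uniform on the configured MAF range, and records generated under the
reaction norm model itself. Defaults for the (co)variance components are
the reference-window prop-gradient estimates for AFC, IFL and CR
(e.g. AFC: σ²a0 = 971.97, σ²a1 = 0.53, σa0a1 = −9.62, σ²e = 3413.70, in
days²).

* **Weather** is an annual sinusoid (mean 11 °C, amplitude 16 °C) plus a
  diurnal sinusoid (amplitude 7 °C, peak mid-afternoon) with Gaussian
  noise and a dew-point depression that shrinks in the humid summer.
  Under the defaults hourly THI spans roughly 15–85 across a year,
  within-day swings reach tens of THI units, mid-summer days reliably
  contain six-hour runs above 72, and both gradients sweep their full
  ranges. It reproduces range and cyclicity only — no weather fronts,
  heat waves with multi-day persistence, or inter-annual trends.
* **Breeding values** are either 100% marker-borne (pairs of per-SNP
  effects drawn from Σ scaled by the founder heterozygosity, so gene
  content times effects reproduces a0/a1 exactly) or polygenic
  (parent-average plus Mendelian sampling with inbreeding-adjusted
  variance). The polygenic mode makes a pedigree-kinship analysis exactly
  correctly specified; the genomic mode does the same for fully
  genotyped analyses.
* **CR** is generated from a clamped linear probability
  `p = clip(μ + fixed + a0 + x·a1, 0, 1)` so the linear analysis model is
  correctly specified (a liability option exists, off by default).
* **Event dates** are mutually consistent: IFL = 0 whenever conception
  occurs at first service; last service = first service + IFL; calving =
  last service + 280 d gestation (configurable); the birth date is set so
  age at first calving equals the generated AFC — hence AFC = age at
  conception + gestation holds exactly, and re-deriving traits from the
  event dates returns the generated values (up to whole-day rounding).
* First-service dates are uniform over the configured years so the
  gradient is well populated; weather coverage extends 120 days past the
  years so any candidate window up to (−90, +60) stays inside the data.

What passing tests on this generator do *not* show: robustness to real
pedigree error, genotyping artefacts, non-random mating or selection,
heterogeneous herd management, informative missingness in service
records, or weather measured far from the herds.

## Validation experiments and problem sizes

The canned experiments in `reactnorm.validation` (run by
`tests/test_acceptance.py` and `scripts/acceptance.py`) use the following
sizes, chosen as the package's validation defaults:

* closed-form parameter checks — arithmetic on reference components;
* dense-oracle equivalence — REML logL on 40-animal fixtures (gap
  < 1e-6), H⁻¹ on a ~90-animal pedigree with a genotyped subset (max-norm
  < 1e-8), heat-day calling vs. a brute-force 6-hour scan;
* parameter recovery — one fit of 10,000 AFC records (250 sires × 40
  daughters, dams unrecorded, polygenic architecture) from the reference
  prop-gradient components; each estimate should cover the truth within
  2 AI standard errors;
* slope-test calibration — 200 replicates of 450 records under a no-G×E
  truth; empirical size compared with the nominal 5% allowing for the
  boundary conservatism noted above;
* ssGWAS recovery — 1,000 genotyped animals × 250 SNPs at high
  heritability (recovery is bounded by EBV accuracy and requires m < n);
  planted-region detection — 800 animals × 2,000 SNPs with two
  large-effect loci on different chromosomes;
* re-ranking — 150 sires × 20 daughters with r(a0,a1) = −0.9 and
  slope-induced gEBV spread comparable to the intercept spread (fewer
  sires would impose a combinatorial floor of 2·50 − n on the top-50
  overlap); the no-G×E contrast applies the overlap diagnostic to the
  null population's zero-slope breeding-value surface, where full overlap
  is exact.

## Numerical notes and limitations

* The MME matrix is strictly positive definite for full-rank designs;
  exactly collinear fixed-effect columns are dropped by pivoted QR at
  design construction.
* All gradient values equal → the slope variance is unidentifiable and
  model construction raises immediately rather than letting REML wander.
* Dense vs sparse backend is chosen automatically by system size and
  fill; both produce identical likelihoods (tested).
* Single records per animal mean σ²e and σ²a0 are separated only through
  the kinship structure; designs with weak family structure give slow,
  flat likelihoods.
* Window scans refit the model once per candidate window; with the
  19-window default grid this is by far the most expensive stage of a
  full S2 pipeline run.
* No multi-trait models, Legendre/quadratic reaction norms, threshold
  models for CR, metafounders, APY approximations, or LD-aware window
  sizing.
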