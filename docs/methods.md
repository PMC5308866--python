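# Methods

## Model and scope

The package targets association mapping in panels of fully homozygous
inbred lines: n individuals (hundreds) genotyped at p biallelic SNPs
(thousands to tens of thousands), a single quantitative trait, and
optional fixed-effect covariates such as population-structure components.
The generating model is

    y = μ + Σ_j Q_j α_j + Σ_i X_i β_i + ε,    ε ~ N(0, σ² I)

with each SNP contributing one column (no heterozygotes, so genotype
codes are {0,1} by default, {−1,+1} optionally; every downstream step
standardizes columns, making the two codings equivalent). Only a sparse
subset of the β_i is nonzero; the task is to find it and estimate it when
p ≫ n.

## The two-stage algorithm

**Stage 1 — screening.** The phenotype is corrected for fixed effects by
OLS (`y_c = y − Qα̂`); an intercept is always included, so with no
covariates this is mean-centering. Columns are standardized to mean 0,
sample sd 1 (n−1 denominator); monomorphic columns are flagged at load
time and never enter the screen. The marginal screen keeps index set
K1 = {i : |corr(x_i, y_c)| significant at level α}, using the exact
two-sided Student test, t = r√((n−2)/(1−r²)) with n−2 df, inverted to a
critical correlation r* = t*/√(t*² + n−2). Defaults: α = 0.01
(r* ≈ 0.182 at n = 199), ties at the threshold kept, no multiple-testing
correction — the screen is a liberal filter whose false entries the later
stages remove. The df is kept at n−2 after fixed-effect correction; the
corrected trait is treated as the working response.

The screened block is then reduced by SCAD-penalized least squares
(below); the selected support is T1, its coefficients are discarded. The
trait is regressed (OLS with intercept) on the T1 columns, and the
screen + SCAD round repeats once on the residual response over the
remaining p − τ1 columns, yielding T2 — this conditional round recovers
loci that are marginally uncorrelated with the trait but associated given
T1. The residual response is standardized before the second screen
(symmetric treatment of the two rounds; the alternative of screening the
raw residuals differs only in the λ scale of the SCAD subproblem). Both
rounds are deterministic. More rounds are configurable
(`isis_rounds`); the default is two total screens.

**Stage 2 — estimation.** The τ = |T1 ∪ T2| survivors are fitted jointly
to the *original* (uncorrected) phenotype with X = [1 | Q] as fixed
effects, under the hierarchical model γ_k ~ N(0, σ²_k) per SNP. The EM
cycle treats the γ_k as missing data:

- E-step (scalar per SNP): E(γ_k) = σ²_k Z_k'V⁻¹(y − Xβ),
  var(γ_k) = σ²_k − σ²_k Z_k'V⁻¹Z_k σ²_k,
  E(γ²_k) = E(γ_k)² + var(γ_k), with V = Σ_k Z_k Z_k'σ²_k + Iσ².
- M-step: β by GLS (X'V⁻¹X)⁻¹X'V⁻¹y; residual variance
  σ² = (1/n)(y − Xβ)'[(y − Xβ) − Σ_k Z_k E(γ_k)]; and the per-SNP
  variance update determined by the prior on σ²_k.

**Choice of prior.** Two priors are implemented. The flat prior gives
σ²_k ← E(γ²_k); it is the likelihood-EM and its observed-data
log-likelihood trace is exactly non-decreasing (audited in the tests),
but it exerts no selection pressure — every screened SNP converges to a
nonzero stationary point, the working support stays dense, and the final
significance test inherits heavy selection optimism. The default is
therefore the scaled inverse-χ²(τ₀, ω₀) prior with the Jeffreys-type
setting (0, 0), giving σ²_k ← E(γ²_k)/3: null components decay
geometrically to zero (a variance below 10⁻⁹ is clamped to exactly zero
and the SNP leaves the model — an absorbing state), which is the
LASSO-like sparsity that makes the second stage a variable selector
rather than a ridge fit. Under this prior the cycle climbs a penalized
likelihood; the raw likelihood trace may dip slightly and is not asserted
monotone. Hyperparameters are configurable
(`em_prior`, `em_prior_params`; (−2, 0) reproduces the flat update).

Initialization: σ²_k = 1 for all k, σ² from the OLS residuals of y on X.
Convergence: max relative parameter change < 10⁻⁶ (max 500 iterations;
non-convergence is a warning, not an error). V solves use one dense
Cholesky per iteration — at the package's design scale (n up to a few
thousand) this is milliseconds, so no low-rank update path is provided.

## SCAD subproblem

The penalty ρ(|β|; λ, γ) is linear (λ|β|) up to |β| = λ, blends
quadratically to γλ, and is constant beyond, leaving large effects
unshrunk; γ = 3.7 by default (the standard choice; γ must exceed 2 for
the middle branch to be defined). The solver minimizes
(1/2n)‖y − Xb‖² + Σρ(|b_j|) by cyclic coordinate descent with the exact
scalar minimizer (soft-threshold / blended / identity in the three |z|
regions), columns internally rescaled to x'x = n so that update is exact
and λ_max = max_j |x_j'y|/n zeroes everything. The λ path is 100
log-spaced values from λ_max down to 10⁻³λ_max, warm-started; after each
full sweep the active set is iterated to stability; convergence is a full
sweep changing no coefficient by more than 10⁻⁴. λ is tuned by BIC
(n log(RSS/n) + df log n, df = support size), ties resolved toward the
smaller support then the larger λ; K-fold CV is available. Because each
coordinate update exactly minimizes its scalar objective, the penalized
objective is non-increasing across sweeps (asserted in tests), and a
brute-force lattice search on 2–3-variable problems confirms the solver
reaches the global grid minimum.

Note the screen-level/sample-size interaction: at n ≈ 200 and α = 0.01,
a SNP at the critical correlation reduces n log RSS by ≈ 6.7 > log n ≈
5.3, so BIC alone cannot prune chance-correlated survivors — by design
the pruning burden rests on the estimation stage's shrinkage.

## Significance testing

Each surviving effect k is tested against H0: γ_(k) = 0 with the LOD
score, LOD = −2(L0 − L1)/(2 ln 10); 2 ln 10 = 4.6052 to printed
precision, and LOD·4.6052 is χ²₁ under the null, so LOD ≥ 3 ⇔
p ≈ 2×10⁻⁴. Default evaluation ("estimates"): L1 is the Gaussian
log-likelihood at the EM estimates and EM residual variance, L0 the same
with effect k zeroed and the others untouched — the statistic measures
what the estimated (shrunken) effect explains, so the estimation stage's
conservatism carries into the test, and a spuriously selected SNP whose
effect was shrunk toward zero cannot ride an optimistic refit over the
threshold. The alternative ("refit") profiles both likelihoods over
OLS-refit effects and ML variance within the support; it guarantees
L1 ≥ L0 but measurably inflates the null LOD distribution through
selection optimism (on synthetic benchmark replicates it roughly
doubles the pooled Type-1 error). Reported effects are always the EM
estimates; r² = 100·effect²·var(x)/var(y), capped at 100.

## Simulator

`simulator` reproduces the three benchmark experiment designs on
synthetic panels: n = 199 lines, p = 10000 SNPs on five chromosomes
(2000 each, uniformly spaced 10 kb), six QTN at allele frequency 0.30
with heritabilities (0.10, 0.05, 0.05, 0.15, 0.05, 0.05), overall mean
10, residual variance 10. Background allele frequencies are uniform on
[0.05, 0.5]. The total variance solves V = (σ² + σ²_poly + Σσ²_epi)/(1 −
Σh²); per-QTN effects are calibrated against the empirical column
variances (a² var(x) = h² V), signs positive by default and
configurable. Experiment 2 adds a polygenic deviation MVN(0, K σ²_poly)
with σ²_poly = 2 (V = 12/0.55, polygenic heritability 0.092), K the
VanRaden-type standardized marker cross-product WW'/p. Experiment 3 adds
three epistatic pairs (product of centered genotype codes, coefficient
scaled to contribute exactly σ²_epi = 1.25 each; heritability 0.05
apiece; interacting loci are placed apart from the six additive QTN and
share their allele frequency). Replicate r draws from sub-seed
seed + r (residual noise drawn before the polygenic term, so the noise
stream is invariant to the panel); the genotype stream uses a disjoint
seed offset.

**What the simulator does not emulate:** linkage disequilibrium (columns
are independent), population structure, minor-allele-frequency spectra of
real panels, dominance, and missing genotypes. Consequences worth
knowing: with independent columns every zero-effect SNP is a fresh
opportunity for a chance correlation, so the measured false positive
rate is, if anything, conservative relative to panels with LD (where
effectively fewer independent tests exist and near-QTN neighbours count
as detections); conversely, power benefits LD would provide via tagging
are absent. A real genotype file can be supplied to the pipeline to keep
the original LD structure. Passing tests on this generator demonstrate
the algorithmic properties at the stated n, p and effect sizes, not
performance on any particular real panel.

## Evaluation harness

A call within 1 kb (same chromosome) of a true QTN is a detection —
several calls in one window count once, taking the highest LOD; any other
call is a false positive. Per-QTN power is the fraction of replicates
with a detection; the Type-1 error pools false calls over (zero-effect
SNPs × replicates), in percent (the pooled denominator is the literal
reading of the definition; per-QTN MSE averages (γ̂ − a)² over the
replicates where that QTN was detected, and is reported missing with
zero detections). Paired t tests compare per-QTN metric vectors between
methods (identical vectors return t = 0, p = 1; a nonzero constant
difference leaves t undefined and is flagged). ROC sweeps map a grid of
67 log-spaced significance levels in [10⁻⁸, 10⁻²] to LOD thresholds via
χ²₁ and re-threshold stored per-SNP LOD statistics. AIC/BIC of a call
set use the Gaussian profile form n log(RSS/n) + {2k, k log n} with
k = columns + 1, collinear columns pruned with a warning. Call tables
from external methods are scored through the same tab-delimited schema.

## Numerical and degenerate-input conventions

- Missing genotypes: column-mean imputation rounded to the nearest legal
  code, ties to the larger code — opt-in; off by default (hard error).
- Monomorphic SNPs are flagged and excluded from screening but retained
  in the matrix so indices line up with the map.
- An empty screen (no significant correlations) yields a valid empty
  result and zero calls, not an error.
- σ̂² ≤ 0 in the EM (exact interpolation) and zero-variance SCAD columns
  are hard errors; E-step posterior variances below −10⁻¹⁰ are treated
  as numerical faults, small negatives are clipped to 0.
- LOD values are clipped at 0; under the "refit" evaluation L1 < L0
  beyond 10⁻⁶ raises (a broken refit), under "estimates" the null is not
  re-optimized so L0 may legitimately exceed L1 (LOD 0).
- Gene annotation distances: 0 inside the gene, negative when the gene
  interval precedes the SNP on the coordinate axis, positive after —
  one convention of several in circulation; recorded, not asserted
  universal.

## Problem sizes used in the shipped tests

Unit and property tests run at n ≤ 199, p ≤ 600. The acceptance suite
runs the full benchmark geometry — 100 replicates at 199 × 10000 for the
Type-1 error bound (~2–3 minutes) and 200 replicates at 199 × 2000 for
parameter recovery against a single-marker OLS baseline (~1–2 minutes) —
sizes chosen so the whole suite completes on one core in well under half
an hour while keeping the Monte-Carlo error on the pooled false-positive
rate a small fraction of the bound being checked.

## Known limitations

- The conditional screening round assumes the round-1 OLS fit is stable
  (τ1 ≪ n); with α much looser than 0.01 this degrades.
- The LOD null calibration is asymptotic (χ²₁) and, for SNPs that
  survived screening and shrinkage, conditional on selection; the
  benchmark false-positive measurements quantify the net effect.
- m_k = 1 throughout: multi-genotype loci (heterozygotes, multiallelic
  markers) are out of scope, as are VCF/PLINK binary inputs.
- Wall-clock performance targets desk scale (p ≤ ~10⁵ on one core);
  no parallel execution.
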