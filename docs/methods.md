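# Methods

This note documents the statistical models implemented in `mosaicbrain`,
the choices made where the methodology was genuinely open, and what the
synthetic-data validation does and does not establish.

## Phylogenetic covariance structures (`mosaicbrain.phylo`)

All analyses condition on a rooted, time-calibrated phylogeny with
non-negative branch lengths. The Brownian-motion covariance between tips
*i* and *j* is the shared root-to-MRCA path time `t_ij`; the diagonal is the
tip depth `T_i`. Pagel's λ multiplies the off-diagonal entries: λ = 0 is the
star-tree (no-signal) limit, λ = 1 the full Brownian expectation. λ is
bounded to [0, 1] rather than its algebraic maximum, matching the usual
interpretation of λ as a signal fraction.

The multi-optimum Ornstein–Uhlenbeck (Hansen) model paints *regimes* onto
branch segments: a shift at relative position *p* on a branch opens a new
regime inherited by everything tipward until another shift intervenes. The
expectation of tip *i* is a weighted combination of regime optima with
weights

    W_ir = Σ_segments in regime r [ e^{−α(T_i − t_end)} − e^{−α(T_i − t_start)} ],

the residual root-state mass `e^{−αT_i}` being assigned to the root regime
(the root is assumed to sit at its regime's optimum, which removes a weakly
identified free parameter at moderate α). Rows of W sum to 1. The covariance
is the root-conditioned (non-stationary) OU matrix

    Cov(i,j) = σ²/(2α) · e^{−α(T_i+T_j−2t_ij)} · (1 − e^{−2α t_ij}),

which converges to σ² × shared path times as α → 0 and to independent tips
with variance σ²/(2α) as α → ∞. Both limits are regression-tested.
Polytomies are allowed; the formulas are topology-agnostic. Trees are
consumed in time units as given; an optional unit-height rescaling flag
exists purely for numerical conditioning and defaults to off.

## PGLS and phylogenetic ANCOVA (`mosaicbrain.pgls`)

PGLS is generalized least squares with residual covariance
σ²·λ-transform(C), fitted by Cholesky whitening on species means. The
Brownian matrix is pre-scaled to unit mean diagonal — a pure rescaling that
leaves estimates, tests, and the profiled log-likelihood unchanged (exactly
so on ultrametric trees) but puts the residual SD on the trait scale, which
Cohen's d requires. λ is profiled by bounded scalar search on [0, 1]
(tolerance 1e−6, endpoints checked, ties toward smaller λ), either on the
ML or the REML criterion:

- **ML λ** feeds AIC/AICc model selection, where the reported
  log-likelihood must be the maximized joint likelihood.
  AICc = AIC + 2p(p+1)/(n−p−1) with p counting coefficients, the residual
  variance, and λ when profiled; candidate models are ranked with a
  Δ cutoff of 2 ("distinguishable" flag).
- **REML λ** feeds the ANCOVA F-tests. ML-estimated λ noticeably inflated
  the type-I error of the nested F-tests at n = 32 (≈ 0.09 at nominal
  0.05 in a 500-replicate null calibration); REML restores ≈ 0.07/0.066,
  inside the calibration band asserted by the acceptance suite, and matches
  the convention of standard GLS software.

The phylogenetically corrected ANCOVA uses nested GLS model comparisons at
the full-model λ̂ (held fixed so the models remain comparable): the slope
test compares the full interaction model against the additive model; the
intercept test compares the additive model against the covariate-only
model; both are F-tests on whitened residual sums of squares with the
larger model's residual df. Pairwise post-hoc contrasts are computed only
when an omnibus test is significant and there are at least three groups:
slope contrasts from the interaction fit, intercept contrasts as
differences of adjusted means evaluated at the grand covariate mean from
the common-slope fit (the estimated-marginal-means convention), each a
t-test on the GLS coefficient covariance, Bonferroni-multiplied by the
number of pairs and capped at 1. Cohen's d is the adjusted-mean contrast
divided by the unbiased GLS residual SD of the common-slope model; other
residual-SD conventions exist in the literature, so d values are
comparable within, not across, software.

## Multiregime OU allometry and reversible-jump MCMC (`mosaicbrain.oumodel`)

The bivariate allometric model couples a response y (log10 brain mass) to a
predictor x (log10 body mass): regime r carries its own slope β_r and
intercept θ_r, and

    E[y_i] = Σ_r W_ir(α) (θ_r + β_r x_i),
    Cov    = OU(α, σ²) + diag(se_i²),

where se_i is the intraspecific standard error of the species mean
(species with one individual receive the mean SE across multi-individual
species). The likelihood is evaluated by Cholesky factorization with an
adaptive jitter up to 1e−8 × trace before declaring failure.

Priors: half-Cauchy(scale 0.1) on α and σ²; a Poisson(mean = 1% of branch
count) truncated at 5% of branches and renormalized on the shift count k,
with placements uniform over k-subsets of non-root branches; independent
normals on every β_r and θ_r. A helper derives empirical (μ, σ) slope and
intercept hyperpriors from a table of per-clade regression fits, with σ
rounded up to the next 0.1.

The reversible-jump sampler sweeps, per iteration: a log-scale multiplier
update of α, of σ², a Gaussian random-walk update of one regime's (β, θ),
and (with configurable probability) one trans-model move. Trans-model
moves are birth (add a shift on a uniformly chosen free branch, drawing its
β, θ from the prior, so the proposal density cancels the prior factor and
the Jacobian is 1), death (the reverse), or a symmetric relocation of an
existing shift to a uniformly chosen free branch. The relocation gate is
applied *before* inspecting k so that its probability cancels exactly in
the birth/death Hastings ratio — an asymmetric gate (relocation only
attempted when k > 0 inside the birth/death branch) breaks detailed balance
between k = 0 and k = 1 and was caught by the prior-recovery test. Shift
positions sit at a fixed relative position on the branch (default 0.5);
with placements uniform and the gate symmetric, the birth acceptance ratio
reduces to the likelihood ratio times the Poisson pmf ratio times a
boundary factor.

Chains are primed with trans-model moves disabled so continuous parameters
equilibrate at the initial k, then run with all moves; samples are thinned
and the first 30% of retained samples discarded as burn-in by default.
Parallel chains are seeded from a SeedSequence spawned off the master seed
and pooled after burn-in; an identical configuration reproduces bitwise
identical chains. Shift support is summarized as the per-branch fraction of
pooled samples containing a shift there, reported above a posterior
probability threshold (default 0.2) with conditional credible intervals for
that regime's β and θ. Effective sample sizes come from arviz; R̂ uses the
classic (non-rank-normalized) Gelman–Rubin form, since the separated-chain
diagnostic expectations are stated on that scale.

Two correctness checks go beyond unit oracles: (i) prior-only runs must
reproduce the truncated-Poisson k prior (χ² test on 1e5 thinned samples)
and the uniform placement distribution; (ii) on a 4-tip tree with k ≤ 1
the chain's visit frequencies across all shift configurations are compared
with the posterior obtained by *analytically* marginalizing (β, θ) — the
model is linear-Gaussian given (α, σ²) — and Monte-Carlo averaging over
the (α, σ²) prior.

Marginal likelihoods for fixed-shift hypothesis models (including the
degenerate single-allometry model and the intercept-only variant in which
all regimes share one slope) use stepping-stone sampling: a power schedule
at Beta(0.3, 1) quantiles (default 50 rungs ending at 1), per-rung MCMC
over the continuous parameters warm-started from the previous rung, 20% of
each rung discarded, and the log marginal likelihood assembled as
Σ_s logmeanexp((b_{s+1} − b_s)·loglik). The estimator is validated against
the closed-form marginal likelihood of a conjugate normal toy (within 0.1
log units at the default schedule). Model comparisons are reported as
2 ln BF.

## pPCA and pFDA (`mosaicbrain.multivar`)

Phylogenetic PCA eigen-decomposes the evolutionary covariance
R = (X−a)ᵀC⁻¹(X−a)/(n−1), where a is the GLS phylogenetic mean; species
scores are (X−a)E and individuals are projected with the same centering and
rotation. Covariance-mode pPCA on raw columns is the default, with a
correlation-mode flag and a z-score normalization helper (sample SD,
ddof = 1) for the normalized variant; the package does not presume whether
volumes should be logged first — both log and raw columns can be supplied,
and the pipeline's default uses log10 volumes, consistent with the
log-scale allometric analyses throughout. Eigenvector signs are fixed by
making each axis's largest-magnitude loading positive; eigenvalue ties
resolve by stable column order.

pFDA follows the two-step procedure: (1) for each λ on a grid (default
0–1, step 0.01) transform predictors and group-indicator matrix by the
inverse Cholesky factor of the λ-scaled phylogenetic *correlation* and
record the regression RSS; λ* is the argmin (ties toward smaller λ by scan
order). (2) At λ*, flexible discriminant analysis by optimal scoring:
regress indicators on whitened traits, eigen-decompose YᵀŶ in the
class-count metric restricted to the complement of the constant score
(yielding exactly g−1 axes), and classify by nearest group centroid in
discriminant space. At λ = 0 this reduces to ordinary FDA and agrees with
an independent optimal-scoring oracle and with LDA classifications on
Gaussian groups. The default pFDA input in the pipeline is the matrix of
per-region PGLS residuals against total brain size, so the discriminant
acts on size-adjusted regional composition.

## Synthetic data (`mosaicbrain.simulate`)

The generators define the validation conditions; their defaults are fixed
and are not tuned against test outcomes.

- **Trees**: forward birth–death simulation from the root split,
  conditioned on n surviving tips by rejection (cap 1e4 histories), with
  the present placed one further waiting time after the nth lineage
  appears so terminal branches have positive length. Pure-birth mean depth
  therefore equals Σ_{k=2..n} 1/(bk), which the suite checks.
- **Traits**: Brownian predictors are simulated branchwise; OU responses
  are drawn from the exact multivariate normal the likelihood evaluates
  (same W, same covariance), so moment-matching and likelihood-consistency
  tests close the loop between simulator and inference.
- **Region emulator**: 32 species in three phenotype groups (18/4/10 —
  non-electrosensory, ampullary-only, electrogenic), seven regions (OB,
  TEL, HB, OT, TS, CB, RoB) whose log10 volumes follow region-specific
  allometries against log10 total brain size (slopes 0.9–1.1, intercepts
  spreading realistic size fractions), group intercept offsets planted per
  (region, group), residuals with λ-structured phylogenetic covariance
  (default λ = 0.5, SD 0.05 log10 units), and body mass correlated with
  brain size. Groups are contiguous blocks in tip order, a deliberately
  crude clade-like assignment. Offsets of 0.1–0.3 log10 units emulate
  plausible mosaic effect sizes; they are synthetic settings, not
  estimates.
- **Replicates**: individual measurements add multiplicative log-normal
  noise of specified CV (default 3 individuals, CV 4%, the magnitude of a
  typical remeasurement QC bound), so species means and intraspecific SEs
  are recomputable and collapse to the species values as CV → 0.

What passing these tests shows: the estimators recover what they model,
at the planted effect sizes, under correctly specified covariance
structures. What they do not show: robustness to tree misspecification,
non-normal residuals, unmodeled measurement covariance, or taxon sampling
bias — none of which the emulator generates.

## Workflow conventions (`mosaicbrain.workflow`)

Trait tables are delimited text, one row per individual; volumes are
stored in mm³ and converted to cm³ before the density-based mass
conversion (default fixed-tissue density 1.32 g/cm³). All allometric
modeling uses base-10 logarithms of species means with intraspecific SE
carried alongside. Derived region-versus-remaining-brain columns (total
minus focal region) let the same ANCOVA code serve region-vs-brain and
region-vs-rest analyses. Rows missing body mass are excluded from models
that require it, with a logged count. The pipeline runner resolves stage
dependencies before any computation, writes every result as TSV, and
emits a provenance record (inputs, config hash, seed, package version)
sufficient to re-run deterministic stages identically.

## Problem sizes in the validation suite

The acceptance checks run at desk scale: oracle comparisons on 3–10-tip
fixtures; prior recovery from 5e5 prior-only iterations (1e5 retained
samples); ANCOVA calibration from 500 null replicates at n = 32; shift
recovery on a 64-tip tree with two 30k-iteration chains; region-ANCOVA
power from 200 emulator replicates; stepping-stone Bayes factors at 25
rungs × 1500 iterations on a 32-tip dataset. These sizes were chosen so
the full validation remains a coffee-break computation on one core while
every Monte-Carlo assertion retains comfortable statistical margins;
production analyses on hundreds of species should scale the chain lengths
and rung counts up (the samplers are O(n³) per covariance update but reuse
factorizations across moves that do not change α or σ²).

## Known limitations

- Single response trait in the OU module; no branch-specific α or σ².
- Shift positions are fixed at a configurable point on the branch rather
  than sampled.
- The post-hoc intercept comparison uses adjusted means at the grand
  covariate mean; raw-intercept comparisons would differ when slopes vary.
- pFDA classification is by nearest centroid in discriminant space;
  class priors and within-class covariance weighting are not applied.
- The stepping-stone sampler estimates each rung from the lower-power
  distribution only (no bidirectional bridge).
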