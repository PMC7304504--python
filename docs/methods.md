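# Methods

This note documents the models implemented in `cattletemp`, the choices made
where the published description leaves the design open, and what the
synthetic data do and do not establish.

## Synthetic herd generator

The generator exists because the study population (weaned beef calves scored
for temperament on subjective scales and a four-platform standing scale) is
not publicly available.  It produces data with the statistical structure the
downstream analysis assumes, so the whole chain is testable and its parameter
recovery measurable.

**Pedigree.**  Discrete generations; founders have unknown parents; each
mating draws a sire and dam (no selfing) from all previous generations.  The
pipeline default — 88 founders, 4 generations × 90 matings × 4 offspring =
1,528 animals — matches the study's number of recorded calves.  For
recovery experiments at the ~2,000-animal scale we use 240 matings × 2
offspring per generation: beef cows raise one calf per year, so large
full-sib families are unrealistic, and many smaller families carry more
information about genetic correlations.

**Breeding values.**  Gene dropping: founders draw `u ~ N(0, Σᵤ)`; an
offspring is the parent average plus a Mendelian-sampling deviation with
covariance `c·Σᵤ`, where `c = ½ − ¼(F_s + F_d)` with two known parents,
`¾ − ¼F` with one, and 1 with none (F = inbreeding coefficient from the
relationship matrix).  These coefficients make the joint covariance exactly
`Σᵤ ⊗ A`; the test suite verifies this against the tabular-method A on small
pedigrees by Monte Carlo.

**Genetic architecture defaults** (the five analysis traits are *difficult*,
*easy*, docility liability, SSD, CVSSD):

* heritabilities 0.40 / 0.40 / 0.28 / 0.20 / 0.20 — the published range
  (0.18–0.40) and ordering (factors > docility > movement scores);
* genetic correlations: the nine published posterior means
  (difficult–easy −0.92; DS with difficult/easy/SSD/CVSSD 0.36 / −0.31 /
  0.42 / 0.34; difficult with SSD/CVSSD 0.42 / 0.35; easy with SSD/CVSSD
  −0.40 / −0.35).  No point estimate exists for SSD–CVSSD (only that it is
  the largest positive correlation); the default is 0.95, configurable.  The
  assembled matrix is checked for positive definiteness and projected to the
  nearest correlation matrix if needed (the default set needs no projection);
* phenotypic variances 1 per trait; residual correlations 0 by default —
  the environmental correlation structure is not reported anywhere, so
  independence is the explicit, configurable default rather than a claim;
* fixed effects: 8 year-by-collection-date levels with evenly spaced effects
  spanning ±0.25 σ_P, a zero breed contrast, and a sex effect (0.2 σ_P) on
  CVSSD and *easy* only, mirroring the reported significance pattern.
  Effects are deliberately small relative to σ_P so that recovery exercises
  measure the genetic machinery, not fixed-effect handling.

**Observation scales.**  Factor scores are standardized and pushed through
the measurement model `T = ΛF + ε` with the reference loading pattern and
specific variances `1 − λ²`.  TS is cut into its 4 levels {1,2,4,5} at
quartiles; QBA attributes map to `68 + 22·z` mm clamped to the 136 mm line;
the docility score thresholds its liability into six equal-probability bins.
Latent SSD maps to `2.0 + 0.5·z` kg and CVSSD to `0.010 + 0.002·z`; the
implied standing weight is SSD/CVSSD (clipped to 80–500 kg), so the simulated
traces realize both movement scores coherently.

**Traces.**  An entry transient (linear ramp with 8%-of-weight spikes over
the first 5 s) followed by a stationary segment, iid Gaussian around the true
weight with SD equal to the target SSD; quadrant weights are a Dirichlet
decomposition of the total, so row sums are exact.

**What the generator does not emulate:** evaluator-to-evaluator scoring
variation (the study averaged ≥3 evaluators per method and analyzed the
averages), autocorrelated or drifting scale noise, missing records, genotypes,
and maternal effects.  Passing recovery tests therefore demonstrates that the
estimators are correct under the stated model, not that real data meet the
model's assumptions.

**Randomness.**  Every simulator accepts one seed; internally
`numpy.random.SeedSequence` spawning derives independent substreams per stage
(pedigree, breeding values, phenotypes, each trace, each MCMC chain), so any
dataset or run is bit-reproducible from (config, seed).

## FPSS scoring

The start point is the earliest record whose total weight is within
`weight_tolerance_kg` of the chute weight and whose look-ahead window of 5
records has all pairwise absolute differences within
`pairwise_tolerance_kg`, with at least 499 records remaining.  The protocol's
numeric tolerances are not published; defaults are 5% and 2% of the chute
weight, configurable, and recorded in every score object.  The implementation
is vectorized (sliding max − min equals the maximal pairwise difference) and
is property-tested against an exhaustive per-index scan.

Scores use the start point plus 499 subsequent records (500 total):
`SSD = sample SD (n−1)` of total weight — with 500 records the n vs n−1
distinction is ~0.1%, and the sample SD is conventional for an estimated
mean — and `CVSSD = SSD / window mean`.  QC flags (short trace, negative or
non-finite weights, no stable start) are advisory: the operator's issue log
did not influence record selection, so flags never alter the window.

## Exploratory factor analysis

Traits are z-scored, so the fit is correlation-based; the likelihood is the
standard Gaussian factor-analysis objective
`−(n/2)[t·log 2π + log det Σ + tr(Σ⁻¹S)]`, `Σ = ΛΛ′ + Ψ`.  (The printed form
of this likelihood in the source description contains two apparent
typographical slips — `nq/2` for `nt/2` and `log(T′Σ⁻¹T)` for `tr(Σ⁻¹S)`;
the standard objective is implemented and documented as such.)  Fitting runs
Rubin–Thayer EM to a 1e−8 log-likelihood tolerance, then an L-BFGS polish of
the Lawley profile likelihood over the uniquenesses; Heywood cases are
floored at 1e−6 with a warning.  The test suite cross-checks the achieved
likelihood against an independent EM implementation (scikit-learn's
`FactorAnalysis`).

Rotation defaults to oblimin (quartimin via oblique gradient projection):
the two temperament factors are expected to correlate, and the oblique family
matches the convention of the R tooling this analysis chain is usually run
with; varimax is available by flag.  The docility score is excluded from the
default EFA trait set — it is recorded under restraint, unlike every other
subjective measure — and can be added back with `include_ds` to reproduce the
low-loading check.

Parallel analysis uses 1,000 simulated null datasets (independent standard
normals at the observed n × t) and the 95th percentile by default, retaining
leading eigenvalues sequentially until the first non-exceedance.

The confirmatory structure assigns each trait to the factor with the largest
absolute loading; exact ties raise an error rather than being broken
silently.  Factors are labeled through anchor traits — the temperament score
anchors *difficult*, "calm" anchors *easy* — which also fixes signs, making
the structure invariant to the sign indeterminacy of the loadings.

## Bayesian confirmatory factor analysis

Gibbs sampler over (F, free Λ, Ψ, Φ) with conjugate updates; factor scores
are augmented data with the exact multivariate-normal conditional
`F_i | θ, t_i ~ N(MΛ′Ψ⁻¹t_i, M)`, `M = (Λ′Ψ⁻¹Λ + Φ⁻¹)⁻¹`.

Design choices where the description is open:

* **Loading prior** "N(0, 0.01)" is read as precision 0.01 (variance 100).
  A variance of 0.01 would shrink every loading to ~0 and is incompatible
  with the magnitude of the reported loadings; precision 0.01 matches the
  weakly-informative default (SD 10) of the Bayesian SEM software family
  this model is normally fit with.  Configurable; the interpretation is
  stamped into the diagnostics output.
* **Identification** is by the marker method: the anchor trait of each
  factor has its raw loading fixed at 1 and Φ is free, preserving conjugacy.
  Because the marker loading is positive, sign/label switching cannot occur.
  Standardized loadings are computed per draw as `λ·sd(F)/sd(T)` with the
  model-implied trait SD `√(λ²Φ_kk + ψ)`, which bounds them by 1.
* **Run length** "6,000 samples and 3,000 burn-in" is read as 6,000 total
  iterations with the first 3,000 discarded, per chain; 3 chains by default.
* **Monitoring**: PSRF (Brooks–Gelman form `√((n−1)/n + B/(nW))`) is
  computed for free loadings, Φ entries and specific variances — not the
  n × q factor scores.  Acceptance threshold 1.2.
* Traits are treated as continuous Gaussian after standardization (including
  the 4-level TS); an ordinal measurement model is out of scope.

Factor scores are summarized as the posterior mean of F over retained draws
and chains (running means; the n × q draws are not stored), and join the
phenotype table as the new *difficult* and *easy* traits.

## Multi-trait animal model

`Y = Xb + Zu + e` for the five analysis traits with
`(u, e) ~ N(0, blockdiag(Σᵤ ⊗ A, Σₑ ⊗ I))`; flat priors on fixed effects,
`IW(I, 5)` on both covariance matrices; defaults 10,000 iterations, 3,000
burn-in, thinning 5.  Unrecorded ancestors enter only through A: breeding
values are sampled for recorded animals with A's recorded-block — the
marginal of a multivariate Gaussian over dropped coordinates is the same
model, so nothing is lost.

**Sampling scheme.**  In the eigenbasis of A (`A = QDQ′`, computed once) the
full conditional of all breeding values factorizes over eigencomponents into
independent k-variate normals with precision `Σₑ⁻¹ + Σᵤ⁻¹/dᵢ`, so u is
redrawn exactly and jointly each iteration at O(n²k) cost.  This replaced a
per-trait blocked scheme: cycling traits conditionally mixes pathologically
slowly when genetic correlations approach ±1 (the chain sat at a biased
correlation for 20,000 iterations in testing), whereas the joint draw leaves
only the standard (u ↔ Σ) alternation.  Fixed effects are drawn from their
matrix-normal conditional `vec(B) ~ N(vec(B̂), Σₑ ⊗ (X′X)⁻¹)`;
`Σᵤ | u ~ IW(I + U′A⁻¹U, 5 + n)` and `Σₑ | e ~ IW(I + E′E, 5 + n)`.

**Prior–scale calibration.**  The identity-scale inverse-Wishart is only
weakly informative when the covariance it governs has entries of order 1.
The traits here differ in scale by orders of magnitude (CVSSD ~0.01 vs DS
~1–6), and even after z-scoring the additive variances are ~0.2–0.4, where
the prior's `tr(Σᵤ⁻¹)` term strongly penalizes high-correlation Σᵤ and
shrinks genetic correlations toward zero (verified by integrating u out of
the likelihood analytically: the marginal posterior itself sits at the
shrunk value, so this is a prior effect, not a sampler defect).  `fit_mtm`
therefore runs a short pilot chain, rescales each trait by its estimated
additive SD so additive variances are near 1, and then runs the main chain
with the stated `IW(I, 5)` prior.  Heritabilities and genetic correlations
are invariant to per-trait linear rescaling, so the calibration changes the
prior-data scale matching, not the estimand.  A residual effect remains for
near-singular correlation pairs: with the default architecture, the
SSD–CVSSD correlation (generated at 0.95, heritabilities 0.2) is posterior-
estimated around 0.80–0.85 at the ~2,000-animal scale.  It remains the
largest positive genetic correlation, but its numeric recovery is limited by
the stated prior, not by chain length.

Summaries are computed per retained draw — `h²ⱼ = σᵤⱼⱼ/(σᵤⱼⱼ+σₑⱼⱼ)` (one
record per animal, no permanent-environment term) and
`r = σᵤⱼₗ/√(σᵤⱼⱼσᵤₗₗ)` — never as transforms of posterior means.  Fixed
effects are declared significant when the 95% HPD interval (narrowest
sorted-window) excludes zero.  The relationship matrix uses the tabular
method with unknown parents as unrelated founders; dense A with one
eigendecomposition is ample at the ≤5,000-animal scale this package targets
(Henderson's sparse A⁻¹ machinery is a non-goal).

## Numerical details and degenerate inputs

* Relationship-matrix eigenvalues are floored at 1e−10 (jitter for
  numerically semi-definite A, e.g. duplicated full-sib rows).
* Inverse-Wishart draws use the Bartlett decomposition; `df ≥ dimension` is
  enforced.
* EFA requires a positive-definite sample correlation matrix and errors
  otherwise; `q = 0` returns the independent-Gaussian null model.
* The start-point search reports, on failure, the best candidate index and
  which criterion it failed (weight agreement vs look-ahead stability).
* HPD intervals require ≥100 draws; constant draws yield a degenerate
  interval.
* PSRF with zero within-chain variance returns `√((n−1)/n)` when the chains
  coincide and ∞ when they differ.

## Problem sizes used in the shipped checks

The test suite and acceptance script run study-sized analyses where that is
cheap (n = 1,528 factor models; 100-replicate parallel-analysis calibration)
and reduced-but-honest sizes elsewhere (a ~2,000-animal pedigree with a
4,000-iteration chain for the genetic model; tiny models for exact oracle
comparisons).  These sizes are the package's own verification design; all of
them are re-runnable with larger settings through the public APIs.

## Known limitations

* Gaussian treatment of ordinal/bounded traits (TS, DS, clamped QBA lines);
  threshold models are not implemented.
* No evaluator-effect modeling, maternal effects, genomic relationships, or
  REML alternative.
* Genetic correlations very close to ±1 are recovered with a conservative
  bias under the stated inverse-Wishart prior (see calibration note above).
* Dense linear algebra throughout: pedigrees beyond ~10⁴ animals need the
  sparse machinery this package deliberately omits.
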