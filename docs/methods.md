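# Methods

This note documents the models, estimators and numerical choices behind
`psycop`, in the order data flows through the pipeline.

## The profiling problem

A cohort of RFID-tagged mice passes through a behavioral battery — an
automated home cage recording corner visits, nosepokes and licks
(acclimatization, place learning, five serial reversals, a sucrose day),
a Y-maze session, acoustic startle with prepulses, open field, fear
conditioning and tail suspension.  Treatments form a 2×2 factorial: a
spironolactone-type factor S and an aripiprazole-type factor A, with a
double-placebo reference cell.  The analysis reduces each mouse to 19
behavioral variables organized by RDoC domain, tests each variable and the
joint profile for S, A and S×A effects, and summarizes treatment effects as
canonical discriminant profiles and placebo-centered Z-score fingerprints.

## Derived behavioral variables

* **Preference score** `(A − B)/(A + B)` ∈ [−1, 1] for sucrose licking
  (left sucrose vs right water bottles) and nocturnality (dark-phase vs
  light-phase visits).  Zero observations yield a missing value, not zero.
* **Chance-weighted place preference** `(A − B/3)/(A + B/3)`: with one
  correct and three incorrect corners, down-weighting incorrect visits by
  1/3 makes a uniform chooser score exactly 0 in expectation.
* **Learning criterion (SPRT)**: trials are visits with ≥1 nosepoke in a
  learning phase; correct = visit to the assigned corner.  The cumulative
  Bernoulli log-likelihood ratio of "learned" (p₁) against chance (p₀) is
  tracked and the criterion is the first trial where it reaches
  `ln((1−β)/α)` — a one-sided acceptance of H₁; sequences that never cross
  return the phase length, flagged censored.  Defaults p₀ = 0.25 (four
  corners), p₁ = 0.75, α = β = 0.05; all configurable.  The chance level is
  forced by apparatus geometry; the remaining parameters are conventional
  error bounds since the original platform's settings are not published.
* **Serial-reversal AUC**: trapezoidal sum of per-phase trials-to-criterion
  across the five reversals, `Σ (cᵢ + cᵢ₊₁)/2`; lower = faster
  re-learning.  First-reversal performance (RvL) is the criterion of
  reversal 1 alone.
* **Spontaneous alternation**: sliding 3-windows of arm entries; a window
  counts iff all three arms are distinct; denominator = entries − 2.
* **Activity**: per-visit instantaneous frequency 1/Δt (h⁻¹) relative to
  the previous visit; the activity score is its mean (a harmonic-type
  statistic, deliberately different from 1/mean-interval), the circadian
  profile its mean per 1-h clock bin pooled over days.  Computed on the
  acclimatization phase, where corner access is unconstrained.
* **PPI**: `100·(1 − mean(prepulse)/mean(baseline))` on trial means per
  prepulse level; negative values (facilitation) are retained.
* Open-field speed/center/rotation, freezing and immobility times are
  consumed as tracking-software summary numbers, not computed from video.

## Factorial inference

Type-2 sums of squares via nested model comparisons on sum-to-zero coded
design matrices: `SS(S|A)`, `SS(A|S)`, `SS(S×A|S,A)`, error from the full
model.  Effect coding is the standard choice for type-2 with interactions
in unbalanced designs.  Univariate tests drop mice with a missing value for
that variable only (listwise per variable), which is why error dfs differ
across variables; multivariate tests run on the imputed matrix.  The same
hypothesis/error SSP matrices feed the MANOVA (Wilks
Λ = det(E)/det(H+E), Rao's F approximation — exact for 1-df terms) and the
per-term CDA, which is why the decomposition is implemented in-package
rather than delegated (statsmodels serves as the oracle in the test suite).

P-values are Benjamini–Hochberg adjusted at FDR 0.1.  The adjustment family
is all variables within one model term (three families of 19); the original
analysis does not state its family composition, so this is a documented,
configurable default.  Simple-effects one-way ANOVAs (S within each A
level) are computed when the interaction survives FDR; the gate can be
disabled.

## Imputation

NIPALS principal components tolerate missing entries because every score
and loading update sums over observed cells only.  Missing cells are
replaced by the rank-k reconstruction (default k = 2, tol 1e−9) of the
column-standardized matrix, back-transformed; observed cells are never
touched.  Because the standardization statistics depend on the completed
matrix, the fill is iterated to its fixed point (re-estimate means/SDs,
refit, repeat ≤100 passes); at the fixed point an exactly rank-k matrix is
recovered exactly, which the tests exploit as an oracle.  Convergence of
each component is declared when either the score vector or the rank-1 fit
objective (residual sum of squares, relative change < tol) stabilizes: under
(near-)tied eigenvalues the component direction wanders inside the tied
subspace indefinitely while the reconstruction — all the imputation uses —
is long converged.  The imputation is
single-pass with respect to the downstream model: the completed matrix is
forwarded once, with no impute→refit EM loop around the MANOVA/CDA.

## Canonical discriminant analysis

Generalized eigenproblem `H v = λ E v`.  For the collapsed 4-group analysis
H is the between-group and E the pooled within-group scatter
(min(g−1, p) = 3 components); for the per-term analysis each term's type-2
H is tested against the shared full-model E (one component per 1-df term),
plus spironolactone-effect CDAs within each aripiprazole level.  Raw
coefficients are scaled so the within-group covariance of scores is the
identity; standardized coefficients multiply by the pooled within-group SD
per variable so heatmap weights are scale-free.  Eigenvector signs are
arbitrary, so a deterministic convention (largest-|coefficient| variable
positive) fixes them.  Component percentages are `100·λᵢ/Σλ` over all
retained components; canonical correlations are `√(λ/(1+λ))`.  Group
scatter in the dimension plot is drawn as Gaussian concentration ellipses
at the χ²(2) quantile of 75% coverage (a convex-hull-quantile construction
would be the alternative; the Gaussian ellipse is the standard choice and
matches a radius of √χ²₂(0.75) ≈ 1.665 on whitened scores).

## Z-score profiles and clustering

Each variable is standardized with the pooled mean/SD over all mice, group
means are taken per cell and the double-placebo row is subtracted, so
profiles read as treatment effects in pooled-SD units.  Group profiles are
clustered on Manhattan (L1) distance; the linkage method is not specified
by the original analysis, so the common heatmap-tool default (complete
linkage) is used, configurable.

## Synthetic cohorts

The generator's defaults are the study conditions: cell sizes 19/19/30/30
(Plc-Plc, Apz-Plc, Plc-Spl, Apz-Spl), a 12 h:12 h light cycle, and the
phase schedule 5 d acclimatization, 2 d place learning, 5×1 d reversals,
1 d sucrose.  Each mouse draws latent traits from population distributions
on transformed scales (log for rates, logit for probabilities); treatment
effects are additive shifts of the transformed means with sum-to-zero cell
codes, so a zero effect specification makes all four cells exchangeable.

* **Visit process**: inhomogeneous Poisson with intensity
  `λ(t) = base·(1 + amp·cos(2π(t − t_peak)/24 h))`, peak mid-dark-phase,
  realized by thinning.  Visits occupy the animal: approaches arriving
  before the current visit ends are discarded, so visits never overlap and
  the instantaneous-frequency statistic is well behaved.  Durations are
  10 s + exponential (mean 110 s); nosepokes per visit are 1 + Poisson(1).
* **Corner choice**: softmax over four delta-rule action values
  (`Q ← Q + α(r − Q)`), reward = door opening at the assigned corner in
  learning phases (every corner in free phases).  This is the minimal
  reinforcement-learning model that produces SPRT-reachable learning
  curves; the original study specifies no generative behavioral model, so
  all simulator choices are stand-ins whose contract is the statistical
  structure the analysis assumes (exchangeability under null, learnable
  under effect injection), not behavioral realism.
* **Startle**: lognormal (σ = 0.3) around the startle gain, multiplied by
  `1 − attenuation(level)` on prepulse trials; 10 trials per condition.
  The trial noise is kept moderate so the convexity bias of the PPI ratio
  estimator (≈cv²/n_trials) stays below 1 %, preserving the contract that
  zero attenuation gives expected PPI ≈ 0.
* **Freezing/immobility**: Beta draws (concentration 30) around propensity
  traits, scaled to the scored interval (120 s fear-conditioning windows,
  360 s tail suspension).
* **Session loss**: each out-of-home-cage test record is dropped with
  probability 0.06 per mouse, mimicking the varying per-variable ns of real
  batteries; home-cage event data stay complete.
* **Y-maze**: entries never repeat the current arm; with probability equal
  to the alternation-bias trait the entry completes a full alternation,
  giving an expected alternation rate (1 + bias)/2 ≈ 0.65 at the default
  bias 0.3.

Trait-population means (3 visits/h, 40 % mid-level PPI attenuation, 45 s
immobile fraction, etc.) were chosen once as plausible values for a male
C57-background cohort and are listed in `simulate._TRAIT_SPECS`.

What the simulator does **not** emulate: within-day non-circadian activity
structure (meals, bouts), corner side biases, social interactions in the
shared cage, drift or habituation across days, heavy-tailed startle
outliers, and any pharmacokinetics — treatment effects act directly on
latent traits.  Passing calibration therefore shows that the *inference
machinery* is correct under the assumed structure, not that the generator
reproduces real mouse behavior.

## Calibration studies and problem sizes

The calibration studies use two paths: a fast trial-sequence path
(identical choice model, no event timing) for per-variable studies, and the
full event pipeline for the multivariate check.  Replicate counts are 1000
cohorts for the univariate type-I error, 150 (acceptance script) / 60
(test suite) for the full-pipeline MANOVA type-I error, and 100 for power —
sizes chosen to keep each study's Monte-Carlo error small relative to the
binomial acceptance band while the whole suite remains quick to run.  The
power study injects a pure crossover interaction on the learning-rate trait
(logit shift 0.3), sized by pilot runs so detection power comfortably
exceeds 80 % and then frozen.

## Known limitations

* Rao's F is exact only for 1-df hypothesis terms (the 2×2 case used here)
  and p ≤ 2; other designs would make it approximate.
* The FDR family and the simple-effects gate follow documented defaults;
  other choices change which variables are starred, not the statistics.
* NIPALS components are extracted greedily with deflation; when singular
  values are nearly tied the individual components (and hence the split of
  variance between them) are not uniquely determined, although the fitted
  subspace and the imputation are.  True non-convergence raises with the
  last score delta rather than returning silently.
* With heavy missingness (rows or columns mostly empty) the rank-2
  reconstruction is a weak estimator; the imputer refuses only the fully
  empty case, so callers should watch per-variable ns in the diagnostics.
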