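# Methods

## Model and estimation

`ksirt` treats a subscale of J polytomous items (integer options
m = 1..M) as indicators of a single latent severity θ.  No parametric
response function is assumed; the estimation chain is:

**Rank-normal latent scores.**  Subjects are ranked by subscale summed
score with mid-ranks over ties and mapped through the standard-normal
quantile function, θ̂ᵢ = Φ⁻¹(rᵢ/(N+1)).  The divisor N+1 keeps quantiles
finite; tied summed scores share a latent score, and θ̂ is nondecreasing in
the summed score by construction.  Because θ̂ is a deterministic function of
ranks, its marginal law is standard normal regardless of the true severity
distribution — several numerical choices below rely on this.

**Kernel-smoothed option curves.**  Each option indicator is regressed on
θ̂ with a Nadaraya–Watson estimator using a standard Gaussian kernel on a
fixed grid (default 51 equally spaced points on [−3, 3]).  The default
bandwidth is h = 1.1·N^(−1/5) — the usual kernel-IRT convention for
standard-normal scores, N^(−1/5) being the one-dimensional optimal rate —
and is exposed as an override.  At N ≈ 3,600 this gives h ≈ 0.21.

**Derived curves.**  From the OCC matrix P[q, m]:

* ICC e(θ_q) = Σₘ m·P[q, m] and conditional variance
  v(θ_q) = Σₘ m²·P[q, m] − e².
* Expected subscale score T(θ_q) = Σⱼ eⱼ(θ_q), projected onto
  nondecreasing functions (pool-adjacent-violators via scikit-learn).  The
  projection only corrects sampling dips; linking requires a monotone T.
* Item information Iⱼ = (eⱼ′)²/vⱼ with derivatives by central differences
  (one-sided at the grid ends); where an item is degenerate (v = 0 forces a
  flat ICC) the information is defined as 0.  The subscale curve reports
  the average over items.
* Score density: a Gaussian KDE of θ̂ transformed to the expected-score
  axis by f_X(T(θ)) = f_θ(θ)/T′(θ) and renormalised (trapezoid) to
  integrate to 1 over the achievable range.  If T is flat on more than 20%
  of the grid the transform is refused with advice to widen the bandwidth.
* Summed-score standard error SE(θ) = √Σⱼ vⱼ(θ), the conditional standard
  deviation of the summed score treating items as locally independent given
  severity (for a 7-item PANSS subscale this sits near 3, matching the
  scale of clinical reports).  The latent-metric alternative 1/√(J·Ī) is
  available as `ksirt.kernel.irt_se`.

**Item diagnostics.**  The item–total correlation is the Pearson
correlation between the item score and the subscale summed score (the
field's "item biserial" label is nomenclature; items have 7 ordered levels,
so no dichotomous biserial formula applies).  The ICC slope is evaluated at
the median option crossing — see "Numerical choices" for the estimator.

## Operational item-selection criteria

Five criteria grade each item from its fitted curves; the published
procedure applied them by visual inspection, so the package declares
explicit operationalisations with tunable cut-offs
(`ksirt.criteria.CriteriaThresholds`):

1. **Options used** — the number of option levels reached by the ICC
   maximum (rounded half-up); Yes when ≥ 5 of 7.
2. **Rapid increase** — No when every non-extreme option stays below
   p_flat = 0.3 everywhere, or no option curve ever doubles from an earlier
   value; Yes when a majority of the non-lowest options reach half-maximum
   at or below the midpoint of the achievable expected-score range;
   Somewhat otherwise (rises confined above the midpoint).
3. **Region ordering** — modal regions (θ intervals where an option is the
   argmax) must be ordered with the option codes; an option with no modal
   region is a violation; Yes at 0 violations, Somewhat at 1–4, No at ≥ 5.
4. **Span** — an option is displaced when its support {P ≥ τ = 0.05} is
   empty, sits entirely above the 25th percentile of the expected-score
   range (two lowest options), or entirely below the 75th percentile (two
   highest options); No when ≥ 4 options are displaced.
5. **Slope** — ICC slope ≥ 0.40 at the median option.

**Global rule.**  Very Good with ≥ 4 Yes ratings, Good with exactly 3,
Weak otherwise; "Somewhat" carries no weight, and no single criterion is a
veto.  This is the unique simple Yes-count rule consistent with all 30
printed rating rows of the published PANSS evaluation (locked by a test),
including a retained item with a No on criterion 5 and the remark that an
item was kept because ≥ 3 criteria were Yes.  The short form keeps exactly
the non-Weak items, preserving subscale grouping; a subscale losing all its
items is an error.

**Where curves are judged.**  Criteria 1–4 are evaluated on the central
99% of the latent axis (|θ| ≤ Φ⁻¹(0.995) ≈ 2.58; `theta_trim = 0.005`).
Rank-normal scores are standard normal by construction, so beyond that band
a grid point is supported by a handful of subjects (≈ 7 effective subjects
at θ = 3 for N = 3,000) and the curve estimates there are pure noise.  The
trim bounds are fixed quantiles of a known distribution, not data-dependent
tuning.

## Synthetic-data generator

The generator is the logistic graded response model: item j has
discrimination a and strictly increasing cumulative thresholds b₂ ≤ … ≤ b_M
with P(X ≥ m | θ) = L(a(θ − bₘ)).  It produces the ordered, unimodal-region
option geometry of a well-behaved rating item and closed-form oracle curves
for recovery tests.  Defaults emulate a schizophrenia-trial baseline:

* severity skew-normal with shape 4, standardised to mean 0 and variance 1
  (right-skewed: very severe patients are rarer);
* 30 items × 7 options in subscales of 7/7/16; sound items draw
  a ∈ [1.0, 1.8] with thresholds spanning roughly [−2, 2] except a top
  threshold at 3.0–3.8, so the extreme option is rarely rated;
* configurable pathological archetypes: *ideal* (a = 1.8, thresholds
  equally spaced on [−2, 2]), *flat* (a = 0.1, thresholds spanning [−6, 6] —
  every option curve low and nearly level on the observable range),
  *ceiling_compressed* (top threshold 3.8: the extreme option is
  essentially never used), *range_restricted* (a = 0.4, thresholds 1–5:
  rarely endorsed beyond the low options), and *disordered_regions*
  (near-coincident interior thresholds: interior options are dominated
  everywhere by their neighbours).
* demographics (age, gender, diagnosis, race) drawn independently of
  severity, with trial-like frequencies.

One master seed drives everything; per-stage child seeds are spawned
deterministically, so cohorts, covariates and splits are independently
reproducible.

What the generator does **not** emulate: rater effects and inter-site
variation, longitudinal structure, treatment arms, covariate–severity
dependence, and item residual correlations beyond the single factor.
Passing recovery and classification tests on these cohorts therefore shows
the estimator and decision rules work where a single latent severity truly
generates the data; they do not certify behaviour under multidimensionality
or rater drift.

A known property of the classical ranking deserves emphasis: each item
contributes to the summed score it is judged against.  For a genuinely
uninformative item inside a 7-item subscale this self-contribution inflates
the apparent discrimination (the item's own variance enters cov(x, T)), so
simulated items with near-zero true severity correlation can still grade
Good in the end-to-end pipeline.  The archetype validation harness
(`ksirt.criteria.classify_archetype`) therefore scores candidate items
against an anchor set of seven ideal items, the candidate excluded from the
ranking; under that design ideal items grade Very Good and flat items Weak
across seeds.  Real weak items — which retain moderate item–total
correlations — sit between these extremes.

## Numerical choices

* **Slope estimator.**  A raw one- or two-point difference of the smoothed
  ICC at a single grid point has standard error ≈ 0.2 at N = 3,000
  (h ≈ 0.22), which is the same order as the 0.40 decision cut.  The slope
  is therefore a local least-squares fit of e on θ over a ±1.0 window
  centred at the median-option crossing, weighted by the standard-normal
  density so sparse edge points contribute negligibly; the crossing itself
  is searched within the central 95% of scores.  The estimator is exact for
  linear ICCs and zero for curves symmetric about the crossing, and its
  noise is an order of magnitude smaller than the pointwise difference.
* **Rounding.**  Criterion-1 option counts and conversion-table cells use
  round-half-up, matching integer table cells.
* **Inversion of T.**  Linear interpolation between bracketing grid
  points; flat segments invert to their midpoint (deterministic); scores
  outside the achievable range clamp to the nearer endpoint with a warning.
* **Conversion tables** span the integers from ⌈min T_short⌉ to
  ⌊max T_short⌋ — data-dependent, like published conversion tables.
* **Degenerate inputs.**  Constant items yield NaN item–total correlations
  and zero information; empty post-cleaning tables, unordered thresholds,
  non-positive-definite correlation matrices and grid mismatches raise
  errors naming the offending object.
* **Splitting.**  The evaluation half receives ⌊N/2⌋ subjects and the
  validation half ⌈N/2⌉ (for N = 7,187: 3,593 and 3,594), by seeded
  permutation.
* **Cleaning.**  Listwise deletion only: rows with a non-whitelisted
  diagnosis (checked first, tallied per diagnosis value) or any missing
  item score are dropped; kernel IRT needs complete summed scores, and
  reported tallies make the precedence auditable.

## Classical statistics

Unidimensionality uses the eigenvalue-ratio rule on the unrotated PCA of
the Pearson item correlation matrix: unidimensional when λ₁/λ₂ ≥ 3 (ratio
reported to 3 decimals; the inclusive cut makes verdicts deterministic —
a published short-form ratio of 3.005 reads Yes).  Polychoric correlations
are deliberately not the default; the printed eigenvalues match
correlation-matrix PCA.  Bartlett's sphericity statistic
−(N−1−(2p+5)/6)·ln det R with p(p−1)/2 df, the KMO sampling-adequacy index
from the anti-image partial correlations, and Cronbach's
α = k/(k−1)·(1 − Σ item variances / variance of sum) are computed from
their closed forms.  Subsample comparisons use the pooled-variance t test
(df = N₁+N₂−2) with Cohen's d and chi-square tests with Cramér's V.

## Pipeline roles

The end-to-end pipeline cleans, splits once by seed, evaluates items and
fits all curves on the *evaluation* half, selects the short form, refits
the short form on the evaluation half (by default re-ranking from the
short form's own summed scores; a flag reuses the full-form ranks by
summing the retained items' ICCs from the full fit), and measures
reliability, long-vs-short correlations and linking bias on the held-out
*validation* half.  All outputs are TSV/JSON plus an optional markdown
report; plots are conveniences, never inputs to decisions.

## Known limitations

* The latent metric is defined by within-sample ranks, so curves from
  different cohorts are comparable only through their expected-score
  functions, not through θ itself.
* Self-inclusion bias of the classical ranking (above) flatters very weak
  items in short subscales; use anchor or rest scoring when candidate items
  are suspect.
* Kernel estimates at |θ| > 2.5 rest on few subjects; curves there are
  reported but excluded from decisions.
* Linking assumes both forms are fitted on the same population and that T
  is strictly increasing after projection; severely flat subscales degrade
  the interpolation.
* No differential item functioning, rater effects, or parametric IRT
  fitting; the graded response model is a generator and oracle only.
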