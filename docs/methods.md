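# Methods

## Model

Each survey domain is scored under a unidimensional graded response
model (GRM).  For an item with K ordered categories, the cumulative
("boundary") probabilities are logistic in the latent trait θ,

    P(X ≥ k+1 | θ) = logistic(a·θ + c_k),    k = 1..K−1,

with discrimination a > 0 and strictly decreasing intercepts
c_1 > … > c_{K−1}; category probabilities are adjacent differences.
Thresholds b_k = −c_k/a give the trait level at which boundary k is
crossed with probability one half.  All probabilities are on the pure
logistic metric.  The scaling constant D = 1.702 is used only to convert
a slope to a normal-ogive standardized loading,
λ = (a/D)/√(1+(a/D)²); outputs are labelled accordingly, since printed
slope/intercept values in the applied literature are conventionally on
the logistic metric.

Domains are calibrated one at a time even though the traits are strongly
correlated across domains.  A full five-dimensional correlated-factor
fit would require 5-D quadrature, which is not desk-scale; instead the
synthetic data are generated with the full correlated-trait structure,
calibration is per-domain, and inter-domain correlations are recovered
from EAP scores with a disattenuation correction (below).  This is an
approximation to a multidimensional factor correlation, and reports
label it as such.

## Calibration (Bock–Aitkin EM)

Marginal maximum likelihood with the trait integrated over a fixed
rectangular grid: 49 equally spaced nodes on [−6, 6] with normal-density
weights renormalized to sum to 1.  Defaults: parameter-change tolerance
1e−4, at most 500 cycles.  The E-step computes each observed response
pattern's posterior over the grid (patterns are deduplicated, so cost
scales with distinct patterns, not respondents); the M-step maximizes
the expected complete-data multinomial log-likelihood per item by
L-BFGS-B on the reparameterization (log a, c_1, log(c_k − c_{k+1})),
which enforces a > 0 and intercept ordering by construction, with
analytic gradients.  Start values are a = 1 and intercepts from the
inverse logistic of observed cumulative category frequencies; an
optional seed jitters the start for multi-start checks.

An M-step update (item or group) is accepted only if it improves its
expected objective, so the algorithm is a generalized EM and the
marginal log-likelihood trace is nondecreasing (the suite checks this to
1e−8).  Non-convergence within the cycle budget returns a result flagged
`converged=False` with a warning, never silently.

Multigroup estimation shares item parameters and gives each group its
own latent N(μ_g, σ_g²); the largest group is the reference, fixed at
N(0, 1), for identification (ties broken by label order).  The group
M-step maximizes the expected log prior mass of the *renormalized
discrete* prior on the grid in (μ, log σ) numerically, warm-started at
the posterior moments; using the exact discrete objective (rather than
the moment update alone) is what makes the ascent property hold exactly
on the quadrature approximation.

Categories never observed in the calibration sample are collapsed into
the adjacent category with a warning, and the recode map is stored in
the result so scoring and fit apply it consistently; an item left with
fewer than two observed categories is an error.

Standard errors come from the empirical cross-product (BHHH) estimator:
per-respondent scores of the marginal log-likelihood by central finite
differences, with steps clipped to half the distance to the nearest
constraint boundary (slope positivity, intercept ordering, σ > 0) so
boundary solutions — e.g. a slope driven to ~0 by a reverse-keyed item —
remain differentiable.  A singular information matrix reports the
affected parameters as unavailable rather than fabricating values.

## Scoring

EAP scores are posterior means over the same grid, with the respondent's
group prior when a multigroup calibration is supplied and the standard
normal otherwise; the posterior SD is reported alongside.  Scores are in
trait-SD units; a 2-dp rounded column is also reported, and only the
unique-value counting uses the rounded column — all other downstream
statistics use the unrounded values.  Doubling the grid (49 → 97 nodes)
moves EAPs by less than 1e−6 on the test battery, so 49 nodes are kept
as the default.

The summed-score table is built by the Lord–Wingersky recursion: at each
node the distribution of the raw-code total (n_items..Σ K_j) is
accumulated item by item, then mixed over the prior to give P(s),
EAP(s), and the posterior SD given s.  On two-item instruments the table
matches exhaustive enumeration of all 25 patterns to 1e−12.

Monotonicity of EAP(s) in s is *not* a theorem for the GRM: with
strongly heterogeneous slopes (ratios beyond ~3) the conversion table
can genuinely dip (a verified counterexample with slopes 1.95 vs 0.55
shows a −0.04 decrease, stable under a 2001-point grid).  On
instrument-like item sets — slopes in [1.0, 2.5], five categories,
realistic threshold layouts — no violation was found in 500 random
draws, and the test battery asserts monotonicity on that band.  Users
building conversion tables for instruments with extreme slope spread
should inspect the table.

The 0–100 reporting transform maps [−5, 5] linearly to [0, 100] by
default (clipped); the bounds are configurable and recorded with the
output.  It is cosmetic: any strictly increasing affine map preserves
correlations and orderings.

## Goodness of fit

Full-information chi-square statistics are unusable here — the
contingency table of a 30-item 5-category instrument is astronomically
sparse — so fit uses the limited-information M2 family on univariate and
bivariate margins.  The implementation uses the *full* (uncollapsed)
margins: categories 1..K−1 per item, s = Σ(K_j−1) + Σ_{i<j}(K_i−1)(K_j−1)
entries.  With e the residual between observed and model-implied
margins, Ξ the margins' asymptotic covariance under the model, and Δ the
Jacobian of implied margins in the q free parameters,

    M2 = n · e′ [Ξ⁻¹ − Ξ⁻¹Δ(Δ′Ξ⁻¹Δ)⁻¹Δ′Ξ⁻¹] e,    df = s − q,

asymptotically chi-square for ML estimates.  Numerically the statistic
is evaluated in orthogonal-complement form — whiten by the
eigendecomposition of Ξ (eigenvalues below a 1e−12 relative threshold
dropped), project out the whitened Jacobian column span — which is
nonnegative by construction.  Ξ is assembled analytically from the
item-independence structure given θ (shared-item entries handled by
category-match/divide rules), and Δ by central finite differences with
the same boundary-respecting steps as above; both choices favor
correctness over speed at desk-scale n.  On correctly specified
simulations the statistic is well calibrated (p ≈ uniform; df = 155 for
five 5-category items with 25 free parameters).

RMSEA = √max(0, (M2 − df)/(df·n)); NNFI compares M2/df against an
independence baseline (all slopes zero, intercepts equal to the observed
margins' inverse logistics, df_b = s − Σ(K_j−1)).  M2 is implemented for
single-group calibrations; multigroup M2 is out of scope.

Marginal reliability is 1 − mean(posterior SD²) under a unit-variance
prior; inter-domain correlations are Pearson correlations of EAP scores,
with the disattenuated variant ρ_ij/√(rel_i·rel_j), capped at |1|.  EAP
shrinkage makes raw correlations understate latent ones, and on
simulations with a known latent correlation of 0.85 the disattenuated
estimate recovers it to within ±0.05 at n = 10,000.

## Synthetic data

The generator emulates a national SAQ-C administration: 30 items in five
domains (5/6/5/10/4 items), 5-point responses, four hospital-level
groups with shares (0.447, 0.364, 0.153, 0.036), correlated domain
traits, and completely-at-random missingness in item cells and in the
group label.  Defaults, chosen once as realistic study conditions:

- **Item slopes** uniform on [1.0, 2.5], covering the 1.5–2.3 band
  well-calibrated safety-survey items occupy.
- **Thresholds** from the base layout (−3.1, −2.2, −1.3, 0.2) with ±0.3
  uniform jitter per item (minimum gap 0.25), i.e. agreement-heavy
  responding: most category switches lie well below the trait mean, so
  first intercepts c_1 = −a·b_1 fall roughly in 3–8.
- **Group latent distributions**: means (0, −0.1, −0.2, −0.3), SDs
  (1.0, 0.95, 1.05, 0.9) — modest separations by hospital level; no
  published group-level latent differences exist for this instrument, so
  tests treat these as arbitrary, not reference values.
- **Inter-domain correlations** uniform in [0.75, 0.91], shrunk toward
  the 0.83 equicorrelation matrix only if needed for positive
  definiteness; one shared matrix across groups.
- **Missingness** 0.005 per item cell and 0.04 for the group label,
  excluding roughly a sixth of questionnaires under listwise filtering —
  the same order as large voluntary administrations.

Randomness is split into four independent streams (labels, traits,
responses, missingness) from one seed, so toggling missingness leaves
the drawn responses bit-identical.  The generator does **not** emulate
response styles (acquiescence, straightlining), informative missingness,
item-parameter drift across administrations, or clustering of
respondents within hospitals; passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Test design and problem sizes

Oracles are independent of the code paths they check: summed-score
tables against brute-force pattern enumeration; EAP against a
10,001-point quadrature; correlations against the two-pass textbook
formula; M2 df against direct margin counting; implied margins against
large-sample Monte-Carlo frequencies.

Simulation-based checks use sizes chosen to make the assertions sharp
while keeping the suite fast: parameter recovery at n = 2,000 on a
five-item domain with moderate truth (slopes 1.0–2.0, centered
thresholds), where ±0.15 on slopes and ±0.25 on intercepts correspond to
roughly 2–3 standard errors — with agreement-heavy thresholds the first
intercept's SE at this n is ~0.3 and such tolerances would be
unattainable for any estimator; fit-index calibration at n = 10,000;
a 40-replicate type-I-error check on a small three-item instrument; and
the mean-vs-IRT resolution contrast on a collected-scale run (45,242
simulated questionnaires, ≈37,400 analyzed after filtering), where the
2-dp EAP column yields 11–16× the unique values of the mean rubric in
every domain and the between-method correlation exceeds 0.95.

## Known limitations

- Per-domain unidimensional calibration; no full-information
  multidimensional estimation, cross-loadings, or multigroup M2.
- The Metropolis–Hastings Robbins–Monro estimator, a faster alternative
  for very large or multidimensional models, is not implemented; the EM
  route was chosen because it underpins the limited-information fit
  statistics.
- Collapsed-margin M2 variants are not implemented (the collapsing rules
  are additional modelling degrees of freedom); fit uses the full
  margins, which needs n comfortably above the margin count.
- EAP scores are shrunken; between-person comparisons at very short
  domain lengths inherit that shrinkage, and the summed-score conversion
  discards pattern information beyond the total.
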