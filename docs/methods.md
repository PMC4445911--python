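# Methods

## The model

`tradepgls` analyses a cross-species response (here the natural log of a
species' sale price) against species traits while accounting for the
non-independence of related species. The model is generalized least
squares with a phylogenetically structured error:

    y = Xβ + ε,    ε ~ N(0, σ² V(λ))

where V is the phylogenetic variance–covariance matrix — entry (i, j) is
the branch length shared by tips i and j from the root to their most
recent common ancestor, the Brownian-motion expectation of trait
covariance — and Pagel's λ ∈ [0, 1] multiplies the off-diagonal of V.
λ = 1 leaves full Brownian signal; λ = 0 erases shared history, reducing
the model to (variance-weighted) independent species. λ is estimated
from the data rather than assumed.

For fixed λ, β and σ² have closed-form ML estimates, so λ is found by
maximizing the profile log-likelihood

    ℓ(λ) = −½ [ n ln 2π + n ln(RSS_W / n) + ln det W + n ],   W = V(λ),

with RSS_W the residual sum of squares after Cholesky whitening by W.
All solves go through the Cholesky factor; no explicit inverse is
formed, and the whitened-QR solution is checked in tests against a dense
normal-equations oracle.

## Estimation details and conventions

- **λ optimizer.** A 21-point coarse grid over [0, 1] locates the basin,
  then a bounded Brent search refines to `xatol = 1e-6`, with explicit
  endpoint checks at λ = 0 and 1 (the maximum often sits on a boundary).
  λ is bounded to [0, 1] for interpretability; no extension to the
  algebraic feasible maximum is attempted.
- **Standard errors and t tests** use the unbiased residual variance
  RSS_W/(n − k) with df = n − k (k = number of regression coefficients,
  intercept included). Multi-level factors additionally get an
  extra-sum-of-squares F test in the whitened metric at the model's λ̂.
- **r²** is 1 − RSS_W/TSS_W, where TSS_W is the residual sum of squares
  of the intercept-only model in the *same* whitened metric (at the
  fitted λ); adjusted r² applies the usual (n−1)/(n−k) correction. There
  is no unique r² for GLS; this convention is recorded in each fit's
  metadata.
- **AICc** uses K = k + 2: every estimated quantity is counted — the k
  coefficients plus σ² plus λ (λ is re-estimated by ML inside every
  submodel, so it is a genuine parameter of each). Rankings are
  insensitive to the +2 offset because all compared models carry it.
- **ML, not REML.** A single ML λ per model keeps likelihoods comparable
  across submodels with different fixed effects, which REML likelihoods
  are not. An REML switch would only be meaningful for variance-component
  reporting, not for the AICc model comparison done here.
- **Complete cases** are fixed by the *global* predictor set before
  enumeration, so all 2^m submodels share one n; information criteria
  are incomparable otherwise. Univariate fits use their own complete
  cases and report their effective n.
- **Ties** in AICc are broken by fewer parameters, then lexicographic
  term list, making rankings deterministic.
- **Percentiles** across trees (median, 5th, 95th) use linear
  interpolation (numpy's default), unit-tested against a hand-computed
  five-value case.
- **Degenerate inputs.** Perfect fits (RSS → 0) return +∞ profile
  likelihood and are reported with r² = 1 rather than erroring; rank
  deficiency raises an error naming the offending column; a tree missing
  more than all-but-one of the table's species fails that tree's fit,
  which ensemble drivers record and skip with a disclosed failure count.

## Multi-model inference

All 2^m subsets of the predictor blocks are fitted (multi-level factors
enter or leave as a block; a guard refuses m > 20). ΔAICc, Akaike
weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), per-predictor importance (the
summed weight of models containing the predictor), and model-averaged
coefficients follow. Conditional (natural) averaging — weights
renormalized over the models containing a term — is primary because
downstream reporting presents per-model coefficients and term-wise
importances; the full average (absent term counts as β = 0) is emitted
alongside, since the two answer different questions. The candidate set
keeps models with ΔAICc strictly below a threshold (default 4).

For the univariate colour screens, significance is judged against a
Bonferroni-adjusted level α/m with m = 11 (one test per colour family),
α = 0.05 by default.

## Tree-ensemble procedure

Phylogenies are never known exactly, so analyses repeat over a sample of
plausible trees: by default 100 trees for univariate models, 10 for the
all-subsets dredge (which is ~2^m times more expensive per tree), and
100 for refitting the candidate set. Candidate selection uses the median
ΔAICc across the small tree sample (a union-across-trees mode exists
behind a flag). Refitting re-ranks the candidates within each tree,
yielding per-tree weights, importances and ranks; everything is
summarized as median [5th, 95th percentile] across trees, plus tallies
of how often each model ranked 1st/2nd/3rd. Tree subsampling from a
larger file is a seeded uniform draw without replacement; the seed is
embedded in every output.

## The synthetic generator

`synthetic` produces the study conditions every test runs under:

- **Trees** are pure-birth (Yule) simulations — the simplest branching
  model with realistic imbalance — rescaled to unit height so λ and σ²
  are comparable across runs; birth rate defaults to 1. Tree uncertainty
  is emulated by multiplying each branch by a lognormal(0, 0.08) jitter:
  topology fixed, divergence times wobbling.
- **Traits**: body mass evolves as Brownian motion on the tree (masses
  around 55 g, lognormal spread ~1.2 on the log scale); counts for sale
  are heavy-tailed lognormal integers clipped to [1, 7420]; breeding
  ranges lognormal around 2×10⁶ km²; CITES listing ~25%, threatened IUCN
  ~15%; native/alien status is clade-blocked (grown from random internal
  nodes to ~55% aliens, with 5% leakage) because alien availability is
  phylogenetically clumped in real markets; song-recording counts follow
  a log-linear regression on range size whose residual is the
  song-attractiveness predictor; colour sheets are binary 14-part ×
  11-colour draws (~3 parts per colour on average, every part at least
  one colour), with optional coverage boosts for colours that carry
  signal.
- **Response**: ln price = Xβ + ε with ε ~ N(0, σ² V(λ)) via Cholesky.
  Default generating effects: strong abundance (−0.5) and mass (+0.6)
  effects, a status effect (+0.5 toward aliens), and a weak song effect
  (−0.1), with λ = 0.9 and σ² = 0.3 — strong phylogenetic signal as
  comparative price data show. Critically, the design columns are
  derived from the *stored* raw values (integer counts, realized song
  counts), so re-ingesting the emitted CSV reproduces the generating
  model exactly and round-trip recovery is a fair test of the estimator,
  not of rounding noise.

What the generator does not emulate: real surveys have missing values
with informative patterns, taxonomy mismatches between table and trees,
non-lognormal price clumps (price points), topological (not just
branch-length) tree uncertainty, and colour scores with strong
inter-colour correlation. Passing recovery tests therefore demonstrates
estimator correctness under the model's own assumptions, not robustness
to survey messiness.

## Recovery experiments (the validation surface)

- **Parameter recovery** (`validation.lambda_recovery_experiment`): 100
  datasets, each on a fresh 300-tip Yule tree, generated with λ = 0.9,
  σ² = 0.5, β = (2, −0.1, 0.6) for intercept, log-counts and log-mass;
  refit by the full pipeline. The medians of λ̂ and each β̂ recover the
  truth (λ̂ median within [0.85, 0.95]; β̂ medians within 5%).
- **Selection recovery** (`validation.selection_recovery_experiment`):
  50 datasets at 150 tips where *every* pool predictor carries a strong
  effect, dredged over all 16 submodels. The generating (full) model is
  expected to rank first nearly always and its terms to reach importance
  ≈ 1. The design deliberately gives all predictors signal: AICc admits
  a truly-null predictor with probability ≈ 0.14 per term (the χ²₁ tail
  beyond the ~2.1-unit penalty), so a dominance criterion is only
  well-posed when no null predictors are in the pool; the experiment
  tests that models *omitting* real effects are decisively rejected,
  which is the property multi-model inference is used for here.

Problem sizes (100 × 300 tips; 50 × 16 models × 150 tips) were chosen so
medians are stable to the third decimal across seeds while the whole
suite stays interactive (~1 minute).

## Known limitations

- λ is profiled by a 1-D search; joint κ/δ transformations,
  Ornstein–Uhlenbeck models, measurement error and phylogenetic logistic
  regression are out of scope.
- The across-tree [5th, 95th] interval quantifies sensitivity to the
  tree sample, not sampling error of β̂; it has no frequentist coverage
  guarantee and should not be read as a confidence interval.
- r² for GLS is convention-dependent (see above); values are not
  comparable across packages using other conventions.
- Colour scoring consumes a pre-scored presence sheet; no image
  processing is attempted, and body parts are equally weighted (the
  "body surface" coverage is parts-based, not area-based).
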