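# Methods

## Data model

Counts are long-format tables keyed by (area, year, stratum) with the 16
strata formed by sex (men/women), race (white/non-white) and age group
(40–59, 60–69, 70–79, 80+).  Reading validates invariants (events ≤
population, non-negativity, unique keys, one region per area) and
zero-fills the complete area × period × stratum grid, so downstream code
can assume rectangular arrays.  Upstream extraction — e.g. restricting a
hospitalization registry to ischemic-heart-disease codes I20–I25 — is a
documented contract on the input file, not something the package performs:
registry dialects vary and the analysis only needs the aggregated table.

Municipality size classes use the population intervals [0, 25 000) =
small, [25 000, 100 000] = medium, (100 000, ∞) = large; the boundary
convention follows the verbal definition ("<25", "25–100", ">100"
thousand) with no gaps or overlaps.  Size class is assessed once from the
supplied total population (a per-year reassessment would be a trivial
extension but introduces label churn for areas near a boundary).  A
missing covariate is a hard error; no imputation rule is offered.

## Indirect standardization

Reference rates are internal: one pooled rate per stratum over all areas
and all periods, `r_s = Σ events / Σ population`.  This makes the
conservation identity `Σ_it E_it = Σ_it O_it` hold globally, so the
all-area SIR is exactly 1 and area ratios are interpretable as relative
deviations.  A year-specific reference (pooling within year) is available
behind a flag; it conserves totals within each year instead.  A stratum
that is empty everywhere (zero population and zero events — routine in
sparse toy tables under the zero-fill contract) receives rate 0, since it
cannot contribute to any expected count; a strict mode turns this into an
error.  Ratios aggregate by summing numerators and denominators before
dividing — the mean of area ratios is biased for small expected counts —
and 0/0 is reported as missing, never as 0, to keep "no population at
risk" distinct from "no events".

## The risk model

Likelihood: `O_it ~ Poisson(E_it θ_it)` with
`log θ_it = α + x_i'β + u_i + v_i + (β_t + δ_i) t`, `t` the 0-based year
index scaled to [0, 1] (a bounded time scale keeps the slope prior's
meaning independent of the number of periods).  Cells with `E_it = 0`
(zero population) carry no likelihood; a positive count with zero expected
is rejected as a data error.

Priors.  `u` is intrinsic CAR over the contiguity graph: precision
`τ_u (D − A)`, improper, identified by a per-component sum-to-zero
constraint.  `v_i ~ N(0, 1/τ_v)` iid.  Slope deviations `δ` take the same
ICAR structure by default (spatially smooth differential trends), with an
iid option; which of the two the motivating analysis used is not
verifiable from its public text, so both are first-class and the choice is
a config field.  Precisions carry Gamma(1, 0.0005) hyperpriors (the
long-tailed historical default family for this model class); fixed effects
carry vague N(0, 100²) priors.  The default "classic" variant uses `Q`
as-is; the "scaled" variant multiplies the prior precision of `u` by the
graph's scaling factor (geometric mean of the constrained-ICAR marginal
variances, computed per connected component by dense eigendecomposition,
feasible to ~2 000 areas) so that `1/τ_u` is the typical marginal variance.

Contiguity defaults to queen (shared boundary point); rook is an option.
Isolated areas form singleton components whose structured effect is fixed
at 0 — their deviation is absorbed by `v` — and the constraint and rank
bookkeeping count components accordingly.

## Sampler

Metropolis-within-Gibbs, all randomness from one seed via spawned
per-chain substreams (default 4 chains × 10 000 iterations, 5 000 burn-in,
thin 5; every test and script states its own reduced sizes):

* Precisions: conjugate Gamma updates (`rank(Q)/2` degrees of freedom for
  ICAR fields, `n/2` for iid fields).
* Latent fields: single-site Gaussian random walks with per-site step
  sizes adapted toward 0.44 acceptance during burn-in
  (Roberts–Rosenthal batching).  Sites are updated in graph-coloring
  classes: within a class no two areas are neighbors, so the ICAR prior
  makes the updates conditionally independent and they vectorize.
* Fixed effects `(α, β)`: two joint random-walk proposals per sweep — one
  shaped by the Poisson GLM covariance (computed once by an IRLS fit that
  also initializes the chains), one adaptive-Metropolis proposal whose
  covariance is learned from the burn-in history and floored by the GLM
  covariance so the adaptation cannot collapse.  Scales target 0.234.
* Interweaving moves: shifting `β_k` by `d` while subtracting `d·x_k`
  from `v` leaves every linear predictor unchanged, so the
  Metropolis ratio involves only the priors.  One such move per
  coefficient per sweep (and one trading `β_t` against iid `δ`)
  decorrelates the fixed effects from the latent fields — without them the
  β chains mix an order of magnitude slower and credibility intervals are
  materially too narrow.
* Identifiability: after each sweep `u` (and ICAR `δ`) are re-centered to
  per-component mean zero, transferring the removed level to the intercept
  (or the shared slope).  For a connected graph this is exactly
  likelihood-invariant; for multi-component graphs it is the standard
  car.normal-style approximation.  All adaptation freezes at the end of
  burn-in, so post-burn-in draws target a fixed kernel and runs are
  seed-reproducible bit for bit.

Stored per kept draw: fixed effects, latent fields, precisions, and the
pointwise log-likelihood over positive-expectation cells (the WAIC input);
the per-cell relative risk `θ_it` accumulates as a running posterior mean.
Split-R̂ and effective sample size come from arviz; any monitored scalar
with R̂ above 1.1 raises a warning flag on the result rather than failing
silently.

WAIC is the deviance-scale form `−2 Σ_obs [log mean_draws(likelihood) −
var_draws(log-likelihood)]` with the sample-variance penalty (zero for a
single draw).  Marginal likelihood is deliberately not computed: stable
estimation from MCMC output is unreliable, and WAIC is the supported
criterion.

Significance of a coefficient is exactly the shared-sign rule on the
equal-tailed 95% interval — not a posterior-probability threshold — and
the reported relative risk is `exp(posterior mean)`.

The VIF screen regresses each covariate on the others under the working
weights (fitted means) of a Poisson GLM with the log-expected offset;
`VIF = 1/(1 − R²_weighted)`, covariates above 5 are dropped iteratively
(largest first; a perfectly collinear covariate has infinite VIF and the
later-listed member of the set goes first, with a warning).

## Synthetic generator

One seed determines everything.  Areas live on an `nrows × ncols` lattice
of unit squares (queen contiguity) or on a supplied graph; regions are
contiguous chunks of about 20 areas.  Total populations are log-normal
(median 8 700, log-sd 1.2 — giving roughly the 80/15/5 small/medium/large
split typical of Brazilian states) and are split across strata with fixed
shares (age 68/18/10/4%, sexes near-even, 70/30 white/non-white).
Baseline stratum rates default to an ischemic-heart-disease-like shape
(fourfold age gradient, male excess, ~0.4%/year baseline) — the magnitudes
are arbitrary and only the structure matters.  The development index is
Uniform(0.3, 0.9); default true effects are ipdm −2.0, small 1.0, medium
0.5, trend 0.3, with precisions τ_u = 4, τ_v = 16, τ_δ = 25.  `u` and `δ`
are drawn exactly from the constrained ICAR via the pseudo-inverse square
root of each component block.  Counts are Poisson with mean
`n_its r_s θ_it`, clipped at the stratum population to respect the data
model (astronomically rare at these rates).  The reference
parameter-recovery scenario uses a 20 × 10 lattice (200 areas, close to a
399-municipality state at half scale) with a strong small-municipality
effect of 3.3 on the log scale (RR ≈ 27).

What the generator does not emulate: real geographies (polygon shapes are
unit squares), demographic drift over time (stratum populations are
constant across years), registry artifacts (under-reporting, duplicate
records, cross-border care seeking), and covariates that are spatially
autocorrelated.  Passing recovery tests therefore demonstrate correctness
of the inference machinery under the model's own assumptions, not
robustness to the ways real registry data violate them; the iid
development index in particular makes covariate/latent-field confounding
milder than it would be for a spatially smooth real index.

## Numerical choices and degenerate inputs

Problem sizes in the test and acceptance suites are chosen to exercise the
statistics at desk scale: 100-area scenarios with single-to-double reduced
chains (2 × 4 000 iterations) for the 20-scenario coverage sweep, 2 × 4 000
for the 200-area recovery fit, 100 replicates of a 25-area no-latent model
for null calibration.  Conservation is checked to 1e-9 relative, the ICAR
quadratic form to 1e-10, cached versus recomputed log-likelihoods to 1e-8,
and the sum-to-zero constraint to 1e-8.  Empty graphs, empty draw vectors,
zero-population scenarios, all-zero rates, 0/0 ratios and singleton
components all have defined behavior and tests.

## Known limitations

* Coverage of the 95% intervals in the reduced-chain sweep runs a few
  points below nominal (≈85% against the ≥80% acceptance floor): the
  β–latent-field geometry still limits effective sample sizes at a few
  thousand iterations.  Longer chains move it toward nominal.
* Re-centering on multi-component graphs perturbs the likelihood slightly
  (exact only for connected graphs); singleton islands are handled, but a
  graph of several large components with a single intercept is better fit
  per component.
* The scaling-factor computation is dense per component and not intended
  beyond ~2 000 areas.
* Inference approximates the posterior by MCMC; results carry Monte-Carlo
  error and are only reproducible for a fixed seed, chain count and
  platform.
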