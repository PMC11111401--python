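# Methods

This note documents the statistical machinery in `paleoresil`, the
choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Calibration and aggregation

A conventional radiocarbon age (CRA) `m ± σ_lab` is calibrated against
a curve giving the expected 14C age `µ(t)` and curve uncertainty
`σ_c(t)` per calendar year `t`: the calibrated mass at `t` is the
Gaussian density of `m` at mean `µ(t)` with variance `σ_lab² + σ_c(t)²`,
evaluated on a 1-year grid. Curves are read from comma-separated
IntCal-style `.14c` files (first three columns cal BP / 14C age / 1σ;
`#` comments) and resampled to an annual grid by linear interpolation of
both the mean and the uncertainty — the convention of standard
calibration software; published curves do not prescribe an
interpolation rule. Densities are **not normalized** in the pipeline
(normalization is a flag used where proper probability masses are
needed, e.g. highest-density intervals at the conventional 95.4%
level), and mass below 10⁻⁷ of the per-date peak is truncated to bound
each density's support.

Dates from one site whose CRAs lie within 50 14C years are pooled by
complete-linkage hierarchical clustering cut at height 50, so every
pair of CRAs in a bin is within the threshold. The regional SPD is the
sum over bins of the per-year *mean* of member densities, restricted to
the model bounds `[a, b]`. Binning damps between-site sampling-intensity
bias, but it is not neutral: where dated events are dense (typically
the young end of a growing population), more of them collide into
shared bins, which flattens the SPD and biases a growth-rate fit on
heavily multi-dated sites downward. With realistic site structure
(~2–3 dates per site, the synthetic generator's default) the effect is
negligible; it is worth knowing about when a few sites contribute many
dates.

All calendar grids are descending cal BP (oldest first); intervals are
closed `[start, end]` with `start ≥ end` in BP.

## Growth model and MCMC

The null model for the calendar age of a dated event is the bounded
exponential `f(t) = r·e^{r(a−t)} / (e^{r(a−b)} − 1)` on `[b, a]`, with
the uniform limit at `r = 0` (used below |r| = 10⁻¹²; the density is
continuous there to < 10⁻⁶). Bounds are fixed per region; only `r` is
sampled. The per-bin likelihood marginalizes calendar age on the annual
grid against the bin-averaged measurement density — the same averaging
unit as the SPD — and the log-likelihood sums over bins. A bin whose
marginal is zero yields −∞ with a diagnostic naming it.

The sampler is random-walk Metropolis with reflection at zero
(equivalent to sampling |r| under a symmetric proposal), under an
exponential prior on `r ≥ 0` with rate 2500 (mean 4·10⁻⁴ per year) — a
weakly informative prior over plausible annual growth rates,
configurable, with an optional symmetric two-sided (Laplace) variant
for exploratory fits where decline is plausible. The proposal scale
adapts every 50 iterations during burn-in toward an acceptance rate in
[0.2, 0.5] and is frozen afterwards, so the retained draws come from a
fixed kernel satisfying detailed balance. Chains start at independent
prior draws. Default settings are 3 chains × 50,000 iterations,
burn-in 5,000, thinning 2; the tests and the acceptance script use
reduced chains (3 × 2,000–5,000) — problem sizes chosen so that each
check completes in seconds to a couple of minutes while still leaving
Monte-Carlo error well inside the asserted tolerances. Convergence is
reported as rank-normalized split R-hat and bulk effective sample size
(via ArviZ). A chain whose post-burn-in acceptance falls below 1%
raises a diagnostic error rather than returning silently.

Regions with documented demographic transitions can be split at
breakpoints: each bin is assigned to a segment by the calendar year of
its density mode (ties go to the older segment) and each segment is
fitted independently; downturns overlapping a breakpoint (± a
configurable margin, default 0) are dropped as potential artefacts of
the subsetting.

## Downturn detection

Each posterior-predictive replicate draws `r` from the pooled posterior,
simulates as many calendar years from `f` as the observed data have
*bins* (the SPD's effective sampling unit), back-calibrates each with a
lab error resampled with replacement from the observed errors, calibrates,
and sums. Pointwise (1−level)/2 and 1−(1−level)/2 quantiles over
replicates (default level 0.90, 1,000 replicates; 200 in the reduced
test configuration) form the envelope. A downturn is a maximal run of
years with observed SPD *strictly* below the lower quantile, longer
than 10 years; its landmarks are the SPD at the first sub-envelope year
(`b` — the alternative convention, the last year above the envelope,
would shift `b` by one grid step), the run minimum (`x`, oldest year on
ties), and the SPD at the last sub-envelope year (`e`).

Two properties of this procedure matter for interpretation. First, it
is *pointwise*: under the null about 5% of years fall below the lower
band, and because the SPD is serially correlated over roughly the
calibration-kernel width (~2× the typical lab error), those years clump
into a small number of short spurious runs — about two per couple of
millennia of record in the test conditions — rather than scattering as
isolated years. Consumers should treat short, shallow downturns with
corresponding caution; the >10-year filter removes only the shortest.
Second, the envelope is slightly conservative, because replicates are
built from single dates rather than bin-averaged groups and because
posterior uncertainty in `r` widens the band.

## Resilience metrics

Per downturn: resistance `1 − 2|b−x|/(|b| + |b−x|)`, resilience
`2|b−x|/(|b−x| + |b−e|) − 1`, pace `time-to-minimum / duration`, and a
per-downturn frequency: for the k-th downturn of a region (oldest
first), `k / (region start − T_end_k) × 1000` events per millennium,
log-transformed with the natural log (standardized coefficients make
the base immaterial). The elapsed-time denominator — from the region's
older bound to the k-th downturn's end — is one of several readings of
"cumulative number normalized by duration"; it is implemented as the
package convention and is configurable at the call site by passing a
different `region_start`. Resilience is undefined when `x = b` (no
drop); such rows are retained with the value marked missing and are
excluded listwise from resilience models. Events with these metrics are
joined to annotation tables (disturbance category/type, land use,
change flag) on region and start year within a ±10-year tolerance.

## Statistical synthesis

Descriptives: medians overall and by category/region/type, duration
classes (≤50, 50–100, 100–500, >500 years), adjusted Fisher–Pearson
skewness, Shapiro–Wilk normality of pace, one-way ANOVA of resistance
and resilience across disturbance categories with η² = SS_between /
SS_total. Mixed models are random-intercept linear models fitted by
REML through statsmodels MixedLM, with gradient-free optimizer
fallbacks for the near-singular fits that arise when the random
variance approaches zero. Standardized coefficients come from refitting
on the z-scored response and z-scored continuous predictors. Stepwise
selection is forward, on marginal (ML) AIC — an adequate stand-in for
conditional AIC when the question is which terms survive — with the
region intercept always retained; the selected model is refitted by
REML. The frequency model regresses log-frequency on land use
(hunter-gatherer reference level), change, disturbance type, and pace;
land-use levels with fewer than two rows are merged into "mixed" with a
warning.

## Synthetic data

The generator draws each region's calendar years from the bounded
exponential reshaped by multiplicative bust deflections, then
back-calibrates with per-assay lab errors (Gaussian, truncated at ≥ 10
years — tighter assays are rare in practice) and assigns dates to sites
round-robin. Two bust shapes are available: a V (linear decline to
`1 − depth` at the midpoint, linear recovery to
`1 − depth + depth·recovery`), whose landmarks are available in closed
form for metric-recovery tests, and a boxcar (full depth across the
interval, sharp onset and offset), used where the *timing* of a
downturn must be recoverable — a tapered edge is intrinsically
undetectable until its deflection clears the envelope, so V-shaped
busts cannot pin both endpoints to ±50 years and boxcar busts can.
`generate_study` builds multi-region cross-sections in which a land-use
class multiplies the regional bust rate by a known factor, and a
downturn-level table derived from the generating truth (with mild
multiplicative observation noise) for exercising the synthesis stage
without the cost of per-region detection.

What passing these tests shows: the estimator recovers the generating
growth rate, the envelope's false-alarm rate is at or below nominal,
sharp injected downturns are found and timed correctly, and the mixed
models recover built-in effects of known size. What they do not show:
robustness to taphonomic loss, spatially structured sampling, research
bias in which sites get dated, calibration-curve plateaus, or downturn
shapes unlike the injected ones — real compilations contain all of
these.

## Numerical choices and limitations

* Truncation of calibrated densities at 10⁻⁷ of peak bounds support;
  well below measurement precision.
* Strict inequality defines "below the envelope"; years exactly on the
  lower bound break runs.
* The >10-year duration filter is exclusive (a run spanning exactly 10
  years is discarded).
* Seeds: all stochastic stages take explicit seeds; the study pipeline
  splits its global seed per region and stage with counter-keyed
  `SeedSequence`s, so adding a region does not perturb the others'
  draws.
* The MCMC explores a single scalar; no attempt is made at model
  comparison (logistic nulls, WAIC/LOO) or hierarchical pooling across
  regions.
* Marine reservoir corrections, ΔR offsets, mixed-curve calibration,
  and SPD smoothing are out of scope.
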