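# Methods

This note documents the statistical model the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details a user
re-running or extending the analyses should know.

## Observation model and pre-processing

Survey observations arrive as age-specific prevalence estimates with
instrument metadata. Pre-processing converts them into binomial pairs
`(y_it, N_it)`:

* **Effective sample size.** If a design-adjusted confidence interval is
  reported, `N_it` is the sample size whose Wilson 95% upper limit at the
  observed prevalence reproduces the reported upper limit (solved by
  bisection to 1e−9 on `n`; no continuity correction; the upper limit is
  used even when the interval is asymmetric). Failing that, a reported
  standard error gives `N_it = p(1−p)/SE²`. Otherwise the raw denominator
  is divided by a default design effect of 2.5 (a typical median for
  complex household surveys; configurable).
* **Counts.** `y_it = round(prevalence × N_it)`, clamped to
  `[0, round(N_it)]`. Rounding to the nearest integer is the
  minimal-distortion way to form a binomial count from a design-adjusted
  prevalence; the induced error is below `1/(2 N_it)`.
* **Denominator imputation.** Missing age-specific denominators are
  allocated proportionally to the country's (or, failing that, region's)
  2010 female age distribution, preserving the study total. Studies with
  no sample size at all get 3,000 (national) or 1,000 (sub-national).
* **Metadata.** Missing end years fall back to the publication year;
  missing upper ages become open-ended bands (sentinel 999 at the I/O
  boundary, folded into the 65+ grid cell internally).
* **Two datasets.** The *adjustment* dataset keeps the broadest age band
  per study × instrument combination (ties broken toward the lower age
  bound) and feeds the crosswalk. The *modeling* dataset keeps one
  gold-standard-preferred observation per study/outcome/age-stratum
  (preference order: all severity ≻ severe-only; physical and/or sexual ≻
  physical-only ≻ sexual-only; ever-partnered ≻ all women ≻ currently
  partnered; any partner ≻ current/most recent), drops urban/rural strata
  when a national estimate exists, and keeps the most granular
  non-overlapping bands (greedy by width; equal-width partial overlaps
  raise an error rather than guess).

## Crosswalk adjustment factors

Estimated outside the main regression to avoid compositional bias.
Within each survey, observations carrying one non-reference covariate are
exactly matched to a reference observation identical on all other
Table-style matching keys (including the identical age band — the
adjustment dataset holds broadest bands, so this is a survey-level
contrast). When several references match, the one closest to the gold
standard wins (fewest non-reference fields, then the preference order
above). Each pair yields a log odds ratio and the usual
`√(1/a+1/b+1/c+1/d)` standard error (0.5 continuity correction on zero
cells). Pairs are pooled by DerSimonian–Laird random-effects
meta-analysis per super-region and overall; a super-region factor is used
only when more than three pairs inform it. Negative DL heterogeneity is
truncated at zero (equivalently, the fixed-effect pool is used there).
Factors for severity, physical-only, sexual-only, and all-women contrasts
are structurally bounded at the null (a subset definition cannot raise
prevalence): point estimates are clamped at 0 and sampled from normals
truncated above at 0.

Urban/rural factors use only surveys reporting national, urban *and*
rural strata, pooled by a mixed logistic model (survey random intercepts,
super-region-varying urban/rural slopes) fitted by penalized
quasi-likelihood — no installed Python library fits grouped-binomial
GLMMs directly, so the PQL iteration (penalized Newton inner loop,
moment-based variance updates) is implemented here. With fewer than two
qualifying surveys a pooled fixed-effect 2×2 contrast is used instead.

Adjustment uncertainty propagates by Latin-hypercube sampling D = 10
full adjustment vectors (truncated-normal marginals for bounded factors),
refitting the model per vector, and mixing all posterior draws with equal
weight. The all-women factor for past-year outcomes reuses the lifetime
factor when past-year matches are absent.

## The hierarchical model

Binomial likelihood with logit link; five nested intercept levels
(world, super-region, region, country, study); hierarchical natural cubic
spline coefficients for the age pattern (knot candidates at single ages
20/25/30/35 or pairs 20+35, 20+40, 25+35, 25+40; chosen by WAIC with DIC
reported; default single knot at 25) and the time trend (one knot at
2011). Ages above 65 are recoded to 65 before basis evaluation, so the
age pattern is flat for 65+. The age basis is evaluated at 5-year band
midpoints (17, 22, …, 62, 65) and centered at age 30; the time basis is
centered at its knot. Basis columns are rescaled to unit maximum absolute
value over the grid — a linear reparametrization that keeps coefficients
O(1) (the raw truncated-power cubic terms reach 10³).

Priors: `N(0, 1000)` (variance 1000, SD ≈ 31.6 — the BUGS-family
precision convention read as variance) on the global intercept and global
spline coefficients; half-Cauchy(0, 25) on every hierarchy SD. The
study-level SD is `σ_n` for nationally representative studies and
`σ_n + τ` for sub-national ones, so sub-national studies are never less
variable. Mixed urban/rural sub-national strata take the sub-national
variance class but no geographic adjustment indicator (only pure urban or
rural strata are crosswalked).

Wide age bands are age-standardized inside the likelihood: `p_it` is the
region-2010-population-weighted mean of the inverse-logit over the bands
covered. Single-band observations reduce to the plain inverse-logit.

## Sampling

The posterior is sampled by an adaptive Metropolis-within-Gibbs scheme
designed for this likelihood:

* every unit-level block (study/country/region/super-region effects, and
  the per-unit spline coefficient vectors) is proposed jointly and
  accepted *per unit* — valid because units partition the observations
  and their priors are conditionally independent;
* variance hyper-parameters alternate centered updates (MH on log σ given
  the effects) with non-centered joint scaling moves that multiply σ and
  its effects together (the prior normalization and Jacobian cancel,
  leaving likelihood × half-Cauchy × c) — the interweaving is what
  traverses the funnel that otherwise traps σ near zero;
* likelihood-invariant translation moves shift mass between adjacent
  hierarchy levels (e.g. region vs country), whose individual values are
  only prior-identified while their sums are data-identified.

Proposal scales adapt only during the adaptation phase (target acceptance
0.44 scalar / 0.30 vector), so retained draws come from a fixed kernel.
Chains are seeded independently; runs are bit-reproducible for a fixed
seed and library stack.

Two run profiles: the **paper profile** (4 chains × 50,000 iterations
after 10,000 adaptation, 5,000 warm-up, thinning 20 → 2,250 retained per
chain) mirrors the full analysis; the **desk profile** (2 chains × 4,000
iterations, 1,000 adaptation, 1,000 warm-up, thinning 2) is sized so the
complete synthetic workflow — both outcomes on a 7-super-region /
21-region / 40-country database — fits in a couple of minutes on one CPU.
Desk-scale chains do not reach the paper profile's ESS ≥ 1,000 bar on the
slowest-mixing identified quantities; diagnostics report this honestly
rather than hiding it, and the desk-scale checks are calibrated on
quantities (country prevalence surfaces) whose coverage is empirically
nominal at that chain length.

Convergence is monitored on *identified* quantities — country-level
intercept sums, fitted prevalences, and the SDs — because the individual
levels (`u_g` vs `u_z` …) trade off freely under diffuse priors and their
split-R̂ would flag a non-problem.

## Constraints

Past-year prevalence cannot exceed lifetime prevalence, and among 15–19
year-olds the lifetime-to-past-year ratio is capped at 3 (girls that
young have had little differential exposure time). The two outcomes are
fitted as parallel meta-regressions and coupled at prediction: draw pairs
violating either constraint at any constrained cell are rejected jointly.
By default constraints apply to countries informed by a single recall
period (and imputed countries) — applying them at every country would
reject nearly all draws whenever two well-identified posteriors overlap,
which is neither needed nor intended. An acceptance rate below 1% raises
an error as a misfit signal.

## Post-processing

Country predictions exclude study effects and instrument offsets (they
are estimates for the reference instrument). Countries without data draw
a fresh intercept from `N(0, σ_c)` per posterior draw (default); a "full"
mode also draws fresh country-level age/time spline deviations.
Broad-age and higher-level aggregates weight age-specific prevalence by
the 2018 female population multiplied by the proportion of women who have
ever had sex (the proxy for ever-partnered denominators), summing implied
counts across countries — which makes aggregation order-invariant.
Reported summaries are posterior medians with equal-tailed 95% credible
intervals.

## Validation

Posterior predictive checks replicate each observation from
`Binomial(p_it, N_it)` on its own instrument scale (study effect and X
offset included). In-sample metrics follow the "error = observed −
predicted" convention in percentage points: median error, median absolute
error, and the share of observations below/above the 95% interval
(credible interval of `p_it` by default; predictive-interval mode
available). Out-of-sample validation refits after excluding 20% of
countries (stratified so no region empties) or 20% of studies, predicts
the held-out observations — country mode through regional imputation,
study mode through the country's prediction — at the observation's own
instrument scale, and reports medians across 20 repeats by default.

## The synthetic-data generator

The generator draws from exactly the model family above: hierarchical
normal effects, spline age/time surfaces, per-study instruments with
injected adjustment odds ratios (defaults echo reported real-data
magnitudes: lifetime prevalence ≈ 27%, past-year ≈ 13%, physical-only OR
0.86, sexual-only 0.26, severe-only 0.38, urban 0.92, rural 1.08; small
between-survey heterogeneity SD 0.03 on the log-OR scale), binomial
sampling at design-deflated effective sizes, and missingness (5% of
studies lack denominators; 30% report design-adjusted CIs). Outcome
surfaces for lifetime and past-year are correlated (ρ = 0.8) so the
ordering constraint is realistic. Three profiles: `tiny` (2 regions / 6
countries) for unit tests, `desk` (7 / 21 / 40) for integration and
recovery runs, `paperlike` (≈300 studies, ≈1,500–1,900 age-specific rows
per outcome, ≈43% of rows needing no adjustment — inside the 41–54% range
real databases show). Dual-instrument reporting (40% of non-reference
studies also publish reference-instrument rows) and a 5% sexual-only
study share are fixed generator defaults chosen so every adjustment
dimension is informed by matched pairs at paperlike scale.

What the generator does **not** emulate: non-binomial overdispersion
beyond the design effect, instrument effects that vary by age, reporting
or disclosure bias, non-random survey placement, and real country
identities. Passing recovery tests therefore demonstrates internal
consistency of the estimator under its own assumptions — not robustness
to the additional misspecification real data carry.

## Numerical details and limitations

* Standardized prevalences are clipped to `(1e−12, 1−1e−12)` before the
  binomial log-pmf; `N_it` is rounded to an integer for the pmf.
* WAIC uses the pointwise binomial log-likelihood of the modeling dataset
  (standardized `p`); DIC is `2·D̄ − D(θ̄)` with `θ̄` the posterior mean.
  Spline selection takes the lowest WAIC, ties (within 0.01) toward fewer
  knots.
* The Wilson inversion brackets `n ∈ [1, 10 × n_reported]`; an
  unbracketable interval falls back to the design-effect rule with a
  logged warning.
* Observations requiring an adjustment factor that could not be estimated
  (no matched pairs anywhere) cannot enter the model; the pipeline
  excludes them with a warning, and building offsets for them directly
  raises.
* The mixture-over-adjustment-vectors step drops sub-fits whose worst
  split-R̂ exceeds a coarse 1.5 screen (desk-scale appropriate; tighten
  for paper-profile runs) and errors if fewer than half survive.
* Desk-scale problem sizes used throughout the test-suite and
  reproduction script: 40-country databases, 2 × 4,000-iteration chains,
  50 crosswalk replications, D = 5 mixture fits at 0.3× chain length.
  These sizes were chosen so the whole suite runs on a single CPU in
  minutes while leaving the checks statistically meaningful.
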