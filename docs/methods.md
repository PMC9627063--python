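# Methods

`ecofingerprint` implements a regional climate-fingerprint analysis for
natural-history-collection data: many heterogeneous, decades-to-centuries-long
records (herbarium sheets, survey counts, occurrence records) are reduced to
annual ecological response series, regressed on year and on mean annual
temperature, pooled across taxa, and examined for changes of trajectory that
may — or may not — coincide with changes in the temperature trend itself.
This note describes the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## From records to annual responses

**Occurrence filtering.** Distribution series are built only from presence
records with full binomial names inside a fixed year window (default
1900–2020), from taxa whose records span at least 50 years, and from
taxon-years with at least five records — a minimum-sampling-effort rule, since
a single stray record says little about a range edge. The rules are applied
in that fixed order; order matters (the span rule is evaluated before the
per-year count rule) and is part of the contract. For marine collections,
taxon-years whose record latitudes span less than 0.4° are additionally
removed: many marine taxa were sampled from one station in a year, which
would fabricate range stability. The comparison is strict (`< 0.4°` removed)
with a 1e-9 guard for floating-point representation of the threshold.

**Binomial canonicalization.** Authorship and infraspecific ranks are
stripped; genus is capitalized, epithet lower-cased. A one-token name, a
placeholder epithet (`sp.`, `cf.`), or a title-case/dotted second token
(authorship) fails the binomial requirement.

**Dates.** Event dates must be full ISO-8601 dates. A bare year is enough
for distribution work (an opt-in flag keeps such records, carrying
`event_date=None`), but never for phenology, where the response *is* the
date. Day-of-year uses the real calendar — leap years give Feb 29 = 60 —
because phenological trends of a few days per century would be distorted by
365-day normalization.

**Peak flowering.** For each taxon, the peak-intensity threshold is the 0.75
empirical quantile of *all* its flowering-intensity scores, zeros included —
zeros are legitimate scores, and excluding them would shift every threshold
upward. A specimen is at peak when its intensity is at or above the
threshold (ties count). The annual response is the earliest day-of-year among
peak specimens; taxa with fewer than 10 qualifying years are excluded.
Quantiles everywhere use the linear-interpolation convention at position
1 + (n−1)q ("type 7"), the numpy default, so the intensity threshold and the
leading-edge percentile share one definition.

**Leading edge.** The annual 0.9 quantile of a taxon's record latitudes — a
range-edge proxy a single extreme locality cannot dominate.

**Abundance and richness.** Abundance: taxa with fewer than 100 observations
across all sites are dropped ("observation" defaults to one table row; a
count column can be designated instead, since source tables differ in what
they call an observation); annual value = mean density over that year's
samples. Richness: replicate richness = distinct taxa in the replicate;
station-year value = maximum over all replicates of all that year's visits
(visits are not distinguished when collapsing — the maximum is over
everything the year produced). The sampling method rides along as a per-year
categorical covariate; a station-year mixing two methods is refused as
ambiguous rather than silently averaged.

## Trends and pooling

Each unit (taxon or station) gets an OLS slope of its annual response on
calendar year, or on the same calendar year's mean annual temperature (no
lag; a lag would be a configurable extension). Method covariates enter as
dummy-coded fixed effects, no interactions. Standard errors are the usual
residual-variance formula.

Pooling is an **unweighted fixed-effects meta-analysis**: pooled estimate =
arithmetic mean of the slopes, SE = √(Σ se_i²)/k, CI = pooled ± 1.96·SE.
Unweighted because the units are different taxa, not replicate estimates of
one parameter; inverse-variance weights would let the best-sampled species
define the regional signal. The alternative empirical SE (sd of slopes/√k)
is available via `se_mode="empirical"` and reported alongside when asked;
it answers a different question (dispersion of true slopes, not sampling
noise of the mean).

For cross-response synthesis, slopes are recomputed on z-scored responses and
log-absolute-transformed (natural log; the base only shifts the synthesis
slope by a constant factor). The synthesis regression is OLS of that
magnitude on dataset duration, pooled and within response kinds; responses
with zero variance or standardized slopes below 1e-12 are excluded with a
warning, as their magnitude is numerical noise.

## Segmented regression

The broken-line model y = a + bx + Σ β_k (x−ψ_k)₊ is fit by the
gap-variable linearization: at the current ψ, OLS on
[1, x, (x−ψ_k)₊, −I(x>ψ_k)] gives slope-change coefficients β̂_k and gap
coefficients γ̂_k, and the update ψ_k ← ψ_k + γ̂_k/β̂_k. Three numerical
safeguards wrap the textbook iteration:

* **Descent enforcement.** Each proposed step is halved (≤6 times) until it
  is admissible (breakpoints strictly interior and ordered, ≥3 points per
  segment) and lowers the broken-line RSS; a point from which no such step
  exists is a stationary point and terminates the iteration. Without this
  the iteration oscillates indefinitely on noisy data.
* **Local polish.** The iteration can rest a fraction of an observation
  spacing from the continuum RSS minimizer near a data-point kink; a
  coordinate-wise coarse-then-fine local grid scan (±1.2 spacings at 0.05,
  then ±0.06 at 0.005) moves it there. Verified against an exhaustive
  0.01-step RSS grid search. The polish is disabled inside Monte-Carlo
  loops, where only the test statistic matters.
* **Identifiability.** β̂_k ≈ 0 (no slope change) flags the fit
  unidentifiable; non-convergence is returned as `converged=False`, never
  hidden.

Starting values are interior quantiles of x (median for one break; thirds
for two). Random restarts exist but are **off by default**: on the
three-phase temperature scenario they measurably inflate breakpoint
dispersion (empirical SD 4.4 vs 3.9 years) by selecting distant spurious RSS
minima, and a full global grid minimizer is worse still. At weak
signal-to-noise the local fit from quantile starts is the better estimator.

**Breakpoint standard errors.** The delta-method SE, se(ψ̂)=se(γ̂)/|β̂|, is
always computed (`psi_se_delta`) and is well calibrated at strong signal,
but at the weak slope changes typical of climate series it underestimates
the sampling SD by ~25% (measured by simulation). The reported `psi_se`
therefore defaults to a parametric-bootstrap SD: 100 seeded refits of data
simulated from the fitted broken line with the fitted residual variance.
`se_method="delta"` restores the first-order formula.

**How many breakpoints.** A sequential Monte-Carlo procedure chooses k ∈
{0, 1, 2}. Step one tests "no break" with a score-type statistic — the
largest |t| of a single extra hinge placed at each of K=10 fixed interior
quantiles of x — against B parametric simulations from the fitted straight
line (p = (1+#exceedances)/(B+1)). If rejected at α, a one-break model is
fit and an additional break is tested with the scaled RSS drop of the
two-break over the one-break fit, again Monte-Carlo calibrated under the
one-break null. The published score test's analytic reference distribution
is deliberately not reproduced; the Monte-Carlo version is exact by
construction up to estimation of the null parameters, and a BIC comparison
over 0/1/2 breaks is provided as a cross-check. Series shorter than 10
points are refused.

**Pooling breakpoint years.** Every response series spanning ≥80 years is
tested; fitted breakpoints of the selected model are rounded half-up to
integer years and pooled. Their distribution is compared by two-sample
Kolmogorov–Smirnov tests (scipy) against three seeded comparators of 10,000
draws each: uniform on the observed range, normal with the observed mean and
SD, and an equal-weight mixture of two normals centred on the temperature
breakpoints with SDs equal to their standard errors. Two-sample KS (not
one-sample) because the comparison targets are themselves simulated samples;
the comparator parameters are all config-exposed since no canonical values
exist. A Shapiro–Wilk statistic on the observed years is reported alongside.
Fewer than 8 observed years, or a degenerate (constant) sample, is refused.

## Penalized-spline smooth and warming phases

The temperature trajectory is smoothed with a P-spline: cubic B-splines on
equally spaced knots extended beyond the data (so the basis is uniform and
the second-difference coefficient penalty leaves straight lines exactly
unpenalized), with λ chosen by GCV, n·RSS/(n−edf)², over a 41-point log grid
spanning 1e-6–1e8. Default basis dimension 13 (10 interior knots + cubic
order). GCV rather than REML avoids committing to a mixed-model
formulation; on data simulated from a known smooth curve the GCV choice
beats both λ extremes in mean squared error.

Uncertainty uses the **Bayesian posterior covariance** of the penalized
coefficients, σ̂²(BᵀB+λP)⁻¹ — the convention of the GAM literature — rather
than the frequentist sandwich, which ignores smoothing bias and gives
derivative bands that are too narrow for phase classification (measured:
three-phase recovery 82% vs 95% on the same simulations). The first
derivative comes from the analytic derivative of the basis, with pointwise
95% bands propagated through the derivative design; bands are pointwise, not
simultaneous, matching the derivative-plotting practice this mirrors. Years
are labelled *increasing* (band above zero), *decreasing* (below), or
*stable* (straddling), and runs of equal labels merge into phases.

## The synthetic scenario

The generators encode the study conditions all recovery tests run under:

| parameter | default | meaning |
|---|---|---|
| years | 1900–2020 | analysis window |
| temperature breaks | 1946, 1979 | trajectory change years |
| phase slopes | 0.05, −0.02, 0.06 °C/yr | warming, slight cooling, warming |
| temperature noise | 0.5 °C | annual SD around the piecewise line |
| phenology sensitivity | −2.06 days/°C | latent peak-flowering shift |
| phenology taxa / specimens | 22 taxa, Poisson(5)/yr | herbarium sampling |
| occurrence taxa / records | 8 taxa, Poisson(12)/yr | distribution records |
| leading-edge drift | 0 °lat/yr | distributions stable by default |
| abundance trend | −500 ind·m⁻³/°C | decline per degree, lognormal noise |
| richness | 12 species, detection 0.7 | constant truth, method switch 2003 |

Temperature is a continuous piecewise-linear mean plus i.i.d. Gaussian
noise. Phenology: each taxon's latent peak DOY = baseline + sensitivity ×
(T − T̄) + N(0, 2 days); specimen dates scatter N(0, 10 days) around the
latent peak and intensity falls off linearly with distance from it
(triangular law, width 30 days), so threshold-qualifying specimens cluster
at the peak and the earliest-peak statistic tracks the latent signal without
bias. Occurrence latitudes are Normal(centre + drift·t, 0.5°); known
numbers of rule-violating records (absent status, non-binomial names,
sub-threshold taxon-years, a 49-year-span taxon) are injected so each filter
rule can be audited count-for-count. Abundance declines linearly in
temperature with multiplicative lognormal noise; one rare taxon carries
exactly 99 observation rows to probe the <100 cutoff. Where the analysis
pattern fixed no value (abundance trend and base densities, noise scales,
record rates), values were chosen once at magnitudes a field dataset of this
kind would show and are not tuned.

Randomness is one seed per scenario split into named substreams per
generator, so enlarging one generator never perturbs another's draws; all
generators are bit-reproducible for a fixed seed and package version.

**What the synthetic tests do not show.** The generators draw i.i.d. noise
around clean parametric signals: no autocorrelated climate noise, no
spatially structured sampling, no taxonomic error, no digitization backlogs
or wartime collection gaps beyond what the effort profile encodes, and no
detection-probability structure in the surveys. Passing the recovery suite
demonstrates that the estimators recover what they claim under the stated
sampling laws — not that real collections satisfy those laws.

## Problem sizes and tolerances

The test suite runs the recovery studies at 200 seeds (500 for the type-I
calibration, which needs tighter Monte-Carlo error on a 5% rate), with B=199
Monte-Carlo replicates for breakpoint p-values (B=99 in the calibration
study), 100 bootstrap refits per reported breakpoint SE, and 10,000-draw KS
comparators — sizes chosen so each study finishes in minutes on one core
while keeping Monte-Carlo error well inside the asserted margins. Unit
tests exercise the same generators at 20 seeds. Numerical tolerances:
breakpoint-vs-grid agreement 0.05 predictor units against a 0.01-step
oracle; spline-vs-OLS agreement 1e-6 on linear data; exact equality for
closed-form pooling.

## Known limitations

* One predictor per trend fit; no lags, no interactions, no random effects,
  no heterogeneity statistics (Q, I²) — deliberately outside scope.
* Breakpoint inference assumes Gaussian residuals in its parametric
  simulations; heavy-tailed residuals would mis-calibrate the p-values.
* The two-break limit is structural: more complex trajectories need a
  different changepoint machinery.
* Phase labels depend on pointwise bands; simultaneous bands would be more
  conservative and are not the default.
* The marine temperature pathway (annual max at depth) is aggregated but the
  desk-scale scenario exercises only the air-temperature path end to end.
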