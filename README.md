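# ecofingerprint

Regional climate-fingerprint analysis for natural-history-collection data.

Museum collections — herbarium sheets, survey archives, occurrence
databases — hold ecological signal at timescales no monitoring program
reaches. This package turns such records into a coherent, testable analysis
of how a region's ecology tracks its climate: it derives annual response
series (flowering phenology, abundance, species richness, range-edge
latitude) from collection-style tables, estimates per-taxon trends against
year and temperature, pools them across taxa, finds changes of trajectory in
both temperature and ecology, and asks whether the ecological shifts
coincide in time with the climatic ones. It is written for ecologists and
biostatisticians working with long, heterogeneous, opportunistically sampled
records.

## The statistics at the core

**Response derivation.** Peak-flowering date per taxon-year = earliest
day-of-year among specimens whose flowering intensity reaches the taxon's
75%-quantile threshold; range leading edge = annual 90th percentile of
record latitudes; richness = maximum distinct-taxon count over a year's
sampling replicates; abundance = mean sampled density. Collection-effort
filters (presence records, binomial names, ≥50-year span, ≥5 records per
taxon-year, marine ≥0.4° annual latitude range) guard against sampling
artefacts.

**Trends and pooling.** Per unit i, OLS slope b_i ± se_i of the response on
year or on mean annual temperature. Pooling is an unweighted fixed-effects
meta-analysis:

    pooled = (1/k) Σ b_i,   SE = √(Σ se_i²)/k,   CI = pooled ± 1.96·SE

— unweighted because taxa are different estimands, not replicates of one.

**Breakpoints.** Broken-line regression
y = a + bx + Σ β_k (x−ψ_k)₊ fit by the iterative gap-variable
linearization (update ψ_k ← ψ_k + γ̂_k/β̂_k), with parametric-bootstrap
standard errors for ψ̂ and a sequential Monte-Carlo test for k ∈ {0,1,2}
breakpoints. Breakpoint years pooled across long (≥80-year) response series
are compared by two-sample Kolmogorov–Smirnov tests against uniform, normal,
and temperature-coincident bimodal nulls.

**Warming phases.** A P-spline smooth of temperature on year (cubic
B-splines, second-difference penalty, GCV-chosen λ); its analytic first
derivative with pointwise 95% bands labels each year increasing / stable /
decreasing.

A synthetic-data module generates every input type from a seeded scenario
with known truth (breakpoints 1946/1979, phase slopes 0.05/−0.02/0.06 °C/yr,
phenology sensitivity −2.06 days/°C, injected filter violations at known
counts), so the whole pipeline is testable without any downloads. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

`examples/phenology_meta_analysis.py` simulates herbarium specimens for 22
taxa whose flowering advances 2.06 days per °C, derives each taxon's
earliest-peak-flowering series, regresses it on temperature and pools:

```
taxa pooled: 22
  Synthetica spaa: -1.66 days/degC (SE 0.26)
  Synthetica spab: -2.26 days/degC (SE 0.29)
  Synthetica spac: -2.00 days/degC (SE 0.31)
  ...
pooled slope: -2.02 days/degC [95% CI -2.14, -1.91]
generating sensitivity: -2.06 days/degC
```

The pooled slope is the regional phenological fingerprint — flowering ~2
days earlier per degree of warming — and its CI covers the truth the data
were generated with. The other scripts in `examples/` demonstrate
segmented-regression breakpoint estimation (`temperature_breakpoints.py`),
derivative-based phase classification (`warming_phases.py`), the
breakpoint-coincidence KS tests (`breakpoint_coincidence.py`), and the full
pipeline with all artifacts (`full_pipeline.py`).

A thin CLI covers shell use:

```sh
ecofp simulate --seed 1 --out inputs/     # synthetic input tables + truth
ecofp run --seed 1 --out results/         # full pipeline, all artifacts
```

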