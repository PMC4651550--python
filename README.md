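# polarland

Analysis pipeline for studying terrestrial habitat use by polar bears
(*Ursus maritimus*) from satellite radio-collar telemetry and sea-ice
concentration rasters.  The scientific question it serves: as summer sea ice
retreats farther and for longer, do more bears come ashore, do they stay
longer, and does the timing of ice retreat from a stretch of coast predict
whether bears summer or den there?

The package is aimed at movement ecologists who have (or can simulate)
Argos/GPS collar data and gridded ice concentration, and want the full chain
from raw fixes to period-comparison statistics as tested, reusable code.

## What it does

1. **Telemetry screening** (`polarland.telemetry`) — keeps standard Argos
   classes (3, 2, 1) and GPS fixes, rejects class Z, and keeps auxiliary
   classes (0, A, B) only when corroborated by a consecutive fix within
   10 km or when implied movement is plausible (< 10 km h⁻¹ and no extreme
   turning angle); truncates dropped collars from activity sensors.
2. **Movement model** (`polarland.ctcrw`) — a continuous-time correlated
   random walk: per axis, velocity is Ornstein–Uhlenbeck,
   dv = −β v dt + σ dW, and position its integral.  The exact discrete
   transition gives a Kalman-filter likelihood over irregular fix times with
   class-specific Gaussian measurement error (3: 150 m, 2: 350 m, 1: 1000 m,
   0: 1500 m, A: 5000 m, B: 10 000 m, GPS: 30 m); (β̂, σ̂) by maximum
   likelihood, daily positions by RTS smoothing.  Days bracketed by
   observations more than 14 days apart are flagged and excluded from
   land-day counts.  Includes withheld-location cross-validation and the
   14-day-gap midpoint validation.
3. **Land use** (`polarland.landuse`) — a bear is on land when its predicted
   position is within 5 km of a coastline polygon.  Per bear-year: total
   (not necessarily consecutive) on-land days in August–October, >7-day and
   >21-day use flags, arrival/departure dates, land-mass attribution, and
   percent of the year on land for records with ≥ 300 located days.
4. **Denning** (`polarland.denning`) — denning is a run of ≥ 35 days of
   collar temperature above a weekly non-denning baseline (mean + k·SD,
   k = 2) within October–May; substrate (land/ice) from observed fixes
   around the event.
5. **Ice phenology** (`polarland.ice`) — weekly mean concentration grids;
   the pack ice as the largest contiguous area at ≥ 15% concentration; per
   25-km coastal segment, the retreat date (first ordinal date the pack is
   > 50 km away) and return date (first date it is back within 50 km), with
   the sentinel (365, 1) for coasts the ice never leaves; August–October
   shelf ice coverage.
6. **Inference** (`polarland.stats`) — two-group logistic regression from
   counts (slope = log odds ratio with Woolf SE), ANOVA from group
   summaries, OLS, conditional logistic regression for the use-availability
   design (exact stratified conditional likelihood, Newton with analytic
   derivatives), AIC ranking and Pearson χ² contingency tests.
7. **Synthetic study** (`polarland.synthetic`) — a seeded generator for the
   whole input suite: OU-velocity tracks with Argos-class error and
   transmission gaps, seasonal ice fields that retreat poleward and return,
   a coastline with a mainland and northern islands, and winter denning
   temperature signatures, with per-bear ground truth.

`polarland.pipeline.run_study` chains everything and returns a
`StudyReport`; the `polarland` CLI exposes each stage
(`simulate`, `filter`, `interpolate`, `summarize`, `den-detect`,
`ice-pheno`, `stats`, `run-study`, `reproduce`).

## Worked example

```python
from polarland import SimConfig, run_study

report = run_study(seed=1)
k1, n1 = report.counts["gt7"]["1986-1995"]
k2, n2 = report.counts["gt7"]["2008-2013"]
print(f"> 7-day land use: {100*k1/n1:.1f}% ({k1}/{n1}) vs {100*k2/n2:.1f}% ({k2}/{n2})")
fit = report.fits["logistic_gt7"]
print(f"logistic slope {fit.coef['slope']:.2f} +- {fit.se['slope']:.2f}, p = {fit.pvalue:.3f}")
dur = report.fits["anova_days_on_land"]
print(f"duration increase {dur.coef['diff']:.1f} +- {dur.se['diff']:.1f} days, "
      f"F = {dur.statistic:.1f}, p = {dur.pvalue:.4f}")
```

With seed 1 this prints:

```
> 7-day land use: 22.2% (12/54) vs 37.5% (12/32)
logistic slope 0.74 +- 0.49, p = 0.130
duration increase 26.6 +- 5.8 days, F = 21.4, p = 0.0001
```

The generator's defaults put 20.0% of early-period and 38.9% of
recent-period bear-years ashore for more than 7 days, with mean onshore
durations of 32.7 and 62.6 days; the run above recovers those conditions
through the full noisy chain (observation error, filtering, interpolation,
gap exclusion).  Bear-years whose August–October window is interrupted by a
> 14-day observation gap are excluded from the comparison, which is why the
denominators are below 80 and 36.

Published group summaries can also be recomputed directly without any
location data:

```bash
polarland reproduce
```

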