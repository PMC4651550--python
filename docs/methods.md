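# Methods

## Coordinate frame and calendar

All geometry lives in a planar, locally distance-preserving projection of
the study area with kilometre units.  The operative distances of the
analysis — the 5-km land buffer, the 10-km corroboration radius, the 50-km
retreat criterion — are small enough that planar distance is an adequate
surrogate for geodesic distance, and a single shared frame lets the
simulator, the classifier and the ice metrics agree exactly.

Time is a float count of days since 00:00 on 1 January of the bear-year's
starting calendar year; day index *d* spans ordinal date *d* + 1.  The year
has 365 days and leap days are dropped, so ordinal dates are always 1–365
and the never-retreat sentinel (365, 1) is well defined.

## Movement model

Per axis, velocity follows an Ornstein–Uhlenbeck process
dv = −β v dt + σ dW and position is its integral; the axes share (β, σ).
β (day⁻¹) sets how quickly velocity decorrelates (default 0.5/day ≈
half-day persistence), σ (km · day^−3/2) the velocity diffusion (default
2, giving day-scale displacements of a few km).  The state (position,
velocity) has an exact Gaussian transition over any interval, so the
likelihood over irregular fix times is computed by a Kalman filter; both
axes share one covariance recursion because measurement error is isotropic.
Measurement SDs are fixed per quality class, not estimated.

Fitting maximises the likelihood over (log β, log σ) by Nelder–Mead from
three starts (convergence 1e-8 on the objective), with standard errors from
the numerical Hessian in log parameters, delta-method transformed.  The
initial state is the first fix with zero velocity and diffuse covariance
(10⁶ km² position, 10⁴ km²/day² velocity); the same initialisation is used
by the brute-force joint-Gaussian oracle in the tests, so likelihood
agreement is exact rather than asymptotic.

Daily positions are smoothed (RTS), i.e. conditioned on all data — the
standard use of this model for track regularisation.  Daily epochs are
00:00.  A predicted day is flagged `gap_excluded` when its bracketing
observations are more than 14 days apart, or when it lies outside the
observation span entirely; flagged days stay listed (so coverage can be
reported) but never contribute to land-day counts.

Two validation procedures mirror the analysis design: withheld-location
cross-validation (five fixes withheld at random, model refit, land/ice
status of predictions compared with the withheld fixes) and the 14-day-gap
midpoint check (for every observed on-land fix flanked by observations at
least 7 days away on both sides, the 14-day window is deleted and the
midpoint re-predicted).  The midpoint check re-predicts with the original
fitted parameters rather than refitting per midpoint: deleting ~5 of
hundreds of fixes moves the MLE negligibly, and the quantity of interest is
the prediction, not the fit.

## Telemetry screening

Standard classes (3/2/1) and GPS are always kept; Z is always dropped;
auxiliary classes (0/A/B) are kept iff a temporally adjacent *kept* fix
lies within 10 km, or implied speeds to both kept neighbours are below
10 km h⁻¹ and the turning angle at the fix is at least 30°.  "Not
extremely acute" is not a number in the field's verbal description, so the
threshold is an exposed parameter (`min_turn_angle_deg`, default 30°,
where 180° is straight-line travel and near-0° is an out-and-back spike).
Auxiliary fixes are evaluated iteratively against the growing kept set;
keeps only accumulate, so the pass terminates and filtering is idempotent.
Collar drops are detected as ≥ 7 consecutive days of zero activity — a
deliberately transparent rule, since drop detection is sensor-specific and
any sustained-zero epoch is unambiguous.

## Land use

A position is on land when it falls inside a coastline polygon or its 5-km
buffer (the buffer absorbs unmapped barrier islands and low-quality fixes).
The summering window is 1 August – 31 October inclusive (92 days); "days on
land" counts non-gap-excluded window days and need not be consecutive.
Arrival is the start of the longest onshore bout and departure the end of
the last bout before 31 December (computed over 1 July – 31 December);
both definitions are configurable because single dates must summarise
possibly multiple bouts.  Land-mass attribution takes the plurality of
on-land days, ties to the earliest-visited mass.  A bear-year with any
gap-excluded day inside the window is flagged ineligible for period
comparisons; whole-year percent-on-land requires ≥ 300 usable days.

## Denning

The detector compares daily collar temperature with a weekly baseline
(mean and SD per 7-day calendar block, pooled over non-denning bears, at
least three series per winter week).  A day is elevated above
mean + k·SD (k = 2); maximal elevated runs may be interrupted by up to two
non-elevated days; runs clipped to 1 October – 31 May count as denning
events when ≥ 35 days long.  This is a transparent threshold run-detector
validated by simulation (≥ 90% sensitivity, ≤ 5% false-event rate at a
3-SD offset over 200 simulated winters), not a reimplementation of any
particular control-chart formulation.

In the full pipeline the non-denning set is unknown a priori, so the
baseline is built iteratively: a robust (median / scaled-MAD) baseline over
all bears, provisional detection, removal of flagged bears, and repetition
until the flagged set stabilises; the final baseline is the plain mean/SD
one over the stable non-denning set.

Substrate: land if any *observed* fix within ±3 days of the event
boundaries (or inside it) classifies on land, ice if such fixes exist and
none do, unknown with no fixes.  The ±3-day tolerance exists because den
transmission is attenuated and the temperature onset rarely coincides with
a fix.  Events are labelled "denning" without asserting maternity versus
shelter use.

## Ice phenology

Weekly grids are per-cell means over fixed 7-day blocks from 1 January
(the last block is short); a week's ordinal date is its first day.  The
pack ice is the largest contiguous component of cells at ≥ 15%
concentration; contiguity is 8-connected by default so diagonally touching
ice is not split (4-connectivity is available).  Coastal segments are
land-adjacent water cells of the 25-km grid, one segment per cell.
Retreat is the first week-start date the minimum centre-to-centre distance
from the segment to any pack cell exceeds 50 km (an empty pack counts as
retreated); return is the first later date the distance is back within
50 km; (365, 1) when retreat never happens, return 365 when ice never
comes back.  Centre-to-centre distance on a 25-km grid bounds the
discrepancy against an edge-based definition by half a cell diagonal
(≈ 17.7 km ≤ 12.5·√2).  Shelf coverage is the daily fraction of shelf
cells at ≥ 15%, averaged over 1 August – 31 October.

## Inference

All tests are Wald-type, at the conventional 0.05 level, without
multiplicity correction — matching how such period comparisons are usually
reported.  The two-group logistic slope is the log odds ratio with the
Woolf SE, which coincides with the IRLS logistic-regression MLE on the
expanded 0/1 data (checked against statsmodels).  Zero cells are reported
as non-finite with a separation warning rather than silently penalised; a
continuity-corrected estimate is not computed by default.  ANOVA from
summaries uses the pooled variance, so F equals the squared equal-variance
t statistic.  The conditional logistic likelihood is maximised by Newton
iterations with analytic gradient and Hessian; covariates with zero
within-stratum variance everywhere are flagged unidentifiable.  The
availability set for each bear-year stratum is all coastal segments of that
year, the used segment being the one nearest the bear's mean on-land
position within the summering window.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, on
a 1000 × 1000 km plane with 25-km raster cells:

* **Geography** — a southern mainland strip, a large northern island (the
  main summering/denning refuge), a small neighbouring island, and a
  far-northern island embedded in perennial ice whose coast exercises the
  never-retreat sentinel.  The continental shelf is the region south of
  y = 800 km.
* **Ice** — cell melt and freeze dates follow linear latitude profiles
  anchored at the mainland coast and the big island's north face, placed so
  that a day-by-day 50-km scan at an anchor coast recovers the configured
  dates; the default south-to-north retreat spread is 126 days, and the
  recent period's profile sits 25 days earlier with ~8-day inter-annual
  noise.  Concentration ramps over ~5 days around each transition with
  small uniform noise; cells north of y = 875 km never melt.
* **Movement** — each bear follows an itinerary (capture point on the
  spring ice; follow the pack edge inside a holding band clear of all
  coastlines; optionally a shore bout; optionally a den) plus a
  mean-reverting OU deviation, tight (1.5 km) while ashore or denning and
  loose (12 km) at sea.  Without an itinerary the generator produces the
  pure integrated-OU process via the exact discrete transition — the same
  model (and code path) the fitter assumes, which is what makes the
  parameter-recovery tests meaningful.
* **Observation** — period 1 collars report every 3 days; period 2 mixes
  GPS collars at 4 fixes/day with Argos collars at 2 days.  Classes are
  drawn from a configurable mixture (fix-success rates and class
  frequencies are free parameters, since no standard values exist); errors
  are isotropic Gaussian with the class SDs.  Five percent of fixes drop
  out; 15% of bear-years contain one 10–20-day outage to exercise the
  14-day rule; transmission during denning is reduced by 80%.
* **Behaviour** — a bear-year is a land user with the period's configured
  probability (defaults 0.200 / 0.389); land users draw an arrival date
  (means 261 / 241, SD 12) and a duration (means 32.7 / 62.6, SD 20,
  truncated at ≥ 8 days so that "land user" coincides with the >7-day
  criterion).  Earlier-retreat years lengthen durations (−0.8 day per
  shifted day), coupling land tenure to ice.  35% of bear-years den,
  88% of dens on land; den starts ~doy 320 (SD 10, clipped to Oct–mid Dec)
  with 61–170-day durations, and all denners also exceed 60 days at the
  den site.  Collar temperature is a seasonal sinusoid (−22 °C winter to
  +6 °C summer) with 1.5 °C daily noise, elevated 8 °C while denning.

What the generator does **not** emulate: real passive-microwave artifacts
(weather filters, land spillover, the pole hole), real coastline shapes,
sea-surface drift of the pack, swimming versus walking, or
behaviour-dependent fix success beyond the denning attenuation.  Passing
tests therefore demonstrate that the pipeline recovers truth under the
model's own assumptions with realistic noise and gap structure — not that
those assumptions hold for any particular real data set.

## Problem sizes

The default synthetic study uses the study-scale cohort (80 + 36
bear-years over 6 + 4 ice years); the acceptance script runs it once.
Parameter-recovery checks use 100 tracks of 300 fixes (movement model),
50 replicates of 200 strata (selection model) and 200 simulated winters
(denning detector); oracle equivalences run on 8×8 grids, ≤ 10-fix tracks
and 3-stratum toys.  These sizes were chosen so the whole suite exercises
every claim at meaningful power while remaining a coffee-break run.

## Known limitations

* The conditional-logistic availability design treats all coastal segments
  of the study year as available to every bear; the pipeline's selection
  coefficients are therefore diluted by unreachable segments (including
  the sentinel coast) and are reported, not asserted.
* Arrival/departure dates summarise multi-bout behaviour with single dates;
  bears that leave and return are represented by their longest and last
  bouts.
* The two-group logistic Wald p-value differs in the third decimal from
  likelihood-ratio or exact alternatives at these sample sizes; the test
  type is a documented choice.
* Substrate assignment depends on fix availability around the den; with
  heavy transmission attenuation a land den with no nearby fixes is
  honestly reported as unknown (or, with only offshore approach fixes, can
  be misread as ice).
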