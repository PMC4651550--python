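"""Seeded synthetic study generator.

Emulates the statistical structure the analysis assumes, so every stage of
the pipeline is testable without real telemetry or passive-microwave data:

* a planar 1000 x 1000 km study area with a southern mainland coast, a large
  and a small northern island (the main summering/denning refuges), and a
  far-northern island embedded in perennial pack ice (whose coast the ice
  never leaves, exercising the (365, 1) sentinel);
* daily sea-ice concentration grids on 25-km cells in which the pack edge
  retreats poleward and returns, with the configured latitude profile giving
  the date the pack moves beyond 50 km of each northing;
* bear movement built from an itinerary (follow the pack edge; optionally
  come ashore for a configured bout; optionally den) plus an
  Ornstein-Uhlenbeck deviation, observed through Argos-class or GPS error
  with per-fix dropout and occasional long outages;
* collar temperature with a seasonal baseline and an elevated plateau while
  denning, and activity that goes silent if the collar drops.

`generate_track` without a plan simulates the pure integrated-OU process
with the exact discrete transition, sharing its model (and code) with the
movement-model fitter so parameter-recovery tests are meaningful.

Everything is reproducible bit-for-bit from (config, seed): each bear, ice
year and noise field draws from its own `numpy` SeedSequence spawn key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from shapely.geometry import box

from .config import CLASS_ERROR_SD_M, PERIOD_1, PERIOD_2, SimConfig
from .ctcrw import _phi_q
from .ice import IceStack
from .landuse import CoastGeometry
from .stats import UseAvailStratum
from .telemetry import Track
from .timeutil import doy_of

# --------------------------------------------------------------------------
# geography

GRID_N = 40  # cells per side
CELL_KM = 25.0

#: land rectangles in km: (x0, y0, x1, y1)
LAND_BOXES = {
    "mainland": (0.0, 0.0, 1000.0, 75.0),
    "big_island": (300.0, 700.0, 500.0, 775.0),
    "small_island": (600.0, 725.0, 650.0, 775.0),
    "polar_island": (400.0, 925.0, 500.0, 975.0),
}
SHELF_MAX_Y = 800.0  # km; continental shelf south of this northing
PERMANENT_ICE_Y = 875.0  # km; ice never melts at/above this northing


@lru_cache(maxsize=4)
def make_coast(buffer_km: float = 5.0) -> CoastGeometry:
    polys = {name: box(*bounds) for name, bounds in LAND_BOXES.items()}
    return CoastGeometry(polys, buffer_km=buffer_km)


def make_masks(grid_n: int = GRID_N, cell_km: float = CELL_KM):
    """Rasterized land/shelf masks plus a land-mass label grid."""
    yy, xx = np.meshgrid(
        (np.arange(grid_n) + 0.5) * cell_km,
        (np.arange(grid_n) + 0.5) * cell_km,
        indexing="ij",
    )
    land = np.zeros((grid_n, grid_n), dtype=bool)
    labels = np.empty((grid_n, grid_n), dtype=object)
    labels[:] = ""
    for name, (x0, y0, x1, y1) in LAND_BOXES.items():
        inside = (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)
        land |= inside
        labels[inside] = name
    shelf = yy <= SHELF_MAX_Y
    return land, shelf, labels


# --------------------------------------------------------------------------
# ice

# profile anchor northings: the mainland coast and the big island's north
# face — both coasts whose 50-km seaward band opens onto the retreating pack,
# so the day-by-day 50-km scan recovers the configured dates there exactly
_PROFILE_Y_S, _PROFILE_Y_N = 87.5, 787.5


def _linear_profile(south_val: float, north_val: float):
    slope = (north_val - south_val) / (_PROFILE_Y_N - _PROFILE_Y_S)

    def profile(y):
        return south_val + slope * (np.asarray(y, float) - _PROFILE_Y_S)

    return profile, slope


def _retreat_profile(config: SimConfig):
    """Configured retreat date by northing: the ordinal date the pack edge
    moves beyond 50 km of that northing."""
    return _linear_profile(
        config.ice_retreat_doy_by_latitude["south"],
        config.ice_retreat_doy_by_latitude["north"],
    )


def _return_profile(config: SimConfig):
    """Configured return date by northing (freeze-up, sweeping southward)."""
    return _linear_profile(
        config.ice_return_doy_by_latitude["south"],
        config.ice_return_doy_by_latitude["north"],
    )


def generate_ice_stack(
    config: SimConfig, year: int, retreat_shift_days: float = 0.0
) -> IceStack:
    """One year of daily concentration grids.

    Cell melt/freeze dates are placed so that, for a coastal segment at
    northing y, the day-by-day 50-km criterion recovers the configured
    retreat profile at y (shifted by `retreat_shift_days` for inter-annual
    variation).  Concentration ramps over ~5 days around each transition
    and carries small seeded noise.  Cells at or above the perennial-ice
    northing never melt.
    """
    config.validate()
    profile, slope = _retreat_profile(config)
    grid_n, cell = config.grid_n, config.grid_cell_km
    land, shelf, _ = make_masks(grid_n, cell)
    y_centres = (np.arange(grid_n) + 0.5) * cell

    # melt/freeze at T such that the 50-km scan at northing y fires at the
    # configured profile value at y
    ret_profile, _ = _return_profile(config)
    t_melt = profile(y_centres - 50.0) + retreat_shift_days
    t_freeze = np.maximum(
        ret_profile(y_centres - 50.0) + retreat_shift_days, t_melt + 10.0
    )
    never = y_centres >= PERMANENT_ICE_Y
    t_melt[never] = np.inf

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1, year))
    )
    days = np.arange(1, 366)
    conc = np.empty((365, grid_n, grid_n))
    base = 0.85
    for i, t in enumerate(days):
        melt_ramp = np.clip((t_melt - t) / 5.0, 0.0, 1.0)
        freeze_ramp = np.clip((t - t_freeze) / 5.0, 0.0, 1.0)
        level = base * np.maximum(melt_ramp, freeze_ramp)
        conc[i] = level[:, None]
    conc += rng.uniform(-0.04, 0.04, size=conc.shape)
    conc = np.clip(conc, 0.0, 1.0)
    conc[:, land] = 0.0
    return IceStack(
        doys=days, conc=conc, land_mask=land, shelf_mask=shelf, cell_km=cell
    )


def ice_edge_y(config: SimConfig, t: float, retreat_shift_days: float = 0.0) -> float:
    """Southern edge (km northing) of the pack at study day t (doy frame)."""
    profile, _ = _retreat_profile(config)
    ret_profile, _ = _return_profile(config)
    doy = doy_of(t)
    grid_n, cell = config.grid_n, config.grid_cell_km
    y = (np.arange(grid_n) + 0.5) * cell
    t_melt = profile(y - 50.0) + retreat_shift_days
    t_freeze = np.maximum(
        ret_profile(y - 50.0) + retreat_shift_days, t_melt + 10.0
    )
    t_melt[y >= PERMANENT_ICE_Y] = np.inf
    icy = (doy < t_melt) | (doy >= t_freeze)
    return float(y[icy].min()) if icy.any() else float(y.max())


# --------------------------------------------------------------------------
# bear plans

@dataclass
class BearPlan:
    bear_id: str
    period: str
    year: int
    year_shift: float  # retreat shift (days) of this bear's year
    collar: str  # "argos" | "gps"
    capture_xy: tuple[float, float]
    capture_label: str
    land_user: bool
    arrival_doy: float | None = None
    duration_days: float | None = None
    land_target: tuple[float, float] | None = None
    land_label: str | None = None
    denner: bool = False
    den_start: float | None = None  # study day
    den_end: float | None = None
    den_on_land: bool | None = None
    den_target: tuple[float, float] | None = None
    collar_drop_day: float | None = None
    outage: tuple[float, float] | None = None


@dataclass
class BearTruth:
    plan: BearPlan
    days: np.ndarray
    x: np.ndarray
    y: np.ndarray
    land_days_window: int = 0
    is_land_user_gt7: bool = False


@dataclass
class SyntheticStudy:
    config: SimConfig
    coast: CoastGeometry
    tracks: list[Track]
    truths: list[BearTruth]
    ice_by_year: dict[int, IceStack]
    year_shifts: dict[int, float]


_LAND_CHOICES = [("big_island", 0.75), ("small_island", 0.08), ("mainland", 0.17)]


def _point_in(label: str, rng) -> tuple[float, float]:
    x0, y0, x1, y1 = LAND_BOXES[label]
    margin = 8.0
    return (
        float(rng.uniform(x0 + margin, x1 - margin)),
        float(rng.uniform(max(y0 + margin, y0), y1 - margin)),
    )


def _plan_bear(config: SimConfig, bear_index: int, period: str, year: int,
               year_shift: float, rng) -> BearPlan:
    collar = "argos"
    if period == PERIOD_2 and rng.random() < config.gps_fraction_period2:
        collar = "gps"
    capture_xy = (float(rng.uniform(200, 800)), float(rng.uniform(150, 400)))
    plan = BearPlan(
        bear_id=f"B{bear_index:03d}",
        period=period,
        year=year,
        year_shift=year_shift,
        collar=collar,
        capture_xy=capture_xy,
        capture_label="alaska_coast" if capture_xy[0] > 500 else "wrangel_area",
        land_user=bool(rng.random() < config.p_land_user_by_period[period]),
    )
    if plan.land_user:
        arr = rng.normal(config.mean_arrival_doy_by_period[period], config.sd_arrival_doy)
        plan.arrival_doy = float(np.clip(arr, 214, 290))
        # earlier-retreat years hold bears ashore longer
        mean_dur = config.mean_days_on_land_by_period[period] - 0.8 * year_shift
        dur = rng.normal(mean_dur, config.sd_days_on_land)
        plan.duration_days = float(max(8.0, dur))
        labels, probs = zip(*_LAND_CHOICES)
        plan.land_label = str(rng.choice(labels, p=probs))
        plan.land_target = _point_in(plan.land_label, rng)
    plan.denner = bool(rng.random() < config.denning_prob)
    if plan.denner:
        start_doy = float(np.clip(rng.normal(320, 10), 285, 345))
        dur = float(np.clip(rng.normal(120, 20), 61, 170))
        plan.den_start = start_doy - 1.0
        plan.den_end = plan.den_start + dur
        plan.den_on_land = bool(rng.random() < config.p_den_on_land)
        if plan.den_on_land:
            lbl = plan.land_label or str(
                rng.choice([L for L, _ in _LAND_CHOICES], p=[p for _, p in _LAND_CHOICES])
            )
            plan.den_target = _point_in(lbl, rng)
        else:
            # on the pack, in a corridor clear of every island's longitude band
            plan.den_target = (float(rng.uniform(700, 900)), float(rng.uniform(840, 900)))
    if rng.random() < config.p_long_outage:
        start = float(rng.uniform(195, 280))
        length = float(rng.uniform(10.0, config.max_outage_days))
        plan.outage = (start, start + length)
    return plan


#: offshore holding band: south of every island's buffer, north of the
#: mainland's, so ice-associated bears never brush a coastline by accident
_OFFSHORE_Y_MIN, _OFFSHORE_Y_MAX = 200.0, 650.0


def _offshore_y(config: SimConfig, t: float, year_shift: float) -> float:
    edge = ice_edge_y(config, t, year_shift)
    return float(np.clip(edge + 75.0, _OFFSHORE_Y_MIN, _OFFSHORE_Y_MAX))


def _itinerary(config: SimConfig, plan: BearPlan, t_grid: np.ndarray) -> np.ndarray:
    """Piecewise mean path (km) honouring the plan's land/den bouts.

    Offshore stretches follow the ice edge (sampled every 10 days) inside a
    holding band clear of all coastlines; shore and den visits approach the
    target along its own longitude over ~4 days, so land occupancy is
    confined to the planned bouts.
    """
    waypoints: list[tuple[float, float, float]] = []  # (t, x, y)
    t0, t1 = t_grid[0], t_grid[-1]
    cx, cy = plan.capture_xy

    def add_offshore_leg(t_from: float, t_to: float, x_from: float, x_to: float) -> None:
        tts = np.append(np.arange(t_from, t_to, 10.0), t_to)
        span = max(t_to - t_from, 1e-9)
        for tt in tts:
            x = x_from + (x_to - x_from) * min((tt - t_from) / span, 1.0)
            waypoints.append((tt, x, _offshore_y(config, tt, plan.year_shift)))

    waypoints.append((t0, cx, cy))
    events: list[tuple[float, float, tuple[float, float]]] = []
    if plan.land_user:
        a = plan.arrival_doy - 1.0
        events.append((a, a + plan.duration_days, plan.land_target))
    if plan.denner:
        events.append((plan.den_start, plan.den_end, plan.den_target))
    events.sort()
    t_cursor = t0
    x_hint = cx
    for a, b, target in events:
        a = max(a, t_cursor + 1.0)
        b = max(b, a + 1.0)
        approach = max(t_cursor, a - 4.0)
        if approach - 1.0 > t_cursor:
            add_offshore_leg(t_cursor + 1.0, approach, x_hint, target[0])
        waypoints.append((a, *target))
        waypoints.append((b, *target))
        t_cursor = b
        x_hint = target[0]
    if t_cursor < t1:
        add_offshore_leg(min(t_cursor + 4.0, t1), t1, x_hint, x_hint)
    wt = np.array([w[0] for w in waypoints])
    wx = np.array([w[1] for w in waypoints])
    wy = np.array([w[2] for w in waypoints])
    order = np.argsort(wt, kind="stable")
    wt, wx, wy = wt[order], wx[order], wy[order]
    keep = np.concatenate([[True], np.diff(wt) > 0])
    wt, wx, wy = wt[keep], wx[keep], wy[keep]
    return np.column_stack([np.interp(t_grid, wt, wx), np.interp(t_grid, wt, wy)])


def _ou_position_deviation(t_grid, sd_by_step, tau_days, rng):
    """Mean-reverting positional deviation with step-dependent stationary SD."""
    n = len(t_grid)
    dev = np.zeros((n, 2))
    dev[0] = rng.normal(0.0, sd_by_step[0], size=2)
    for i in range(1, n):
        dt = t_grid[i] - t_grid[i - 1]
        a = math.exp(-dt / tau_days)
        sd = sd_by_step[i]
        dev[i] = a * dev[i - 1] + rng.normal(0.0, sd * math.sqrt(1 - a * a), size=2)
    return dev


def simulate_ou_track(
    beta: float, sigma: float, t_grid: np.ndarray, rng,
    start: tuple[float, float] = (0.0, 0.0), v0: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Pure integrated-OU positions at t_grid via the exact transition."""
    if beta <= 0 or sigma < 0:
        raise ValueError("process parameters must be positive")
    n = len(t_grid)
    out = np.empty((n, 2))
    state = np.array([[start[0], v0[0]], [start[1], v0[1]]])
    out[0] = state[:, 0]
    sigma2 = sigma * sigma
    for i in range(1, n):
        dt = float(t_grid[i] - t_grid[i - 1])
        (f0, f1, e), (qxx, qxv, qvv) = _phi_q(beta, sigma2, dt)
        Q = np.array([[qxx, qxv], [qxv, qvv]])
        if sigma2 > 0:
            L = np.linalg.cholesky(Q + 1e-300 * np.eye(2))
        else:
            L = np.zeros((2, 2))
        for ax in range(2):
            mean = np.array(
                [state[ax, 0] + f1 * state[ax, 1], e * state[ax, 1]]
            )
            state[ax] = mean + L @ rng.standard_normal(2)
        out[i] = state[:, 0]
    return out


def _fix_times(config: SimConfig, plan: BearPlan, t_grid, rng) -> np.ndarray:
    if plan.collar == "gps":
        interval = config.fix_interval_days_by_period[PERIOD_2]
    elif plan.period == PERIOD_2:
        interval = 2.0
    else:
        interval = config.fix_interval_days_by_period[PERIOD_1]
    step = max(1, int(round(interval / 0.25)))
    times = t_grid[::step]
    keep = rng.random(len(times)) >= config.p_fix_dropout
    # reduced transmission from inside the den
    if plan.denner:
        in_den = (times >= plan.den_start) & (times <= plan.den_end)
        keep &= ~(in_den & (rng.random(len(times)) < 0.8))
    if plan.outage is not None:
        keep &= ~((times >= plan.outage[0]) & (times <= plan.outage[1]))
    keep[0] = True
    return times[keep]


def _bear_rng(config: SimConfig, bear_index: int, stream: int):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2, bear_index, stream))
    )


def generate_track(
    config: SimConfig,
    bear_index: int,
    plan: BearPlan | None = None,
    n_fixes: int | None = None,
) -> tuple[Track, BearTruth | None]:
    """One bear's observed track (and its ground truth when planned).

    Without a plan the true path is the pure integrated-OU process started
    at the origin with zero velocity (`n_fixes` fixes at the period-1
    schedule) — the degenerate sigma -> 0 case therefore stays at the start
    point.  With a plan, the true path is the plan's itinerary plus a
    mean-reverting OU deviation (tight while ashore or denning, loose at
    sea), observed through the collar's schedule, class mixture and
    class-specific Gaussian error.
    """
    config.validate()
    rng = _bear_rng(config, bear_index, 0)

    if plan is None:
        interval = config.fix_interval_days_by_period[PERIOD_1]
        n = n_fixes or 100
        t_fix = config.track_start_doy - 1.0 + interval * np.arange(n)
        true = simulate_ou_track(config.ctcrw_beta, config.ctcrw_sigma, t_fix, rng)
        qclasses = rng.choice(
            list(config.argos_class_mix), p=list(config.argos_class_mix.values()),
            size=n,
        )
        truth = None
        t_obs, true_obs = t_fix, true
    else:
        t0 = config.track_start_doy - 1.0
        t_grid = t0 + 0.25 * np.arange(int(config.track_days / 0.25) + 1)
        mean_path = _itinerary(config, plan, t_grid)
        tight = np.zeros(len(t_grid), bool)
        if plan.land_user:
            a = plan.arrival_doy - 1.0
            tight |= (t_grid >= a) & (t_grid <= a + plan.duration_days)
        if plan.denner:
            tight |= (t_grid >= plan.den_start) & (t_grid <= plan.den_end)
        sd_by_step = np.where(tight, 1.5, 12.0)
        dev = _ou_position_deviation(t_grid, sd_by_step, tau_days=3.0, rng=rng)
        true = mean_path + dev
        t_fix = _fix_times(config, plan, t_grid, rng)
        idx = np.searchsorted(t_grid, t_fix)
        t_obs, true_obs = t_fix, true[idx]
        if plan.collar == "gps":
            qclasses = np.array(["GPS"] * len(t_fix))
        else:
            qclasses = rng.choice(
                list(config.argos_class_mix), p=list(config.argos_class_mix.values()),
                size=len(t_fix),
            )
        truth = _truth_from_path(plan, t_grid, true)

    sds_m = np.array(
        [CLASS_ERROR_SD_M.get(q, 3e5) for q in qclasses]
    )
    obs = true_obs + rng.standard_normal(true_obs.shape) * (sds_m[:, None] / 1000.0)
    fixes = pd.DataFrame(
        {
            "t": t_obs,
            "x_km": obs[:, 0],
            "y_km": obs[:, 1],
            "qclass": qclasses,
            "error_sd_m": sds_m,
        }
    )
    bear_id = plan.bear_id if plan else f"B{bear_index:03d}"
    period = plan.period if plan else PERIOD_1
    temp, act = None, None
    if plan is not None:
        den = (plan.den_start, plan.den_end) if plan.denner else None
        # the collar archives temperature over a full year even where the
        # location record is shorter, so every winter week has baseline data
        temp = generate_temperature(
            config, den, rng=_bear_rng(config, bear_index, 1),
            start_day=int(t_obs[0]), n_days=max(config.track_days, 365),
        )
        act = _activity_series(
            plan, rng=_bear_rng(config, bear_index, 2),
            start_day=int(t_obs[0]), n_days=config.track_days,
        )
    track = Track(
        bear_id=bear_id,
        period=period,
        fixes=fixes,
        temperature=temp,
        activity=act,
        capture_label=plan.capture_label if plan else "",
        year=plan.year if plan else 0,
    )
    return track, truth


def _truth_from_path(plan: BearPlan, t_grid, true) -> BearTruth:
    days = np.arange(int(t_grid[0]), int(t_grid[-1]) + 1)
    idx = np.searchsorted(t_grid, days.astype(float))
    coast = make_coast()
    x, y = true[idx, 0], true[idx, 1]
    doys = np.array([doy_of(d) for d in days])
    in_window = (doys >= 213) & (doys <= 304)
    on_land = coast.on_land_many(x[in_window], y[in_window])
    n_land = int(on_land.sum())
    return BearTruth(
        plan=plan, days=days, x=x, y=y,
        land_days_window=n_land, is_land_user_gt7=n_land > 7,
    )


def seasonal_baseline_temp(doy) -> np.ndarray:
    """Ambient-driven collar temperature baseline (deg C) by ordinal date."""
    doy = np.asarray(doy, float)
    return -8.0 + 14.0 * np.cos(2 * np.pi * (doy - 200.0) / 365.0)


def generate_temperature(
    config: SimConfig,
    denning_interval: tuple[float, float] | None,
    rng=None,
    start_day: int = 104,
    n_days: int = 330,
) -> pd.Series:
    """Daily collar temperature: seasonal baseline + noise, elevated in den.

    The denning interval (study days) must fall inside the October-May
    window; `None` means no denning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if denning_interval is not None:
        from .timeutil import month_of_doy

        for t in denning_interval:
            if month_of_doy(doy_of(t)) not in {10, 11, 12, 1, 2, 3, 4, 5}:
                raise ValueError("denning interval must lie within October-May")
    days = np.arange(start_day, start_day + n_days)
    doys = np.array([doy_of(d) for d in days])
    vals = seasonal_baseline_temp(doys) + rng.normal(0, config.temp_noise_sd, len(days))
    if denning_interval is not None:
        a, b = denning_interval
        vals[(days >= a) & (days <= b)] += config.den_temp_offset
    return pd.Series(vals, index=days)


def _activity_series(plan: BearPlan, rng, start_day: int, n_days: int) -> pd.Series:
    days = np.arange(start_day, start_day + n_days)
    vals = rng.gamma(shape=2.0, scale=10.0, size=n_days)
    if plan.collar_drop_day is not None:
        vals[days >= plan.collar_drop_day] = 0.0
    return pd.Series(vals, index=days)


# --------------------------------------------------------------------------
# whole-study generation

_YEARS = {PERIOD_1: [1987, 1988, 1990, 1991, 1992, 1993], PERIOD_2: [2009, 2010, 2011, 2013]}


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Full seeded synthetic study: tracks, truths, ice years, coast."""
    config.validate()
    coast = make_coast()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
    )
    year_shifts: dict[int, float] = {}
    for period, years in _YEARS.items():
        # the recent period's ice retreats earlier everywhere
        base = 0.0 if period == PERIOD_1 else -25.0
        for yr in years:
            year_shifts[yr] = base + float(rng.normal(0.0, 8.0))

    plans: list[BearPlan] = []
    counts = {PERIOD_1: config.n_bears_period1, PERIOD_2: config.n_bears_period2}
    bear_index = 0
    for period, n in counts.items():
        years = _YEARS[period]
        for i in range(n):
            yr = years[i % len(years)]
            prng = _bear_rng(config, bear_index, 3)
            plans.append(
                _plan_bear(config, bear_index, period, yr, year_shifts[yr], prng)
            )
            bear_index += 1

    tracks: list[Track] = []
    truths: list[BearTruth] = []
    for i, plan in enumerate(plans):
        track, truth = generate_track(config, i, plan=plan)
        tracks.append(track)
        truths.append(truth)

    ice_by_year = {
        yr: generate_ice_stack(config, yr, retreat_shift_days=shift)
        for yr, shift in year_shifts.items()
    }
    return SyntheticStudy(
        config=config, coast=coast, tracks=tracks, truths=truths,
        ice_by_year=ice_by_year, year_shifts=year_shifts,
    )


# --------------------------------------------------------------------------
# direct use-availability simulator (for the selection-model recovery tests)

def simulate_use_avail(
    n_strata: int,
    beta: float,
    n_alternatives: int = 25,
    seed: int = 0,
    covariate_range: tuple[float, float] = (120.0, 300.0),
) -> list[UseAvailStratum]:
    """Strata drawn exactly from the conditional-logistic model.

    Each stratum has `n_alternatives` segments with retreat dates uniform on
    `covariate_range`; the used segment is drawn with probability
    proportional to exp(beta * retreat_date).
    """
    rng = np.random.default_rng(seed)
    strata = []
    for s in range(n_strata):
        x = rng.uniform(*covariate_range, size=n_alternatives)
        w = np.exp(beta * (x - x.mean()))
        used_idx = rng.choice(n_alternatives, p=w / w.sum())
        used = np.zeros(n_alternatives, int)
        used[used_idx] = 1
        strata.append(UseAvailStratum(f"s{s}", used, x[:, None]))
    return strata
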