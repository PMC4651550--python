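"""Denning detection from collar temperature.

A denning bear insulates its collar: winter collar temperatures sit well
above the ambient-driven baseline.  Detection compares each bear's daily
temperature with a weekly baseline built from non-denning bears and flags
maximal elevated runs of at least 35 days falling inside the winter window
(1 Oct - 31 May).  Substrate (land vs ice) is assigned from observed fixes
near or during the event, since fixes inside a snow den are scarce and poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeutil import doy_of, month_of_doy, week_of_doy

WINTER_MONTHS = {10, 11, 12, 1, 2, 3, 4, 5}


@dataclass
class WeeklyBaseline:
    """Per-calendar-week mean and SD of non-denning collar temperature."""

    mean: np.ndarray  # length 53
    sd: np.ndarray
    n_series: np.ndarray

    def threshold(self, k: float) -> np.ndarray:
        return self.mean + k * self.sd


def build_baseline(
    nondenning_temps: list[pd.Series], min_series: int = 3, robust: bool = False
) -> WeeklyBaseline:
    """Weekly baseline from a collection of non-denning temperature series.

    Each series is daily temperature indexed by integer study day.  Every
    winter week must be covered by at least `min_series` series.  With
    `robust=True` the location/scale are median and 1.4826*MAD, useful for a
    first pass when the non-denning subset is not yet known.
    """
    samples: list[list[float]] = [[] for _ in range(53)]
    contributors: list[set[int]] = [set() for _ in range(53)]
    for si, series in enumerate(nondenning_temps):
        days = np.asarray(series.index, float)
        vals = series.to_numpy(float)
        for d, v in zip(days, vals):
            if not np.isfinite(v):
                continue
            w = week_of_doy(doy_of(d))
            samples[w].append(v)
            contributors[w].add(si)

    mean = np.full(53, np.nan)
    sd = np.full(53, np.nan)
    n_series = np.zeros(53, dtype=int)
    for w in range(53):
        n_series[w] = len(contributors[w])
        if samples[w]:
            arr = np.asarray(samples[w])
            if robust:
                mean[w] = np.median(arr)
                sd[w] = 1.4826 * np.median(np.abs(arr - mean[w]))
            else:
                mean[w] = arr.mean()
                sd[w] = arr.std(ddof=0)

    winter_weeks = {
        w for w in range(53)
        if month_of_doy(min(7 * w + 1, 365)) in WINTER_MONTHS
    }
    short = [w for w in sorted(winter_weeks) if n_series[w] < min_series]
    if short:
        raise ValueError(
            f"winter weeks {short} have fewer than {min_series} contributing series"
        )
    return WeeklyBaseline(mean=mean, sd=sd, n_series=n_series)


@dataclass
class DenningEvent:
    bear_id: str
    start_day: float  # study day
    end_day: float
    duration: int
    substrate: str = "unknown"  # land | ice | unknown
    land_mass_label: str | None = None
    source: str = "temperature"

    @property
    def start_doy(self) -> int:
        return doy_of(self.start_day)

    @property
    def end_doy(self) -> int:
        return doy_of(self.end_day)


def detect_denning(
    temps: pd.Series,
    baseline: WeeklyBaseline,
    k: float = 2.0,
    min_days: int = 35,
    max_interruption_days: int = 2,
    bear_id: str = "",
) -> list[DenningEvent]:
    """Elevated-temperature run detection within the winter window.

    A day is elevated when its temperature exceeds the weekly baseline mean
    plus `k` SDs.  Elevated runs may be interrupted by up to
    `max_interruption_days` consecutive non-elevated days; runs are clipped
    to the 1 Oct - 31 May window and reported when at least `min_days` long.
    """
    days = np.asarray(temps.index, float)
    vals = temps.to_numpy(float)
    order = np.argsort(days)
    days, vals = days[order], vals[order]

    in_winter = np.array([month_of_doy(doy_of(d)) in WINTER_MONTHS for d in days])
    thr = baseline.threshold(k)
    elevated = np.array(
        [
            np.isfinite(v) and v > thr[week_of_doy(doy_of(d))]
            for d, v in zip(days, vals)
        ]
    )
    flag = elevated & in_winter

    events: list[DenningEvent] = []
    i = 0
    n = len(days)
    while i < n:
        if not flag[i]:
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        interruption = 0
        while j < n and days[j] == days[j - 1] + 1 and in_winter[j]:
            if flag[j]:
                end = j
                interruption = 0
            else:
                interruption += 1
                if interruption > max_interruption_days:
                    break
            j += 1
        duration = int(days[end] - days[start]) + 1
        if duration >= min_days:
            events.append(
                DenningEvent(
                    bear_id=bear_id,
                    start_day=days[start],
                    end_day=days[end],
                    duration=duration,
                )
            )
        i = end + 1
    return events


def assign_substrate(
    event: DenningEvent, track, coast, tolerance_days: float = 3.0
) -> str:
    """Den substrate from observed (not interpolated) fixes around the event.

    'land' if any fix within [start - tol, end + tol] classifies on land,
    'ice' if such fixes exist but none are on land, 'unknown' with no fixes.
    """
    f = track.fixes
    t = f["t"].to_numpy(float)
    in_win = (t >= event.start_day - tolerance_days) & (
        t <= event.end_day + tolerance_days
    )
    if not np.any(in_win):
        event.substrate = "unknown"
        return "unknown"
    on_land = [
        coast.on_land(x, y)
        for x, y in zip(f["x_km"].to_numpy()[in_win], f["y_km"].to_numpy()[in_win])
    ]
    if any(on_land):
        event.substrate = "land"
        idx = np.nonzero(in_win)[0][int(np.argmax(on_land))]
        event.land_mass_label = coast.land_mass_label(
            f["x_km"].iloc[idx], f["y_km"].iloc[idx]
        )
    else:
        event.substrate = "ice"
    return event.substrate
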