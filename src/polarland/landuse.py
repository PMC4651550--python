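"""Coastline geometry and per-bear-year land-use summaries.

A bear is "on land" when its (predicted) position falls inside a land
polygon or within a 5-km buffer of one; the buffer absorbs small barrier
islands missing from coarse coastlines and the error of low-quality fixes.
Summaries count non-consecutive on-land days inside the August-October
window, derive arrival/departure dates from onshore bouts, and attribute a
bear-year to the land mass holding the plurality of its on-land days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from shapely.prepared import prep

from .ctcrw import PredictedPath
from .timeutil import doy_of

WINDOW_START_DOY = 213  # 1 Aug
WINDOW_END_DOY = 304  # 31 Oct
WINDOW_DAYS = WINDOW_END_DOY - WINDOW_START_DOY + 1  # 92


class CoastGeometry:
    """Land polygons (planar km) with a fixed 5-km on-land buffer.

    Parameters
    ----------
    polygons : mapping of label -> shapely Polygon
        Closed land polygons in study-plane kilometres.
    buffer_km : float
        Distance from land within which a position counts as on land.
    """

    def __init__(self, polygons: dict[str, Polygon], buffer_km: float = 5.0):
        for label, poly in polygons.items():
            if not poly.is_valid or poly.is_empty:
                raise ValueError(f"invalid land polygon {label!r}")
        self.polygons = dict(polygons)
        self.buffer_km = float(buffer_km)
        self.land = unary_union(list(polygons.values()))
        self.buffered = self.land.buffer(buffer_km)
        self._prepared = prep(self.buffered)
        self._prepared_by_label = {
            label: prep(poly.buffer(buffer_km)) for label, poly in polygons.items()
        }

    def on_land(self, x: float, y: float) -> bool:
        """True iff (x, y) lies on land or within the buffer of it."""
        return bool(self._prepared.covers(Point(x, y)))

    def on_land_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.array([self.on_land(xi, yi) for xi, yi in zip(x, y)], dtype=bool)

    def land_mass_label(self, x: float, y: float) -> str | None:
        """Label of the (buffered) land mass containing the point, else None."""
        for label, prepared in self._prepared_by_label.items():
            if prepared.covers(Point(x, y)):
                return label
        return None


def classify_on_land(x: float, y: float, coast: CoastGeometry) -> bool:
    """Point-on-land test: inside a land polygon or within 5 km of one."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("coordinates must be finite")
    return coast.on_land(x, y)


@dataclass
class BearYearSummary:
    """Land-use metrics for one bear-year."""

    bear_id: str
    period: str
    days_on_land_aug_oct: int = 0
    used_gt7: bool = False
    used_gt21: bool = False
    arrival_doy: int | None = None
    departure_doy: int | None = None
    land_mass_label: str | None = None
    percent_locations_on_land: float | None = None
    n_days_with_locations: int = 0
    denned: bool | None = None
    den_substrate: str | None = None
    eligible: bool = True  # False when gaps intrude on the Aug-Oct window
    indeterminate: bool = False
    notes: list[str] = field(default_factory=list)


def _bouts(days: np.ndarray, flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive calendar days with flags True.

    Returns (start_day, end_day) pairs in the same day frame as `days`.
    """
    out: list[tuple[int, int]] = []
    start = prev = None
    for d, f in zip(days, flags):
        if f:
            if start is None:
                start = d
            elif d != prev + 1:
                out.append((start, prev))
                start = d
            prev = d
        else:
            if start is not None:
                out.append((start, prev))
                start = None
    if start is not None:
        out.append((start, prev))
    return out


def summarize_bear_year(
    path: PredictedPath,
    coast: CoastGeometry,
    bear_id: str = "",
    period: str = "",
    window: tuple[int, int] = (WINDOW_START_DOY, WINDOW_END_DOY),
) -> BearYearSummary:
    """Summering metrics for one predicted daily path.

    Counts non-gap-excluded window days on land (need not be consecutive),
    derives arrival (start of the longest onshore bout) and departure (end of
    the last bout before 31 Dec), and attributes the bear-year to the land
    mass with the plurality of on-land days.  A bear-year whose window
    contains any gap-excluded day is flagged ineligible for the period
    comparisons; a fully gap-excluded window is indeterminate.
    """
    s = BearYearSummary(bear_id=bear_id, period=period)
    days = path.days
    doys = np.array([doy_of(d) for d in days])
    lo, hi = window
    in_window = (doys >= lo) & (doys <= hi)
    usable = ~path.gap_excluded

    if not np.any(in_window & usable):
        s.indeterminate = True
        s.eligible = False
        return s
    if np.any(in_window & ~usable):
        s.eligible = False

    on_land = np.zeros(len(days), dtype=bool)
    on_land[usable] = coast.on_land_many(path.x[usable], path.y[usable])

    s.days_on_land_aug_oct = int(np.sum(on_land & in_window))
    s.used_gt7 = s.days_on_land_aug_oct > 7
    s.used_gt21 = s.days_on_land_aug_oct > 21
    s.n_days_with_locations = int(np.sum(usable))

    # bouts over 1 Jul - 31 Dec (usable days only)
    season = (doys >= 182) & (doys <= 365) & usable
    bouts = _bouts(days[season], on_land[season])
    if bouts:
        longest = max(bouts, key=lambda b: (b[1] - b[0], -b[0]))
        s.arrival_doy = doy_of(longest[0])
        s.departure_doy = doy_of(bouts[-1][1])

    if np.any(on_land):
        labels: dict[str, int] = {}
        order: dict[str, int] = {}
        for i in np.nonzero(on_land)[0]:
            lbl = coast.land_mass_label(path.x[i], path.y[i])
            if lbl is not None:
                labels[lbl] = labels.get(lbl, 0) + 1
                order.setdefault(lbl, i)
        if labels:
            # plurality of on-land days; ties to the earliest-visited mass
            s.land_mass_label = max(labels, key=lambda L: (labels[L], -order[L]))
    return s


def percent_year_on_land(
    path: PredictedPath, coast: CoastGeometry, min_days: int = 300
) -> float:
    """Percent of non-gap-excluded predicted days on land over a bear-year.

    Requires at least `min_days` usable days; shorter records are excluded
    from the whole-year comparison.
    """
    usable = ~path.gap_excluded
    n = int(np.sum(usable))
    if n < min_days:
        raise ValueError(
            f"bear-year has {n} days with locations; {min_days} required"
        )
    on_land = coast.on_land_many(path.x[usable], path.y[usable])
    return 100.0 * float(np.mean(on_land))
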