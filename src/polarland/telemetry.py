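"""Raw telemetry containers and pre-analysis screening.

Satellite collars yield fixes of very unequal quality.  Standard Argos
classes (3, 2, 1) and GPS fixes are kept unconditionally; class Z fixes
carry no location estimate and are discarded; auxiliary classes (0, A, B)
are kept only when corroborated by a temporally adjacent kept fix within
10 km, or when the movement they imply is plausible (speeds to both kept
neighbours under 10 km/h and a turning angle that is not extremely acute).
Dropped collars are truncated at the first sustained bout of zero activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .config import AUXILIARY_CLASSES, CLASS_ERROR_SD_M, STANDARD_CLASSES


@dataclass
class Track:
    """Observed fixes and sensor streams for one bear-year.

    `fixes` columns: t (float days since 1 Jan of the start year), x_km,
    y_km, qclass, error_sd_m.  Sensor streams are daily series indexed by
    integer day in the same frame.
    """

    bear_id: str
    period: str
    fixes: pd.DataFrame
    temperature: pd.Series | None = None
    activity: pd.Series | None = None
    capture_label: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        t = self.fixes["t"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("fix timestamps must be strictly increasing")
        for qc, sd in zip(self.fixes["qclass"], self.fixes["error_sd_m"]):
            expected = CLASS_ERROR_SD_M.get(str(qc))
            if expected is not None and not np.isclose(sd, expected):
                raise ValueError(
                    f"error_sd {sd} inconsistent with class {qc} ({expected})"
                )

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def subset(self, mask: np.ndarray) -> "Track":
        return replace(self, fixes=self.fixes.loc[mask].reset_index(drop=True))


class Reason(str, Enum):
    standard_class = "standard_class"
    rejected_Z = "rejected_Z"
    corroborated_10km = "corroborated_10km"
    rate_angle_pass = "rate_angle_pass"
    rate_fail = "rate_fail"
    angle_fail = "angle_fail"
    post_drop = "post_drop"


@dataclass
class FilterDecision:
    index: int
    kept: bool
    reason: Reason


def _turn_angle_deg(p0, p1, p2) -> float:
    """Interior angle at p1 between segments p0->p1 and p1->p2.

    180 deg is straight-line travel; near 0 deg is an out-and-back spike,
    the signature of an implausible fix.
    """
    u = np.asarray(p0, float) - np.asarray(p1, float)
    v = np.asarray(p2, float) - np.asarray(p1, float)
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        return 180.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def filter_track(
    track: Track,
    max_rate: float = 10.0,
    corroboration_radius: float = 10.0,
    min_turn_angle_deg: float = 30.0,
) -> tuple[Track, list[FilterDecision]]:
    """Screen fixes for plausibility before movement modelling.

    Auxiliary fixes are evaluated against the kept set iteratively (keeps
    only ever accumulate, so the pass converges and the whole operation is
    idempotent); a consecutive kept fix within `corroboration_radius` km on
    either side corroborates, otherwise speeds to both kept neighbours must
    be below `max_rate` km/h and the turning angle at the fix must be at
    least `min_turn_angle_deg`.
    """
    if track.n_fixes == 0:
        raise ValueError("cannot filter an empty track")
    t = track.fixes["t"].to_numpy(float)
    x = track.fixes["x_km"].to_numpy(float)
    y = track.fixes["y_km"].to_numpy(float)
    qc = track.fixes["qclass"].astype(str).to_numpy()

    unknown = set(qc) - set(CLASS_ERROR_SD_M) - {"Z"}
    if unknown:
        raise ValueError(f"unknown quality classes: {sorted(unknown)}")

    n = len(t)
    kept = np.zeros(n, dtype=bool)
    reason = np.empty(n, dtype=object)
    for i in range(n):
        if qc[i] in STANDARD_CLASSES:
            kept[i] = True
            reason[i] = Reason.standard_class
        elif qc[i] == "Z":
            reason[i] = Reason.rejected_Z

    aux = [i for i in range(n) if qc[i] in AUXILIARY_CLASSES]
    changed = True
    while changed:
        changed = False
        for i in aux:
            if kept[i]:
                continue
            prev_k = next((j for j in range(i - 1, -1, -1) if kept[j]), None)
            next_k = next((j for j in range(i + 1, n) if kept[j]), None)
            neighbours = [j for j in (prev_k, next_k) if j is not None]
            if not neighbours:
                continue
            dists = [np.hypot(x[i] - x[j], y[i] - y[j]) for j in neighbours]
            if min(dists) <= corroboration_radius:
                kept[i] = True
                reason[i] = Reason.corroborated_10km
                changed = True
                continue
            speeds = [
                np.hypot(x[i] - x[j], y[i] - y[j]) / (abs(t[i] - t[j]) * 24.0)
                for j in neighbours
            ]
            if any(s >= max_rate for s in speeds):
                reason[i] = Reason.rate_fail
                continue
            if prev_k is not None and next_k is not None:
                ang = _turn_angle_deg(
                    (x[prev_k], y[prev_k]), (x[i], y[i]), (x[next_k], y[next_k])
                )
                if ang < min_turn_angle_deg:
                    reason[i] = Reason.angle_fail
                    continue
            kept[i] = True
            reason[i] = Reason.rate_angle_pass
            changed = True

    # aux fixes with no kept neighbour at all: uncorroboratable, drop as rate_fail
    for i in aux:
        if not kept[i] and reason[i] is None:
            reason[i] = Reason.rate_fail

    decisions = [FilterDecision(i, bool(kept[i]), reason[i]) for i in range(n)]
    return track.subset(kept), decisions


def truncate_dropped_collar(track: Track, min_zero_days: int = 7) -> Track:
    """Remove fixes after the first sustained zero-activity epoch.

    A collar lying on the ground reports zero activity indefinitely; a run of
    at least `min_zero_days` consecutive days of zero activity marks the drop
    and every fix from the run's first day onward is discarded.
    """
    if track.activity is None:
        raise ValueError("activity series required to detect dropped collars")
    act = track.activity
    days = np.asarray(act.index, dtype=float)
    zero = act.to_numpy() == 0
    run = 0
    drop_day: float | None = None
    for d, z in zip(days, zero):
        if z:
            run += 1
            if run >= min_zero_days:
                drop_day = d - (run - 1)
                break
        else:
            run = 0
    if drop_day is None:
        return track
    keep = track.fixes["t"].to_numpy(float) < drop_day
    return track.subset(keep)


def decisions_frame(decisions: list[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [d.index for d in decisions],
            "kept": [d.kept for d in decisions],
            "reason": [d.reason.value if d.reason else "" for d in decisions],
        }
    )
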