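"""End-to-end study orchestration.

`run_study` drives the whole analysis on a seeded synthetic study: generate
→ screen fixes → fit the movement model and predict daily positions →
classify land use and summering metrics → detect denning → compute ice
phenology → run every statistical comparison, returning a `StudyReport`
whose numbers all trace back to module outputs.

`reproduce_printed_stats` recomputes the comparison statistics directly
from a table of group counts / means / SDs, so the published summary
numbers can be regenerated without any location data.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PERIOD_1, PERIOD_2, SimConfig, StudyConfig
from .ctcrw import PredictedPath, data_gap_fraction, fit_ctcrw, predict_daily
from .denning import assign_substrate, build_baseline, detect_denning
from .ice import coastal_segments, segment_phenology, shelf_ice_fraction
from .landuse import percent_year_on_land, summarize_bear_year
from .stats import (
    FitResult,
    UseAvailStratum,
    anova_from_summary,
    aic_compare,
    chi2_contingency,
    conditional_logistic,
    linear_regression,
    logistic_two_group,
)
from .synthetic import generate_study, make_masks
from .telemetry import filter_track, truncate_dropped_collar


@dataclass
class StudyReport:
    """Headline results of one end-to-end run."""

    seed: int
    counts: dict = field(default_factory=dict)
    proportions: dict = field(default_factory=dict)
    durations: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    denning: dict = field(default_factory=dict)
    ice: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, FitResult):
                return o.to_dict()
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return o

        return conv(dataclasses.asdict(self) | {"fits": self.fits})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))


def _period_counts(summaries, attr: str) -> dict[str, tuple[int, int]]:
    out = {}
    for period in (PERIOD_1, PERIOD_2):
        rows = [s for s in summaries if s.period == period and s.eligible]
        out[period] = (sum(getattr(s, attr) for s in rows), len(rows))
    return out


def _group_summary(values: list[float]):
    arr = np.asarray(values, float)
    return float(arr.mean()), float(arr.std(ddof=1)), len(arr)


def run_study(
    sim_config: SimConfig | None = None,
    study_config: StudyConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Run the full pipeline on a synthetic study; deterministic in (config, seed)."""
    sim = sim_config or SimConfig()
    if seed is not None:
        sim = dataclasses.replace(sim, seed=seed)
    cfg = study_config or StudyConfig()
    report = StudyReport(seed=sim.seed)

    study = generate_study(sim)
    coast = study.coast

    # --- screening, movement model, daily prediction -----------------------
    paths: list[PredictedPath | None] = []
    kept_tracks = []
    for track in study.tracks:
        if track.activity is not None:
            track = truncate_dropped_collar(track, cfg.drop_zero_activity_days)
        filtered, _ = filter_track(
            track, cfg.max_rate_kmh, cfg.corroboration_radius_km,
            cfg.min_turn_angle_deg,
        )
        kept_tracks.append(filtered)
        try:
            fit = fit_ctcrw(filtered)
            t = filtered.fixes["t"].to_numpy(float)
            path = predict_daily(
                fit, filtered, int(t[0]), int(t[-1]), cfg.max_gap_days
            )
        except ValueError:
            path = None
        paths.append(path)

    summaries = []
    pct_year = {PERIOD_1: [], PERIOD_2: []}
    for track, path in zip(kept_tracks, paths):
        if path is None:
            continue
        s = summarize_bear_year(
            path, coast, bear_id=track.bear_id, period=track.period,
            window=(cfg.window_start_doy, cfg.window_end_doy),
        )
        summaries.append(s)
        try:
            s.percent_locations_on_land = percent_year_on_land(
                path, coast, cfg.min_year_days
            )
            pct_year[track.period].append(s.percent_locations_on_land)
        except ValueError:
            pass

    # --- land-use comparisons ----------------------------------------------
    gt7 = _period_counts(summaries, "used_gt7")
    gt21 = _period_counts(summaries, "used_gt21")
    report.counts["gt7"] = gt7
    report.counts["gt21"] = gt21
    report.counts["excluded_for_gaps"] = sum(1 for s in summaries if not s.eligible)
    for name, counts in (("gt7", gt7), ("gt21", gt21)):
        (k1, n1), (k2, n2) = counts[PERIOD_1], counts[PERIOD_2]
        report.proportions[name] = {
            PERIOD_1: k1 / n1 if n1 else float("nan"),
            PERIOD_2: k2 / n2 if n2 else float("nan"),
        }
        try:
            report.fits[f"logistic_{name}"] = logistic_two_group(
                k1, n1, k2, n2, label=f"land use >{name[2:]} days"
            )
        except ValueError as exc:
            report.fits[f"logistic_{name}"] = str(exc)

    users = [s for s in summaries if s.eligible and s.used_gt7]
    for metric, attr, subset in (
        ("days_on_land", "days_on_land_aug_oct", users),
        ("arrival_doy", "arrival_doy", [s for s in users if s.arrival_doy]),
    ):
        groups = {
            p: [getattr(s, attr) for s in subset if s.period == p]
            for p in (PERIOD_1, PERIOD_2)
        }
        if all(len(v) >= 2 for v in groups.values()):
            m1, sd1, n1 = _group_summary(groups[PERIOD_1])
            m2, sd2, n2 = _group_summary(groups[PERIOD_2])
            report.durations[metric] = {
                PERIOD_1: {"mean": m1, "sd": sd1, "n": n1},
                PERIOD_2: {"mean": m2, "sd": sd2, "n": n2},
            }
            report.fits[f"anova_{metric}"] = anova_from_summary(
                m1, sd1, n1, m2, sd2, n2, label=metric
            )
    if all(len(v) >= 2 for v in pct_year.values()):
        m1, sd1, n1 = _group_summary(pct_year[PERIOD_1])
        m2, sd2, n2 = _group_summary(pct_year[PERIOD_2])
        report.fits["anova_pct_locations"] = anova_from_summary(
            m1, sd1, n1, m2, sd2, n2, label="percent locations on land"
        )

    # --- denning ------------------------------------------------------------
    temp_series = [t.temperature for t in kept_tracks if t.temperature is not None]
    events_by_bear: dict[str, list] = {}
    if len(temp_series) >= 3:
        # iterate: robust baseline over presumed non-denners, re-detect,
        # drop newly flagged denners, until the non-denning set stabilises;
        # the final baseline is the plain mean/SD one over that set
        with_temp = [t for t in kept_tracks if t.temperature is not None]
        provisional: set[str] = set()
        for _ in range(5):
            pool = [
                t.temperature for t in with_temp if t.bear_id not in provisional
            ]
            if len(pool) < 3:
                break
            rough = build_baseline(pool, robust=True)
            flagged = {
                t.bear_id
                for t in with_temp
                if detect_denning(
                    t.temperature, rough, cfg.denning_k_sd, cfg.min_denning_days,
                    cfg.denning_max_interruption_days,
                )
            }
            if flagged == provisional:
                break
            provisional = flagged
        nondenning = [
            t.temperature for t in with_temp if t.bear_id not in provisional
        ]
        baseline = (
            build_baseline(nondenning)
            if len(nondenning) >= 3
            else build_baseline(temp_series, robust=True)
        )
        for track in kept_tracks:
            if track.temperature is None:
                continue
            events = detect_denning(
                track.temperature, baseline, cfg.denning_k_sd,
                cfg.min_denning_days, cfg.denning_max_interruption_days,
                bear_id=track.bear_id,
            )
            for ev in events:
                assign_substrate(ev, track, coast)
            if events:
                events_by_bear[track.bear_id] = events
        substrate = {
            p: {"land": 0, "ice": 0, "unknown": 0} for p in (PERIOD_1, PERIOD_2)
        }
        for track in kept_tracks:
            for ev in events_by_bear.get(track.bear_id, []):
                substrate[track.period][ev.substrate] += 1
        report.denning["substrate"] = substrate
        report.denning["n_events"] = sum(len(v) for v in events_by_bear.values())
        l1, i1 = substrate[PERIOD_1]["land"], substrate[PERIOD_1]["ice"]
        l2, i2 = substrate[PERIOD_2]["land"], substrate[PERIOD_2]["ice"]
        if min(l1 + i1, l2 + i2) > 0:
            try:
                report.fits["logistic_den_substrate"] = logistic_two_group(
                    l1, l1 + i1, l2, l2 + i2, label="den on land vs ice"
                )
            except ValueError as exc:
                report.fits["logistic_den_substrate"] = str(exc)

    # --- ice phenology -------------------------------------------------------
    land_mask, shelf_mask, labels = make_masks(sim.grid_n, sim.grid_cell_km)
    seg_by_year = {}
    shelf_frac_by_year = {}
    for yr, stack in study.ice_by_year.items():
        segs = coastal_segments(land_mask, labels)
        segment_phenology(
            stack, segs, cfg.ice_threshold, cfg.retreat_distance_km,
            cfg.connectivity,
        )
        seg_by_year[yr] = segs
        shelf_frac_by_year[yr] = shelf_ice_fraction(
            stack, (cfg.window_start_doy, cfg.window_end_doy), cfg.ice_threshold
        )
    report.ice["shelf_fraction_by_year"] = shelf_frac_by_year
    report.ice["mean_shelf_fraction"] = {
        p: float(
            np.mean([
                shelf_frac_by_year[t.year]
                for t in kept_tracks if t.period == p
            ])
        )
        for p in (PERIOD_1, PERIOD_2)
    }
    sentinels = {
        yr: sum(
            1 for s in segs if (s.retreat_doy, s.return_doy) == (365, 1)
        )
        for yr, segs in seg_by_year.items()
    }
    report.ice["n_sentinel_segments_by_year"] = sentinels

    # --- days on land vs shelf ice cover -------------------------------------
    year_of = {t.bear_id: t.year for t in kept_tracks}
    by_year: dict[int, list[float]] = {}
    for s in users:
        by_year.setdefault(year_of[s.bear_id], []).append(s.days_on_land_aug_oct)
    xs, ys = [], []
    for yr, vals in sorted(by_year.items()):
        if len(vals) >= 2:
            xs.append(shelf_frac_by_year[yr] * 100.0)
            ys.append(float(np.mean(vals)))
    if len(xs) >= 3:
        report.fits["regression_days_vs_ice"] = linear_regression(
            xs, ys, label="mean days on land vs shelf ice cover (%)"
        )

    # --- resource selection (use-availability) -------------------------------
    strata_retreat, strata_return = [], []
    for s in users:
        if s.land_mass_label is None:
            continue
        yr = year_of[s.bear_id]
        segs = seg_by_year[yr]
        track = next(t for t in kept_tracks if t.bear_id == s.bear_id)
        path = paths[[t.bear_id for t in kept_tracks].index(s.bear_id)]
        doys = path.days % 365 + 1
        usable = (
            ~path.gap_excluded
            & (doys >= cfg.window_start_doy)
            & (doys <= cfg.window_end_doy)
        )
        on_land = coast.on_land_many(path.x[usable], path.y[usable])
        if not on_land.any():
            continue
        cx = float(np.mean(path.x[usable][on_land]))
        cy = float(np.mean(path.y[usable][on_land]))
        cells = np.array([
            ((c.cell[1] + 0.5) * sim.grid_cell_km, (c.cell[0] + 0.5) * sim.grid_cell_km)
            for c in segs
        ])
        used_idx = int(np.argmin((cells[:, 0] - cx) ** 2 + (cells[:, 1] - cy) ** 2))
        used = np.zeros(len(segs), int)
        used[used_idx] = 1
        is_p2 = 1.0 if s.period == PERIOD_2 else 0.0
        retreat = np.array([c.retreat_doy for c in segs], float)
        ret = np.array([c.return_doy for c in segs], float)
        strata_retreat.append(
            UseAvailStratum(
                s.bear_id, used, np.column_stack([retreat, retreat * is_p2])
            )
        )
        strata_return.append(
            UseAvailStratum(s.bear_id, used, np.column_stack([ret, ret * is_p2]))
        )
    if strata_retreat:
        fit_retreat = conditional_logistic(
            strata_retreat, names=["retreat_doy", "retreat_doy:period2"],
            label="selection ~ retreat date",
        )
        fit_return = conditional_logistic(
            strata_return, names=["return_doy", "return_doy:period2"],
            label="selection ~ return date",
        )
        report.fits["clogit_retreat"] = fit_retreat
        report.fits["clogit_return"] = fit_return
        report.fits["aic_table"] = aic_compare([fit_retreat, fit_return])

    # --- capture vs summering location ---------------------------------------
    rows = {}
    for s in users:
        track = next(t for t in kept_tracks if t.bear_id == s.bear_id)
        rows.setdefault(track.capture_label, {}).setdefault(s.land_mass_label, 0)
        rows[track.capture_label][s.land_mass_label] += 1
    if len(rows) >= 2:
        cols = sorted({c for r in rows.values() for c in r})
        table = [[rows[r].get(c, 0) for c in cols] for r in sorted(rows)]
        try:
            report.fits["chi2_capture_vs_summering"] = chi2_contingency(
                table, label="capture vs summering location"
            )
        except ValueError as exc:
            report.fits["chi2_capture_vs_summering"] = str(exc)

    report.counts["data_gap_fraction_gt4d"] = {
        p: float(
            np.nanmean([
                data_gap_fraction(t) for t in kept_tracks if t.period == p
            ])
        )
        for p in (PERIOD_1, PERIOD_2)
    }
    report.provenance["bear_ids"] = [t.bear_id for t in kept_tracks]
    report.provenance["n_tracks"] = len(kept_tracks)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "study_report.json")
        manifest = {
            "seed": sim.seed,
            "n_bears": {PERIOD_1: sim.n_bears_period1, PERIOD_2: sim.n_bears_period2},
            "outputs": ["study_report.json"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def reproduce_printed_stats(table_path: str | Path | None = None) -> dict[str, FitResult]:
    """Recompute comparison statistics from printed group summaries.

    The bundled table carries the group counts (logistic rows) and group
    mean/SD/n triples (ANOVA rows) of the published comparisons; each row is
    recomputed with the same closed-form estimators used on pipeline output.
    """
    if table_path is None:
        ref = importlib.resources.files("polarland").joinpath(
            "data/printed_summaries.csv"
        )
        df = pd.read_csv(ref)
    else:
        df = pd.read_csv(table_path)
    required = {"kind", "label"}
    if df.empty:
        return {}
    if not required.issubset(df.columns):
        raise ValueError("summary table must have 'kind' and 'label' columns")
    out: dict[str, FitResult] = {}
    for _, row in df.iterrows():
        if row["kind"] == "logistic":
            out[row["label"]] = logistic_two_group(
                int(row["k1"]), int(row["n1"]), int(row["k2"]), int(row["n2"]),
                label=row["label"],
            )
        elif row["kind"] == "anova":
            out[row["label"]] = anova_from_summary(
                float(row["mean1"]), float(row["sd1"]), int(row["n1"]),
                float(row["mean2"]), float(row["sd2"]), int(row["n2"]),
                label=row["label"],
            )
        else:
            raise ValueError(f"unknown row kind {row['kind']!r}")
    return out
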