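"""Study configuration.

All analysis thresholds live in :class:`StudyConfig`; everything the
synthetic-data generator needs lives in :class:`SimConfig`.  Both are plain
dataclasses serialisable to/from a single JSON file so that a whole study run
is reproducible from ``(config, seed)``.

Coordinates are planar kilometres in a locally equal-distance projection of
the study area; the operative distances of the analysis (5, 10 and 50 km) are
all small enough that planar geometry is adequate.  Calendar handling uses
ordinal dates 1-365; leap days are dropped throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

#: Prescribed measurement error (metres, 1-sigma per axis) for each Argos
#: location quality class, plus GPS.  Class Z carries no usable accuracy and
#: is always rejected by the filter.
CLASS_ERROR_SD_M: dict[str, float] = {
    "3": 150.0,
    "2": 350.0,
    "1": 1000.0,
    "0": 1500.0,
    "A": 5000.0,
    "B": 10000.0,
    "GPS": 30.0,
}

#: Classes always kept by the plausibility filter.
STANDARD_CLASSES = ("3", "2", "1", "GPS")
#: Auxiliary classes kept only when corroborated or movement-plausible.
AUXILIARY_CLASSES = ("0", "A", "B")

PERIOD_1 = "1986-1995"
PERIOD_2 = "2008-2013"


@dataclass
class StudyConfig:
    """Thresholds of the land-use analysis (defaults are the study's values)."""

    land_buffer_km: float = 5.0
    ice_threshold: float = 0.15
    retreat_distance_km: float = 50.0
    min_denning_days: int = 35
    max_gap_days: float = 14.0
    summer_use_days: int = 7
    extended_use_days: int = 21
    min_year_days: int = 300
    window_start_doy: int = 213  # 1 Aug
    window_end_doy: int = 304  # 31 Oct
    max_rate_kmh: float = 10.0
    corroboration_radius_km: float = 10.0
    min_turn_angle_deg: float = 30.0
    drop_zero_activity_days: int = 7
    denning_k_sd: float = 2.0
    denning_max_interruption_days: int = 2
    grid_cell_km: float = 25.0
    connectivity: int = 8


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    Defaults emulate the observed study conditions: two collaring periods
    with different fix schedules, Argos-class error mixtures, the observed
    proportions of bear-years summering on land (0.200 vs 0.389 for the
    >7-day criterion) and the observed mean onshore durations (32.7 vs 62.6
    days).
    """

    seed: int = 0
    n_bears_period1: int = 80
    n_bears_period2: int = 36
    # OU-velocity movement process
    ctcrw_beta: float = 0.5  # 1/day, velocity autocorrelation decay
    ctcrw_sigma: float = 2.0  # km/day^1.5, velocity diffusion
    # observation schedule (days between fixes) per period; period 2 mixes
    # Argos and GPS collars, GPS reporting four times per day
    fix_interval_days_by_period: dict[str, float] = field(
        default_factory=lambda: {PERIOD_1: 3.0, PERIOD_2: 0.25}
    )
    gps_fraction_period2: float = 0.6
    p_fix_dropout: float = 0.05
    p_long_outage: float = 0.15  # per bear-year; outage up to 20 days
    max_outage_days: float = 20.0
    argos_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "3": 0.10,
            "2": 0.15,
            "1": 0.20,
            "0": 0.20,
            "A": 0.20,
            "B": 0.13,
            "Z": 0.02,
        }
    )
    # land-use behaviour
    p_land_user_by_period: dict[str, float] = field(
        default_factory=lambda: {PERIOD_1: 0.200, PERIOD_2: 0.389}
    )
    mean_days_on_land_by_period: dict[str, float] = field(
        default_factory=lambda: {PERIOD_1: 32.7, PERIOD_2: 62.6}
    )
    sd_days_on_land: float = 20.0
    mean_arrival_doy_by_period: dict[str, float] = field(
        default_factory=lambda: {PERIOD_1: 261.0, PERIOD_2: 241.0}
    )
    sd_arrival_doy: float = 12.0
    denning_prob: float = 0.35
    p_den_on_land: float = 0.88
    den_temp_offset: float = 8.0  # deg C above seasonal baseline
    temp_noise_sd: float = 1.5  # deg C daily noise
    # ice field: ordinal retreat date as a function of northing (km); the
    # northernmost coast retreats ~126 days after the southernmost
    ice_retreat_doy_by_latitude: dict[str, float] = field(
        default_factory=lambda: {"south": 150.0, "north": 276.0}
    )
    # freeze-up sweeps southward: the northern coast sees ice return first
    ice_return_doy_by_latitude: dict[str, float] = field(
        default_factory=lambda: {"south": 364.0, "north": 312.0}
    )
    grid_cell_km: float = 25.0
    grid_n: int = 40  # grid is grid_n x grid_n cells
    track_start_doy: int = 105  # mid-April capture
    track_days: int = 330

    def validate(self) -> None:
        if self.ctcrw_beta <= 0 or self.ctcrw_sigma <= 0:
            raise ValueError("OU process parameters must be positive")
        probs = (
            [self.p_fix_dropout, self.p_long_outage, self.denning_prob,
             self.p_den_on_land, self.gps_fraction_period2]
            + list(self.p_land_user_by_period.values())
            + list(self.argos_class_mix.values())
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.argos_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("argos_class_mix must sum to 1")


def save_config(cfg, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2))


def load_config(path: str | Path, cls=SimConfig):
    data = json.loads(Path(path).read_text())
    return cls(**data)
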