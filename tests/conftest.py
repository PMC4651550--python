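import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from polarland.config import SimConfig
from polarland.landuse import CoastGeometry
from polarland.telemetry import Track


@pytest.fixture(scope="session")
def simple_coast():
    """One square island (100x100 km at origin-ish) plus a southern mainland."""
    return CoastGeometry(
        {
            "island": box(100.0, 100.0, 200.0, 200.0),
            "mainland": box(0.0, 0.0, 500.0, 20.0),
        },
        buffer_km=5.0,
    )


def make_track(times, xy, qclass="GPS", bear_id="T1", period="1986-1995",
               activity=None, temperature=None):
    """Convenience Track builder used across the suite."""
    from polarland.config import CLASS_ERROR_SD_M

    times = np.asarray(times, float)
    xy = np.asarray(xy, float)
    if isinstance(qclass, str):
        qclass = [qclass] * len(times)
    sds = [CLASS_ERROR_SD_M.get(q, 3e5) for q in qclass]
    fixes = pd.DataFrame(
        {
            "t": times,
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "qclass": qclass,
            "error_sd_m": sds,
        }
    )
    return Track(
        bear_id=bear_id, period=period, fixes=fixes,
        activity=activity, temperature=temperature,
    )


@pytest.fixture()
def sim_config():
    return SimConfig(seed=123)
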