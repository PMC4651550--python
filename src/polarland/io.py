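"""Plain-text serialisation: track CSVs, ASCII ice rasters, JSON results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ice import IceStack
from .telemetry import Track


def write_track_csv(track: Track, path: str | Path) -> None:
    df = track.fixes.copy()
    df.insert(0, "bear_id", track.bear_id)
    df.insert(1, "period", track.period)
    df.to_csv(path, index=False)


def read_track_csv(path: str | Path) -> Track:
    df = pd.read_csv(path, dtype={"qclass": str})
    bear_id = str(df["bear_id"].iloc[0])
    period = str(df["period"].iloc[0])
    fixes = df[["t", "x_km", "y_km", "qclass", "error_sd_m"]].reset_index(drop=True)
    return Track(bear_id=bear_id, period=period, fixes=fixes)


def write_ice_stack(stack: IceStack, directory: str | Path) -> None:
    """One whitespace-separated ASCII grid per day plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {
        "cell_km": stack.cell_km,
        "shape": list(stack.conc.shape[1:]),
        "layers": [],
    }
    for doy, grid in zip(stack.doys, stack.conc):
        name = f"conc_d{int(doy):03d}.asc"
        np.savetxt(directory / name, grid, fmt="%.4f")
        index["layers"].append({"doy": int(doy), "file": name})
    np.savetxt(directory / "land_mask.asc", stack.land_mask.astype(int), fmt="%d")
    np.savetxt(directory / "shelf_mask.asc", stack.shelf_mask.astype(int), fmt="%d")
    (directory / "index.json").write_text(json.dumps(index, indent=1))


def read_ice_stack(directory: str | Path) -> IceStack:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    doys = np.array([layer["doy"] for layer in index["layers"]])
    conc = np.stack(
        [np.loadtxt(directory / layer["file"]) for layer in index["layers"]]
    )
    land = np.loadtxt(directory / "land_mask.asc").astype(bool)
    shelf = np.loadtxt(directory / "shelf_mask.asc").astype(bool)
    return IceStack(
        doys=doys, conc=conc, land_mask=land, shelf_mask=shelf,
        cell_km=float(index["cell_km"]),
    )
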