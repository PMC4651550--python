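"""Sea-ice phenology from daily concentration grids.

Metrics per year: weekly mean concentration grids; the pack ice, defined as
the largest contiguous (8-connected by default) area of weekly mean
concentration at or above 15%; per-coastal-segment retreat and return dates,
where retreat is the first ordinal date the pack ice lies more than 50 km
from the segment and return is the first subsequent date it is back within
50 km; and the mean daily fraction of the continental shelf covered by ice
of at least 15% concentration during August-October.  A coast the pack ice
never leaves receives the sentinel dates (365, 1).

Grids are regular 25-km planar rasters held as numpy arrays; distances are
centre-to-centre Euclidean kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .timeutil import N_WEEKS, week_of_doy, week_start_doy


@dataclass
class IceStack:
    """Dated concentration grids with land and shelf masks.

    `conc` has shape (n_days, ny, nx) with values in [0, 1] or NaN;
    `doys` gives the ordinal date of each layer.  `cell_km` is the grid
    spacing; masks share the grid shape.
    """

    doys: np.ndarray
    conc: np.ndarray
    land_mask: np.ndarray
    shelf_mask: np.ndarray
    cell_km: float = 25.0
    is_weekly: bool = False

    def __post_init__(self) -> None:
        if self.conc.ndim != 3 or self.conc.shape[0] != len(self.doys):
            raise ValueError("concentration stack must be (n_days, ny, nx)")
        if self.land_mask.shape != self.conc.shape[1:]:
            raise ValueError("land mask must match grid shape")
        finite = self.conc[np.isfinite(self.conc)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("concentrations must lie in [0, 1]")


@dataclass
class CoastalSegment:
    """One 25-km land-adjacent water cell with its phenology dates."""

    segment_id: int
    cell: tuple[int, int]  # (row, col)
    land_mass_label: str | None = None
    retreat_doy: int | None = None
    return_doy: int | None = None


def weekly_mean(stack: IceStack) -> IceStack:
    """Per-cell mean concentration over 7-day blocks starting 1 Jan.

    Missing days are ignored within each block; a block with no days at all
    is an error.
    """
    weeks = np.array([week_of_doy(int(d)) for d in stack.doys])
    present = sorted(set(weeks.tolist()))
    out = np.full((len(present), *stack.conc.shape[1:]), np.nan)
    doys = np.empty(len(present), dtype=int)
    for k, w in enumerate(present):
        block = stack.conc[weeks == w]
        if block.size == 0 or np.all(np.isnan(block)):
            raise ValueError(f"week {w} has no concentration data")
        with np.errstate(invalid="ignore"):
            out[k] = np.nanmean(block, axis=0)
        doys[k] = week_start_doy(w)
    return IceStack(
        doys=doys,
        conc=out,
        land_mask=stack.land_mask,
        shelf_mask=stack.shelf_mask,
        cell_km=stack.cell_km,
        is_weekly=True,
    )


_STRUCTURE = {4: ndimage.generate_binary_structure(2, 1),
              8: ndimage.generate_binary_structure(2, 2)}


def pack_ice_component(
    grid: np.ndarray,
    threshold: float = 0.15,
    land_mask: np.ndarray | None = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Boolean mask of the largest contiguous ice area at >= threshold.

    Contiguity is 8-connected by default; land cells never belong to the
    pack.  Returns an all-False mask when no cell reaches the threshold.
    Ties between equal-sized components resolve to the one whose first cell
    appears earliest in row-major order.
    """
    above = np.asarray(grid) >= threshold
    if land_mask is not None:
        above = above & ~land_mask
    labels, n = ndimage.label(above, structure=_STRUCTURE[connectivity])
    if n == 0:
        return np.zeros_like(above, dtype=bool)
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax: earliest label on ties
    return labels == best


def _min_distance_km(cell: tuple[int, int], component: np.ndarray, cell_km: float):
    """Centre-to-centre distance from a cell to the nearest component cell."""
    if not component.any():
        return np.inf
    rows, cols = np.nonzero(component)
    d2 = (rows - cell[0]) ** 2 + (cols - cell[1]) ** 2
    return float(np.sqrt(d2.min())) * cell_km


def retreat_return_dates(
    segment_cell: tuple[int, int],
    weekly_components: list[tuple[int, np.ndarray]],
    distance_km: float = 50.0,
    cell_km: float = 25.0,
) -> tuple[int, int]:
    """Ice retreat and return ordinal dates for one coastal segment.

    `weekly_components` is a list of (week_start_doy, pack-ice mask) in
    chronological order.  Retreat is the first week-start date with the pack
    more than `distance_km` away (an empty pack counts as retreated); return
    is the first later date with the pack back within `distance_km`.  A
    segment the ice never leaves gets (365, 1); ice that never comes back
    gets return 365.
    """
    retreat: int | None = None
    ret: int | None = None
    for doy, comp in weekly_components:
        d = _min_distance_km(segment_cell, comp, cell_km)
        if retreat is None:
            if d > distance_km:
                retreat = int(doy)
        elif ret is None and d <= distance_km:
            ret = int(doy)
            break
    if retreat is None:
        return 365, 1
    return retreat, (ret if ret is not None else 365)


def shelf_ice_fraction(
    stack: IceStack,
    window: tuple[int, int] = (213, 304),
    threshold: float = 0.15,
) -> float:
    """Mean daily fraction of shelf cells covered by >= threshold ice.

    The window defaults to 1 Aug - 31 Oct, bracketing the annual minimum.
    """
    shelf = stack.shelf_mask & ~stack.land_mask
    n_shelf = int(shelf.sum())
    if n_shelf == 0:
        raise ValueError("shelf mask is empty")
    lo, hi = window
    sel = (stack.doys >= lo) & (stack.doys <= hi)
    if not np.any(sel):
        raise ValueError("no layers fall inside the window")
    fracs = [
        float(np.sum(day[shelf] >= threshold)) / n_shelf for day in stack.conc[sel]
    ]
    return float(np.mean(fracs))


def coastal_segments(
    land_mask: np.ndarray, labels: np.ndarray | None = None
) -> list[CoastalSegment]:
    """Land-adjacent water cells, one segment per cell (8-neighbourhood)."""
    dilated = ndimage.binary_dilation(land_mask, structure=_STRUCTURE[8])
    coastal = dilated & ~land_mask
    segments = []
    for sid, (r, c) in enumerate(zip(*np.nonzero(coastal))):
        lbl = None
        if labels is not None:
            r0, r1 = max(r - 1, 0), min(r + 2, land_mask.shape[0])
            c0, c1 = max(c - 1, 0), min(c + 2, land_mask.shape[1])
            patch = labels[r0:r1, c0:c1]
            vals = [v for v in patch.ravel() if v]
            lbl = vals[0] if vals else None
        segments.append(
            CoastalSegment(segment_id=sid, cell=(int(r), int(c)), land_mass_label=lbl)
        )
    return segments


def segment_phenology(
    stack: IceStack,
    segments: list[CoastalSegment],
    threshold: float = 0.15,
    distance_km: float = 50.0,
    connectivity: int = 8,
) -> list[CoastalSegment]:
    """Fill retreat/return dates for every segment from a daily stack."""
    wk = stack if stack.is_weekly else weekly_mean(stack)
    comps = [
        (int(doy), pack_ice_component(grid, threshold, wk.land_mask, connectivity))
        for doy, grid in zip(wk.doys, wk.conc)
    ]
    for seg in segments:
        seg.retreat_doy, seg.return_doy = retreat_return_dates(
            seg.cell, comps, distance_km=distance_km, cell_km=stack.cell_km
        )
    return segments
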