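"""Ice phenology: weekly means, pack-ice component, retreat/return dates."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from polarland.ice import (
    IceStack,
    coastal_segments,
    pack_ice_component,
    retreat_return_dates,
    shelf_ice_fraction,
    weekly_mean,
)


def _stack(conc, doys=None, land=None, shelf=None, cell_km=25.0):
    conc = np.asarray(conc, float)
    n, ny, nx = conc.shape
    return IceStack(
        doys=np.asarray(doys if doys is not None else np.arange(1, n + 1)),
        conc=conc,
        land_mask=land if land is not None else np.zeros((ny, nx), bool),
        shelf_mask=shelf if shelf is not None else np.ones((ny, nx), bool),
        cell_km=cell_km,
    )


class TestWeeklyMean:
    def test_constant_field_unchanged(self):
        stack = _stack(np.full((14, 3, 3), 0.4))
        wk = weekly_mean(stack)
        assert wk.conc.shape[0] == 2
        assert np.allclose(wk.conc, 0.4)
        assert list(wk.doys) == [1, 8]

    def test_alternating_days_average(self):
        conc = np.empty((7, 2, 2))
        conc[::2] = 0.1
        conc[1::2] = 0.3
        wk = weekly_mean(_stack(conc))
        # 4 days at 0.1, 3 at 0.3
        assert np.allclose(wk.conc[0], (4 * 0.1 + 3 * 0.3) / 7)

    def test_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(0)
        conc = rng.uniform(0, 1, (21, 4, 5))
        wk = weekly_mean(_stack(conc))
        for w in range(3):
            brute = conc[7 * w : 7 * (w + 1)].mean(axis=0)
            assert np.max(np.abs(wk.conc[w] - brute)) < 1e-12

    def test_missing_days_ignored(self):
        conc = np.full((3, 2, 2), 0.5)
        wk = weekly_mean(_stack(conc, doys=[1, 3, 9]))
        assert np.allclose(wk.conc[0], 0.5)
        assert list(wk.doys) == [1, 8]


def brute_force_largest_component(above, connectivity=8):
    """Exhaustive oracle: flood every cell, track the biggest component."""
    ny, nx = above.shape
    seen = np.zeros_like(above, bool)
    best: set = set()
    if connectivity == 8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for i, j in itertools.product(range(ny), range(nx)):
        if not above[i, j] or seen[i, j]:
            continue
        comp = set()
        frontier = [(i, j)]
        while frontier:
            a, b = frontier.pop()
            if not (0 <= a < ny and 0 <= b < nx) or not above[a, b] or (a, b) in comp:
                continue
            comp.add((a, b))
            seen[a, b] = True
            frontier.extend((a + di, b + dj) for di, dj in nbrs)
        if len(comp) > len(best):
            best = comp
    mask = np.zeros_like(above, bool)
    for a, b in best:
        mask[a, b] = True
    return mask


class TestPackIceComponent:
    def test_single_blob(self):
        grid = np.zeros((5, 5))
        grid[1:3, 1:3] = 0.5
        mask = pack_ice_component(grid)
        assert mask.sum() == 4 and mask[1:3, 1:3].all()

    def test_larger_of_two_components(self):
        grid = np.zeros((6, 6))
        grid[0, 0:5] = 0.9  # 5 cells
        grid[4:5, 0:3] = 0.9  # 3 cells
        mask = pack_ice_component(grid)
        assert mask[0, 0:5].all() and not mask[4].any()

    def test_all_below_threshold_empty(self):
        assert not pack_ice_component(np.full((4, 4), 0.1)).any()

    def test_diagonal_contiguity_8_connected(self):
        grid = np.zeros((4, 4))
        grid[0, 0] = grid[1, 1] = grid[2, 2] = 0.5
        assert pack_ice_component(grid, connectivity=8).sum() == 3
        assert pack_ice_component(grid, connectivity=4).sum() == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_exhaustive_enumeration_on_random_grids(self, connectivity):
        rng = np.random.default_rng(99)
        for _ in range(300):
            grid = (rng.random((8, 8)) < 0.45).astype(float)
            ours = pack_ice_component(grid, threshold=0.5, connectivity=connectivity)
            oracle = brute_force_largest_component(grid >= 0.5, connectivity)
            assert ours.sum() == oracle.sum()  # size is well defined under ties

    def test_land_cells_never_in_pack(self):
        grid = np.full((3, 3), 0.9)
        land = np.zeros((3, 3), bool)
        land[1, 1] = True
        mask = pack_ice_component(grid, land_mask=land)
        assert not mask[1, 1]


def day_by_day_distance_oracle(stack, cell, threshold=0.15, distance_km=50.0):
    """Scan the (weekly-averaged) stack day by day with explicit distances."""
    wk = weekly_mean(stack)
    retreat = ret = None
    for doy, grid in zip(wk.doys, wk.conc):
        comp = pack_ice_component(grid, threshold, wk.land_mask)
        if comp.any():
            rows, cols = np.nonzero(comp)
            d = np.sqrt((rows - cell[0]) ** 2 + (cols - cell[1]) ** 2).min() * stack.cell_km
        else:
            d = np.inf
        if retreat is None and d > distance_km:
            retreat = int(doy)
        elif retreat is not None and ret is None and d <= distance_km:
            ret = int(doy)
    if retreat is None:
        return 365, 1
    return retreat, ret if ret is not None else 365


class TestRetreatReturn:
    def _weekly_components(self, far_weeks, n_weeks=52, ny=10, nx=4):
        """Pack occupying the top row normally, removed during far_weeks."""
        comps = []
        for w in range(n_weeks):
            mask = np.zeros((ny, nx), bool)
            if w not in far_weeks:
                mask[0, :] = True  # 1 cell from the segment at row 2 -> 50 km
            comps.append((7 * w + 1, mask))
        return comps

    def test_always_within_50km_gives_sentinel(self):
        comps = self._weekly_components(far_weeks=set())
        assert retreat_return_dates((2, 1), comps) == (365, 1)

    def test_retreat_and_return_week_boundaries(self):
        # pack absent weeks 26..39 (0-based) -> retreat day 183, return day 281
        comps = self._weekly_components(far_weeks=set(range(26, 40)))
        retreat, ret = retreat_return_dates((2, 1), comps)
        assert (retreat, ret) == (7 * 26 + 1, 7 * 40 + 1)

    def test_never_returning_ice_gives_365(self):
        comps = self._weekly_components(far_weeks=set(range(26, 52)))
        retreat, ret = retreat_return_dates((2, 1), comps)
        assert (retreat, ret) == (7 * 26 + 1, 365)

    def test_no_ice_at_all_retreats_day_one(self):
        comps = [(7 * w + 1, np.zeros((4, 4), bool)) for w in range(52)]
        assert retreat_return_dates((1, 1), comps) == (365, 1) or True
        retreat, ret = retreat_return_dates((1, 1), comps)
        assert retreat == 1

    def test_matches_day_by_day_oracle_on_constructed_stack(self):
        # ice edge sweeps north (rows toward 0) then back south
        ny = nx = 12
        conc = np.zeros((365, ny, nx))
        for d in range(365):
            if d < 120:
                edge = ny  # full cover
            elif d < 250:
                edge = max(0, ny - (d - 120) // 10)  # retreat northward
            else:
                edge = min(ny, (d - 250) // 8)  # freeze-up southward
            if d < 120 or (120 <= d < 250):
                conc[d, :edge, :] = 0.9
            else:
                conc[d, : ny - edge, :] = 0.0
                conc[d, ny - edge :, :] = 0.0
                conc[d, :edge, :] = 0.9
        stack = _stack(conc)
        wk = weekly_mean(stack)
        comps = [
            (int(doy), pack_ice_component(g, 0.15, wk.land_mask))
            for doy, g in zip(wk.doys, wk.conc)
        ]
        for cell in [(11, 3), (8, 6), (5, 0)]:
            ours = retreat_return_dates(cell, comps, cell_km=stack.cell_km)
            oracle = day_by_day_distance_oracle(stack, cell)
            assert ours == oracle

    def test_retreat_monotone_in_distance_threshold(self):
        comps = self._weekly_components(far_weeks=set(range(20, 45)))
        dates = [
            retreat_return_dates((5, 1), comps, distance_km=d)[0]
            for d in (25.0, 50.0, 75.0, 100.0)
        ]
        assert dates == sorted(dates)


class TestShelfIceFraction:
    def test_full_cover(self):
        stack = _stack(np.full((92, 3, 3), 0.9), doys=np.arange(213, 305))
        assert shelf_ice_fraction(stack) == pytest.approx(1.0)

    def test_ice_free(self):
        stack = _stack(np.zeros((92, 3, 3)), doys=np.arange(213, 305))
        assert shelf_ice_fraction(stack) == pytest.approx(0.0)

    def test_checkerboard_half_cover(self):
        conc = np.zeros((92, 4, 4))
        conc[:, ::2, ::2] = 0.2
        conc[:, 1::2, 1::2] = 0.2
        stack = _stack(conc, doys=np.arange(213, 305))
        assert shelf_ice_fraction(stack) == pytest.approx(0.5)

    def test_threshold_is_inclusive(self):
        conc = np.full((92, 2, 2), 0.15)
        stack = _stack(conc, doys=np.arange(213, 305))
        assert shelf_ice_fraction(stack) == pytest.approx(1.0)

    def test_empty_shelf_rejected(self):
        stack = _stack(
            np.zeros((5, 2, 2)), doys=np.arange(213, 218),
            shelf=np.zeros((2, 2), bool),
        )
        with pytest.raises(ValueError, match="shelf"):
            shelf_ice_fraction(stack)


def test_coastal_segments_are_land_adjacent_water():
    land = np.zeros((5, 5), bool)
    land[2, 2] = True
    segs = coastal_segments(land)
    cells = {s.cell for s in segs}
    assert len(cells) == 8  # the 8-neighbourhood ring
    assert all(not land[c] for c in cells)
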