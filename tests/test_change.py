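"""Binarization, areas, range change, overlap, centroids, richness, zones."""

import numpy as np
import pytest

from nichekit import (BinaryMap, GridSpec, OccurrenceSet, SuitabilityMap,
                      binarize, cell_area, centroid, genus_centroid,
                      overlap_matrix, range_change, relative_overlap_change,
                      richness, richness_delta, schoener_d, zone_frequency)
from nichekit.errors import (EmptyRangeError, UndefinedOverlapError,
                             UndefinedRCIError)

from conftest import make_stack


def bmap(values, cell_size=1000.0, crs="EPSG:32652", origin=(0.0, 0.0)):
    values = np.asarray(values, dtype=np.uint8)
    grid = GridSpec(values.shape[0], values.shape[1], cell_size,
                    origin[0], origin[1], crs)
    return BinaryMap(grid, values, np.ones(values.shape, bool))


def smap(values, cell_size=1000.0):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(values.shape[0], values.shape[1], cell_size)
    return SuitabilityMap(grid, values, np.ones(values.shape, bool))


class TestBinarize:
    def test_threshold_zero_marks_everything(self, rng):
        s = smap(rng.uniform(size=(6, 6)))
        assert binarize(s, 0.0).values.all()

    def test_threshold_above_max_marks_nothing(self, rng):
        s = smap(rng.uniform(0, 0.9, size=(6, 6)))
        assert not binarize(s, 1.0).values.any()

    def test_suitable_count_non_increasing_in_threshold(self, rng):
        s = smap(rng.uniform(size=(20, 20)))
        counts = [binarize(s, t).values.sum() for t in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nested_ranges(self, rng):
        s = smap(rng.uniform(size=(15, 15)))
        low, high = binarize(s, 0.3), binarize(s, 0.6)
        assert not (high.suitable & ~low.suitable).any()


class TestCellArea:
    def test_projected_250m_cell(self):
        grid = GridSpec(4, 4, 250.0)
        assert cell_area(grid, 0) == pytest.approx(0.0625)

    def test_equator_row_of_geographic_grid(self):
        # origin chosen so row 0's center latitude is exactly 0
        grid = GridSpec(1, 4, 1.0, 0.0, 0.5, "EPSG:4326")
        assert cell_area(grid, 0) == pytest.approx(111.32**2)

    def test_cosine_shrinks_poleward(self):
        grid = GridSpec(40, 4, 0.25, 125.0, 40.0, "EPSG:4326")
        areas = cell_area(grid, np.arange(40))
        assert (np.diff(areas) > 0).all()  # southward rows are nearer the equator

    def test_total_area_count_times_cell(self):
        grid = GridSpec(100, 100, 1000.0)
        assert np.sum(cell_area(grid, np.repeat(np.arange(100), 100))) == \
            pytest.approx(10_000.0)


class TestRangeChange:
    def test_identical_maps_give_zero(self, rng):
        b = bmap(rng.integers(0, 2, (8, 8)))
        assert range_change(b, b).rci == pytest.approx(0.0)

    def test_complete_loss_gives_minus_100(self, rng):
        base = bmap(rng.integers(0, 2, (10, 10)))
        if not base.values.any():
            base.values[0, 0] = 1
        lost = bmap(np.zeros((10, 10)))
        summary = range_change(base, lost)
        assert summary.rci == pytest.approx(-100.0)
        assert summary.s_colonization == 0.0

    def test_hand_counted_5x5_example(self):
        base = np.zeros((5, 5))
        base[0, :5], base[1, :5] = 1, 1          # 10 suitable cells
        future = base.copy()
        future[1, 1:5] = 0                       # lose 4
        future[3, 0], future[3, 1] = 1, 1        # gain 2
        summary = range_change(bmap(base), bmap(future))
        assert summary.rci == pytest.approx(-20.0)
        assert summary.s_present == pytest.approx(10.0)
        assert summary.s_stable + summary.s_extinction == pytest.approx(10.0)

    def test_zero_iff_colonization_equals_extinction(self, rng):
        base = bmap(rng.integers(0, 2, (12, 12)))
        fut = bmap(rng.integers(0, 2, (12, 12)))
        summary = range_change(base, fut)
        if summary.rci == 0:
            assert summary.s_colonization == pytest.approx(summary.s_extinction)

    def test_empty_baseline_raises(self):
        with pytest.raises(UndefinedRCIError):
            range_change(bmap(np.zeros((4, 4))), bmap(np.ones((4, 4))))

    def test_geographic_grid_uses_cosine_weights(self):
        base = np.zeros((4, 4)); base[0, 0] = 1; base[3, 0] = 1
        fut = np.zeros((4, 4)); fut[3, 0] = 1
        # northern cell lost on a lat grid: weight of lost cell < half the total
        b = bmap(base, cell_size=1.0, crs="EPSG:4326", origin=(0.0, 60.0))
        f = bmap(fut, cell_size=1.0, crs="EPSG:4326", origin=(0.0, 60.0))
        summary = range_change(b, f)
        assert -50.0 < summary.rci < 0.0


class TestSchoenerD:
    def test_identical_maps_overlap_fully(self, rng):
        b = bmap(rng.integers(0, 2, (8, 8)))
        b.values[0, 0] = 1
        assert schoener_d(b, b) == pytest.approx(1.0)

    def test_disjoint_maps_do_not_overlap(self):
        a = np.zeros((4, 4)); a[:2] = 1
        b = np.zeros((4, 4)); b[2:] = 1
        assert schoener_d(bmap(a), bmap(b)) == pytest.approx(0.0)

    def test_hand_normalized_four_cells(self):
        a = bmap(np.array([[1, 1, 0, 0]]))
        b = bmap(np.array([[1, 0, 1, 0]]))
        assert schoener_d(a, b) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = smap(rng.uniform(size=(10, 10)))
        b = smap(rng.uniform(size=(10, 10)))
        assert schoener_d(a, b, "continuous") == pytest.approx(
            schoener_d(b, a, "continuous"))

    def test_scale_invariance_continuous(self, rng):
        vals = rng.uniform(size=(10, 10))
        a, b = smap(vals), smap(rng.uniform(size=(10, 10)))
        scaled = smap(vals * 0.37)
        assert schoener_d(a, b, "continuous") == pytest.approx(
            schoener_d(scaled, b, "continuous"))

    def test_zero_total_raises(self):
        with pytest.raises(UndefinedOverlapError):
            schoener_d(bmap(np.zeros((3, 3))), bmap(np.ones((3, 3))))

    def test_matrix_marks_zero_total_species_nan(self, rng):
        maps = {"alive": bmap(rng.integers(0, 2, (6, 6)) | np.eye(6, dtype=int)),
                "extinct": bmap(np.zeros((6, 6)))}
        m = overlap_matrix(maps)
        assert np.isnan(m.pair("alive", "extinct"))
        assert np.isnan(m.pair("extinct", "extinct"))
        assert m.pair("alive", "alive") == 1.0

    def test_matrix_symmetric_unit_diagonal(self, rng):
        maps = {f"sp{i}": bmap(rng.integers(0, 2, (8, 8)) | (np.arange(64) == i).reshape(8, 8))
                for i in range(3)}
        m = overlap_matrix(maps)
        np.testing.assert_allclose(m.d, m.d.T)
        np.testing.assert_allclose(np.diag(m.d), 1.0)
        assert ((m.d >= 0) & (m.d <= 1)).all()


class TestRelativeOverlapChange:
    @pytest.mark.parametrize("d0,d1,expect", [
        (0.654, 0.479, -26.8),
        (0.411, 0.085, -79.3),
        (0.281, 0.050, -82.2),
        (0.654, 0.342, -47.7),
    ])
    def test_reported_scenario_declines(self, d0, d1, expect):
        assert relative_overlap_change(d0, d1) == expect

    def test_no_change_is_zero(self):
        assert relative_overlap_change(0.5, 0.5) == 0.0

    def test_zero_baseline_raises(self):
        with pytest.raises(UndefinedOverlapError):
            relative_overlap_change(0.0, 0.2)


class TestCentroid:
    def test_single_cell_returns_its_center(self):
        vals = np.zeros((5, 5)); vals[2, 3] = 1
        b = bmap(vals, cell_size=1.0, origin=(0.0, 5.0))
        c = centroid(b)
        assert (c.median_lon, c.median_lat, c.n_cells) == (3.5, 2.5, 1)

    def test_symmetric_cross_centers_on_middle(self):
        vals = np.zeros((5, 5))
        vals[2, :], vals[:, 2] = 1, 1
        b = bmap(vals, cell_size=1.0, origin=(0.0, 5.0))
        c = centroid(b)
        assert (c.median_lon, c.median_lat) == (2.5, 2.5)

    def test_matches_order_statistic_oracle(self, rng):
        vals = np.zeros((20, 20))
        cells = rng.choice(400, size=25, replace=False)
        vals[cells // 20, cells % 20] = 1
        elev = rng.uniform(0, 1500, (20, 20))
        b = bmap(vals, cell_size=1.0, origin=(0.0, 20.0))
        c = centroid(b, elev)
        rows, cols = np.nonzero(vals)
        xs = sorted(cols + 0.5); ys = sorted(20 - (rows + 0.5))
        es = sorted(elev[rows, cols])
        assert c.median_lon == xs[12] and c.median_lat == ys[12]
        assert c.median_elev == es[12]

    def test_even_count_uses_midpoint(self):
        vals = np.zeros((4, 4)); vals[0, 0] = 1; vals[0, 3] = 1
        c = centroid(bmap(vals, cell_size=1.0, origin=(0.0, 4.0)))
        assert c.median_lon == pytest.approx((0.5 + 3.5) / 2)

    def test_empty_map_raises(self):
        with pytest.raises(EmptyRangeError):
            centroid(bmap(np.zeros((3, 3))))

    def test_genus_union_vs_mean_methods(self, rng):
        a = np.zeros((6, 6)); a[0, 0] = 1
        b = np.zeros((6, 6)); b[5, 5] = 1
        maps = [bmap(a, cell_size=1.0, origin=(0.0, 6.0)),
                bmap(b, cell_size=1.0, origin=(0.0, 6.0))]
        u = genus_centroid(maps, method="union")
        m = genus_centroid(maps, method="mean")
        assert u.n_cells == 2
        assert m.median_lon == pytest.approx(3.0)
        assert u.median_lon == pytest.approx(3.0)


class TestRichness:
    def test_all_species_suitable_sums_to_n(self, rng):
        maps = [bmap(np.ones((4, 4))) for _ in range(4)]
        r = richness(maps)
        assert (r.sr == 4).all()
        np.testing.assert_allclose(r.sr_norm, 1.0)

    def test_delta_with_itself_is_zero(self, rng):
        maps = [bmap(rng.integers(0, 2, (6, 6))) for _ in range(3)]
        r = richness(maps)
        assert (richness_delta(r, r) == 0).all()

    def test_elementwise_sum_oracle(self, rng):
        arrays = [rng.integers(0, 2, (7, 7)) for _ in range(3)]
        r = richness([bmap(a) for a in arrays])
        np.testing.assert_array_equal(r.sr, sum(arrays))
        assert r.sr.max() <= 3

    def test_delta_bounded_by_species_count(self, rng):
        base = [bmap(rng.integers(0, 2, (6, 6))) for _ in range(3)]
        fut = [bmap(rng.integers(0, 2, (6, 6))) for _ in range(3)]
        d = richness_delta(richness(fut), richness(base))
        assert d.min() >= -3 and d.max() <= 3


class TestZoneFrequency:
    def _zones(self, values):
        return make_stack({"zone": values}, cell_size=1.0, origin=(0.0, 4.0))

    def test_all_points_in_one_zone(self):
        zones = self._zones(np.ones((4, 4)))
        occ = OccurrenceSet("sp", np.array([[0.5, 3.5], [1.5, 2.5]]))
        t = zone_frequency(occ, zones)
        assert t.loc[0, "percent"] == 100.0

    def test_three_to_one_split(self):
        z = np.ones((4, 4)); z[:, 2:] = 2
        occ = OccurrenceSet("sp", np.array([[0.5, 3.5], [1.5, 3.5],
                                            [0.5, 2.5], [3.5, 0.5]]))
        t = zone_frequency(occ, self._zones(z)).set_index("zone")
        assert t.loc[1, "percent"] == 75.0
        assert t.loc[2, "percent"] == 25.0

    def test_matches_direct_lookup_and_reports_off_zone(self, rng):
        z = rng.integers(1, 4, (4, 4))
        pts = np.column_stack([rng.uniform(0, 4, 30), rng.uniform(0, 4, 30)])
        pts = np.vstack([pts, [[99.0, 99.0]]])  # one off-grid point
        occ = OccurrenceSet("sp", pts)
        t = zone_frequency(occ, self._zones(z))
        # independent tally
        counts = {}
        for x, y in pts[:-1]:
            counts[z[int(4 - y) if y != 4 else 0, int(x)]] = \
                counts.get(z[int(4 - y) if y != 4 else 0, int(x)], 0) + 1
        got = {z_: c for z_, c in zip(t["zone"], t["count"]) if z_ != "<off-zone>"}
        assert got == counts
        off = t[t["zone"] == "<off-zone>"]
        assert off["count"].iloc[0] == 1
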