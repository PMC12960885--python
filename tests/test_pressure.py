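"""Pressure index: class lookups, the three pressure maps and the cumulative score."""

import numpy as np
import pytest
from shapely.geometry import box

from bcmap import (
    DistanceClassTable,
    DrainageBasin,
    ProportionClassTable,
    classify_distance,
    classify_proportion,
    cumulative_pressure,
    patchify,
)
from bcmap.grid import GridRaster
from bcmap.habitats import HABITAT_CODES, LANDCOVER_CODES
from bcmap.pressure import (
    agricultural_pressure,
    basin_modified_proportion,
    basin_pressure,
    urban_pressure,
    urban_pressure_rings,
)

from oracles import brute_min_cell_distance, scan_distance_class, scan_proportion_class


def _single_patch(rows_cols, shape=(40, 120), cell_size=10.0):
    data = np.zeros(shape, dtype=np.int16)
    for r, c in rows_cols:
        data[r, c] = HABITAT_CODES["seagrass"]
    return patchify(GridRaster(data, cell_size=cell_size))


class TestClassLookups:
    @pytest.mark.parametrize(
        "d, expected",
        [(0, 4), (100, 4), (101, 3), (400, 3), (1000, 2), (5000, 1), (6000, 0)],
    )
    def test_distance_class_values(self, d, expected):
        assert classify_distance(d) == expected

    @pytest.mark.parametrize(
        "p, expected",
        [(0, 0), (10, 0), (19.9, 0), (20, 1), (40, 2), (59.9, 2), (60, 3), (80, 4), (90, 4), (100, 4)],
    )
    def test_proportion_class_values(self, p, expected):
        assert classify_proportion(p) == expected

    def test_distance_scan_matches_interval_oracle(self):
        rng = np.random.default_rng(5)
        for d in rng.uniform(0, 8000, 500):
            assert classify_distance(d) == scan_distance_class(d)

    def test_proportion_scan_matches_interval_oracle(self):
        rng = np.random.default_rng(6)
        for p in rng.uniform(0, 100, 500):
            assert classify_proportion(p) == scan_proportion_class(p)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            classify_distance(-1)
        with pytest.raises(ValueError):
            classify_proportion(101)
        with pytest.raises(ValueError):
            DistanceClassTable(breaks=(400.0, 100.0, 1000.0, 5000.0))
        with pytest.raises(ValueError):
            ProportionClassTable(breaks=(20.0, 20.0, 60.0, 80.0))


class TestProximityPressure:
    def test_overlapping_agriculture_is_class_four(self):
        patches = _single_patch([(5, 5)])
        agri = np.zeros((40, 120), dtype=bool)
        agri[5, 5] = True
        assert agricultural_pressure(patches, GridRaster(agri))[0] == 4

    def test_absent_stressor_gives_zero(self):
        patches = _single_patch([(5, 5)])
        assert agricultural_pressure(patches, GridRaster(np.zeros((40, 120), dtype=bool)))[0] == 0
        assert urban_pressure(patches, [])[0] == 0

    def test_urban_polygon_fifty_metres_away_is_class_four(self):
        patches = _single_patch([(5, 5)])
        # patch cell centre at (55, 55); polygon edge 50 m east of it
        urban = [box(105, 40, 125, 70)]
        assert urban_pressure(patches, urban)[0] == 4

    def test_urban_ten_km_away_is_class_zero(self):
        patches = _single_patch([(0, 0)], shape=(40, 1200))
        urban = [box(11000, 0, 11050, 50)]
        assert urban_pressure(patches, urban)[0] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_raster_distances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = (50, 50)
        habitat = np.zeros(shape, dtype=np.int16)
        habitat[rng.random(shape) < 0.05] = HABITAT_CODES["seagrass"]
        agri = rng.random(shape) < 0.03
        patches = patchify(GridRaster(habitat))
        if not patches or not agri.any():
            pytest.skip("degenerate draw")
        values = agricultural_pressure(patches, GridRaster(agri))
        ar, ac = np.nonzero(agri)
        for patch, value in zip(patches, values):
            d = brute_min_cell_distance(patch.rows, patch.cols, ar, ac, 10.0)
            assert value == scan_distance_class(d)

    @pytest.mark.parametrize("seed", range(10))
    def test_ring_and_distance_constructions_agree(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = (60, 60)
        habitat = np.zeros(shape, dtype=np.int16)
        habitat[rng.random(shape) < 0.04] = HABITAT_CODES["open_wetland"]
        patches = patchify(GridRaster(habitat))
        urban = [
            box(x, y, x + rng.uniform(20, 80), y + rng.uniform(20, 80))
            for x, y in rng.uniform(0, 550, size=(3, 2))
        ]
        assert np.array_equal(
            urban_pressure(patches, urban), urban_pressure_rings(patches, urban)
        )

    def test_moving_a_stressor_closer_never_decreases_pressure(self):
        patches = _single_patch([(20, 5)], shape=(40, 700))
        previous = -1
        for col in (650, 400, 150, 60, 10):
            urban = np.zeros((40, 700), dtype=bool)
            urban[20, col] = True
            value = int(urban_pressure(patches, GridRaster(urban))[0])
            assert value >= previous
            previous = value


class TestBasinPressure:
    def _patch_at(self, cells, shape=(40, 200)):
        return _single_patch(cells, shape=shape)

    def test_spanning_two_basins_takes_the_unrounded_mean(self):
        patches = self._patch_at([(5, 9), (5, 10)])
        basins = [
            DrainageBasin("a", box(0, 0, 100, 400), 25.0, 1),
            DrainageBasin("b", box(100, 0, 300, 400), 65.0, 3),
        ]
        v, excluded = basin_pressure(patches, basins)
        assert v[0] == pytest.approx(2.0) and not excluded[0]

    def test_patch_seaward_within_link_radius_gets_nearest_basin(self):
        # patch 300 m west of a basin with value 4
        patches = self._patch_at([(5, 10)])
        basins = [DrainageBasin("a", box(405, 0, 800, 400), 90.0, 4)]
        v, excluded = basin_pressure(patches, basins, link_radius=500.0)
        assert v[0] == 4.0 and not excluded[0]

    def test_patch_beyond_link_radius_is_excluded(self):
        patches = self._patch_at([(5, 10)])
        basins = [DrainageBasin("a", box(705, 0, 900, 400), 90.0, 4)]
        v, excluded = basin_pressure(patches, basins, link_radius=500.0)
        assert v[0] == 0.0 and excluded[0]

    def test_empty_basin_list_excludes_everything(self):
        patches = self._patch_at([(5, 10)])
        v, excluded = basin_pressure(patches, [])
        assert excluded.all() and (v == 0).all()

    def test_increasing_modified_proportion_never_decreases_value(self):
        previous = -1
        for prop in (5, 25, 45, 65, 85):
            value = classify_proportion(prop)
            assert value >= previous
            previous = value


class TestBasinProportion:
    def test_fully_urban_basin_is_one_hundred_percent(self):
        lc = np.full((10, 10), LANDCOVER_CODES["urban"], dtype=np.int16)
        assert basin_modified_proportion(box(0, 0, 100, 100), GridRaster(lc)) == 100.0

    def test_unmodified_basin_is_zero(self):
        lc = np.zeros((10, 10), dtype=np.int16)
        assert basin_modified_proportion(box(0, 0, 100, 100), GridRaster(lc)) == 0.0

    def test_random_basin_matches_cell_counting_oracle(self):
        rng = np.random.default_rng(3)
        lc = rng.choice(
            [0, LANDCOVER_CODES["agriculture"], LANDCOVER_CODES["urban"]], size=(20, 20)
        ).astype(np.int16)
        basin = box(25, 35, 155, 165)
        result = basin_modified_proportion(basin, GridRaster(lc))
        rr, cc = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        x, y = (cc + 0.5) * 10.0, (rr + 0.5) * 10.0
        inside = (x > 25) & (x < 155) & (y > 35) & (y < 165)
        modified = np.isin(lc, [LANDCOVER_CODES["agriculture"], LANDCOVER_CODES["urban"]])
        assert result == pytest.approx(100.0 * (inside & modified).sum() / inside.sum())

    def test_zero_area_basin_errors(self):
        lc = GridRaster(np.zeros((5, 5), dtype=np.int16))
        with pytest.raises(ValueError, match="zero area"):
            basin_modified_proportion(box(1000, 1000, 1001, 1001), lc)


class TestCumulative:
    def test_maximum_and_minimum(self):
        top = cumulative_pressure(4, 4, 4)
        assert top.cumulative == 12 and top.high_pressure
        bottom = cumulative_pressure(0, 0, 0)
        assert bottom.cumulative == 0 and not bottom.high_pressure

    def test_six_is_inside_the_high_pressure_band(self):
        score = cumulative_pressure(2, 2, 2)
        assert score.cumulative == 6 and score.high_pressure

    def test_out_of_range_components_error(self):
        with pytest.raises(ValueError):
            cumulative_pressure(5, 0, 0)
        with pytest.raises(ValueError):
            cumulative_pressure(0, -1, 0)

    def test_bounds_hold_on_random_triples(self):
        rng = np.random.default_rng(12)
        for v in rng.uniform(0, 4, size=(2000, 3)):
            s = cumulative_pressure(*v)
            assert 0.0 <= s.cumulative <= 12.0
            assert s.high_pressure == (s.cumulative >= 6.0)
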