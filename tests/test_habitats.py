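"""Habitat compilation: wetland merging, SAV persistence and classification, patchify."""

import numpy as np
import pytest
from shapely.geometry import box

from bcmap import classify_sav, filter_sav_persistence, patchify
from bcmap.grid import GridRaster
from bcmap.habitats import (
    HABITAT_CODES,
    LANDCOVER_CODES,
    REGION_RULES,
    merge_wetland_layers,
    merge_wetland_raster,
)

from oracles import union_find_components


def _landcover(make_raster, codes):
    return make_raster(np.asarray(codes, dtype=np.int16))


class TestWetlandMerge:
    def test_empty_vector_source_equals_raster_wetlands(self, make_raster):
        lc = np.zeros((5, 5), dtype=np.int16)
        lc[1, 1] = LANDCOVER_CODES["open_wetland"]
        lc[3, 3] = LANDCOVER_CODES["forested_wetland"]
        merged = merge_wetland_raster(_landcover(make_raster, lc))
        assert merged.data[1, 1] == HABITAT_CODES["open_wetland"]
        assert merged.data[3, 3] == HABITAT_CODES["forested_wetland"]
        assert (merged.data > 0).sum() == 2

    def test_identical_sources_are_idempotent(self, make_raster):
        lc = np.zeros((4, 4), dtype=np.int16)
        lc[0:2, 0:2] = LANDCOVER_CODES["open_wetland"]
        poly = box(0, 0, 20, 20)  # covers the same 2x2 cells at 10 m
        merged = merge_wetland_raster(_landcover(make_raster, lc), [(poly, "open_wetland")])
        only_raster = merge_wetland_raster(_landcover(make_raster, lc))
        assert np.array_equal(merged.data, only_raster.data)

    def test_vector_source_wins_on_class_conflict(self, make_raster):
        lc = np.zeros((4, 4), dtype=np.int16)
        lc[0:2, 0:2] = LANDCOVER_CODES["open_wetland"]
        poly = box(0, 0, 20, 10)  # overwrites the bottom row as forested
        merged = merge_wetland_raster(_landcover(make_raster, lc), [(poly, "forested_wetland")])
        # per-cell oracle with vector precedence
        expected = np.zeros((4, 4), dtype=np.int16)
        expected[0:2, 0:2] = HABITAT_CODES["open_wetland"]
        expected[0, 0:2] = HABITAT_CODES["forested_wetland"]
        assert np.array_equal(merged.data, expected)

    def test_unknown_landcover_code_is_reported(self, make_raster):
        lc = np.zeros((3, 3), dtype=np.int16)
        lc[1, 1] = 99
        with pytest.raises(ValueError, match="99"):
            merge_wetland_raster(_landcover(make_raster, lc))

    def test_merge_returns_patches(self, make_raster):
        lc = np.zeros((5, 5), dtype=np.int16)
        lc[0, 0:3] = LANDCOVER_CODES["open_wetland"]
        patches = merge_wetland_layers(_landcover(make_raster, lc))
        assert len(patches) == 1 and patches[0].habitat_class == "open_wetland"
        assert patches[0].n_cells == 3


class TestPersistenceFilter:
    def test_min_years_boundary_is_inclusive(self, make_raster):
        counts = make_raster([[4, 3], [5, 0]], dtype=np.int16)
        mask = filter_sav_persistence(counts, min_years=4)
        assert np.array_equal(mask.data, [[True, False], [True, False]])

    def test_min_years_one_is_the_maximal_extent(self, make_raster):
        counts = make_raster([[0, 1], [2, 5]], dtype=np.int16)
        mask = filter_sav_persistence(counts, min_years=1)
        assert np.array_equal(mask.data, np.asarray(counts.data) >= 1)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_retained_count_matches_counting_oracle(self, make_raster, seed):
        rng = np.random.default_rng(seed)
        counts = make_raster(rng.integers(0, 6, (30, 30)), dtype=np.int16)
        for k in range(1, 6):
            mask = filter_sav_persistence(counts, min_years=k)
            assert mask.count_true() == int((counts.data >= k).sum())

    def test_stricter_threshold_is_a_subset(self, make_raster):
        rng = np.random.default_rng(7)
        counts = make_raster(rng.integers(0, 6, (25, 25)), dtype=np.int16)
        for k in range(1, 5):
            loose = filter_sav_persistence(counts, min_years=k).data
            strict = filter_sav_persistence(counts, min_years=k + 1).data
            assert not (strict & ~loose).any()

    def test_out_of_range_counts_error(self, make_raster):
        with pytest.raises(ValueError, match="0..5"):
            filter_sav_persistence(make_raster([[6]], dtype=np.int16))
        with pytest.raises(ValueError, match="min_years"):
            filter_sav_persistence(make_raster([[3]], dtype=np.int16), min_years=0)


class TestClassifySAV:
    def _rasters(self, make_raster, rule, model):
        sav = make_raster([[True]], dtype=bool)
        model_r = make_raster([[model]], dtype=bool)
        rules = make_raster([[REGION_RULES[rule]]], dtype=np.int16)
        return sav, model_r, rules

    @pytest.mark.parametrize(
        "rule, model, expected",
        [
            ("model_overlap", True, "seagrass"),
            ("model_overlap", False, "other_rooted_macrophytes"),
            ("all_seagrass", False, "seagrass"),
            ("all_other", True, "other_rooted_macrophytes"),
        ],
    )
    def test_rule_application(self, make_raster, rule, model, expected):
        sav, model_r, rules = self._rasters(make_raster, rule, model)
        out = classify_sav(sav, model_r, rules)
        assert out.data[0, 0] == HABITAT_CODES[expected]

    def test_cells_without_sav_stay_unlabeled(self, make_raster):
        sav = make_raster([[False, True]], dtype=bool)
        model = make_raster([[True, True]], dtype=bool)
        rules = make_raster([[1, 1]], dtype=np.int16)
        out = classify_sav(sav, model, rules)
        assert out.data[0, 0] == 0 and out.data[0, 1] == HABITAT_CODES["seagrass"]

    def test_every_sav_cell_gets_exactly_one_submerged_class(self, make_raster):
        rng = np.random.default_rng(11)
        shape = (40, 40)
        sav = make_raster(rng.random(shape) < 0.4, dtype=bool)
        model = make_raster(rng.random(shape) < 0.5, dtype=bool)
        rules = make_raster(rng.integers(0, 3, shape), dtype=np.int16)
        out = classify_sav(sav, model, rules).data
        assert ((out > 0) == sav.data).all()
        # brute-force rule application
        for r, c in zip(*np.nonzero(sav.data)):
            rule = rules.data[r, c]
            if rule == REGION_RULES["all_seagrass"]:
                expected = HABITAT_CODES["seagrass"]
            elif rule == REGION_RULES["all_other"]:
                expected = HABITAT_CODES["other_rooted_macrophytes"]
            else:
                expected = (
                    HABITAT_CODES["seagrass"]
                    if model.data[r, c]
                    else HABITAT_CODES["other_rooted_macrophytes"]
                )
            assert out[r, c] == expected

    def test_missing_rule_tag_errors(self, make_raster):
        sav = make_raster([[True]], dtype=bool)
        model = make_raster([[True]], dtype=bool)
        rules = make_raster([[9]], dtype=np.int16)
        with pytest.raises(ValueError, match="rule"):
            classify_sav(sav, model, rules)


class TestPatchify:
    def test_single_blob_area_arithmetic(self, make_raster):
        data = np.zeros((5, 5), dtype=np.int16)
        data[0, 0:5] = HABITAT_CODES["seagrass"]
        data[1, 0:5] = HABITAT_CODES["seagrass"]
        patches = patchify(make_raster(data, dtype=np.int16))
        assert len(patches) == 1
        assert patches[0].area_km2 == pytest.approx(10 * 0.0001)  # 10 cells of 100 m²

    def test_diagonal_blobs_are_separate_under_4_connectivity(self, make_raster):
        data = np.zeros((4, 4), dtype=np.int16)
        data[0, 0] = data[1, 1] = HABITAT_CODES["open_wetland"]
        patches = patchify(make_raster(data, dtype=np.int16))
        assert len(patches) == 2
        assert len(patchify(make_raster(data, dtype=np.int16), connectivity=8)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_component_count_matches_union_find_oracle(self, make_raster, seed):
        rng = np.random.default_rng(seed)
        data = (rng.random((30, 30)) < 0.35).astype(np.int16) * HABITAT_CODES["seagrass"]
        patches = patchify(make_raster(data, dtype=np.int16))
        assert len(patches) == union_find_components(data > 0)

    def test_area_conservation_per_class(self, default_scene):
        raster = default_scene.truth.true_habitat_class
        patches = patchify(raster)
        for code, name in ((v, k) for k, v in HABITAT_CODES.items()):
            class_area = sum(p.area_km2 for p in patches if p.habitat_class == name)
            assert class_area == pytest.approx(
                int((raster.data == code).sum()) * raster.cell_area_km2
            )

    def test_empty_raster_gives_empty_list(self, make_raster):
        assert patchify(make_raster(np.zeros((4, 4), dtype=np.int16), dtype=np.int16)) == []
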