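"""Intensity profiles, sub-grid/spot detection, and the full pipeline."""

import numpy as np
import pytest

import omtgrid as og
from omtgrid.geometry import Rect
from omtgrid.gridding import (
    GridConfig,
    condition_profile,
    detect_spots,
    detect_subgrids,
    grid_image,
    intensity_profile,
)
from omtgrid.image import MicroarrayImage

from conftest import small_spec


class TestIntensityProfile:
    def test_row_sums_count_pixels(self):
        img = MicroarrayImage(np.ones((2, 3), dtype=np.uint16))
        h = intensity_profile(img, "rows")
        assert h.masses.tolist() == [3.0, 3.0]

    def test_subregion_profile_equals_cropped_image_profile(self):
        rng = np.random.default_rng(4)
        img = MicroarrayImage(rng.integers(0, 1000, (30, 40)).astype(np.uint16))
        b = Rect(5, 25, 10, 30)
        h1 = intensity_profile(img, "cols", b)
        h2 = intensity_profile(img.crop(*b.as_tuple()), "cols")
        assert np.array_equal(h1.masses, h2.masses)

    def test_zero_mass_region_is_an_error(self):
        img = MicroarrayImage(np.zeros((10, 10), dtype=np.uint16))
        with pytest.raises(ValueError):
            intensity_profile(img, "rows")

    def test_gap_valleys_visible_in_column_profile(self, small_clean):
        img, truth = small_clean
        h, off = condition_profile(intensity_profile(img, "cols"))
        m = h.masses
        for gap_lo, gap_hi in truth.subgrid_gap_intervals("cols"):
            gap_vals = m[gap_lo - off + 2 : gap_hi - off - 2]
            assert gap_vals.max() == 0.0  # conditioned gaps are empty


class TestDetectSubgrids:
    def test_clean_small_layout_lines_inside_true_gaps(self, small_clean):
        img, truth = small_clean
        geom = detect_subgrids(img)
        assert len(geom.horizontal_lines) == 2
        assert len(geom.vertical_lines) == 2
        for line, (lo, hi) in zip(geom.horizontal_lines, truth.subgrid_gap_intervals("rows")):
            assert lo < line < hi
        assert og.score_lines(geom, truth, "subgrid").as_percentages() == (0.0, 0.0, 100.0)

    def test_flat_noise_image_yields_no_split(self):
        rng = np.random.default_rng(0)
        img = MicroarrayImage(rng.integers(0, 3000, (200, 300)).astype(np.uint16))
        geom = detect_subgrids(img)
        assert geom.horizontal_lines == ()
        assert geom.vertical_lines == ()

    def test_intensity_scaling_equivariance(self, small_noisy):
        img, _ = small_noisy
        scaled = MicroarrayImage((img.pixels.astype(np.uint32) * 3).astype(np.uint32))
        g1 = detect_subgrids(img)
        g2 = detect_subgrids(scaled)
        assert g1.horizontal_lines == g2.horizontal_lines
        assert g1.vertical_lines == g2.vertical_lines

    def test_translation_equivariance(self, small_noisy):
        # rolling by whole pixels permutes the profile bins, so detection
        # must shift by exactly the same offset (roll < margin keeps the
        # grid contiguous)
        img, _ = small_noisy
        shift = 13
        arr = np.roll(np.roll(img.pixels, shift, axis=0), shift, axis=1)
        g1 = detect_subgrids(img)
        g2 = detect_subgrids(MicroarrayImage(arr))
        assert tuple(x + shift for x in g1.horizontal_lines) == g2.horizontal_lines
        assert tuple(x + shift for x in g1.vertical_lines) == g2.vertical_lines


class TestDetectSpots:
    def test_clean_cells_give_full_line_sets(self, small_clean):
        img, truth = small_clean
        sub = detect_subgrids(img)
        for row in sub.cells():
            for cell in row:
                g = detect_spots(img, cell)
                assert len(g.horizontal_lines) == truth.spec.spot_rows - 1
                assert len(g.vertical_lines) == truth.spec.spot_cols - 1

    def test_missing_spots_do_not_change_line_counts(self):
        img, truth = og.generate(
            small_spec(noise_sd=1625.0, missing_spot_fraction=0.10, seed=11)
        )
        sub = detect_subgrids(img)
        counts = set()
        for row in sub.cells():
            for cell in row:
                g = detect_spots(img, cell)
                counts.add((len(g.horizontal_lines), len(g.vertical_lines)))
        assert counts == {(truth.spec.spot_rows - 1, truth.spec.spot_cols - 1)}

    def test_spot_regions_tile_each_subgrid_cell(self, small_clean):
        img, _ = small_clean
        sub = detect_subgrids(img)
        cell = sub.cells()[1][1]
        g = detect_spots(img, cell)
        area = sum(c.height * c.width for row in g.cells() for c in row)
        assert area == cell.height * cell.width


class TestGridImage:
    def test_unrotated_pipeline_matches_rotation_skipped(self, small_noisy):
        img, _ = small_noisy
        a = grid_image(img, GridConfig(rotation=True))
        b = grid_image(img, GridConfig(rotation=False))
        assert not a.rotation_applied
        assert a.subgrid_geometry == b.subgrid_geometry
        assert a.spot_geometries == b.spot_geometries

    def test_deterministic_for_fixed_input(self, small_noisy):
        img, _ = small_noisy
        a = grid_image(img, GridConfig(rotation=False))
        b = grid_image(img, GridConfig(rotation=False))
        assert a.to_dict() == b.to_dict()

    def test_reproduces_ground_truth_spot_count(self, small_clean):
        img, truth = small_clean
        res = grid_image(img, GridConfig(rotation=False))
        s = truth.spec
        n_regions = sum(
            len(g.cells()) * len(g.cells()[0])
            for row in res.spot_geometries
            for g in row
        )
        assert n_regions == s.subgrid_rows * s.subgrid_cols * s.spot_rows * s.spot_cols

    def test_report_is_json_serializable_with_diagnostics(self, small_noisy):
        import json

        img, _ = small_noisy
        res = grid_image(img, GridConfig(rotation=False, report_indices=True))
        doc = json.loads(json.dumps(res.to_dict(), sort_keys=True))
        assert doc["subgrids"]["layout"] == [3, 3]
        assert {r["K"] for r in doc["indices"]["rows"]} == set(
            range(2, len(doc["indices"]["rows"]) + 2)
        )

    def test_stage_errors_carry_stage_name(self):
        img = MicroarrayImage(np.zeros((10, 10), dtype=np.uint16))
        with pytest.raises(ValueError, match="subgrid stage"):
            grid_image(img, GridConfig(rotation=False))
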