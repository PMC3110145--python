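"""Synthetic image generator and the perfect/marginal/incorrect scorer."""

import numpy as np
import pytest

import omtgrid as og
from omtgrid.geometry import GridGeometry, Rect
from omtgrid.synthetic import LayoutSpec, LineScore, diln_preset, geo_preset, smd_preset

from conftest import small_spec


class TestLayoutSpec:
    def test_presets_match_published_layouts(self):
        smd = smd_preset()
        assert (smd.subgrid_rows, smd.subgrid_cols) == (4, 12)
        assert (smd.spot_rows, smd.spot_cols) == (18, 18)
        assert smd.resolve()[0] == (1910, 5550)
        geo = geo_preset()
        assert (geo.subgrid_rows, geo.subgrid_cols) == (4, 12)
        assert (geo.spot_rows, geo.spot_cols) == (14, 13)
        assert geo.resolve()[0] == (1900, 5500)
        diln = diln_preset()
        assert (diln.subgrid_rows, diln.subgrid_cols) == (2, 5)
        assert (diln.spot_rows, diln.spot_cols) == (8, 8)

    def test_layout_that_does_not_fit_reports_required_size(self):
        spec = small_spec(image_size=(50, 50))
        with pytest.raises(ValueError, match="at least"):
            spec.resolve()

    @pytest.mark.parametrize("field,value", [
        ("subgrid_rows", 0), ("spot_gap_px", 0), ("missing_spot_fraction", 1.5),
    ])
    def test_invalid_spec_rejected(self, field, value):
        with pytest.raises(ValueError):
            small_spec(**{field: value})


class TestGenerate:
    def test_same_seed_is_bit_identical(self):
        spec = small_spec(noise_sd=900.0, missing_spot_fraction=0.1, seed=5)
        img1, _ = og.generate(spec)
        img2, _ = og.generate(spec)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_different_seed_differs(self):
        img1, _ = og.generate(small_spec(noise_sd=900.0, seed=5))
        img2, _ = og.generate(small_spec(noise_sd=900.0, seed=6))
        assert not np.array_equal(img1.pixels, img2.pixels)

    def test_clean_profile_has_exact_background_in_subgrid_gaps(self):
        spec = small_spec(background_level=0.0)
        img, truth = og.generate(spec)
        colsum = img.pixels.sum(axis=0)
        for lo, hi in truth.subgrid_gap_intervals("cols"):
            # interior of the gap (outside the spot-cell glow ring)
            assert colsum[lo + spec.spot_gap_px // 2 + 1 : hi - spec.spot_gap_px // 2 - 1].max() == 0

    def test_noise_sd_within_five_percent_of_spec(self):
        spec = small_spec(background_level=30000.0, noise_sd=2000.0,
                          spot_intensity_range=(0.0, 0.0), halo_fraction=0.0, seed=9)
        img, _ = og.generate(spec)
        # background 30000 keeps clipping negligible; spots disabled
        assert img.pixels.std() == pytest.approx(2000.0, rel=0.05)

    def test_missing_fraction_approximately_respected(self):
        spec = small_spec(missing_spot_fraction=0.2, seed=3)
        _, truth = og.generate(spec)
        frac = 1.0 - truth.spot_present.mean()
        assert frac == pytest.approx(0.2, abs=0.05)

    def test_rotation_recorded_and_canvas_padded(self):
        spec = small_spec(rotation_deg=12.0)
        img, truth = og.generate(spec)
        assert truth.rotation_deg == 12.0
        assert img.n_rows > truth.original_shape[0]

    def test_artifacts_add_bright_blobs(self):
        clean, _ = og.generate(small_spec(seed=2))
        dirty, _ = og.generate(small_spec(artifact_count=5, seed=2))
        assert dirty.pixels.astype(int).sum() > clean.pixels.astype(int).sum()

    def test_truth_round_trips_through_json(self):
        import json

        _, truth = og.generate(small_spec(missing_spot_fraction=0.1, seed=4))
        doc = json.loads(json.dumps(truth.to_dict()))
        back = og.SyntheticGroundTruth.from_dict(doc)
        assert back.spec == truth.spec
        assert np.array_equal(back.spot_centers, truth.spot_centers)
        assert np.array_equal(back.spot_present, truth.spot_present)


class TestGenerateDilution:
    def test_true_log2_peak_decay_is_one_per_step(self):
        _, truth = og.generate_dilution(steps=8, fold=2.0, seed=0)
        peaks = {}
        for p, s in zip(truth.spot_peaks, truth.dilution_step):
            peaks.setdefault(int(s), p)
        logs = [np.log2(peaks[s]) for s in sorted(peaks)]
        diffs = np.diff(logs)
        assert np.allclose(diffs, -1.0)

    def test_steps_tile_across_spot_columns(self):
        _, truth = og.generate_dilution(steps=8, fold=2.0, seed=0)
        assert np.array_equal(truth.dilution_step, truth.spot_index[:, 1] % 8 + 1)

    def test_seed_determinism(self):
        a, _ = og.generate_dilution(steps=8, fold=2.0, seed=2)
        b, _ = og.generate_dilution(steps=8, fold=2.0, seed=2)
        assert np.array_equal(a.pixels, b.pixels)

    def test_shrinking_variant_reduces_late_step_radii(self):
        _, truth = og.generate_dilution(steps=8, fold=2.0, seed=0, shrink_with_step=True)
        r1 = truth.spot_radii[truth.dilution_step == 1].mean()
        r8 = truth.spot_radii[truth.dilution_step == 8].mean()
        assert r8 == pytest.approx(1.5, abs=0.01)
        assert r1 > 3 * r8


class TestScoreLines:
    def test_truth_aligned_lines_are_all_perfect(self, small_clean):
        img, truth = small_clean
        gaps_r = truth.subgrid_gap_intervals("rows")
        gaps_c = truth.subgrid_gap_intervals("cols")
        geom = GridGeometry(
            horizontal_lines=tuple((a + b) // 2 for a, b in gaps_r),
            vertical_lines=tuple((a + b) // 2 for a, b in gaps_c),
            bounds=Rect(0, img.n_rows, 0, img.n_cols),
        )
        assert og.score_lines(geom, truth, "subgrid").as_percentages() == (0.0, 0.0, 100.0)

    def test_lines_through_spot_centers_all_incorrect(self, small_clean):
        img, truth = small_clean
        centers_r = sorted({int(c) for c in truth.spot_centers[:3, 0]})
        geom = GridGeometry(
            horizontal_lines=(int(truth.spot_centers[0, 0]),),
            vertical_lines=(int(truth.spot_centers[0, 1]),),
            bounds=Rect(0, img.n_rows, 0, img.n_cols),
        )
        s = og.score_lines(geom, truth, "subgrid")
        assert s.n_incorrect >= 2  # both placed lines cross masks
        assert s.perfect_pct < 100.0

    def test_percentages_sum_to_100_for_random_geometries(self, small_clean):
        img, truth = small_clean
        rng = np.random.default_rng(0)
        for _ in range(10):
            h = tuple(sorted(rng.choice(np.arange(5, img.n_rows - 5), 2, replace=False)))
            v = tuple(sorted(rng.choice(np.arange(5, img.n_cols - 5), 2, replace=False)))
            s = og.score_lines(
                GridGeometry(h, v, Rect(0, img.n_rows, 0, img.n_cols)), truth, "subgrid"
            )
            assert sum(s.as_percentages()) == pytest.approx(100.0)

    def test_line_count_mismatch_counted_incorrect(self, small_clean):
        img, truth = small_clean
        gaps_r = truth.subgrid_gap_intervals("rows")
        geom = GridGeometry(
            horizontal_lines=((gaps_r[0][0] + gaps_r[0][1]) // 2,),  # 1 of 2
            vertical_lines=(),  # 0 of 2
            bounds=Rect(0, img.n_rows, 0, img.n_cols),
        )
        s = og.score_lines(geom, truth, "subgrid")
        assert s.n_lines == 4
        assert s.n_incorrect == 3
        assert s.n_perfect == 1

    def test_score_invariant_to_geometry_ordering(self, small_clean):
        img, truth = small_clean
        sub = og.detect_subgrids(img)
        gs = [og.detect_spots(img, c) for row in sub.cells() for c in row]
        a = og.score_lines(gs, truth, "spot")
        b = og.score_lines(list(reversed(gs)), truth, "spot")
        assert a == b

    def test_scores_pool_additively(self):
        a = LineScore(1, 2, 3)
        b = LineScore(0, 1, 5)
        assert (a + b) == LineScore(1, 3, 8)
        assert (a + b).n_lines == 12
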