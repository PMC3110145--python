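"""Shared fixtures.

The acceptance-style batches (full-canvas synthetic images through the
whole pipeline) are expensive, so they are computed once per session and
shared by every test that needs them; each batch stores scores and
diagnostics, not the images themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

import omtgrid as og
from omtgrid.gridding import detect_spots, detect_subgrids
from omtgrid.refinement import refine_geometry
from omtgrid.rotation import correct_rotation, estimate_rotation, rotate_image
from omtgrid.synthetic import LayoutSpec, LineScore


def small_spec(**kw) -> LayoutSpec:
    """A 320x320-ish 3x3 sub-grid layout for fast unit tests."""
    base = dict(
        subgrid_rows=3, subgrid_cols=3, spot_rows=6, spot_cols=6,
        spot_diameter_px=10, spot_gap_px=4,
        subgrid_gap_row_px=20, subgrid_gap_col_px=20,
        margin_row_px=20, margin_col_px=20,
        noise_sd=0.0, seed=0,
    )
    base.update(kw)
    return LayoutSpec(**base)


@pytest.fixture(scope="session")
def small_clean():
    """Noise-free small image + truth."""
    return og.generate(small_spec())


@pytest.fixture(scope="session")
def small_noisy():
    """Moderate-noise small image + truth (5% of mean spot peak)."""
    return og.generate(small_spec(noise_sd=1625.0, seed=7))


def _spot_geometries(img, sub_geom, refine):
    out = []
    for row in sub_geom.cells():
        for cell in row:
            g = detect_spots(img, cell)
            out.append(refine_geometry(img, g) if refine else g)
    return out


@dataclass
class PipelineRecord:
    seed: int
    best_rows: int
    best_cols: int
    angle_x: float
    angle_y: float
    subgrid_score: LineScore
    spot_score_raw: LineScore
    spot_score_refined: LineScore
    spot_counts: set = field(default_factory=set)


def _run_pipeline(spec, with_rotation=True) -> PipelineRecord:
    img, truth = og.generate(spec)
    ax = ay = 0.0
    if with_rotation:
        est = estimate_rotation(img)
        ax, ay = est.angle_x, est.angle_y
        if max(abs(ax), abs(ay)) > 0.2:
            img = correct_rotation(img, est, output_shape=truth.original_shape)
    sub_geom, prof = detect_subgrids(img, with_profiles=True)
    sub_geom = refine_geometry(img, sub_geom)
    raw = _spot_geometries(img, sub_geom, refine=False)
    refined = [refine_geometry(img, g) for g in raw]
    return PipelineRecord(
        seed=spec.seed,
        best_rows=prof["rows"].best_K,
        best_cols=prof["cols"].best_K,
        angle_x=ax,
        angle_y=ay,
        subgrid_score=og.score_lines(sub_geom, truth, "subgrid"),
        spot_score_raw=og.score_lines(raw, truth, "spot"),
        spot_score_refined=og.score_lines(refined, truth, "spot"),
        spot_counts={(len(g.horizontal_lines), len(g.vertical_lines)) for g in raw},
    )


@pytest.fixture(scope="session")
def smd_batch():
    """20 seeded SMD-layout images, moderate noise, full pipeline."""
    return [
        _run_pipeline(og.smd_preset(noise="moderate", seed=s)) for s in range(1, 21)
    ]


@pytest.fixture(scope="session")
def geo_count_batch():
    """20 seeded GEO-layout images, moderate noise: sub-grid K only."""
    out = []
    for s in range(1, 21):
        img, _ = og.generate(og.geo_preset(noise="moderate", seed=s))
        _, prof = detect_subgrids(img, with_profiles=True)
        out.append((prof["rows"].best_K, prof["cols"].best_K))
    return out


@pytest.fixture(scope="session")
def diln_count_batch():
    """20 seeded DILN-layout images, moderate noise: sub-grid K only."""
    out = []
    for s in range(1, 21):
        img, _ = og.generate(og.diln_preset(noise="moderate", seed=s))
        _, prof = detect_subgrids(img, with_profiles=True)
        out.append((prof["rows"].best_K, prof["cols"].best_K))
    return out


@pytest.fixture(scope="session")
def smd_spot_batch():
    """10 SMD images, moderate noise + 5% missing spots, full pipeline."""
    return [
        _run_pipeline(
            og.smd_preset(noise="moderate", missing_spot_fraction=0.05, seed=s)
        )
        for s in range(1, 11)
    ]


@pytest.fixture(scope="session")
def geo_spot_batch():
    """10 GEO images, low noise, full pipeline."""
    return [
        _run_pipeline(og.geo_preset(noise="low", seed=s)) for s in range(1, 11)
    ]


@pytest.fixture(scope="session")
def rotation_sweep(smd_batch):
    """Rotations of one SMD image (+-5..25 deg): recovered angle + spot score.

    The unrotated baseline is the seed-1 record of the SMD batch.
    """
    spec = og.smd_preset(noise="moderate", seed=1)
    img, truth = og.generate(spec)
    out = {}
    for ang in (5.0, 10.0, 15.0, 20.0, 25.0, -5.0, -10.0, -15.0, -20.0, -25.0):
        rot = rotate_image(img, ang)
        est = estimate_rotation(rot)
        corr = correct_rotation(rot, est, output_shape=truth.original_shape)
        sub = refine_geometry(corr, detect_subgrids(corr))
        spots = [refine_geometry(corr, g) for g in _spot_geometries(corr, sub, refine=False)]
        out[ang] = {
            "angle_x": est.angle_x,
            "angle_y": est.angle_y,
            "subgrid": og.score_lines(sub, truth, "subgrid"),
            "spot": og.score_lines(spots, truth, "spot"),
        }
    return out
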