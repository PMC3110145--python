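"""Two-stage gridding pipeline: sub-grids on the whole image, then spots.

Both stages share one mechanism: project the (rotation-corrected) image
onto an axis as a positional intensity histogram, let the alpha index pick
the number of blocks, place the optimal separating thresholds, and convert
thresholds to line coordinates.  The horizontal and vertical axes never
share state.  An optional refinement pass then nudges every line to the
locally emptiest row/column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GridGeometry, Rect
from .image import MicroarrayImage
from .indices import ValidityProfile, select_K
from .mlt import IntensityHistogram
from .refinement import refine_geometry
from .rotation import RotationEstimate, correct_rotation, estimate_rotation

__all__ = [
    "GridConfig",
    "GridResult",
    "intensity_profile",
    "detect_subgrids",
    "detect_spots",
    "grid_image",
]


def intensity_profile(
    img: MicroarrayImage, axis: str, bounds: Rect | None = None
) -> IntensityHistogram:
    """Row or column intensity sums within ``bounds`` as a histogram.

    ``axis="rows"`` produces one bin per pixel row (summed over columns);
    bin i (1-based) corresponds to pixel row ``bounds.row_start + i - 1``.
    """
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    b = bounds or Rect(0, img.n_rows, 0, img.n_cols)
    if not (0 <= b.row_start < b.row_end <= img.n_rows and 0 <= b.col_start < b.col_end <= img.n_cols):
        raise ValueError(f"bounds {b} outside image {img.shape}")
    sub = img.pixels[b.row_start : b.row_end, b.col_start : b.col_end]
    masses = sub.sum(axis=1, dtype=np.float64) if axis == "rows" else sub.sum(axis=0, dtype=np.float64)
    return IntensityHistogram(masses)


#: fraction of the conditioned profile maximum that counts as signal when
#: trimming the analysis window to the grid's support
_SUPPORT_FRACTION = 0.05


def condition_profile(h: IntensityHistogram) -> tuple[IntensityHistogram, int]:
    """Baseline-remove and support-trim a profile for model selection.

    Scanner background plus zero-clipped noise put a pedestal under the
    row/column sums that fills the valleys the thresholding relies on; the
    profile's 1st percentile estimates that pedestal and is subtracted
    (clipped at zero).  Bins outside the first/last bin holding at least
    5% of the conditioned maximum (empty outer margins) are then dropped,
    so low-mass margin runs cannot masquerade as extra grid classes.
    Returns the conditioned histogram and the bin offset of its first bin
    relative to the input.  Degenerate profiles come back unchanged.
    """
    m = h.masses
    cond = np.clip(m - np.percentile(m, 1.0), 0.0, None)
    if cond.max() <= 0.0:
        return h, 0
    sig = np.nonzero(cond >= _SUPPORT_FRACTION * cond.max())[0]
    lo, hi = int(sig[0]), int(sig[-1]) + 1
    if hi - lo < 4:  # too little support to subdivide
        return h, 0
    return IntensityHistogram(cond[lo:hi]), lo


def _detect_axis(
    img: MicroarrayImage, axis: str, bounds: Rect, delta: int | None
) -> tuple[tuple[int, ...], ValidityProfile]:
    """Separating-line coordinates along one axis plus the alpha profile."""
    try:
        raw = intensity_profile(img, axis, bounds)
        h, trim = condition_profile(raw)
        profile = select_K(h, delta=delta)
    except ValueError as exc:
        raise ValueError(f"{axis} axis: {exc}") from exc
    start = (bounds.row_start if axis == "rows" else bounds.col_start) + trim
    if not profile.confident:
        return (), profile  # no evidence of structure: best treated as one block
    T = profile.best_thresholds()  # already valley-centered by select_K
    # threshold t is a 1-based bin; the line sits on the boundary after it
    return tuple(start + t for t in T.thresholds), profile


def detect_subgrids(
    img: MicroarrayImage,
    bounds: Rect | None = None,
    delta: int | None = None,
    with_profiles: bool = False,
):
    """Sub-grid separating lines with counts chosen by the alpha index.

    Returns a :class:`GridGeometry`; with ``with_profiles=True`` also the
    per-axis :class:`ValidityProfile` diagnostics (the Fig. "index curve"
    analog).
    """
    b = bounds or Rect(0, img.n_rows, 0, img.n_cols)
    h_lines, prof_rows = _detect_axis(img, "rows", b, delta)
    v_lines, prof_cols = _detect_axis(img, "cols", b, delta)
    geom = GridGeometry(horizontal_lines=h_lines, vertical_lines=v_lines, bounds=b)
    if with_profiles:
        return geom, {"rows": prof_rows, "cols": prof_cols}
    return geom


def detect_spots(
    img: MicroarrayImage,
    subgrid: Rect,
    delta: int | None = None,
    with_profiles: bool = False,
):
    """Spot separating lines within one sub-grid cell (same mechanism)."""
    return detect_subgrids(img, bounds=subgrid, delta=delta, with_profiles=with_profiles)


@dataclass(frozen=True)
class GridConfig:
    """Pipeline switches; everything is parameterless by default."""

    rotation: bool = True
    refine: bool = True
    max_angle: float = 30.0
    #: estimated angles at or below this are treated as exactly zero
    min_correct_angle: float = 0.2
    #: crop/pad the corrected image to this frame (e.g. a pre-rotation size)
    output_shape: tuple[int, int] | None = None
    report_indices: bool = False


@dataclass(frozen=True)
class GridResult:
    """Full pipeline output: rotation, sub-grid and per-sub-grid geometry."""

    rotation_estimate: RotationEstimate | None
    rotation_applied: bool
    subgrid_geometry: GridGeometry
    spot_geometries: tuple[tuple[GridGeometry, ...], ...]
    subgrid_profiles: dict | None = None
    spot_best_K: tuple[tuple[tuple[int, int], ...], ...] = ()
    corrected_image: MicroarrayImage | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        """JSON-serializable report (stable key order when dumped sorted)."""
        doc: dict = {
            "rotation": None,
            "subgrids": {
                "bounds": list(self.subgrid_geometry.bounds.as_tuple()),
                "horizontal_lines": list(self.subgrid_geometry.horizontal_lines),
                "vertical_lines": list(self.subgrid_geometry.vertical_lines),
                "layout": [
                    self.subgrid_geometry.n_row_blocks,
                    self.subgrid_geometry.n_col_blocks,
                ],
            },
            "spots": [
                [
                    {
                        "bounds": list(g.bounds.as_tuple()),
                        "horizontal_lines": list(g.horizontal_lines),
                        "vertical_lines": list(g.vertical_lines),
                    }
                    for g in row
                ]
                for row in self.spot_geometries
            ],
        }
        if self.rotation_estimate is not None:
            doc["rotation"] = {
                "angle_x": self.rotation_estimate.angle_x,
                "angle_y": self.rotation_estimate.angle_y,
                "applied": self.rotation_applied,
            }
        if self.subgrid_profiles is not None:
            doc["indices"] = {
                axis: [
                    {
                        "K": r.K,
                        "i_index": r.i_index,
                        "a_index": r.a_index,
                        "alpha_index": r.alpha_index,
                    }
                    for r in prof.records
                ]
                for axis, prof in self.subgrid_profiles.items()
            }
        return doc


def grid_image(img: MicroarrayImage, config: GridConfig | None = None) -> GridResult:
    """Run the full pipeline: rotation -> sub-grids -> spots -> refinement.

    Deterministic for a fixed image and config.  Stage failures carry the
    stage name.
    """
    cfg = config or GridConfig()

    est = None
    applied = False
    work = img
    if cfg.rotation:
        try:
            est = estimate_rotation(img, max_angle=cfg.max_angle)
        except ValueError as exc:
            raise ValueError(f"rotation stage: {exc}") from exc
        if max(abs(est.angle_x), abs(est.angle_y)) > cfg.min_correct_angle:
            work = correct_rotation(img, est, output_shape=cfg.output_shape)
            applied = True
        elif cfg.output_shape is not None and cfg.output_shape != img.shape:
            work = correct_rotation(
                img, RotationEstimate(0.0, 0.0, {}, {}), output_shape=cfg.output_shape
            )

    try:
        sub_geom, sub_prof = detect_subgrids(work, with_profiles=True)
    except ValueError as exc:
        raise ValueError(f"subgrid stage: {exc}") from exc
    if cfg.refine:
        sub_geom = refine_geometry(work, sub_geom)

    spot_rows: list[tuple[GridGeometry, ...]] = []
    best_ks: list[tuple[tuple[int, int], ...]] = []
    for cell_row in sub_geom.cells():
        out_row = []
        k_row = []
        for cell in cell_row:
            try:
                g, prof = detect_spots(work, cell, with_profiles=True)
            except ValueError as exc:
                raise ValueError(f"spot stage, cell {cell}: {exc}") from exc
            if cfg.refine:
                g = refine_geometry(work, g)
            out_row.append(g)
            k_row.append((prof["rows"].best_K, prof["cols"].best_K))
        spot_rows.append(tuple(out_row))
        best_ks.append(tuple(k_row))

    return GridResult(
        rotation_estimate=est,
        rotation_applied=applied,
        subgrid_geometry=sub_geom,
        spot_geometries=tuple(spot_rows),
        subgrid_profiles=sub_prof if cfg.report_indices else None,
        spot_best_K=tuple(best_ks),
        corrected_image=work if applied else None,
    )
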