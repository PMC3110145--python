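"""Local relocation of separating lines to minimal along-line intensity.

Each detected line is allowed to slide within a window (half the median
spacing of its parallel neighbours, so it can never jump into an adjacent
spot row/column) and is moved to the position whose pixel row/column sums
the least intensity over the line's bounded extent.  Ties keep the
position nearest the original (then the smaller coordinate), so a line
only moves on strict improvement; one extra pass runs if anything moved,
which reaches the idempotent fixed point.
"""

from __future__ import annotations

import numpy as np

from .geometry import GridGeometry
from .image import MicroarrayImage

__all__ = ["refine_line", "refine_geometry"]


def refine_line(
    img: MicroarrayImage,
    line: int,
    axis: str,
    bounds: tuple[int, int],
    window: int,
    lo: int | None = None,
    hi: int | None = None,
) -> int:
    """Best coordinate for one line within +-window, clamped to (lo, hi).

    ``axis`` is "h" (constant-row line) or "v" (constant-column); ``bounds``
    is the half-open perpendicular interval the line spans.  A line at
    coordinate c is the boundary between pixel rows/columns c-1 and c, so
    the intensity "along the line" is the summed intensity of those two
    straddling pixel lines over the interval (symmetric in the boundary
    convention).  An empty search range returns the original line.
    """
    if axis not in ("h", "v"):
        raise ValueError(f"axis must be 'h' or 'v', got {axis!r}")
    if window < 0:
        raise ValueError("window must be >= 0")
    px = img.pixels
    limit = px.shape[0] if axis == "h" else px.shape[1]
    c_lo = max(1, line - window, (lo + 1) if lo is not None else 1)
    c_hi = min(limit - 1, line + window, (hi - 1) if hi is not None else limit - 1)
    if c_hi < c_lo:
        return line
    b0, b1 = bounds
    if axis == "h":
        strip = px[c_lo - 1 : c_hi + 1, b0:b1].sum(axis=1, dtype=np.int64)
    else:
        strip = px[b0:b1, c_lo - 1 : c_hi + 1].sum(axis=0, dtype=np.int64)
    sums = strip[:-1] + strip[1:]
    cands = np.arange(c_lo, c_hi + 1)
    best = sums.min()
    tied = cands[sums == best]
    # nearest the original line, then the smaller coordinate
    return int(tied[np.lexsort((tied, np.abs(tied - line)))[0]])


def _median_half_spacing(edges: tuple[int, ...]) -> int:
    gaps = np.diff(edges)
    return max(0, int(np.median(gaps) // 2))


def refine_geometry(
    img: MicroarrayImage,
    geom: GridGeometry,
    window: int | None = None,
    max_passes: int = 2,
) -> GridGeometry:
    """Refine every line of a geometry; ordering and counts are preserved.

    Vertical lines are refined left to right, then horizontal top to
    bottom; each line is clamped between its (already refined) neighbours.
    """
    b = geom.bounds
    h = list(geom.horizontal_lines)
    v = list(geom.vertical_lines)
    w_h = window if window is not None else _median_half_spacing(geom.row_edges())
    w_v = window if window is not None else _median_half_spacing(geom.col_edges())

    for _ in range(max_passes):
        moved = False
        for i, line in enumerate(v):
            lo = v[i - 1] if i > 0 else b.col_start - 1
            hi = v[i + 1] if i + 1 < len(v) else b.col_end
            new = refine_line(img, line, "v", (b.row_start, b.row_end), w_v, lo, hi)
            if new != line:
                v[i] = new
                moved = True
        for j, line in enumerate(h):
            lo = h[j - 1] if j > 0 else b.row_start - 1
            hi = h[j + 1] if j + 1 < len(h) else b.row_end
            new = refine_line(img, line, "h", (b.col_start, b.col_end), w_h, lo, hi)
            if new != line:
                h[j] = new
                moved = True
        if not moved:
            break
    return GridGeometry(horizontal_lines=tuple(h), vertical_lines=tuple(v), bounds=b)
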