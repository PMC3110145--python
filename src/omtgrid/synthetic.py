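"""Ground-truthed synthetic cDNA microarray images and line scoring.

The generator emulates the three scanner layouts used throughout the
package's evaluation:

* ``smd``  — 1910x5550 canvas, 4x12 sub-grids of 18x18 spots, 18 px spots
  at 24 px pitch, 30 px sub-grid gaps;
* ``geo``  — 1900x5500 canvas, 4x12 sub-grids of 13 (cols) x 14 (rows)
  spots, 12 px spots at 20 px pitch, 200 px sub-grid gaps;
* ``diln`` — 604x960 canvas, 2x5 sub-grids of 8x8 spots, 12 px spots,
  200 px vertical / 25 px horizontal sub-grid gaps (dilution-series
  layout).

Spots are rendered as Gaussian-profiled disks (sigma = diameter/4) drawn on
the full spot cell (box plus half the inter-spot gap on each side), so
tails bleed into the ~6-8 px gaps between neighbouring spots the way real
printed spots do, while inter-sub-grid gaps stay at background level.  That
bleed is what lets the alpha index tell the spot-level partition apart from
the sub-grid-level one.  Noise is additive Gaussian clipped to the 16-bit
range; a fraction of spots can be dropped; bright elliptical artifacts can
be stamped on; a global rotation can be applied with the same bilinear
resampling the rotation module uses.  Everything is seeded and ground truth
is recorded pre-noise in the unrotated frame.

Detected separating lines are scored against the true spot masks:
a line crossing a mask interior is *incorrect*, within 1 px of a mask
*marginal*, otherwise *perfect* (an automated stand-in for the visual
incorrect/marginal/perfect taxonomy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GridGeometry, Rect
from .image import MicroarrayImage
from .rotation import rotate_image

__all__ = [
    "LayoutSpec",
    "SyntheticGroundTruth",
    "LineScore",
    "generate",
    "generate_dilution",
    "score_lines",
    "smd_preset",
    "geo_preset",
    "diln_preset",
    "NOISE_LEVELS",
]

_U16_MAX = 65535

#: noise presets as a fraction of the reference spot peak intensity
NOISE_LEVELS = {"none": 0.0, "low": 0.02, "moderate": 0.05}


@dataclass(frozen=True)
class LayoutSpec:
    """Full description of a synthetic array layout.

    Gaps separate spot *boxes* within a sub-grid (``spot_gap_px``) and
    sub-grid blocks from each other (``subgrid_gap_*``).  If ``image_size``
    is given the layout is centered on that canvas (error if it does not
    fit); otherwise the canvas derives from the layout plus margins.
    """

    subgrid_rows: int
    subgrid_cols: int
    spot_rows: int
    spot_cols: int
    spot_diameter_px: int
    spot_gap_px: int = 6
    subgrid_gap_row_px: int = 30
    subgrid_gap_col_px: int = 30
    margin_row_px: int | None = None
    margin_col_px: int | None = None
    image_size: tuple[int, int] | None = None
    background_level: float = 100.0
    spot_intensity_range: tuple[float, float] = (20000.0, 45000.0)
    #: amplitude of the wide hybridization-glow halo as a fraction of the
    #: spot peak (halo sigma is half the spot pitch, truncated at the cell)
    halo_fraction: float = 0.1
    noise_sd: float = 0.0
    missing_spot_fraction: float = 0.0
    artifact_count: int = 0
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("subgrid_rows", "subgrid_cols", "spot_rows", "spot_cols"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.spot_diameter_px < 2:
            raise ValueError("spot_diameter_px must be >= 2")
        if self.spot_gap_px < 1 or self.subgrid_gap_row_px < 1 or self.subgrid_gap_col_px < 1:
            raise ValueError("gaps must be >= 1 px")
        if not 0.0 <= self.missing_spot_fraction <= 1.0:
            raise ValueError("missing_spot_fraction must be in [0, 1]")

    # ---- derived geometry -------------------------------------------------
    @property
    def pitch(self) -> int:
        return self.spot_diameter_px + self.spot_gap_px

    def block_height(self) -> int:
        return self.spot_rows * self.spot_diameter_px + (self.spot_rows - 1) * self.spot_gap_px

    def block_width(self) -> int:
        return self.spot_cols * self.spot_diameter_px + (self.spot_cols - 1) * self.spot_gap_px

    def _required(self) -> tuple[int, int]:
        h = self.subgrid_rows * self.block_height() + (self.subgrid_rows - 1) * self.subgrid_gap_row_px
        w = self.subgrid_cols * self.block_width() + (self.subgrid_cols - 1) * self.subgrid_gap_col_px
        return h, w

    def resolve(self) -> tuple[tuple[int, int], int, int]:
        """((n_rows, n_cols), margin_row, margin_col) of the concrete canvas."""
        h, w = self._required()
        if self.image_size is not None:
            nr, nc = self.image_size
            mr, mc = (nr - h) // 2, (nc - w) // 2
            if mr < 0 or mc < 0:
                raise ValueError(
                    f"layout needs at least {h}x{w} px but image_size is {nr}x{nc}"
                )
            return (nr, nc), mr, mc
        mr = self.margin_row_px if self.margin_row_px is not None else self.subgrid_gap_row_px
        mc = self.margin_col_px if self.margin_col_px is not None else self.subgrid_gap_col_px
        return (h + 2 * mr, w + 2 * mc), mr, mc

    def block_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Half-open (start, end) extents of sub-grid blocks per axis."""
        (_, _), mr, mc = self.resolve()
        rows = []
        r = mr
        for _ in range(self.subgrid_rows):
            rows.append((r, r + self.block_height()))
            r += self.block_height() + self.subgrid_gap_row_px
        cols = []
        c = mc
        for _ in range(self.subgrid_cols):
            cols.append((c, c + self.block_width()))
            c += self.block_width() + self.subgrid_gap_col_px
        return rows, cols


def smd_preset(
    noise: str | float = "moderate",
    missing_spot_fraction: float = 0.0,
    rotation_deg: float = 0.0,
    seed: int = 0,
) -> LayoutSpec:
    """High-resolution Arabidopsis-style layout (1910x5550, 4x12, 18x18)."""
    return _preset(
        LayoutSpec(
            subgrid_rows=4, subgrid_cols=12, spot_rows=18, spot_cols=18,
            spot_diameter_px=18, spot_gap_px=6,
            subgrid_gap_row_px=30, subgrid_gap_col_px=30,
            image_size=(1910, 5550),
        ),
        noise, missing_spot_fraction, rotation_deg, seed,
    )


def geo_preset(
    noise: str | float = "moderate",
    missing_spot_fraction: float = 0.0,
    rotation_deg: float = 0.0,
    seed: int = 0,
) -> LayoutSpec:
    """Salmon-array-style layout (1900x5500, 4x12, 13x14 spots, 200 px gaps)."""
    return _preset(
        LayoutSpec(
            subgrid_rows=4, subgrid_cols=12, spot_rows=14, spot_cols=13,
            spot_diameter_px=12, spot_gap_px=8,
            subgrid_gap_row_px=200, subgrid_gap_col_px=200,
            image_size=(1900, 5500),
        ),
        noise, missing_spot_fraction, rotation_deg, seed,
    )


def diln_preset(
    noise: str | float = "low",
    missing_spot_fraction: float = 0.0,
    rotation_deg: float = 0.0,
    seed: int = 0,
) -> LayoutSpec:
    """Dilution-series layout (2x5 sub-grids of 8x8 spots)."""
    return _preset(
        LayoutSpec(
            subgrid_rows=2, subgrid_cols=5, spot_rows=8, spot_cols=8,
            spot_diameter_px=12, spot_gap_px=8,
            subgrid_gap_row_px=200, subgrid_gap_col_px=25,
            margin_row_px=50, margin_col_px=50,
        ),
        noise, missing_spot_fraction, rotation_deg, seed,
    )


def _preset(base: LayoutSpec, noise, missing, rotation, seed) -> LayoutSpec:
    if isinstance(noise, str):
        peak_ref = sum(base.spot_intensity_range) / 2.0
        noise_sd = NOISE_LEVELS[noise] * peak_ref
    else:
        noise_sd = float(noise)
    return replace(
        base, noise_sd=noise_sd, missing_spot_fraction=missing,
        rotation_deg=rotation, seed=seed,
    )


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Everything needed to score a detection against the construction."""

    spec: LayoutSpec
    original_shape: tuple[int, int]
    rotation_deg: float
    subgrid_row_blocks: tuple[tuple[int, int], ...]
    subgrid_col_blocks: tuple[tuple[int, int], ...]
    spot_subgrid: np.ndarray  # (N, 2) sub-grid (row, col) index
    spot_index: np.ndarray  # (N, 2) spot (row, col) index within sub-grid
    spot_centers: np.ndarray  # (N, 2) float (row, col), unrotated frame
    spot_radii: np.ndarray  # (N,)
    spot_present: np.ndarray  # (N,) bool
    spot_peaks: np.ndarray  # (N,) rendered peak intensity
    dilution_step: np.ndarray | None = None  # (N,) step label, or None

    # ---- derived ----------------------------------------------------------
    def subgrid_gap_intervals(self, axis: str) -> list[tuple[int, int]]:
        blocks = self.subgrid_row_blocks if axis == "rows" else self.subgrid_col_blocks
        return [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]

    def spot_gap_intervals(self, axis: str, subgrid_rc: tuple[int, int]) -> list[tuple[int, int]]:
        s = self.spec
        i, j = subgrid_rc
        if axis == "rows":
            b0, n = self.subgrid_row_blocks[i][0], s.spot_rows
        else:
            b0, n = self.subgrid_col_blocks[j][0], s.spot_cols
        d, g = s.spot_diameter_px, s.spot_gap_px
        return [(b0 + (t + 1) * d + t * g, b0 + (t + 1) * (d + g)) for t in range(n - 1)]

    def expected_line_counts(self, stage: str) -> tuple[int, int]:
        """(horizontal, vertical) separating-line counts for the stage."""
        s = self.spec
        if stage == "subgrid":
            return s.subgrid_rows - 1, s.subgrid_cols - 1
        return s.spot_rows - 1, s.spot_cols - 1

    # ---- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "spec": asdict(self.spec),
            "original_shape": list(self.original_shape),
            "rotation_deg": self.rotation_deg,
            "subgrid_row_blocks": [list(b) for b in self.subgrid_row_blocks],
            "subgrid_col_blocks": [list(b) for b in self.subgrid_col_blocks],
            "spot_subgrid": self.spot_subgrid.tolist(),
            "spot_index": self.spot_index.tolist(),
            "spot_centers": self.spot_centers.tolist(),
            "spot_radii": self.spot_radii.tolist(),
            "spot_present": self.spot_present.tolist(),
            "spot_peaks": self.spot_peaks.tolist(),
            "dilution_step": None if self.dilution_step is None else self.dilution_step.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticGroundTruth":
        spec_doc = dict(doc["spec"])
        for key in ("image_size", "spot_intensity_range"):
            if spec_doc.get(key) is not None:
                spec_doc[key] = tuple(spec_doc[key])
        return cls(
            spec=LayoutSpec(**spec_doc),
            original_shape=tuple(doc["original_shape"]),
            rotation_deg=doc["rotation_deg"],
            subgrid_row_blocks=tuple(tuple(b) for b in doc["subgrid_row_blocks"]),
            subgrid_col_blocks=tuple(tuple(b) for b in doc["subgrid_col_blocks"]),
            spot_subgrid=np.asarray(doc["spot_subgrid"], dtype=np.int32),
            spot_index=np.asarray(doc["spot_index"], dtype=np.int32),
            spot_centers=np.asarray(doc["spot_centers"], dtype=float),
            spot_radii=np.asarray(doc["spot_radii"], dtype=float),
            spot_present=np.asarray(doc["spot_present"], dtype=bool),
            spot_peaks=np.asarray(doc["spot_peaks"], dtype=float),
            dilution_step=None
            if doc.get("dilution_step") is None
            else np.asarray(doc["dilution_step"], dtype=np.int64),
        )


def _render(spec: LayoutSpec, rng: np.random.Generator, peaks_override=None,
            radii_override=None, dilution_step=None):
    (nr, nc), _, _ = spec.resolve()
    row_blocks, col_blocks = spec.block_intervals()
    d, g = spec.spot_diameter_px, spec.spot_gap_px
    sigma = d / 4.0

    img = np.full((nr, nc), float(spec.background_level))

    n_spots = spec.subgrid_rows * spec.subgrid_cols * spec.spot_rows * spec.spot_cols
    lo, hi = spec.spot_intensity_range
    peaks = rng.uniform(lo, hi, n_spots) if peaks_override is None else peaks_override
    present = rng.random(n_spots) >= spec.missing_spot_fraction

    sg_idx = np.empty((n_spots, 2), dtype=np.int32)
    sp_idx = np.empty((n_spots, 2), dtype=np.int32)
    centers = np.empty((n_spots, 2))
    radii = np.empty(n_spots)

    half_cell = (d + g) / 2.0
    t = 0
    for i, (r0, _) in enumerate(row_blocks):
        for j, (c0, _) in enumerate(col_blocks):
            for sr in range(spec.spot_rows):
                for sc in range(spec.spot_cols):
                    cr = r0 + sr * (d + g) + d / 2.0 - 0.5
                    cc = c0 + sc * (d + g) + d / 2.0 - 0.5
                    rad = d / 2.0 if radii_override is None else radii_override[t]
                    sg_idx[t] = (i, j)
                    sp_idx[t] = (sr, sc)
                    centers[t] = (cr, cc)
                    radii[t] = rad
                    if present[t]:
                        sig = rad / 2.0 if radii_override is not None else sigma
                        _stamp_gaussian(img, cr, cc, peaks[t], sig, half_cell,
                                        spec.halo_fraction, (d + g) / 2.0)
                    t += 1

    for _ in range(spec.artifact_count):
        ar = rng.uniform(0, nr)
        ac = rng.uniform(0, nc)
        rr = rng.uniform(5, 30)
        rc = rng.uniform(5, 30)
        amp = rng.uniform(0.8 * hi, 1.2 * hi)
        _stamp_ellipse(img, ar, ac, rr, rc, amp)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    pixels = np.clip(np.rint(img), 0, _U16_MAX).astype(np.uint16)
    micro = MicroarrayImage(pixels)
    truth = SyntheticGroundTruth(
        spec=spec,
        original_shape=(nr, nc),
        rotation_deg=spec.rotation_deg,
        subgrid_row_blocks=tuple(row_blocks),
        subgrid_col_blocks=tuple(col_blocks),
        spot_subgrid=sg_idx,
        spot_index=sp_idx,
        spot_centers=centers,
        spot_radii=radii,
        spot_present=present,
        spot_peaks=np.where(present, peaks, 0.0),
        dilution_step=dilution_step,
    )
    if spec.rotation_deg != 0.0:
        micro = rotate_image(micro, spec.rotation_deg)
    return micro, truth


def _stamp_gaussian(img, cr, cc, amp, sigma, half_cell, halo_fraction=0.0, halo_sigma=None):
    """Gaussian spot core plus an optional wide low halo, on the spot cell.

    The halo emulates the hybridization glow that keeps the valleys between
    neighbouring spots visibly above background in real scans; both
    components are cut at the cell edge so inter-sub-grid gaps stay clean.
    """
    r0 = max(0, int(math.floor(cr - half_cell + 0.5)))
    r1 = min(img.shape[0], int(math.ceil(cr + half_cell + 0.5)))
    c0 = max(0, int(math.floor(cc - half_cell + 0.5)))
    c1 = min(img.shape[1], int(math.ceil(cc + half_cell + 0.5)))
    rr = np.arange(r0, r1)[:, None] - cr
    ccd = np.arange(c0, c1)[None, :] - cc
    d2 = rr**2 + ccd**2
    patch = np.exp(-d2 / (2.0 * sigma**2))
    if halo_fraction > 0.0 and halo_sigma:
        patch = patch + halo_fraction * np.exp(-d2 / (2.0 * halo_sigma**2))
    img[r0:r1, c0:c1] += amp * patch


def _stamp_ellipse(img, cr, cc, rr, rc, amp):
    r0 = max(0, int(cr - rr))
    r1 = min(img.shape[0], int(cr + rr) + 1)
    c0 = max(0, int(cc - rc))
    c1 = min(img.shape[1], int(cc + rc) + 1)
    if r1 <= r0 or c1 <= c0:
        return
    y = (np.arange(r0, r1)[:, None] - cr) / rr
    x = (np.arange(c0, c1)[None, :] - cc) / rc
    img[r0:r1, c0:c1][y**2 + x**2 <= 1.0] += amp


def generate(spec: LayoutSpec) -> tuple[MicroarrayImage, SyntheticGroundTruth]:
    """Render a seeded synthetic microarray image with full ground truth.

    Ground truth (blocks, centers, masks) refers to the *unrotated* frame;
    when ``spec.rotation_deg`` is nonzero the returned image is the rotated
    (padded) canvas and ``truth.original_shape`` gives the frame to map
    back onto.
    """
    rng = np.random.default_rng(spec.seed)
    return _render(spec, rng)


def generate_dilution(
    steps: int = 8,
    fold: float = 2.0,
    seed: int = 0,
    noise_sd: float = 200.0,
    base_peak: float = 60000.0,
    shrink_with_step: bool = False,
    spec: LayoutSpec | None = None,
) -> tuple[MicroarrayImage, SyntheticGroundTruth]:
    """Dilution-series image: spot peaks decay by exactly ``fold`` per step.

    Steps tile across spot columns (column j is step j+1).  Footprints stay
    constant by default so the true spot volume also decays by exactly
    ``fold`` per step; ``shrink_with_step`` instead shrinks diameters from
    the layout's size down to 3 px across the series, mimicking scans where
    diluted spots print smaller (volume then decays faster than ``fold``).
    """
    if steps < 2:
        raise ValueError("need at least 2 dilution steps")
    if spec is None:
        spec = diln_preset(noise=noise_sd, seed=seed)
        if spec.spot_cols != steps:
            spec = replace(spec, spot_cols=steps)
    spec = replace(spec, noise_sd=float(noise_sd), seed=seed)
    rng = np.random.default_rng(seed)

    n_spots = spec.subgrid_rows * spec.subgrid_cols * spec.spot_rows * spec.spot_cols
    sc = np.tile(
        np.tile(np.arange(spec.spot_cols), spec.spot_rows),
        spec.subgrid_rows * spec.subgrid_cols,
    )
    step = sc % steps
    peaks = base_peak / fold**step
    radii = None
    if shrink_with_step:
        diam = np.linspace(spec.spot_diameter_px, 3.0, steps)
        radii = diam[step] / 2.0
    img, truth = _render(spec, rng, peaks_override=peaks, radii_override=radii,
                         dilution_step=step + 1)
    assert truth.dilution_step is not None and len(truth.dilution_step) == n_spots
    return img, truth


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class LineScore:
    """Pooled incorrect/marginal/perfect tallies over scored lines."""

    n_incorrect: int = 0
    n_marginal: int = 0
    n_perfect: int = 0

    @property
    def n_lines(self) -> int:
        return self.n_incorrect + self.n_marginal + self.n_perfect

    @property
    def incorrect_pct(self) -> float:
        return 100.0 * self.n_incorrect / self.n_lines if self.n_lines else 0.0

    @property
    def marginal_pct(self) -> float:
        return 100.0 * self.n_marginal / self.n_lines if self.n_lines else 0.0

    @property
    def perfect_pct(self) -> float:
        return 100.0 * self.n_perfect / self.n_lines if self.n_lines else 0.0

    def as_percentages(self) -> tuple[float, float, float]:
        return (self.incorrect_pct, self.marginal_pct, self.perfect_pct)

    def __add__(self, other: "LineScore") -> "LineScore":
        return LineScore(
            self.n_incorrect + other.n_incorrect,
            self.n_marginal + other.n_marginal,
            self.n_perfect + other.n_perfect,
        )


def _classify_line(coord, lo, hi, perp_centers, perp_radii, along_lo, along_hi):
    """Classify one separating line against the spot disks it could touch.

    ``coord`` is the line's coordinate on its own axis, the line spans
    [lo, hi) on the perpendicular axis; ``perp_centers`` are spot centers on
    the line's axis, ``along_lo/hi`` the spots' extents along the line.
    Returns 0 incorrect, 1 marginal, 2 perfect.
    """
    overlap = (along_hi > lo) & (along_lo < hi)
    if not overlap.any():
        return 2
    dist = np.abs(perp_centers[overlap] - coord)
    rad = perp_radii[overlap]
    if np.any(dist < rad):
        return 0
    if np.any(dist < rad + 1.0):
        return 1
    return 2


def _score_geometry(g: GridGeometry, truth: SyntheticGroundTruth, stage: str) -> LineScore:
    present = truth.spot_present
    cr = truth.spot_centers[present, 0]
    cc = truth.spot_centers[present, 1]
    rad = truth.spot_radii[present]
    exp_h, exp_v = truth.expected_line_counts(stage)
    b = g.bounds

    counts = [0, 0, 0]
    for axis, lines, n_exp in (
        ("h", g.horizontal_lines, exp_h),
        ("v", g.vertical_lines, exp_v),
    ):
        for coord in lines:
            if axis == "h":
                cls = _classify_line(coord, b.col_start, b.col_end, cr, rad,
                                     cc - rad, cc + rad)
            else:
                cls = _classify_line(coord, b.row_start, b.row_end, cc, rad,
                                     cr - rad, cr + rad)
            counts[cls] += 1
        n_det = len(lines)
        if n_det < n_exp:  # missing separators count as incorrect
            counts[0] += n_exp - n_det
        elif n_det > n_exp:  # surplus separators demoted to incorrect
            surplus = n_det - n_exp
            take = min(surplus, counts[2])
            counts[2] -= take
            counts[0] += take
            rest = surplus - take
            moved = min(rest, counts[1])
            counts[1] -= moved
            counts[0] += moved
    return LineScore(n_incorrect=counts[0], n_marginal=counts[1], n_perfect=counts[2])


def score_lines(detected, truth: SyntheticGroundTruth, stage: str) -> LineScore:
    """Score detected separating lines as incorrect/marginal/perfect.

    ``detected`` is a :class:`GridGeometry` (sub-grid stage, or one
    sub-grid's spot geometry) or any nested sequence of them (spot stage
    over all sub-grids); results pool.  Percentages always sum to 100.
    """
    if stage not in ("subgrid", "spot"):
        raise ValueError(f"unknown stage {stage!r}")
    if isinstance(detected, GridGeometry):
        return _score_geometry(detected, truth, stage)
    total = LineScore()
    for item in detected:
        total = total + score_lines(item, truth, stage)
    return total
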