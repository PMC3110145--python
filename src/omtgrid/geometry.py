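"""Grid geometry: separating lines, spot regions, JSON/TSV serialization.

Conventions (documented in every geometry file written):
0-based coordinates, half-open intervals.  A "horizontal line" is a
constant-row boundary separating sub-grid (or spot) rows; p sub-grid rows
are separated by exactly p-1 horizontal lines.  Lines are strictly
increasing and strictly inside the enclosing bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Rect",
    "SpotRegion",
    "GridGeometry",
    "write_geometry",
    "read_geometry",
    "export_spot_regions_tsv",
]


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError(f"empty rectangle: {self}")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.row_start, self.row_end, self.col_start, self.col_end)


@dataclass(frozen=True)
class SpotRegion:
    """One spot's rectangular cell inside a sub-grid."""

    row_interval: tuple[int, int]
    col_interval: tuple[int, int]

    def __post_init__(self):
        for a, b in (self.row_interval, self.col_interval):
            if b <= a:
                raise ValueError(f"empty interval [{a}, {b})")

    @property
    def rect(self) -> Rect:
        return Rect(*self.row_interval, *self.col_interval)


@dataclass(frozen=True)
class GridGeometry:
    """Separating lines subdividing ``bounds`` into a grid of cells."""

    horizontal_lines: tuple[int, ...]
    vertical_lines: tuple[int, ...]
    bounds: Rect

    def __post_init__(self):
        h = tuple(int(v) for v in self.horizontal_lines)
        v = tuple(int(x) for x in self.vertical_lines)
        object.__setattr__(self, "horizontal_lines", h)
        object.__setattr__(self, "vertical_lines", v)
        b = self.bounds
        for name, lines, lo, hi in (
            ("horizontal", h, b.row_start, b.row_end),
            ("vertical", v, b.col_start, b.col_end),
        ):
            if any(y <= x for x, y in zip(lines, lines[1:])):
                raise ValueError(f"{name} lines not strictly increasing: {lines}")
            if lines and (lines[0] <= lo or lines[-1] >= hi):
                raise ValueError(
                    f"{name} lines must lie strictly inside [{lo}, {hi}): {lines}"
                )

    @property
    def n_row_blocks(self) -> int:
        return len(self.horizontal_lines) + 1

    @property
    def n_col_blocks(self) -> int:
        return len(self.vertical_lines) + 1

    def row_edges(self) -> tuple[int, ...]:
        return (self.bounds.row_start, *self.horizontal_lines, self.bounds.row_end)

    def col_edges(self) -> tuple[int, ...]:
        return (self.bounds.col_start, *self.vertical_lines, self.bounds.col_end)

    def cells(self) -> list[list[Rect]]:
        """Row-major grid of half-open cells tiling the bounds exactly."""
        re = self.row_edges()
        ce = self.col_edges()
        return [
            [Rect(r0, r1, c0, c1) for c0, c1 in zip(ce, ce[1:])]
            for r0, r1 in zip(re, re[1:])
        ]

    def regions(self) -> list[list[SpotRegion]]:
        return [
            [SpotRegion((c.row_start, c.row_end), (c.col_start, c.col_end)) for c in row]
            for row in self.cells()
        ]


def write_geometry(g: GridGeometry, path: str | Path) -> None:
    """Serialize to JSON; round-trips losslessly via :func:`read_geometry`."""
    doc = {
        "coordinate_convention": "0-based, half-open intervals",
        "bounds": {
            "row_start": g.bounds.row_start,
            "row_end": g.bounds.row_end,
            "col_start": g.bounds.col_start,
            "col_end": g.bounds.col_end,
        },
        "horizontal_lines": list(g.horizontal_lines),
        "vertical_lines": list(g.vertical_lines),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_geometry(path: str | Path) -> GridGeometry:
    doc = json.loads(Path(path).read_text())
    b = doc["bounds"]
    return GridGeometry(
        horizontal_lines=tuple(doc["horizontal_lines"]),
        vertical_lines=tuple(doc["vertical_lines"]),
        bounds=Rect(b["row_start"], b["row_end"], b["col_start"], b["col_end"]),
    )


def export_spot_regions_tsv(
    spot_geoms: Sequence[Sequence[GridGeometry]], path: str | Path
) -> None:
    """Write every spot region as one TSV row.

    ``spot_geoms[i][j]`` is the spot-level geometry of the sub-grid in
    sub-grid row i, column j.
    """
    lines = [
        "subgrid_row\tsubgrid_col\tspot_row\tspot_col\t"
        "row_start\trow_end\tcol_start\tcol_end"
    ]
    for i, grow in enumerate(spot_geoms):
        for j, g in enumerate(grow):
            for r, cells in enumerate(g.cells()):
                for c, cell in enumerate(cells):
                    lines.append(
                        f"{i}\t{j}\t{r}\t{c}\t{cell.row_start}\t{cell.row_end}"
                        f"\t{cell.col_start}\t{cell.col_end}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")
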