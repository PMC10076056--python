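"""Readers and writers for the on-disk formats used throughout the package.

Point annotations and detection tables are plain comma-separated text
(comma separator, ``.`` decimal, UNIX newlines, UTF-8); density and
attention grids are single-channel 32-bit float TIFF; images are 8-bit
RGB PNG/JPEG.  All writers round-trip losslessly through the matching
reader (text to six printed decimals, TIFF bit-exact).

Coordinate convention, used everywhere in the package: ``x`` is the
column index, ``y`` the row index, both 0-based, with pixel centers at
integer coordinates and coordinates expressed at input-image scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile


class ParseError(ValueError):
    """A malformed row in a point/detection file."""


class FormatError(ValueError):
    """A shape or dtype that the on-disk format cannot represent."""


@dataclass
class PointSet:
    """Plant-center coordinates at input-image pixel scale.

    May be empty: a zero-plant image is legal input for every stage.
    """

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2), float))

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if pts.size and np.any(pts < 0):
            raise ValueError("point coordinates must be non-negative")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __iter__(self):
        return iter(self.points)


@dataclass
class DetectionTable:
    """Rows of (x, y, size): one axis-aligned square box per plant.

    ``size`` is the side length of the square centered at (x, y), at
    input-image scale.
    """

    xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2), float))
    sizes: np.ndarray = field(default_factory=lambda: np.empty((0,), float))

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.sizes = np.asarray(self.sizes, dtype=float).reshape(-1)
        if self.xy.shape[0] != self.sizes.shape[0]:
            raise FormatError("xy and sizes must have equal length")
        if self.sizes.size and np.any(self.sizes <= 0):
            raise FormatError("detection sizes must be strictly positive")

    def __len__(self) -> int:
        return self.xy.shape[0]


def _read_table(path, header: str, ncols: int) -> np.ndarray:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != header:
        raise ParseError(f"{path}: expected header {header!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != ncols:
            raise ParseError(f"{path}: line {lineno}: expected {ncols} fields, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value") from exc
    return np.asarray(rows, float).reshape(-1, ncols)


def _write_table(arr: np.ndarray, path, header: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for row in arr:
            fh.write(",".join(f"{v:.6f}" for v in row) + "\n")


def read_points(path) -> PointSet:
    """Read a ``x,y`` annotation file, preserving row order."""
    return PointSet(_read_table(path, "x,y", 2))


def write_points(points: PointSet, path) -> None:
    _write_table(points.points, path, "x,y")


def read_detections(path) -> DetectionTable:
    arr = _read_table(path, "x,y,size", 3)
    return DetectionTable(arr[:, :2], arr[:, 2])


def write_detections(table: DetectionTable, path) -> None:
    arr = np.column_stack([table.xy, table.sizes]) if len(table) else np.empty((0, 3))
    _write_table(arr, path, "x,y,size")


def read_image(path) -> np.ndarray:
    """Read an 8-bit image as an H×W×3 uint8 array."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {img.shape}")
    return np.ascontiguousarray(img[..., :3]).astype(np.uint8)


def write_image(image: np.ndarray, path) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise FormatError(f"expected H×W×3 image, got shape {image.shape}")
    iio.imwrite(os.fspath(path), image.astype(np.uint8))


def write_grid(grid: np.ndarray, path) -> None:
    """Write a 2-D grid as single-channel float32 TIFF (bit-exact round trip)."""
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise FormatError(f"expected a 2-D grid, got shape {grid.shape}")
    tifffile.imwrite(os.fspath(path), grid.astype(np.float32))


def read_grid(path) -> np.ndarray:
    grid = tifffile.imread(os.fspath(path))
    if grid.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel grid")
    return grid.astype(np.float32)
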