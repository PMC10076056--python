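"""Training targets from point annotations.

Three quantities are derived from the dot annotations alone:

* a Gaussian **density map** whose integral equals the plant count —
  each annotated center contributes a discretized isotropic Gaussian of
  standard deviation ``sigma`` (grid cells), renormalized to unit mass
  after truncation and boundary clipping so counting-by-integration is
  exact;
* a binary **attention map**, the support of the density map thresholded
  at 0.001, used as the plant-presence target for the attention branch;
* the **pseudo-average plant size** ``D_mean``: the per-plant mean of
  the beta-scaled distances to its K nearest neighbours, averaged over
  all plants.  Under the even-spacing assumption of a transplanted field
  this is a usable per-image size target without any box labels.

Targets live on a grid at half the input-image resolution (``scale=2``),
matching the resolution of the network's density output; annotation
coordinates are divided by the grid scale before kernel placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import PointSet

log = logging.getLogger(__name__)

ATTENTION_THRESHOLD = 0.001  # density support level defining plant presence
KERNEL_TRUNCATION_SIGMAS = 4.0  # mass beyond 4 sigma is < 1e-4 and is renormalized away


class SizeUndefinedError(ValueError):
    """Too few points to define a K-nearest-neighbour pseudo-size."""


@dataclass
class DensityGrid:
    """Non-negative 2-D grid whose integral is the plant count.

    ``scale`` is the down-sampling factor relative to the input image
    (fixed at 2 throughout the package).
    """

    values: np.ndarray
    scale: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("DensityGrid requires a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> float:
        return float(self.values.sum(dtype=np.float64))


@dataclass
class AttentionGrid:
    """Per-cell plant-presence map in [0,1]; ground truth is binary."""

    values: np.ndarray
    scale: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("AttentionGrid requires a 2-D array")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("attention values must lie in [0,1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def make_density_map(points: PointSet, grid_shape: tuple[int, int], sigma: float,
                     scale: int = 2) -> DensityGrid:
    """Gaussian density target on a ``grid_shape`` grid at ``scale``:1.

    Each point (input-image pixels) is divided by ``scale`` and stamped
    as a Gaussian kernel of sd ``sigma`` (grid cells), truncated at
    4 sigma and renormalized to unit mass after clipping at the grid
    border, so ``sum == len(points)`` to 1e-6 regardless of boundary
    proximity.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    rows, cols = grid_shape
    values = np.zeros((rows, cols), dtype=np.float64)
    radius = int(np.ceil(KERNEL_TRUNCATION_SIGMAS * sigma))
    for x, y in points:
        cx, cy = x / scale, y / scale
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = max(ix - radius, 0), min(ix + radius + 1, cols)
        y0, y1 = max(iy - radius, 0), min(iy + radius + 1, rows)
        if x0 >= x1 or y0 >= y1:
            continue  # kernel window entirely outside the grid
        gx = np.arange(x0, x1, dtype=np.float64) - cx
        gy = np.arange(y0, y1, dtype=np.float64) - cy
        kern = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2.0 * sigma * sigma))
        mass = kern.sum()
        if mass > 0:
            values[y0:y1, x0:x1] += kern / mass
    return DensityGrid(values.astype(np.float32), scale=scale)


def make_attention_gt(density: DensityGrid) -> AttentionGrid:
    """Binary plant-presence target: 1 where density exceeds 0.001."""
    mask = (density.values > ATTENTION_THRESHOLD).astype(np.float32)
    return AttentionGrid(mask, scale=density.scale)


def _knn_mean_distances(pts: np.ndarray, k: int) -> np.ndarray:
    """Per-point mean Euclidean distance to the k nearest other points."""
    tree = cKDTree(pts)
    # first neighbour is the point itself at distance 0
    dists, _ = tree.query(pts, k=k + 1)
    return dists[:, 1:].mean(axis=1)


def pseudo_mean_size(points: PointSet, k: int = 3, beta: float = 0.8) -> float:
    """Pseudo-average plant size D_mean from K-nearest-neighbour distances.

    Per point j the initial size is ``(beta / k) * sum of its k nearest
    neighbour distances``; D_mean is the mean of these over all points.
    Requires at least ``k + 1`` points; ties in neighbour distance are
    resolved by a stable (distance, index) order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be strictly positive")
    pts = points.points
    if len(points) < k + 1:
        raise SizeUndefinedError(
            f"need at least {k + 1} points for k={k} neighbours, got {len(points)}")
    mean_d = _knn_mean_distances(pts, k)
    d_mean = float(beta * mean_d.mean())
    if d_mean == 0.0:
        log.warning("pseudo_mean_size is 0: coincident points (degenerate annotation)")
    return d_mean
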