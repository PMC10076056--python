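"""Per-plant size estimation by KNN/regression fusion.

Each detected center gets an initial size from the beta-scaled mean
distance to its K nearest fellow detections; because that estimate blows
up for plants in sparse regions, it is capped by the per-image size
limit ``d_p`` regressed by the network's size head.  The fused size is
the side of an axis-aligned square box centered on the detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .groundtruth import _knn_mean_distances
from .io import DetectionTable, PointSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SizingParams:
    k: int = 3
    beta: float = 0.8
    fallback_size: float = 8.0  # used when fewer than 2 detections exist

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.beta <= 0 or self.fallback_size <= 0:
            raise ValueError("beta and fallback_size must be strictly positive")


def knn_sizes(centers: PointSet, params: SizingParams = SizingParams()) -> np.ndarray:
    """Initial per-plant sizes from K-nearest-neighbour distances.

    Returns one size per center, in center order.  With fewer than
    ``k + 1`` centers all available neighbours are used (with a
    warning); with fewer than 2 centers every size is the configured
    fallback.
    """
    n = len(centers)
    if n < 2:
        log.warning("knn_sizes: %d center(s); using fallback size %.3g", n,
                    params.fallback_size)
        return np.full(n, params.fallback_size, float)
    k = params.k
    if n - 1 < k:
        log.warning("knn_sizes: only %d neighbours available for k=%d", n - 1, k)
        k = n - 1
    return params.beta * _knn_mean_distances(centers.points, k)


def fuse_sizes(knn: np.ndarray, d_p: float) -> np.ndarray:
    """Cap KNN sizes by the regressed limit: elementwise min(knn, d_p)."""
    if d_p <= 0:
        raise ValueError("d_p must be strictly positive")
    return np.minimum(np.asarray(knn, float), d_p)


def make_detections(centers: PointSet, sizes: np.ndarray) -> DetectionTable:
    """Assemble square boxes (side = size) centered on each detection."""
    sizes = np.asarray(sizes, float)
    if len(centers) != sizes.shape[0]:
        raise ValueError(f"{len(centers)} centers but {sizes.shape[0]} sizes")
    return DetectionTable(centers.points.copy(), sizes)
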