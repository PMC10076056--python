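"""Plant localization by local non-maximum suppression (LNMS).

A predicted density map of a near-evenly spaced stand has one local peak
per plant, so plant centers are recovered by keeping every cell equal to
the maximum of its w×w neighbourhood (w derived from the pseudo-average
plant size), then discarding weak candidates below an adaptive fraction
of the global maximum.  An all-but-empty map (global maximum below
``min_peak``) yields the empty set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.spatial.distance import cdist

from .groundtruth import DensityGrid
from .io import PointSet


@dataclass(frozen=True)
class LNMSParams:
    """Constants of the suppression rule.

    ``kernel_fraction`` scales the pseudo-average plant size into the
    max-pool window; ``threshold_fraction`` sets the adaptive threshold
    as a fraction of the global maximum; ``min_peak`` is the floor below
    which the map is declared empty.
    """

    kernel_fraction: float = 0.3
    threshold_fraction: float = 0.3
    min_peak: float = 0.01

    def __post_init__(self):
        if self.kernel_fraction <= 0 or self.threshold_fraction <= 0 or self.min_peak <= 0:
            raise ValueError("LNMS parameters must be strictly positive")
        if self.kernel_fraction > 1 or self.threshold_fraction > 1:
            raise ValueError("LNMS fractions must be <= 1")


def window_size(d_mean: float, kernel_fraction: float = 0.3) -> int:
    """Odd window side >= 3 nearest to ``d_mean * kernel_fraction``."""
    w = int(round(d_mean * kernel_fraction))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def lnms(fdm: DensityGrid, d_mean: float, params: LNMSParams = LNMSParams()) -> PointSet:
    """Extract plant centers from a density map.

    ``d_mean`` is the pseudo-average plant size expressed in grid cells
    (callers holding an image-pixel size divide by ``fdm.scale`` first).
    Every cell equal to its w×w neighbourhood maximum (window clipped at
    the borders) and strictly above ``threshold_fraction`` of the global
    maximum is kept; flat plateaus therefore yield one detection per
    plateau cell.  Returned coordinates are at input-image scale
    (grid coordinate × ``fdm.scale``), ordered row-major.
    """
    if d_mean <= 0:
        raise ValueError("d_mean must be strictly positive")
    vals = np.asarray(fdm.values, np.float64)
    if vals.size == 0:
        return PointSet()
    m = float(vals.max())
    if m < params.min_peak:
        return PointSet()
    w = window_size(d_mean, params.kernel_fraction)
    local_max = maximum_filter(vals, size=w, mode="constant", cval=0.0)
    keep = (vals == local_max) & (vals > m * params.threshold_fraction)
    ys, xs = np.nonzero(keep)
    pts = np.column_stack([xs, ys]).astype(float) * fdm.scale
    return PointSet(pts)


def match_points(predicted: PointSet, truth: PointSet, radius: float):
    """Greedy one-to-one matching by ascending pairwise distance.

    Pairs farther apart than ``radius`` stay unmatched.  Returns
    ``(hits, misses, false_alarms)``.
    """
    if radius <= 0:
        raise ValueError("radius must be strictly positive")
    np_, nt = len(predicted), len(truth)
    if np_ == 0 or nt == 0:
        return 0, nt, np_
    d = cdist(predicted.points, truth.points)
    pairs = np.argwhere(d <= radius)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_p = np.zeros(np_, bool)
    used_t = np.zeros(nt, bool)
    hits = 0
    for i, j in pairs[order]:
        if not used_p[i] and not used_t[j]:
            used_p[i] = used_t[j] = True
            hits += 1
    return hits, nt - hits, np_ - hits
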