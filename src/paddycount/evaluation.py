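"""Counting and localization metrics.

Counting accuracy is summarized by the mean absolute error and root
mean square error between true and predicted per-image counts, plus a
coefficient of determination.  Two R² conventions are provided: the
``standard`` one (denominator = variance of the truth) and the
``as_printed`` variant whose denominator measures the spread of the
*predictions* around the mean truth; the two differ whenever the
prediction spread differs from the truth spread, and neither is
silently substituted for the other.  The predicted per-image count is
the integral of the final density map; the detection count from LNMS is
reported separately, never substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groundtruth import DensityGrid


@dataclass
class CountPairs:
    """Per-image (truth, predicted) counts."""

    truth: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        self.truth = np.asarray(self.truth, float).reshape(-1)
        self.predicted = np.asarray(self.predicted, float).reshape(-1)
        if self.truth.shape != self.predicted.shape:
            raise ValueError("truth and predicted must have equal length")
        if np.any(self.truth < 0):
            raise ValueError("truth counts must be >= 0")

    def __len__(self):
        return self.truth.size


def _nonempty(pairs: CountPairs) -> CountPairs:
    if len(pairs) == 0:
        raise ValueError("metrics are undefined for an empty set of pairs")
    return pairs


def mae(pairs: CountPairs) -> float:
    """Mean absolute count error over images."""
    p = _nonempty(pairs)
    return float(np.mean(np.abs(p.truth - p.predicted)))


def rmse(pairs: CountPairs) -> float:
    """Root mean square count error over images."""
    p = _nonempty(pairs)
    return float(np.sqrt(np.mean((p.truth - p.predicted) ** 2)))


def r_squared(pairs: CountPairs, mode: str = "as_printed") -> float:
    """Coefficient of determination between predicted and true counts.

    ``standard``: 1 - SS_res / sum((G_i - mean G)^2).
    ``as_printed``: 1 - SS_res / sum((P_i - mean G)^2), i.e. the
    denominator spreads the predictions around the mean truth.
    """
    p = _nonempty(pairs)
    g_bar = p.truth.mean()
    num = float(np.sum((p.predicted - p.truth) ** 2))
    if mode == "standard":
        den = float(np.sum((p.truth - g_bar) ** 2))
    elif mode == "as_printed":
        den = float(np.sum((p.predicted - g_bar) ** 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0:
        raise ValueError("R^2 denominator is zero for these pairs")
    return 1.0 - num / den


def count_from_density(fdm: DensityGrid) -> float:
    """Predicted count = integral (sum) of the density map."""
    return fdm.count()


def write_report(rows: list[dict], summary: dict, csv_path, json_path) -> None:
    """Per-image table as CSV plus a JSON metric summary.

    Non-finite metrics (e.g. an undefined R² on constant truth counts)
    are written as JSON null.
    """
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    clean = {k: (float(v) if np.isfinite(v) else None) if isinstance(v, (int, float, np.floating)) else v
             for k, v in summary.items()}
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(clean, fh, indent=2)
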