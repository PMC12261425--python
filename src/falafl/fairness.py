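"""Deviation from perfect correlation of per-patient informativeness.

A site's lineage-informativeness across ``n`` patients is a vector
``v ∈ [0,1]^n``.  Universality is measured as the Euclidean distance from
the point ``v`` to the diagonal line through the origin and the all-ones
point (the "line of perfect equality"); projecting out the diagonal
component leaves

    distance(v) = sqrt( sum_i (v_i - mean(v))^2 )

which is 0 exactly when all patients agree.  For comparability across
cohort sizes this is normalized by the maximum distance attainable inside
the unit hypercube, reached at corner vectors with half the coordinates 1:

    max_distance(n) = sqrt(n/4)                  for even n
                      sqrt((n+1)(n-1) / (4n))    for odd n

so the normalized deviation always lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DeviationResult", "deviation", "max_distance", "deviation_table"]


@dataclass
class DeviationResult:
    raw_distance: float
    max_distance: float
    normalized: float
    mean_v: float


def max_distance(n: int) -> float:
    """Maximum L2 distance from the diagonal within the unit hypercube.

    Attained at binary corner vectors with ``floor(n/2)`` or ``ceil(n/2)``
    ones; equals the corner-enumeration maximum of the raw deviation.
    """
    if n < 2:
        raise ValueError("need at least 2 patients")
    if n % 2 == 0:
        return float(np.sqrt(n / 4.0))
    return float(np.sqrt((n + 1) * (n - 1) / (4.0 * n)))


def deviation(v) -> DeviationResult:
    """Deviation of one per-patient vector from perfect correlation."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("v must be a 1-D vector with >= 2 patients")
    if (v < 0).any() or (v > 1).any() or not np.isfinite(v).all():
        raise ValueError("all entries of v must lie in [0, 1]")
    raw = float(np.sqrt(((v - v.mean()) ** 2).sum()))
    mx = max_distance(v.size)
    return DeviationResult(raw, mx, raw / mx, float(v.mean()))


def deviation_table(js: pd.DataFrame) -> pd.DataFrame:
    """Vectorized deviations for a sites × patients table of JS distances.

    Returns the input with appended columns ``raw_distance``,
    ``normalized_deviation`` and ``mean_v``.
    """
    vals = js.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 patient columns")
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("JS distances must lie in [0, 1]")
    raw = np.sqrt(((vals - vals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    out = js.copy()
    out["raw_distance"] = raw
    out["normalized_deviation"] = raw / max_distance(vals.shape[1])
    out["mean_v"] = vals.mean(axis=1)
    return out
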