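"""Trunk-sway quantification from waist angular velocities.

The waist IMU's pitch and roll angular velocities pv(t), pr(t) (deg/s) are
folded into the first quadrant as (|pv|, |pr|).  The sway index is the
radius of the quarter-circle that encloses 95 % of these points — i.e. the
95th percentile (nearest-rank) of the Euclidean norms sqrt(pv^2 + pr^2).
A larger radius means a less stable subject.

For walking exercises the validity mask from the gait module removes body
turns, so only straight-walking sway enters the index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError

MIN_RETAINED_SAMPLES = 100


@dataclass
class SwayResult:
    radius_deg_per_s: float
    n_points: int
    excluded_fraction: float
    scatter: np.ndarray | None = None  # (n, 2) retained (|pv|, |pr|)

    def scatter_frame(self) -> pd.DataFrame:
        """Retained points as a DataFrame for Figure-style scatter export."""
        if self.scatter is None:
            raise ValueError("scatter was not retained; pass keep_scatter=True")
        return pd.DataFrame(self.scatter, columns=["abs_pv", "abs_pr"])


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Smallest value v such that at least ceil(q*n) of the values are <= v."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    k = int(np.ceil(q * n))
    return float(values[max(k, 1) - 1])


def sway_index(
    pv: np.ndarray,
    pr: np.ndarray,
    valid_mask: np.ndarray | None = None,
    coverage: float = 0.95,
    keep_scatter: bool = False,
) -> SwayResult:
    """Radius of the quadrant enclosing ``coverage`` of the (|pv|, |pr|) points.

    Nearest-rank quantile convention: the radius is an observed norm, the
    smallest one with >= 95 % of points at or inside it.  Scaling both
    series by c > 0 scales the radius by exactly c, and the statistic is
    invariant to sample order.
    """
    pv = np.abs(np.asarray(pv, dtype=float))
    pr = np.abs(np.asarray(pr, dtype=float))
    if pv.shape != pr.shape:
        raise FormatError("pv and pr must have equal length")
    n_total = pv.size
    if valid_mask is not None:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if valid_mask.shape != pv.shape:
            raise FormatError("valid_mask must match series length")
        pv, pr = pv[valid_mask], pr[valid_mask]
    n = pv.size
    if n < MIN_RETAINED_SAMPLES:
        raise InsufficientDataError(
            f"{n} retained samples < {MIN_RETAINED_SAMPLES} required for the sway index"
        )
    r = np.hypot(pv, pr)
    radius = nearest_rank_quantile(r, coverage)
    excluded = 1.0 - n / n_total if n_total else 0.0
    scatter = np.column_stack([pv, pr]) if keep_scatter else None
    return SwayResult(radius, n, excluded, scatter)
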