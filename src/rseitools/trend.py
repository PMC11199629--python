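"""Sen's slope, Mann--Kendall significance, trend-class rasters, and
piecewise-regression breakpoint detection for annual series.

Sen's slope is the median (default; the arithmetic mean is available as a
variant) of all pairwise slopes (x_j - x_i)/(j - i).  The MK test uses
the signed pair-count statistic S, tie-corrected variance

    VAR(S) = [n(n-1)(2n+5) - sum_k q_k (q_k-1)(2q_k+5)] / 18

and the continuity-corrected normal approximation Z = (S-1)/sqrt(VAR) for
S > 0, 0 for S = 0, (S+1)/sqrt(VAR) for S < 0.

Breakpoints on an annual mean series are found by exhaustive search over
all admissible placements (each segment >= ``min_seg`` points, default 3),
each segment fitted by independent OLS, minimizing the summed cost
J = sum_segments (1/(2 m_seg)) * SSR_seg.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .raster import RasterStack

TREND_CLASS_LABELS = ("significant decrease", "decrease", "stable",
                      "increase", "significant increase")


@dataclass
class MKResult:
    S: int
    VAR_S: float
    Z: float
    p: float
    slope: float


def sen_slope(series: np.ndarray, estimator: str = "median",
              times: np.ndarray | None = None) -> float:
    """Aggregate of all pairwise slopes; NaN if fewer than 2 valid points."""
    if estimator not in ("median", "mean"):
        raise ValueError("estimator must be 'median' or 'mean'")
    y = np.asarray(series, dtype=float)
    t = np.arange(y.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    ok = np.isfinite(y)
    y, t = y[ok], t[ok]
    if y.size < 2:
        return np.nan
    i, j = np.triu_indices(y.size, k=1)
    slopes = (y[j] - y[i]) / (t[j] - t[i])
    return float(np.median(slopes) if estimator == "median" else np.mean(slopes))


def mk_test(series: np.ndarray, estimator: str = "median",
            tie_epsilon: float = 0.0) -> MKResult:
    """Mann--Kendall trend test with tie-corrected variance.

    ``tie_epsilon`` is the threshold below which a pairwise difference
    counts as a tie (0 = exact ties only).
    """
    y = np.asarray(series, dtype=float)
    y = y[np.isfinite(y)]
    n = y.size
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 valid points")
    diff = y[None, :] - y[:, None]            # diff[i, j] = x_j - x_i
    iu = np.triu_indices(n, k=1)
    d = diff[iu]
    sgn = np.where(np.abs(d) <= tie_epsilon, 0, np.sign(d))
    S = int(sgn.sum())

    # tie groups over values (within epsilon -> exact grouping for eps=0)
    _, counts = np.unique(y, return_counts=True)
    tie_term = (counts * (counts - 1) * (2 * counts + 5)).sum()
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if var_s <= 0 or S == 0:
        z = 0.0
    elif S > 0:
        z = (S - 1) / np.sqrt(var_s)
    else:
        z = (S + 1) / np.sqrt(var_s)
    p = 1.0 if var_s <= 0 else float(2.0 * stats.norm.sf(abs(z)))
    return MKResult(S=S, VAR_S=float(var_s), Z=float(z), p=p,
                    slope=sen_slope(y, estimator))


def _mk_stack(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized S and VAR(S) for an all-valid (T, P) array."""
    T = values.shape[0]
    sgn = np.sign(values[None, :, :] - values[:, None, :])   # (T, T, P)
    iu = np.triu_indices(T, k=1)
    S = sgn[iu].sum(axis=0)
    base = T * (T - 1) * (2 * T + 5)
    srt = np.sort(values, axis=0)
    same = srt[1:] == srt[:-1]
    # tie groups are rare for float series: correct only pixels that have any
    tie_term = np.zeros(values.shape[1])
    has_ties = same.any(axis=0)
    for p in np.where(has_ties)[0]:
        _, counts = np.unique(values[:, p], return_counts=True)
        tie_term[p] = (counts * (counts - 1) * (2 * counts + 5)).sum()
    var_s = (base - tie_term) / 18.0
    return S, var_s


def mk_z_from_s(S: np.ndarray, var_s: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(S > 0, (S - 1) / np.sqrt(var_s),
                     np.where(S < 0, (S + 1) / np.sqrt(var_s), 0.0))
    return np.where(var_s > 0, z, 0.0)


def trend_raster(stack: RasterStack, estimator: str = "median",
                 z_sig: float = 1.96, z_strong: float = 2.58
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel Sen slope + MK Z + five-class trend grid.

    Classes: |Z| >= ``z_strong`` -> significant increase/decrease,
    ``z_sig`` <= |Z| < ``z_strong`` -> increase/decrease, else stable.
    Pixels with fewer than 3 valid layers are nodata (class -1).
    """
    T, R, C = stack.shape
    if T < 3:
        raise ValueError("need at least 3 layers for a trend raster")
    y = stack.values.reshape(T, -1)
    valid = np.isfinite(y)
    complete = valid.all(axis=0)

    slope = np.full(y.shape[1], np.nan)
    Z = np.full(y.shape[1], np.nan)
    if complete.any():
        vals = y[:, complete]
        t = np.arange(T, dtype=float)
        i, j = np.triu_indices(T, k=1)
        pair = (vals[j] - vals[i]) / (t[j] - t[i])[:, None]
        slope[complete] = (np.median(pair, axis=0) if estimator == "median"
                           else pair.mean(axis=0))
        S, var_s = _mk_stack(vals)
        Z[complete] = mk_z_from_s(S, var_s)
    # gappy pixels: per-pixel path
    for p in np.where(~complete & (valid.sum(axis=0) >= 3))[0]:
        res = mk_test(y[:, p], estimator)
        slope[p], Z[p] = res.slope, res.Z

    classes = np.full(y.shape[1], -1, dtype=np.int8)
    ok = np.isfinite(Z) & np.isfinite(slope)
    az = np.abs(Z[ok])
    sgn = np.sign(slope[ok])
    cls = np.full(az.shape, 2, dtype=np.int8)            # stable
    cls[(az >= z_sig) & (sgn > 0)] = 3
    cls[(az >= z_strong) & (sgn > 0)] = 4
    cls[(az >= z_sig) & (sgn < 0)] = 1
    cls[(az >= z_strong) & (sgn < 0)] = 0
    classes[ok] = cls
    return slope.reshape(R, C), Z.reshape(R, C), classes.reshape(R, C)


@dataclass
class BreakpointModel:
    """Piecewise-OLS fit: break positions, per-segment fits, total cost."""

    breakpoints: list[int]        # index of the first point of each new segment
    segments: list[dict]          # {start, stop, intercept, slope, r2, cost}
    cost: float
    degenerate: bool = False      # True when no split beats a straight line


def _segment_fit(t: np.ndarray, y: np.ndarray) -> dict:
    m = t.size
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return {"start": int(t[0]), "stop": int(t[-1]), "intercept": float(intercept),
            "slope": float(slope), "r2": r2, "cost": ssr / (2 * m), "m": m}


def _evaluate_placement(t: np.ndarray, y: np.ndarray, cuts: tuple[int, ...]) -> tuple[float, list[dict]]:
    bounds = [0, *cuts, t.size]
    segs = [_segment_fit(t[a:b], y[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]
    return sum(s["cost"] for s in segs), segs


def breakpoint_search(series: np.ndarray, k_breaks: int, min_seg: int = 3,
                      degenerate_tol: float = 1e-12) -> BreakpointModel:
    """Exhaustive minimum-cost piecewise OLS with ``k_breaks`` breakpoints.

    A breakpoint at index b starts a new segment at position b; every
    segment must contain at least ``min_seg`` points.  Ties in total cost
    break toward the earliest placement.  The ``degenerate`` flag is set
    when the best split improves on the single-line cost by less than
    ``degenerate_tol`` (no real breakpoint in the data).
    """
    y = np.asarray(series, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("breakpoint_search requires a complete series")
    n = y.size
    if k_breaks < 1 or n < (k_breaks + 1) * min_seg:
        raise ValueError(f"series of {n} points cannot host {k_breaks} breaks "
                         f"with segments of >= {min_seg}")
    t = np.arange(n, dtype=float)

    best_cost, best_cuts, best_segs = np.inf, None, None
    for cuts in combinations(range(min_seg, n - min_seg + 1), k_breaks):
        if any(b - a < min_seg for a, b in zip((0, *cuts), (*cuts, n))):
            continue
        cost, segs = _evaluate_placement(t, y, cuts)
        if cost < best_cost - 1e-15:
            best_cost, best_cuts, best_segs = cost, cuts, segs

    single = _segment_fit(t, y)["cost"] if k_breaks >= 1 else best_cost
    degenerate = (single - best_cost) <= degenerate_tol
    return BreakpointModel(list(best_cuts), best_segs, float(best_cost), degenerate)


def compare_models(series: np.ndarray, candidates: list[list[int]],
                   min_seg: int = 3) -> pd.DataFrame:
    """Rank candidate breakpoint placements by total cost J.

    Placements violating ``min_seg`` are kept in the table but flagged
    rejected with a reason and ranked last.
    """
    y = np.asarray(series, dtype=float)
    t = np.arange(y.size, dtype=float)
    rows = []
    for cand in candidates:
        cuts = tuple(sorted(int(c) for c in cand))
        lengths = np.diff((0, *cuts, y.size))
        if (lengths < min_seg).any() or len(set(cuts)) != len(cuts):
            rows.append({"breakpoints": list(cuts), "J": np.inf, "r2": None,
                         "rejected": True,
                         "reason": f"segment shorter than {min_seg} points"})
            continue
        cost, segs = _evaluate_placement(t, y, cuts)
        rows.append({"breakpoints": list(cuts), "J": cost,
                     "r2": [s["r2"] for s in segs], "rejected": False, "reason": ""})
    table = pd.DataFrame(rows).sort_values("J", kind="stable").reset_index(drop=True)
    return table
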