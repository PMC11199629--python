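"""Geographical detector: factor q-statistic and pairwise interactions.

The factor detector measures how much a stratification X explains the
spatial variation of a response Y:

    q = 1 - SSW / SST = 1 - sum_h N_h sigma_h^2 / (N sigma^2)

with population (1/N_h) variances so the identity is exact; q is in
[0, 1] and invariant to affine transforms of Y.  Significance comes from
a permutation test by default, with the noncentral-F transformation as an
option.  The interaction detector stratifies on the co-occurrence of two
factors and classifies q(X1 inter X2) against q(X1), q(X2) into the five
standard categories (nonlinear weakening, single-factor nonlinear
weakening, two-factor enhancement, independent, nonlinear enhancement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

INTERACTION_CATEGORIES = (
    "nonlinear weakening",
    "single-factor nonlinear weakening",
    "two-factor enhancement",
    "independent",
    "nonlinear enhancement",
)


def discretize(values: np.ndarray, method: str = "quantile", k: int = 5
               ) -> np.ndarray:
    """Stratify a continuous variable into k classes.

    ``quantile`` uses equal-count edges, ``equal-interval`` equal-width
    edges, ``natural-breaks`` the exact minimum within-class sum of
    squares partition (Fisher-Jenks by dynamic programming).  Categorical
    (non-float, or explicitly ``method="categorical"``) input is passed
    through unchanged as integer codes.
    """
    v = np.asarray(values)
    if method == "categorical" or v.dtype.kind in "iubSUO":
        _, codes = np.unique(v, return_inverse=True)
        return codes.astype(int)
    x = v.astype(float)
    if not np.isfinite(x).all():
        raise ValueError("discretize expects finite values")
    if k < 2:
        raise ValueError("k must be >= 2")
    if method == "quantile":
        if np.unique(x).size < k:
            raise ValueError(f"need >= {k} distinct values for quantile binning")
        edges = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
        return np.digitize(x, edges, right=True).astype(int)
    if method == "equal-interval":
        edges = np.linspace(x.min(), x.max(), k + 1)[1:-1]
        return np.digitize(x, edges, right=True).astype(int)
    if method == "natural-breaks":
        return _fisher_jenks(x, k)
    raise ValueError(f"unknown method {method!r}")


def _fisher_jenks(x: np.ndarray, k: int) -> np.ndarray:
    """Optimal 1-D k-partition by within-class SS (O(n^2 k) DP on sorted data)."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def ss(a: int, b: int) -> float:          # within-SS of xs[a:b]
        m = b - a
        s = csum[b] - csum[a]
        return (csq[b] - csq[a]) - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for b in range(j, n + 1):
            for a in range(j - 1, b):
                c = cost[j - 1, a] + ss(a, b)
                if c < cost[j, b]:
                    cost[j, b] = c
                    cut[j, b] = a
    bounds = [n]
    for j in range(k, 0, -1):
        bounds.append(cut[j, bounds[-1]])
    bounds = bounds[::-1]
    codes_sorted = np.empty(n, dtype=int)
    for g, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        codes_sorted[a:b] = g
    codes = np.empty(n, dtype=int)
    codes[order] = codes_sorted
    return codes


def _q_value(y: np.ndarray, strata: np.ndarray) -> float:
    sst = y.size * y.var()
    if sst == 0:
        return np.nan
    ssw = 0.0
    for s in np.unique(strata):
        ys = y[strata == s]
        ssw += ys.size * ys.var()
    return 1.0 - ssw / sst


def factor_q(y: np.ndarray, strata: np.ndarray, permutations: int = 999,
             seed: int = 0, p_method: str = "permutation"
             ) -> tuple[float, float]:
    """q-statistic of one stratified factor plus its p-value.

    ``p_method="permutation"`` shuffles Y over samples (seeded);
    ``"ncf"`` uses the noncentral-F transformation
    F = (N-L)/(L-1) * q/(1-q) with noncentrality
    lambda = [sum_h ybar_h^2 N_h- (sum_h sqrt(N_h) ybar_h)^2 / N] / sigma^2.
    """
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if y.shape != strata.shape:
        raise ValueError("y and strata must align")
    labels = np.unique(strata)
    if labels.size < 2:
        return _q_value(y, strata), np.nan
    obs = _q_value(y, strata)
    if np.isnan(obs):
        return np.nan, np.nan
    if p_method == "ncf":
        N, L = y.size, labels.size
        if obs >= 1.0:
            return obs, 0.0
        F = (N - L) / (L - 1) * obs / (1.0 - obs)
        means = np.array([y[strata == s].mean() for s in labels])
        sizes = np.array([(strata == s).sum() for s in labels])
        lam = (means**2 @ sizes - (np.sqrt(sizes) @ means) ** 2 / N) / y.var()
        p = float(stats.ncf.sf(F, L - 1, N - L, max(lam, 0.0)))
        return obs, p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        if _q_value(rng.permutation(y), strata) >= obs:
            count += 1
    return obs, (count + 1) / (permutations + 1)


def interaction_strata(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Co-occurrence (cartesian) strata of two factors."""
    pairs = np.stack([np.asarray(s1), np.asarray(s2)], axis=1)
    _, codes = np.unique(pairs, axis=0, return_inverse=True)
    return codes


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-9) -> str:
    """Five-way interaction category from the standard comparison table."""
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "nonlinear enhancement"
    if q12 > hi + tol:
        return "two-factor enhancement"
    if q12 >= lo - tol:
        return "single-factor nonlinear weakening"
    return "nonlinear weakening"


def interaction_q(y: np.ndarray, s1: np.ndarray, s2: np.ndarray,
                  tol: float = 1e-9) -> dict:
    """q of the intersection stratification plus its category.

    Returns ``{"q1", "q2", "q12", "category"}``; raises if the
    co-occurrence leaves fewer than 2 strata.
    """
    y = np.asarray(y, dtype=float)
    inter = interaction_strata(s1, s2)
    if np.unique(inter).size < 2:
        raise ValueError("interaction leaves fewer than 2 strata")
    q1 = _q_value(y, np.asarray(s1))
    q2 = _q_value(y, np.asarray(s2))
    q12 = _q_value(y, inter)
    return {"q1": q1, "q2": q2, "q12": q12,
            "category": classify_interaction(q1, q2, q12, tol)}


@dataclass
class DetectorResult:
    """Per-factor q/p table plus symmetric interaction matrices."""

    factors: pd.DataFrame                 # columns: factor, q, p, n_strata
    interaction: pd.DataFrame             # q(Xi inter Xj), symmetric
    categories: pd.DataFrame              # category labels, symmetric


def detector_report(y: np.ndarray, drivers: dict[str, np.ndarray],
                    bin_method: str = "quantile", k: int = 5,
                    permutations: int = 999, seed: int = 0,
                    p_method: str = "permutation",
                    sample_step: int | None = None) -> DetectorResult:
    """Factor + interaction detection of driver grids against a response grid.

    All grids must be co-registered; pixels with any NaN are dropped.
    ``sample_step`` optionally thins pixels on a regular step (fishnet-like
    sampling) before computing, which is how large scenes stay tractable.
    """
    yg = np.asarray(y, dtype=float)
    if sample_step and sample_step > 1:
        sl = (slice(sample_step // 2, None, sample_step),) * 2
        yg = yg[sl]
        drivers = {n: np.asarray(g)[sl] for n, g in drivers.items()}
    flat_y = yg.ravel()
    valid = np.isfinite(flat_y)
    strat = {}
    for name, g in drivers.items():
        fg = np.asarray(g).ravel()
        if fg.shape != flat_y.shape:
            raise ValueError(f"driver {name!r} not co-registered")
        if np.asarray(g).dtype.kind == "f":
            valid &= np.isfinite(fg)
    yv = flat_y[valid]
    for name, g in drivers.items():
        strat[name] = discretize(np.asarray(g).ravel()[valid], bin_method, k)

    rows = []
    for name, s in strat.items():
        q, p = factor_q(yv, s, permutations, seed, p_method)
        rows.append({"factor": name, "q": q, "p": p,
                     "n_strata": int(np.unique(s).size)})
    factors = pd.DataFrame(rows)

    names = list(strat)
    qmat = pd.DataFrame(np.nan, index=names, columns=names)
    cmat = pd.DataFrame("", index=names, columns=names)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            res = interaction_q(yv, strat[names[a]], strat[names[b]])
            qmat.iloc[a, b] = qmat.iloc[b, a] = res["q12"]
            cmat.iloc[a, b] = cmat.iloc[b, a] = res["category"]
    return DetectorResult(factors, qmat, cmat)
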