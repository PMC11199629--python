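"""Remote Sensing Ecological Index (RSEI) construction.

Pipeline per year: mask water with MNDWI, min-max normalize the four
component indices (greenness NDVI, wetness TCW, dryness NDBSI, heat LST)
over the unmasked domain, take the first principal component of the 4x4
covariance of pixel vectors, rescale the PC1 score to [0, 1], and orient
it so that higher = ecologically better (if the NDVI and TCW loadings are
negative the score is flipped as 1 - PC1).  The final RSEI is classified
into five levels: poor [0, 0.2), fair [0.2, 0.4), moderate [0.4, 0.6),
good [0.6, 0.8), excellent [0.8, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RSEI_INDEX_ORDER = ("NDVI", "TCW", "NDBSI", "LST")
CLASS_LABELS = ("poor", "fair", "moderate", "good", "excellent")
CLASS_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RSEIResult:
    """One year's RSEI: PC1 loadings, variance share, grids, summary."""

    year: object
    loadings: np.ndarray          # unit vector in RSEI_INDEX_ORDER
    contribution_rate: float      # % variance explained by PC1
    sign_corrected: bool
    rsei: np.ndarray              # [0, 1] grid, NaN where masked
    classes: np.ndarray           # int codes into CLASS_LABELS, -1 = nodata
    mean_rsei: float


def water_mask(mndwi: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Boolean exclusion mask: True where MNDWI exceeds the water threshold."""
    m = np.asarray(mndwi, dtype=float)
    return np.isfinite(m) & (m > threshold)


def rescale01(grid: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Min-max normalization over valid, unmasked pixels.

    Raises on a constant grid (the normalization is undefined there).
    Masked/invalid pixels come back NaN.
    """
    g = np.asarray(grid, dtype=float).copy()
    if mask is not None:
        g[np.asarray(mask, dtype=bool)] = np.nan
    valid = np.isfinite(g)
    vals = g[valid]
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("rescale01 undefined for constant or near-empty grid")
    lo, hi = vals.min(), vals.max()
    out = np.full(g.shape, np.nan)
    out[valid] = (g[valid] - lo) / (hi - lo)
    return out


def pca_pc1(indices: dict[str, np.ndarray], mask: np.ndarray | None = None,
            standardize: str = "minmax"
            ) -> tuple[np.ndarray, float, np.ndarray]:
    """First principal component of the four normalized index grids.

    Returns ``(loadings, contribution_rate, score_grid)`` where loadings
    is the unit eigenvector (index order NDVI, TCW, NDBSI, LST) of the
    covariance matrix of unmasked pixel vectors with the largest
    eigenvalue, contribution_rate = 100 * lambda1 / sum(lambda), and the
    score grid is the centered projection.  ``standardize`` selects the
    pre-PCA normalization: "minmax" (default), "zscore", or "none"
    (grids used as given).
    """
    missing = [k for k in RSEI_INDEX_ORDER if k not in indices]
    if missing:
        raise KeyError(f"missing indices: {missing}")
    grids = []
    for k in RSEI_INDEX_ORDER:
        g = np.asarray(indices[k], dtype=float).copy()
        if mask is not None:
            g[np.asarray(mask, dtype=bool)] = np.nan
        if standardize == "minmax":
            g = rescale01(g)
        elif standardize == "zscore":
            mu, sd = np.nanmean(g), np.nanstd(g)
            if sd == 0:
                raise ValueError(f"zscore undefined for constant grid {k}")
            g = (g - mu) / sd
        grids.append(g)
    X = np.stack([g.ravel() for g in grids], axis=1)      # (P, 4)
    valid = np.isfinite(X).all(axis=1)
    n = int(valid.sum())
    if n < X.shape[1]:
        raise ValueError(f"only {n} valid pixels; need at least {X.shape[1]}")
    if n < 5:
        raise ValueError("need at least 5 unmasked pixels for a stable PC1")
    Xv = X[valid]
    mu = Xv.mean(axis=0)
    Xc = Xv - mu
    cov = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(cov)                    # ascending
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        warnings.warn("rank-deficient index covariance; PC1 still computed",
                      RuntimeWarning, stacklevel=2)
    loadings = evecs[:, -1]
    contribution = float(100.0 * evals[-1] / evals.sum())
    score = np.full(X.shape[0], np.nan)
    score[valid] = Xc @ loadings
    return loadings, contribution, score.reshape(grids[0].shape)


def sign_correct(loadings: np.ndarray, score: np.ndarray
                 ) -> tuple[np.ndarray, bool]:
    """Orient PC1 so higher = better; returns (RSEI_0 grid in [0,1], flipped?).

    The score is min-max rescaled to [0, 1] first; if the greenness and
    wetness loadings are both negative the oriented score is 1 - PC1.
    Mixed signs fall back to the sign of (NDVI + TCW - NDBSI - LST
    loadings) with a warning.
    """
    l_ndvi, l_tcw, l_ndbsi, l_lst = np.asarray(loadings, dtype=float)
    pc1 = rescale01(score)
    if l_ndvi == 0 or l_tcw == 0:
        warnings.warn("zero NDVI/TCW loading: orientation ambiguous",
                      RuntimeWarning, stacklevel=2)
    if l_ndvi > 0 and l_tcw > 0:
        flip = False
    elif l_ndvi < 0 and l_tcw < 0:
        flip = True
    else:
        direction = l_ndvi + l_tcw - l_ndbsi - l_lst
        flip = direction < 0
        warnings.warn("mixed-sign NDVI/TCW loadings; orientation resolved by "
                      "majority ecological direction", RuntimeWarning, stacklevel=2)
    return (1.0 - pc1, True) if flip else (pc1, False)


def classify(rsei: np.ndarray) -> np.ndarray:
    """Five-level classification; bins left-closed, top bin closed at 1.

    Returns int codes into :data:`CLASS_LABELS`; NaN pixels get -1.
    """
    g = np.asarray(rsei, dtype=float)
    valid = np.isfinite(g)
    if valid.any() and ((g[valid] < 0) | (g[valid] > 1)).any():
        raise ValueError("RSEI values must lie in [0, 1]")
    codes = np.full(g.shape, -1, dtype=np.int8)
    codes[valid] = np.clip(np.digitize(g[valid], CLASS_EDGES[1:-1], right=False),
                           0, len(CLASS_LABELS) - 1)
    return codes


def build_rsei(indices: dict[str, np.ndarray], mndwi: np.ndarray | None = None,
               water_threshold: float = 0.0, year: object = None,
               standardize: str = "minmax") -> RSEIResult:
    """Full single-year RSEI: mask, normalize, PCA, orient, rescale, classify."""
    mask = water_mask(mndwi, water_threshold) if mndwi is not None else None
    loadings, contribution, score = pca_pc1(indices, mask, standardize)
    rsei0, flipped = sign_correct(loadings, score)
    rsei = rescale01(rsei0)   # idempotent when rsei0 already spans [0, 1]
    return RSEIResult(year=year, loadings=loadings, contribution_rate=contribution,
                      sign_corrected=flipped, rsei=rsei, classes=classify(rsei),
                      mean_rsei=float(np.nanmean(rsei)))


def annual_summary(results: list[RSEIResult], decimals: int = 2) -> pd.DataFrame:
    """Per-year loadings / contribution / mean-RSEI table with a Mean row.

    The Mean row averages the yearly columns and is rounded half-even to
    ``decimals`` (as are the yearly rows in the returned table).
    """
    if not results:
        raise ValueError("no yearly results")
    rows = []
    for r in results:
        rows.append({"year": r.year,
                     "NDVI": r.loadings[0], "TCW": r.loadings[1],
                     "NDBSI": r.loadings[2], "LST": r.loadings[3],
                     "contribution_rate": r.contribution_rate,
                     "rsei_mean": r.mean_rsei})
    table = pd.DataFrame(rows)
    return summarize_annual_table(table, decimals=decimals)


def summarize_annual_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Append a Mean row (column averages, half-even rounded) to a yearly table."""
    numeric = [c for c in table.columns if c != "year"]
    mean_row = {"year": "Mean"}
    for c in numeric:
        mean_row[c] = np.round(pd.to_numeric(table[c]).mean(), decimals)
    out = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    out[numeric] = out[numeric].astype(float).round(decimals)
    return out


def difference_map(rsei_a: np.ndarray, rsei_b: np.ndarray,
                   band: float = 0.15) -> tuple[np.ndarray, dict]:
    """Per-pixel a - b plus the fraction of pixels inside +/- band."""
    a = np.asarray(rsei_a, dtype=float)
    b = np.asarray(rsei_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("grids must be co-registered")
    diff = a - b
    valid = np.isfinite(diff)
    n = int(valid.sum())
    within = float(np.mean(np.abs(diff[valid]) <= band)) if n else np.nan
    summary = {"band": band, "fraction_within": within, "n_valid": n,
               "mean_diff": float(np.nanmean(diff)) if n else np.nan}
    return diff, summary


def sample_table(rsei: np.ndarray, indices: dict[str, np.ndarray],
                 n_points: int, seed: int) -> pd.DataFrame:
    """Random unmasked-pixel sample of (row, col, four indices, RSEI).

    Sampling is uniform without replacement; if fewer unmasked pixels than
    requested exist, all of them are returned with a warning.
    """
    r = np.asarray(rsei, dtype=float)
    valid = np.isfinite(r)
    for k in RSEI_INDEX_ORDER:
        valid &= np.isfinite(np.asarray(indices[k], dtype=float))
    flat = np.flatnonzero(valid)
    if flat.size < n_points:
        warnings.warn(f"only {flat.size} unmasked pixels available "
                      f"(requested {n_points})", RuntimeWarning, stacklevel=2)
        n_points = flat.size
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n_points, replace=False)
    rows, cols = np.unravel_index(chosen, r.shape)
    data = {"row": rows, "col": cols}
    for k in RSEI_INDEX_ORDER:
        data[k] = np.asarray(indices[k], dtype=float)[rows, cols]
    data["RSEI"] = r[rows, cols]
    return pd.DataFrame(data)
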