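"""Spatial autocorrelation of ecological quality: fishnet sampling,
lattice spatial weights, global and local Moran's I, permutation
significance and LISA cluster classes.

The global statistic (default form) is

    I = (m / S0) * sum_ij W_ij z_i z_j / sum_i z_i^2,   z_i = D_i - Dbar

with S0 = sum_ij W_ij; an "as_printed" variant with the weight inside the
denominator (I = m * sum_ij W_ij z_i z_j / sum_ij W_ij z_i^2) is kept for
comparison with formulations that fold S0 into the denominator.  The
local statistic is I_i = z_i * sum_j W_ij z_j / sum_i z_i^2, with LISA
classes HH / LL / LH / HL assigned to points whose conditional-permutation
pseudo-p falls below alpha, and "not significant" otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LISA_LABELS = ("not significant", "HH", "LH", "LL", "HL")


def fishnet_sample(grid: np.ndarray, spacing: float, pixel_size: float = 1.0
                   ) -> pd.DataFrame:
    """Cell-centered regular lattice of sample points over a raster.

    ``spacing`` and ``pixel_size`` share units (e.g. meters); points fall
    at the centers of spacing x spacing cells and take the value of the
    underlying pixel.  Nodata points are dropped.  Returns columns
    ``id, i, j, row, col, x, y, value`` where (i, j) are lattice indices.
    """
    g = np.asarray(grid, dtype=float)
    if spacing < pixel_size:
        raise ValueError("spacing must be >= pixel size")
    step = int(round(spacing / pixel_size))
    if step > min(g.shape):
        raise ValueError("spacing exceeds raster extent")
    offs = step // 2
    rows = np.arange(offs, g.shape[0], step)
    cols = np.arange(offs, g.shape[1], step)
    jj, ii = np.meshgrid(np.arange(cols.size), np.arange(rows.size))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    table = pd.DataFrame({
        "i": ii.ravel(), "j": jj.ravel(),
        "row": rr.ravel(), "col": cc.ravel(),
        "x": (cc.ravel() + 0.5) * pixel_size,
        "y": (rr.ravel() + 0.5) * pixel_size,
        "value": g[rr.ravel(), cc.ravel()],
    })
    table = table[np.isfinite(table["value"])].reset_index(drop=True)
    table.insert(0, "id", np.arange(len(table)))
    return table


@dataclass
class SpatialWeights:
    """Sparse neighbor structure over sample points."""

    ids: np.ndarray
    neighbors: list                       # list of int arrays (positions)
    weights: list                         # list of float arrays
    scheme: str
    row_standardized: bool
    islands: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag sum_j W_ij x_j per point."""
        x = np.asarray(values, dtype=float)
        out = np.zeros(self.n)
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            out[i] = (w * x[nb]).sum() if nb.size else 0.0
        return out

    def to_dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            W[i, nb] = w
        return W


def build_weights(points: pd.DataFrame, scheme: str = "queen", k: int = 8,
                  row_standardize: bool = True) -> SpatialWeights:
    """Neighbor weights over fishnet points.

    ``queen``/``rook`` use the lattice indices (i, j) from
    :func:`fishnet_sample` (8- and 4-neighborhood respectively, binary
    before standardization, symmetric).  ``knn`` uses Euclidean (x, y)
    distance with deterministic tie-breaking by point id.  Islands
    (points with no neighbor) are flagged.
    """
    n = len(points)
    if n < 3:
        raise ValueError("need at least 3 points")
    neighbors: list[np.ndarray] = []
    weights: list[np.ndarray] = []

    if scheme in ("queen", "rook"):
        key = {(int(r.i), int(r.j)): pos for pos, r in enumerate(points.itertuples())}
        if scheme == "rook":
            moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        else:
            moves = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                     if (di, dj) != (0, 0)]
        for r in points.itertuples():
            nb = [key[(int(r.i) + di, int(r.j) + dj)] for di, dj in moves
                  if (int(r.i) + di, int(r.j) + dj) in key]
            nb = np.array(sorted(nb), dtype=int)
            neighbors.append(nb)
            weights.append(np.ones(nb.size))
    elif scheme == "knn":
        if k >= n:
            raise ValueError(f"k={k} must be < n={n}")
        xy = points[["x", "y"]].to_numpy(dtype=float)
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        order_ids = points["id"].to_numpy()
        for i in range(n):
            # sort by (distance, id) so exact distance ties are deterministic
            order = np.lexsort((order_ids, d2[i]))
            nb = np.sort(order[:k]).astype(int)
            neighbors.append(nb)
            weights.append(np.ones(nb.size))
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use queen, rook or knn")

    islands = np.array([i for i, nb in enumerate(neighbors) if nb.size == 0], dtype=int)
    if islands.size:
        warnings.warn(f"{islands.size} island point(s) with no neighbors",
                      RuntimeWarning, stacklevel=2)
    if row_standardize:
        weights = [w / w.sum() if w.size else w for w in weights]
    return SpatialWeights(points["id"].to_numpy(), neighbors, weights,
                          scheme, row_standardize, islands)


@dataclass
class MoranResult:
    I: float
    expected: float                      # -1/(n-1)
    p_sim: float
    n: int
    permutations: int
    local_I: np.ndarray | None = None
    quadrant: np.ndarray | None = None   # 1=HH 2=LH 3=LL 4=HL, 0 undefined
    p_local: np.ndarray | None = None
    lisa_class: np.ndarray | None = None


def _moran_value(z: np.ndarray, w: SpatialWeights, variant: str) -> float:
    num = float(z @ w.lag(z))
    if variant == "standard":
        return (w.n / w.s0) * num / float(z @ z)
    if variant == "as_printed":
        row_sums = w.lag(np.ones(w.n))
        denom = float(row_sums @ (z * z))
        return w.n * num / denom if denom != 0 else np.nan
    raise ValueError(f"unknown variant {variant!r}")


def global_moran(values: np.ndarray, weights: SpatialWeights,
                 variant: str = "standard", permutations: int = 999,
                 seed: int = 0, alternative: str = "greater") -> MoranResult:
    """Global Moran's I with permutation pseudo-p.

    ``alternative="greater"`` (default) tests for positive spatial
    autocorrelation, the usual question for clustered quality surfaces;
    "less" tests the dispersion side.  The pseudo-p under "greater" is
    uniform on the null, which the calibration tests rely on.
    """
    x = np.asarray(values, dtype=float)
    if x.size != weights.n:
        raise ValueError("values / weights size mismatch")
    z = x - x.mean()
    if (z == 0).all():
        return MoranResult(np.nan, -1.0 / (x.size - 1), np.nan, x.size, 0)
    obs = _moran_value(z, weights, variant)
    expected = -1.0 / (x.size - 1)
    p_sim = np.nan
    if permutations:
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for s in range(permutations):
            zp = rng.permutation(z)
            sims[s] = _moran_value(zp, weights, variant)
        if alternative == "greater":
            extreme = int((sims >= obs).sum())
        elif alternative == "less":
            extreme = int((sims <= obs).sum())
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
        p_sim = (extreme + 1) / (permutations + 1)
    return MoranResult(float(obs), expected, float(p_sim), x.size, permutations)


def local_moran(values: np.ndarray, weights: SpatialWeights
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point local Moran I_i and scatterplot quadrant codes.

    Quadrants follow the Moran scatter convention on (z_i, lag_i):
    1 = HH, 2 = LH, 3 = LL, 4 = HL; 0 where z or lag is exactly zero.
    """
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("zero variance: local Moran undefined")
    lag = weights.lag(z)
    local = z * lag / ss
    quad = np.zeros(x.size, dtype=np.int8)
    quad[(z > 0) & (lag > 0)] = 1
    quad[(z < 0) & (lag > 0)] = 2
    quad[(z < 0) & (lag < 0)] = 3
    quad[(z > 0) & (lag < 0)] = 4
    return local, quad


def lisa_classify(values: np.ndarray, weights: SpatialWeights,
                  n_permutations: int = 999, alpha: float = 0.05,
                  seed: int = 0) -> MoranResult:
    """Local Moran with conditional-permutation significance and LISA classes.

    For each point its own value is held fixed and neighbor values are
    drawn from the remaining points; the pseudo-p is the two-sided
    2 * (min(#above, #below) + 1) / (n_permutations + 1), capped at 1, so
    the significance rate under an i.i.d. null stays near alpha.  Points
    with pseudo-p < alpha are labelled by quadrant, the rest "not
    significant".
    """
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations gives coarse pseudo-p",
                      RuntimeWarning, stacklevel=2)
    x = np.asarray(values, dtype=float)
    n = x.size
    z = x - x.mean()
    ss = float(z @ z)
    local, quad = local_moran(x, weights)

    rng = np.random.default_rng(seed)
    max_k = max((nb.size for nb in weights.neighbors), default=0)
    # shared permutation table: each row a draw without replacement from the
    # n-1 "other" positions (classic conditional-randomization shortcut)
    rids = np.empty((n_permutations, max_k), dtype=int)
    for s in range(n_permutations):
        rids[s] = rng.permutation(n - 1)[:max_k]

    p_local = np.full(n, np.nan)
    idx_all = np.arange(n)
    for i in range(n):
        nb = weights.neighbors[i]
        if nb.size == 0:
            continue
        others = z[idx_all != i]
        draws = others[rids[:, :nb.size]]                 # (perm, k)
        lag_sim = draws @ weights.weights[i]
        sim = z[i] * lag_sim / ss
        above = int((sim >= local[i]).sum())
        tail = min(above, n_permutations - above)
        p_local[i] = min(1.0, 2.0 * (tail + 1) / (n_permutations + 1))

    classes = np.zeros(n, dtype=np.int8)                  # 0 = not significant
    sig = np.isfinite(p_local) & (p_local < alpha)
    classes[sig] = quad[sig]
    glob = global_moran(x, weights, permutations=n_permutations, seed=seed)
    return MoranResult(glob.I, glob.expected, glob.p_sim, n, n_permutations,
                       local_I=local, quadrant=quad, p_local=p_local,
                       lisa_class=classes)


def lisa_table(points: pd.DataFrame, result: MoranResult) -> pd.DataFrame:
    """Per-point LISA CSV table (id, x, y, value, local I, quadrant, p, class)."""
    out = points[["id", "x", "y", "value"]].copy()
    out["local_I"] = result.local_I
    out["quadrant"] = result.quadrant
    out["p_sim"] = result.p_local
    out["lisa_class"] = [LISA_LABELS[c] for c in result.lisa_class]
    return out
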