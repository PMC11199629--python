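"""Harmonic Analysis of Time Series (HANTS).

Least-squares fit of a mean level plus ``nf`` sine/cosine pairs at
frequencies ``i / base_period`` to an irregular, gappy series:

    y~(t) = a0 + sum_i [ a_i cos(2 pi f_i t) + b_i sin(2 pi f_i t) ]

The default is the plain (unweighted) least-squares solution; classical
one-sided outlier suppression (iteratively dropping points that deviate
beyond a tolerance above/below the current fit, as used to reject
cloud-contaminated observations) is available via ``outlier_mode``.

Accuracy statistics (Pearson R, STD of the reconstruction, RMSE between
original and reconstruction) and the nf = 1..10 frequency sweep used to
populate a Taylor diagram live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterStack


@dataclass
class HANTSParams:
    """Fit configuration.

    ``base_period`` is in the series' time units (1.0 = annual cycle for a
    fractional-year axis).  A pixel needs at least ``2*nf + 1`` valid
    samples to be fittable.
    """

    nf: int = 1
    base_period: float = 1.0
    outlier_mode: str = "none"        # none | high | low | both
    max_iterations: int = 20
    fit_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.nf < 1:
            raise ValueError("nf must be >= 1")
        if self.base_period <= 0:
            raise ValueError("base_period must be positive")
        if self.outlier_mode not in ("none", "high", "low", "both"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")

    @property
    def n_coeffs(self) -> int:
        return 2 * self.nf + 1

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(1, self.nf + 1) / self.base_period


@dataclass
class HANTSFit:
    """Per-series harmonic coefficients and residuals."""

    a0: float
    a: np.ndarray                     # (nf,) cosine coefficients
    b: np.ndarray                     # (nf,) sine coefficients
    params: HANTSParams
    valid_count: int
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def is_valid(self) -> bool:
        return np.isfinite(self.a0)


def design_matrix(times: np.ndarray, params: HANTSParams) -> np.ndarray:
    """Columns [1, cos(2 pi f_i t), sin(2 pi f_i t)] for i = 1..nf."""
    t = np.asarray(times, dtype=float)
    cols = [np.ones_like(t)]
    for f in params.frequencies:
        cols.append(np.cos(2 * np.pi * f * t))
        cols.append(np.sin(2 * np.pi * f * t))
    return np.column_stack(cols)


def _invalid_fit(params: HANTSParams, times: np.ndarray, n_valid: int) -> HANTSFit:
    return HANTSFit(np.nan, np.full(params.nf, np.nan), np.full(params.nf, np.nan),
                    params, n_valid, np.asarray(times, dtype=float),
                    np.full(np.asarray(times).size, np.nan))


def fit_harmonics(values: np.ndarray, times: np.ndarray, params: HANTSParams,
                  valid: np.ndarray | None = None) -> HANTSFit:
    """Fit one series; NaNs (or ``valid=False``) are treated as missing.

    A series with fewer than ``2*nf + 1`` usable samples is returned as an
    invalid (all-NaN) fit rather than raising, so stack application can
    propagate nodata.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have the same length")
    use = np.isfinite(y)
    if valid is not None:
        use = use & np.asarray(valid, dtype=bool)
    if use.sum() < params.n_coeffs:
        return _invalid_fit(params, t, int(use.sum()))

    A_full = design_matrix(t, params)
    for _ in range(max(1, params.max_iterations if params.outlier_mode != "none" else 1)):
        coef, *_ = np.linalg.lstsq(A_full[use], y[use], rcond=None)
        fitted = A_full @ coef
        resid = y - fitted
        if params.outlier_mode == "none":
            break
        drop = np.zeros_like(use)
        if params.outlier_mode in ("high", "both"):
            drop |= use & (resid > params.fit_tolerance)
        if params.outlier_mode in ("low", "both"):
            drop |= use & (resid < -params.fit_tolerance)
        if not drop.any() or (use & ~drop).sum() < params.n_coeffs:
            break
        use = use & ~drop

    residuals = np.where(use, y - A_full @ coef, np.nan)
    return HANTSFit(float(coef[0]), coef[1::2].copy(), coef[2::2].copy(),
                    params, int(use.sum()), t, residuals)


def reconstruct(fit: HANTSFit, times: np.ndarray) -> np.ndarray:
    """Evaluate the harmonic sum at arbitrary times (gap filling included)."""
    t = np.asarray(times, dtype=float)
    if not fit.is_valid:
        return np.full(t.shape, np.nan)
    out = np.full(t.shape, fit.a0, dtype=float)
    for f, ai, bi in zip(fit.params.frequencies, fit.a, fit.b):
        out += ai * np.cos(2 * np.pi * f * t) + bi * np.sin(2 * np.pi * f * t)
    return out


def fit_stack(stack: RasterStack, params: HANTSParams,
              out_times: np.ndarray | None = None
              ) -> tuple[RasterStack, dict[str, np.ndarray]]:
    """Per-pixel HANTS over a stack, vectorized via batched normal equations.

    Returns the reconstructed stack (at ``out_times``, default the original
    timestamps) and coefficient grids ``{"a0", "a", "b", "valid_count"}``.
    Pixels with fewer than ``2*nf + 1`` valid samples are nodata throughout.

    Outlier suppression, when requested, falls back to the per-pixel path.
    """
    T, R, C = stack.shape
    if T < params.n_coeffs:
        raise ValueError(f"stack has {T} layers; nf={params.nf} needs >= {params.n_coeffs}")
    times = stack.times
    tout = times if out_times is None else np.asarray(out_times, dtype=float)

    if params.outlier_mode != "none":
        return _fit_stack_loop(stack, params, tout)

    A = design_matrix(times, params)                      # (T, K)
    y = stack.values.reshape(T, -1)                       # (T, P)
    w = np.isfinite(y)
    yz = np.where(w, y, 0.0)
    wf = w.astype(float)
    # batched A^T W A and A^T W y
    G = np.einsum("ti,tp,tj->pij", A, wf, A, optimize=True)
    rhs = np.einsum("ti,tp->pi", A, yz, optimize=True)

    fittable = w.sum(axis=0) >= params.n_coeffs
    K = params.n_coeffs
    coef = np.full((y.shape[1], K), np.nan)
    if fittable.any():
        Gf, rf = G[fittable], rhs[fittable]
        # guard rank-deficient designs (all samples coincident in phase)
        ok = np.linalg.matrix_rank(Gf) == K
        sol = np.full_like(rf, np.nan)
        if ok.all():
            sol = np.linalg.solve(Gf, rf[..., None])[..., 0]
        else:
            if ok.any():
                sol[ok] = np.linalg.solve(Gf[ok], rf[ok][..., None])[..., 0]
            for i in np.where(~ok)[0]:
                sol[i] = np.linalg.lstsq(Gf[i], rf[i], rcond=None)[0]
        coef[fittable] = sol

    Aout = design_matrix(tout, params)                    # (To, K)
    recon = (Aout @ coef.T).reshape(len(tout), R, C)
    grids = {
        "a0": coef[:, 0].reshape(R, C),
        "a": coef[:, 1::2].T.reshape(params.nf, R, C),
        "b": coef[:, 2::2].T.reshape(params.nf, R, C),
        "valid_count": w.sum(axis=0).reshape(R, C),
    }
    return RasterStack(recon, tout, stack.name, dict(stack.meta)), grids


def _fit_stack_loop(stack: RasterStack, params: HANTSParams, tout: np.ndarray):
    T, R, C = stack.shape
    coef_a0 = np.full((R, C), np.nan)
    coef_a = np.full((params.nf, R, C), np.nan)
    coef_b = np.full((params.nf, R, C), np.nan)
    counts = np.zeros((R, C), dtype=int)
    recon = np.full((len(tout), R, C), np.nan)
    for r in range(R):
        for c in range(C):
            fit = fit_harmonics(stack.values[:, r, c], stack.times, params)
            counts[r, c] = fit.valid_count
            if fit.is_valid:
                coef_a0[r, c] = fit.a0
                coef_a[:, r, c] = fit.a
                coef_b[:, r, c] = fit.b
                recon[:, r, c] = reconstruct(fit, tout)
    grids = {"a0": coef_a0, "a": coef_a, "b": coef_b, "valid_count": counts}
    return RasterStack(recon, tout, stack.name, dict(stack.meta)), grids


@dataclass
class FitQuality:
    """Taylor-diagram statistics for one original/reconstructed pair."""

    R: float      # Pearson correlation (NaN if undefined)
    STD: float    # population standard deviation of the reconstruction
    RMSE: float   # root mean squared pairwise difference


def evaluate(original: np.ndarray, reconstructed: np.ndarray) -> FitQuality:
    """R / STD / RMSE over jointly valid samples.

    R is the standard Pearson correlation; RMSE is the root mean squared
    pairwise difference.  With fewer than two joint samples or zero
    variance on either side, R is NaN while RMSE is still reported.
    """
    o = np.asarray(original, dtype=float).ravel()
    d = np.asarray(reconstructed, dtype=float).ravel()
    if o.shape != d.shape:
        raise ValueError("series lengths differ")
    use = np.isfinite(o) & np.isfinite(d)
    o, d = o[use], d[use]
    if o.size == 0:
        return FitQuality(np.nan, np.nan, np.nan)
    rmse = float(np.sqrt(np.mean((o - d) ** 2)))
    std = float(np.std(d))
    if o.size < 2 or np.std(o) == 0 or std == 0:
        return FitQuality(np.nan, std, rmse)
    r = float(np.corrcoef(o, d)[0, 1])
    return FitQuality(r, std, rmse)


def evaluate_stack(original: RasterStack, reconstructed: RasterStack
                   ) -> tuple[float, float, float]:
    """Pixel-mean (R, STD, RMSE) between two co-registered stacks."""
    o = original.values.reshape(original.n_layers, -1)
    d = reconstructed.values.reshape(reconstructed.n_layers, -1)
    use = np.isfinite(o) & np.isfinite(d)
    n = use.sum(axis=0)
    oz = np.where(use, o, 0.0)
    dz = np.where(use, d, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        om = oz.sum(axis=0) / n
        dm = dz.sum(axis=0) / n
        oc = np.where(use, o - om, 0.0)
        dc = np.where(use, d - dm, 0.0)
        cov = (oc * dc).sum(axis=0) / n
        so = np.sqrt((oc**2).sum(axis=0) / n)
        sd = np.sqrt((dc**2).sum(axis=0) / n)
        r = cov / (so * sd)
        rmse = np.sqrt(((oz - dz) ** 2 * use).sum(axis=0) / n)
    good = n >= 2
    return (float(np.nanmean(np.where(good & (so > 0) & (sd > 0), r, np.nan))),
            float(np.nanmean(np.where(good, sd, np.nan))),
            float(np.nanmean(np.where(n >= 1, rmse, np.nan))))


def frequency_sweep(stack: RasterStack, nf_values=range(1, 11),
                    base_period: float = 1.0,
                    out_csv: str | Path | None = None) -> pd.DataFrame:
    """Refit the stack at each nf and tabulate mean R / STD / RMSE.

    The resulting table is Taylor-diagram-ready (one row per nf).
    """
    rows = []
    for nf in nf_values:
        params = HANTSParams(nf=nf, base_period=base_period)
        if stack.n_layers < params.n_coeffs:
            rows.append({"nf": nf, "R": np.nan, "STD": np.nan, "RMSE": np.nan})
            continue
        recon, _ = fit_stack(stack, params)
        r, std, rmse = evaluate_stack(stack, recon)
        rows.append({"nf": nf, "R": r, "STD": std, "RMSE": rmse})
    table = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False)
    return table
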