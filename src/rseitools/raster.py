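"""Raster containers and TIFF-based I/O.

A :class:`RasterStack` is the package's in-memory unit for one index or
band observed at several dates: a ``(time, row, col)`` float array with
NaN as nodata, a per-layer time axis in fractional years, and a free-form
georeferencing/metadata dict.  Stacks are written as multi-page TIFF with
a CSV sidecar of layer timestamps so everything round-trips in plain,
inspectable formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class RasterStack:
    """Time-stacked single-variable raster.

    Parameters
    ----------
    values
        Array of shape ``(n_times, n_rows, n_cols)``; NaN marks nodata.
    times
        Observation times in fractional years (e.g. ``2000.45``), one per
        layer, strictly increasing is not required but conventional.
    name
        Variable name (``"NDVI"``, ``"LST"``, ...).
    meta
        Georeferencing and provenance tags (pixel size, origin, CRS name).
    """

    values: np.ndarray
    times: np.ndarray
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, row, col)")
        if self.times.shape != (self.values.shape[0],):
            raise ValueError("times must have one entry per layer")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def select(self, t_min: float, t_max: float) -> "RasterStack":
        """Sub-stack of layers with time in ``[t_min, t_max]``."""
        keep = (self.times >= t_min) & (self.times <= t_max)
        if not keep.any():
            raise ValueError(f"no layers in window [{t_min}, {t_max}]")
        return RasterStack(self.values[keep], self.times[keep], self.name, dict(self.meta))

    def copy(self) -> "RasterStack":
        return RasterStack(self.values.copy(), self.times.copy(), self.name, dict(self.meta))


def write_stack(stack: RasterStack, path: str | Path) -> None:
    """Write a stack as multi-page float32 TIFF + ``<path>.dates.csv`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.values.astype(np.float32))
    pd.DataFrame({"layer": np.arange(stack.n_layers), "time": stack.times}).to_csv(
        path.with_suffix(path.suffix + ".dates.csv"), index=False
    )
    if stack.meta or stack.name:
        sidecar = {"name": stack.name, "meta": stack.meta}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> RasterStack:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    if values.ndim == 2:
        values = values[None]
    dates = pd.read_csv(path.with_suffix(path.suffix + ".dates.csv"))
    name, meta = "", {}
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        sidecar = json.loads(meta_path.read_text())
        name, meta = sidecar.get("name", ""), sidecar.get("meta", {})
    return RasterStack(values, dates["time"].to_numpy(), name, meta)


def write_grid(grid: np.ndarray, path: str | Path) -> None:
    """Write a single 2-D grid as float32 TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))


def read_grid(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)
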