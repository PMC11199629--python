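"""Component ecological indices from surface-reflectance bands.

Greenness (NDVI), wetness (tasseled-cap wetness, TCW), dryness (NDBSI =
mean of a bare-soil index SI and the index-based built-up index IBI) and
the water index MNDWI, plus growing-season median compositing.  LST is
consumed as a data product (thermal band inversion is out of scope) and
only unit-normalized here.

All normalized-difference ratios return NaN where the denominator is zero
or an input is NaN; reflectance convention is 0--1 float internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .raster import RasterStack

#: Tasseled-cap wetness coefficients, keyed by sensor, band order
#: (blue, green, red, nir, swir1, swir2).  Transcribed from the standard
#: reflectance-based derivations for each sensor generation (Crist-style for
#: TM, the ETM+ at-satellite reflectance set, and the OLI set); the table is
#: editable/injectable so correctness never rests on the transcription.
TCW_COEFFICIENTS: dict[str, tuple[float, ...]] = {
    "TM":   (0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109),
    "ETM+": (0.2626, 0.2141, 0.0926, 0.0656, -0.7629, -0.5388),
    "OLI":  (0.1511, 0.1973, 0.3283, 0.3407, -0.7117, -0.4559),
}


def load_tcw_coefficients(path: str | Path) -> dict[str, tuple[float, ...]]:
    """Read a sensor-keyed wetness coefficient table from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for sensor, coeffs in raw.items():
        coeffs = tuple(float(c) for c in coeffs)
        if len(coeffs) != 6:
            raise ValueError(f"sensor {sensor}: expected 6 coefficients, got {len(coeffs)}")
        out[sensor] = coeffs
    return out


@dataclass
class BandSet:
    """Co-registered six-band reflectance set plus LST for one composite date."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir1: np.ndarray
    swir2: np.ndarray
    lst: np.ndarray | None = None
    sensor: str = "OLI"
    lst_unit: str = "K"
    reflectance_scale: float = 1.0   # divide raw bands by this (10000 for integer SR)

    def __post_init__(self) -> None:
        names = ["blue", "green", "red", "nir", "swir1", "swir2"]
        arrs = [np.asarray(getattr(self, n), dtype=float) for n in names]
        shape = arrs[0].shape
        for n, a in zip(names, arrs):
            if a.shape != shape:
                raise ValueError(f"band {n} shape {a.shape} != {shape}")
            setattr(self, n, a / self.reflectance_scale if self.reflectance_scale != 1.0 else a)
        if self.lst is not None:
            self.lst = np.asarray(self.lst, dtype=float)
            if self.lst.shape != shape:
                raise ValueError("lst shape mismatch")
            if self.lst_unit.upper().startswith("C"):
                self.lst = self.lst + 273.15
                self.lst_unit = "K"

    @property
    def reflectance_bands(self) -> tuple[np.ndarray, ...]:
        return (self.blue, self.green, self.red, self.nir, self.swir1, self.swir2)


def _norm_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return out


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """(NIR − red) / (NIR + red)."""
    return _norm_diff(nir, red)


def mndwi(green: np.ndarray, swir1: np.ndarray) -> np.ndarray:
    """(green − SWIR1) / (green + SWIR1); positive over open water."""
    return _norm_diff(green, swir1)


def tcw(bands: BandSet, coefficients: dict | None = None) -> np.ndarray:
    """Tasseled-cap wetness: sensor-specific linear combination of six bands."""
    table = TCW_COEFFICIENTS if coefficients is None else coefficients
    if bands.sensor not in table:
        raise KeyError(f"no wetness coefficients for sensor {bands.sensor!r}; "
                       f"known: {sorted(table)}")
    c = table[bands.sensor]
    out = np.zeros_like(bands.blue)
    for ci, band in zip(c, bands.reflectance_bands):
        out = out + ci * band
    return out


def soil_index(bands: BandSet) -> np.ndarray:
    """Bare-soil index SI = [(swir1+red) − (nir+blue)] / [(swir1+red) + (nir+blue)]."""
    return _norm_diff(bands.swir1 + bands.red, bands.nir + bands.blue)


def built_up_index(bands: BandSet) -> np.ndarray:
    """Index-based built-up index (IBI) in its ratio form.

    IBI = (A − B) / (A + B) with the built-up term
    A = 2*swir1/(swir1 + nir) and the vegetation/water term
    B = nir/(nir + red) + green/(green + swir1).  Positive over built or
    bare surfaces, negative over vegetation and water; the ratio terms
    (rather than signed normalized differences) keep the denominator
    positive over reflective surfaces.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(bands.swir1 + bands.nir != 0,
                     2 * bands.swir1 / (bands.swir1 + bands.nir), np.nan)
        b = (np.where(bands.nir + bands.red != 0,
                      bands.nir / (bands.nir + bands.red), np.nan)
             + np.where(bands.green + bands.swir1 != 0,
                        bands.green / (bands.green + bands.swir1), np.nan))
    return _norm_diff(a, b)


def ndbsi(bands: BandSet) -> np.ndarray:
    """Dryness component: (SI + IBI) / 2."""
    return (soil_index(bands) + built_up_index(bands)) / 2.0


def median_composite(stack: RasterStack, window: tuple[float, float] | None = None
                     ) -> np.ndarray:
    """Per-pixel median of valid observations inside a time window.

    ``window`` is an inclusive ``(t_min, t_max)`` pair in the stack's time
    units; ``None`` uses every layer.  Pixels with no valid observation in
    the window come back NaN.
    """
    sub = stack if window is None else stack.select(*window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        return np.nanmedian(sub.values, axis=0)
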