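"""Synthetic Landsat-like scene generator with known ground truth.

Emulates the data regime of a growing-season (May--October) ecological
quality study: per-land-cover seasonal harmonic dynamics of the four
ecological indices (NDVI, TCW, NDBSI, LST) plus MNDWI for water masking,
cloud-induced missing observations, additive sensor noise, interannual
linear trends with optional planted breakpoint years, a spatially
autocorrelated quality surface, and driver rasters with configurable
monotone effects on that surface.

Every downstream stage (HANTS fitting, RSEI construction, Sen+MK trends,
Moran/LISA, geodetector, land-cover transitions) is testable against the
stored :class:`GroundTruth` without any external download.

All randomness flows from ``SceneConfig.seed`` through named substreams;
identical configs produce bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .raster import RasterStack

INDEX_NAMES = ("NDVI", "TCW", "NDBSI", "LST")
CLASS_NAMES = ("forest", "cropland", "grassland", "shrub", "impervious", "water")

DAYS_PER_YEAR = 365.0
SEASON_START_DOY = 121.0   # May 1
SEASON_END_DOY = 304.0     # Oct 31

# substream tags (fixed; keyed with the user seed)
_STREAMS = {"landcover": 11, "quality": 13, "noise": 17, "gaps": 19, "drivers": 23}


def _default_class_harmonics() -> dict:
    # (mean level, seasonal amplitude, phase in days-of-year at peak)
    # Levels are field-plausible growing-season values; LST in Kelvin.
    return {
        "forest":     {"NDVI": (0.75, 0.10, 200), "TCW": (0.10, 0.05, 200),
                       "NDBSI": (-0.35, 0.05, 200), "LST": (293.0, 4.0, 200),
                       "MNDWI": (-0.40, 0.02, 200)},
        "cropland":   {"NDVI": (0.55, 0.20, 210), "TCW": (0.00, 0.05, 210),
                       "NDBSI": (-0.10, 0.08, 210), "LST": (297.0, 5.0, 200),
                       "MNDWI": (-0.30, 0.02, 200)},
        "grassland":  {"NDVI": (0.45, 0.15, 205), "TCW": (-0.05, 0.04, 205),
                       "NDBSI": (-0.05, 0.06, 205), "LST": (296.0, 5.0, 200),
                       "MNDWI": (-0.30, 0.02, 200)},
        "shrub":      {"NDVI": (0.55, 0.12, 205), "TCW": (0.00, 0.04, 205),
                       "NDBSI": (-0.15, 0.05, 205), "LST": (295.0, 4.0, 200),
                       "MNDWI": (-0.35, 0.02, 200)},
        "impervious": {"NDVI": (0.15, 0.03, 200), "TCW": (-0.20, 0.02, 200),
                       "NDBSI": (0.35, 0.03, 200), "LST": (302.0, 5.0, 200),
                       "MNDWI": (-0.20, 0.01, 200)},
        "water":      {"NDVI": (0.05, 0.02, 200), "TCW": (0.45, 0.02, 200),
                       "NDBSI": (-0.45, 0.02, 200), "LST": (291.0, 2.0, 200),
                       "MNDWI": (0.50, 0.02, 200)},
    }


def _default_noise_sd() -> dict:
    # Matched to the accuracy regime of Landsat SR index series: wetness and
    # dryness composites are very clean (<0.01), greenness noisier, LST ~1.5 K.
    return {"NDVI": 0.03, "TCW": 0.008, "NDBSI": 0.008, "LST": 1.5, "MNDWI": 0.01}


def _default_spatial_sd() -> dict:
    # magnitude of the smooth within-class quality modulation per index
    return {"NDVI": 0.05, "TCW": 0.02, "NDBSI": -0.04, "LST": -1.0, "MNDWI": 0.0}


@dataclass
class SceneConfig:
    """Parameters of a synthetic growing-season scene.

    ``class_fractions`` must sum to 1; ``gap_fraction`` is the i.i.d.
    probability that a (pixel, time) sample is cloud-masked.  Trends are
    per-year slopes applied per class and index; ``breakpoint_years``
    plants piecewise slope changes (``breakpoint_slope_deltas`` adds the
    listed delta to every class's slope after each break).
    """

    grid_shape: tuple[int, int] = (64, 64)
    n_years: int = 21
    obs_per_season: int = 12
    class_fractions: dict = field(default_factory=lambda: {
        "forest": 0.50, "cropland": 0.20, "grassland": 0.10,
        "shrub": 0.08, "impervious": 0.05, "water": 0.07})
    class_harmonics: dict = field(default_factory=_default_class_harmonics)
    trend_slopes: dict = field(default_factory=dict)   # class -> {index: slope/yr}
    breakpoint_years: list = field(default_factory=list)
    breakpoint_slope_deltas: dict = field(default_factory=dict)  # index -> [delta per break]
    noise_sd: dict = field(default_factory=_default_noise_sd)
    spatial_sd: dict = field(default_factory=_default_spatial_sd)
    gap_fraction: float = 0.3
    gap_mode: str = "iid"          # "iid" or "blob"
    spatial_corr_length: float = 8.0
    driver_effects: dict = field(default_factory=lambda: {
        "temperature": -0.4, "precipitation": 0.3, "slope": 0.3,
        "aspect": 0.0, "altitude": 0.6})
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.class_fractions
        if any(v < 0 or v > 1 for v in fracs.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")
        if self.obs_per_season < 3:
            raise ValueError("need at least 3 observations per season")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])

    def observation_times(self) -> np.ndarray:
        """Fractional-year timestamps: obs_per_season per May--October window."""
        doy = np.linspace(SEASON_START_DOY, SEASON_END_DOY, self.obs_per_season)
        years = np.arange(self.n_years)
        return (years[:, None] + doy[None, :] / DAYS_PER_YEAR).ravel()


@dataclass
class GroundTruth:
    """Noise-independent truth for a generated scene."""

    landcover: np.ndarray                  # (R, C) int codes into class_names
    class_names: tuple
    quality: np.ndarray                    # standardized smooth quality surface
    harmonics: dict                        # index -> {mean, amplitude, phase_rad} grids
    slopes: dict                           # index -> (R, C) per-year slope grid
    breakpoint_years: list
    driver_effects: dict

    def class_grid(self, name: str) -> np.ndarray:
        return self.landcover == self.class_names.index(name)


def _smooth_field(shape, corr_length, rng) -> np.ndarray:
    """Standardized Gaussian random field with ~corr_length correlation."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_length, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landcover(cfg: SceneConfig) -> np.ndarray:
    """Spatially contiguous land-cover patches honouring class fractions.

    A smoothed random field is thresholded at the cumulative class-fraction
    quantiles, which yields contiguous patches whose realized fractions are
    exact up to quantile resolution.
    """
    rng = cfg.rng("landcover")
    f = _smooth_field(cfg.grid_shape, cfg.spatial_corr_length, rng)
    classes = [c for c in CLASS_NAMES if cfg.class_fractions.get(c, 0.0) > 0]
    fractions = np.array([cfg.class_fractions[c] for c in classes])
    edges = np.quantile(f, np.cumsum(fractions)[:-1]) if len(classes) > 1 else []
    codes = np.digitize(f, edges)
    out = np.zeros(cfg.grid_shape, dtype=np.int16)
    for k, c in enumerate(classes):
        out[codes == k] = CLASS_NAMES.index(c)
    return out


def _truth_from_landcover(cfg: SceneConfig, landcover: np.ndarray) -> GroundTruth:
    quality = _smooth_field(cfg.grid_shape, cfg.spatial_corr_length, cfg.rng("quality"))
    harmonics: dict = {}
    slopes: dict = {}
    indices = list(INDEX_NAMES) + ["MNDWI"]
    for idx in indices:
        mean = np.zeros(cfg.grid_shape)
        amp = np.zeros(cfg.grid_shape)
        phase = np.zeros(cfg.grid_shape)
        slope = np.zeros(cfg.grid_shape)
        for c in CLASS_NAMES:
            sel = landcover == CLASS_NAMES.index(c)
            if not sel.any():
                continue
            m, a, p_days = cfg.class_harmonics[c][idx]
            mean[sel] = m
            amp[sel] = a
            phase[sel] = 2 * np.pi * p_days / DAYS_PER_YEAR
            slope[sel] = cfg.trend_slopes.get(c, {}).get(idx, 0.0)
        mean = mean + cfg.spatial_sd.get(idx, 0.0) * quality
        harmonics[idx] = {"mean": mean, "amplitude": amp, "phase_rad": phase}
        slopes[idx] = slope
    return GroundTruth(landcover, CLASS_NAMES, quality, harmonics, slopes,
                       list(cfg.breakpoint_years), dict(cfg.driver_effects))


def _trend_offset(cfg: SceneConfig, idx: str, years: np.ndarray,
                  base_slope: np.ndarray) -> np.ndarray:
    """Piecewise-linear interannual offset, shape (n_times, R, C).

    ``years`` is the fractional-year time of each sample; the base slope
    applies from year 0, and after each planted breakpoint the per-index
    slope delta is added on top (hinge terms).
    """
    t = years[:, None, None]
    offset = t * base_slope[None]
    deltas = cfg.breakpoint_slope_deltas.get(idx, [])
    for by, d in zip(cfg.breakpoint_years, deltas):
        offset = offset + d * np.clip(t - by, 0.0, None)
    return offset


def true_series(truth: GroundTruth, cfg: SceneConfig, idx: str,
                times: np.ndarray) -> np.ndarray:
    """Noise-free signal for one index at the given times, (T, R, C)."""
    h = truth.harmonics[idx]
    t = np.asarray(times)[:, None, None]
    signal = h["mean"][None] + h["amplitude"][None] * np.cos(
        2 * np.pi * t - h["phase_rad"][None])
    signal = signal + _trend_offset(cfg, idx, np.asarray(times), truth.slopes[idx])
    if idx != "LST":
        signal = np.clip(signal, -1.0, 1.0)
    return signal


def generate_index_stacks(cfg: SceneConfig, truth: GroundTruth,
                          indices: tuple = INDEX_NAMES + ("MNDWI",),
                          ) -> dict[str, RasterStack]:
    """Noisy, gappy index stacks following the harmonic + trend signal model."""
    times = cfg.observation_times()
    noise_rng = cfg.rng("noise")
    gap_rng = cfg.rng("gaps")
    shape = (times.size,) + tuple(cfg.grid_shape)

    if cfg.gap_fraction > 0:
        if cfg.gap_mode == "blob":
            gaps = np.empty(shape, dtype=bool)
            for k in range(times.size):
                f = _smooth_field(cfg.grid_shape, cfg.spatial_corr_length, gap_rng)
                gaps[k] = f > np.quantile(f, 1.0 - cfg.gap_fraction)
        else:
            gaps = gap_rng.random(shape) < cfg.gap_fraction
    else:
        gaps = np.zeros(shape, dtype=bool)

    stacks = {}
    for idx in indices:
        signal = true_series(truth, cfg, idx, times)
        sd = cfg.noise_sd.get(idx, 0.0)
        if sd > 0:
            signal = signal + sd * noise_rng.standard_normal(shape)
            if idx != "LST":
                signal = np.clip(signal, -1.0, 1.0)
        values = signal.astype(float)
        values[gaps] = np.nan
        stacks[idx] = RasterStack(values, times, name=idx,
                                  meta={"pixel_size_m": 30.0, "origin": [0.0, 0.0],
                                        "crs": "synthetic-utm"})
    return stacks


def _window_fraction(mask: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones((window, window)) / window**2
    return ndimage.convolve(mask.astype(float), kernel, mode="nearest")


def generate_drivers(cfg: SceneConfig, truth: GroundTruth,
                     window: int = 7) -> dict[str, np.ndarray]:
    """Eight driver rasters; continuous ones tied to the quality surface.

    Each continuous driver is built as ``effect * quality + sqrt(1-effect^2)
    * independent smooth field`` and then mapped to plausible physical units,
    so a configured effect of 1.0 makes the driver a deterministic monotone
    function of quality.  Class-ratio drivers are moving-window fractions of
    the land-cover grid and inherit their association with quality through
    the class structure itself.
    """
    rng = cfg.rng("drivers")
    q = truth.quality

    def mix(effect: float) -> np.ndarray:
        noise = _smooth_field(cfg.grid_shape, cfg.spatial_corr_length, rng)
        e = float(np.clip(effect, -1.0, 1.0))
        return e * q + np.sqrt(max(0.0, 1.0 - e * e)) * noise

    eff = truth.driver_effects
    drivers = {
        # yearly means over the plateau climate envelope
        "temperature": 19.8 + 2.2 * mix(eff.get("temperature", 0.0)),
        "precipitation": 894.0 + 53.0 * mix(eff.get("precipitation", 0.0)),
        "slope": np.clip(15.0 + 8.0 * mix(eff.get("slope", 0.0)), 0.0, None),
        "aspect": (180.0 + 90.0 * mix(eff.get("aspect", 0.0))) % 360.0,
        "altitude": 2300.0 + 400.0 * mix(eff.get("altitude", 0.0)),
        "forest_ratio": _window_fraction(truth.class_grid("forest"), window),
        "impervious_ratio": _window_fraction(truth.class_grid("impervious"), window),
        "cropland_ratio": _window_fraction(truth.class_grid("cropland"), window),
    }
    return drivers


def evolve_landcover(landcover: np.ndarray, conversions: dict[str, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Second-epoch land cover: convert random fractions of source classes.

    ``conversions`` maps ``"from->to"`` strings to the fraction of the
    source class's pixels reassigned (e.g. ``{"cropland->impervious":
    0.05}``), emulating urban expansion and afforestation between epochs.
    """
    out = np.asarray(landcover).copy()
    for key, frac in conversions.items():
        src, dst = (s.strip() for s in key.split("->"))
        src_code, dst_code = CLASS_NAMES.index(src), CLASS_NAMES.index(dst)
        candidates = np.flatnonzero(out.ravel() == src_code)
        n = int(round(frac * candidates.size))
        if n == 0:
            continue
        chosen = rng.choice(candidates, size=n, replace=False)
        out.ravel()[chosen] = dst_code
    return out


def generate_scene(cfg: SceneConfig):
    """Convenience: landcover + truth + index stacks + drivers."""
    landcover = generate_landcover(cfg)
    truth = _truth_from_landcover(cfg, landcover)
    stacks = generate_index_stacks(cfg, truth)
    drivers = generate_drivers(cfg, truth)
    return truth, stacks, drivers
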