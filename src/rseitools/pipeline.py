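"""End-to-end orchestration: simulate -> HANTS -> annual RSEI -> trends &
breakpoints -> Moran/LISA -> geodetector -> land-cover transitions.

One YAML config drives every stage; a run manifest records effective
parameters, per-stage seeds and output hashes so a rerun with the same
config is reproducible (CSV/JSON outputs byte-identical).  Per-stage
seeds are derived from the global seed by hashing the stage name, so each
stage has an independent, stable stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hants, landcover, rsei, spatial, trend
from .geodetector import detector_report
from .raster import RasterStack, write_grid, write_stack
from .spectral_indices import median_composite
from .synthetic_scene import (CLASS_NAMES, INDEX_NAMES, SceneConfig,
                              evolve_landcover, generate_drivers,
                              generate_index_stacks, generate_landcover,
                              _truth_from_landcover)

log = logging.getLogger("rseitools.pipeline")

STAGES = ("simulate", "hants", "rsei", "trend", "moran", "geodetect", "transitions")

_ALLOWED_SCHEMES = ("queen", "rook", "knn")
_ALLOWED_BINS = ("quantile", "equal-interval", "natural-breaks")


@dataclass
class PipelineConfig:
    """Validated parameters for a full run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    nf: int = 1
    base_period: float = 1.0
    outlier_mode: str = "none"
    hants_mode: str = "per_year"   # "per_year" or "full" record fitting
    water_threshold: float = 0.0
    z_sig: float = 1.96
    z_strong: float = 2.58
    k_breaks: int = 3
    min_seg: int = 3
    moran_spacing_px: int = 4
    weights_scheme: str = "queen"
    moran_permutations: int = 199
    lisa_alpha: float = 0.05
    detector_bins: str = "quantile"
    detector_k: int = 5
    detector_permutations: int = 199
    detector_sample_step: int = 1
    conversions: dict = field(default_factory=lambda: {
        "cropland->impervious": 0.05, "grassland->forest": 0.05,
        "cropland->forest": 0.03})
    seed: int = 0
    output_dir: str = "rsei_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        scene_raw = raw.pop("scene", {})
        if isinstance(scene_raw, dict):
            if "grid_shape" in scene_raw:
                scene_raw["grid_shape"] = tuple(scene_raw["grid_shape"])
            scene = SceneConfig(**scene_raw)
        else:
            scene = scene_raw
        cfg = cls(scene=scene, **raw)
        # the global seed flows into the scene unless the scene pins its own
        if "seed" not in scene_raw:
            cfg.scene.seed = cfg.seed
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (zlib.crc32(stage.encode()) ^ (self.seed * 2654435761)) % (2**31)


def validate(config: PipelineConfig) -> list[str]:
    """Cross-field checks; returns a list of error messages (empty = valid)."""
    errors = []
    c = config
    needed = 2 * c.nf + 1
    if c.hants_mode not in ("per_year", "full"):
        errors.append(f"unknown hants_mode {c.hants_mode!r}; use per_year or full")
    per_fit_obs = (c.scene.obs_per_season if c.hants_mode == "per_year"
                   else c.scene.n_years * c.scene.obs_per_season)
    if per_fit_obs < needed:
        errors.append(f"nf={c.nf} needs >= {needed} valid samples per fit; "
                      f"{c.hants_mode} mode provides only {per_fit_obs} "
                      f"observations")
    if c.weights_scheme not in _ALLOWED_SCHEMES:
        errors.append(f"unknown weights scheme {c.weights_scheme!r}; "
                      f"allowed: {', '.join(_ALLOWED_SCHEMES)}")
    if c.detector_bins not in _ALLOWED_BINS:
        errors.append(f"unknown binning {c.detector_bins!r}; "
                      f"allowed: {', '.join(_ALLOWED_BINS)}")
    if c.k_breaks >= 1 and c.scene.n_years < (c.k_breaks + 1) * c.min_seg:
        errors.append(f"{c.k_breaks} breakpoints with segments of >= {c.min_seg} "
                      f"need >= {(c.k_breaks + 1) * c.min_seg} years; scene has "
                      f"{c.scene.n_years}")
    if c.moran_spacing_px < 1 or c.moran_spacing_px > min(c.scene.grid_shape):
        errors.append("moran_spacing_px must be >= 1 and fit inside the grid")
    if not 0 <= c.water_threshold <= 1:
        errors.append("water_threshold must lie in [0, 1]")
    return errors


def _nanmean_grid(values: np.ndarray) -> np.ndarray:
    """Time-mean ignoring NaN; pixels with no valid year stay NaN quietly."""
    count = np.isfinite(values).sum(axis=0)
    total = np.nansum(values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / count, np.nan)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRunner:
    """Stage-by-stage executor with in-memory caching of intermediates."""

    def __init__(self, config: PipelineConfig, output_dir: str | Path | None = None):
        errs = validate(config)
        if errs:
            raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errs))
        self.cfg = config
        self.out = Path(output_dir if output_dir is not None else config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict = {}
        self.manifest: dict = {"seed": config.seed, "stages": {}}

    # -- stages ---------------------------------------------------------
    def simulate(self) -> dict:
        if "scene" in self._cache:
            return self._cache["scene"]
        cfg = self.cfg.scene
        lc = generate_landcover(cfg)
        truth = _truth_from_landcover(cfg, lc)
        stacks = generate_index_stacks(cfg, truth)
        drivers = generate_drivers(cfg, truth)
        write_grid(lc, self.out / "landcover.tif")
        for name, stack in stacks.items():
            write_stack(stack, self.out / f"{name.lower()}_raw.tif")
        self._record("simulate", {"grid_shape": list(cfg.grid_shape),
                                  "n_years": cfg.n_years,
                                  "obs_per_season": cfg.obs_per_season,
                                  "gap_fraction": cfg.gap_fraction,
                                  "seed": cfg.seed},
                     ["landcover.tif"])
        scene = {"truth": truth, "stacks": stacks, "drivers": drivers}
        self._cache["scene"] = scene
        return scene

    def run_hants(self) -> dict[str, RasterStack]:
        if "recon" in self._cache:
            return self._cache["recon"]
        scene = self.simulate()
        params = hants.HANTSParams(nf=self.cfg.nf, base_period=self.cfg.base_period,
                                   outlier_mode=self.cfg.outlier_mode)
        recon = {}
        for name in INDEX_NAMES:
            stack = scene["stacks"][name]
            if self.cfg.hants_mode == "per_year":
                # independent harmonic fit per growing season so interannual
                # variation survives into the annual composites
                pieces = []
                for y in range(self.cfg.scene.n_years):
                    sub = stack.select(y, y + 1 - 1e-9)
                    rec_y, _ = hants.fit_stack(sub, params)
                    pieces.append(rec_y)
                rec = RasterStack(np.concatenate([p.values for p in pieces]),
                                  np.concatenate([p.times for p in pieces]),
                                  stack.name, dict(stack.meta))
            else:
                rec, _ = hants.fit_stack(stack, params)
            recon[name] = rec
            write_stack(rec, self.out / f"{name.lower()}_recon.tif")
        self._record("hants", {"nf": self.cfg.nf, "base_period": self.cfg.base_period,
                               "mode": self.cfg.hants_mode,
                               "outlier_mode": self.cfg.outlier_mode},
                     [f"{n.lower()}_recon.tif" for n in INDEX_NAMES])
        self._cache["recon"] = recon
        return recon

    def run_rsei(self) -> dict:
        if "rsei" in self._cache:
            return self._cache["rsei"]
        scene = self.simulate()
        recon = self.run_hants()
        n_years = self.cfg.scene.n_years
        mndwi_stack = scene["stacks"]["MNDWI"]
        results = []
        annual = np.full((n_years,) + tuple(self.cfg.scene.grid_shape), np.nan)
        for y in range(n_years):
            window = (y, y + 1 - 1e-9)
            comps = {n: median_composite(recon[n], window) for n in INDEX_NAMES}
            mndwi = median_composite(mndwi_stack, window)
            res = rsei.build_rsei(comps, mndwi, self.cfg.water_threshold, year=y)
            results.append(res)
            annual[y] = res.rsei
        summary = rsei.annual_summary(results)
        summary.to_csv(self.out / "rsei_summary.csv", index=False)
        annual_stack = RasterStack(annual, np.arange(n_years, dtype=float) + 0.5,
                                   name="RSEI", meta=dict(mndwi_stack.meta))
        write_stack(annual_stack, self.out / "rsei_annual.tif")
        self._record("rsei", {"water_threshold": self.cfg.water_threshold},
                     ["rsei_summary.csv", "rsei_annual.tif"])
        out = {"results": results, "summary": summary, "annual_stack": annual_stack}
        self._cache["rsei"] = out
        return out

    def run_trend(self) -> dict:
        if "trend" in self._cache:
            return self._cache["trend"]
        r = self.run_rsei()
        annual_stack = r["annual_stack"]
        means = np.array([res.mean_rsei for res in r["results"]])
        out: dict = {"annual_means": means}
        series_mk = trend.mk_test(means)
        out["mk"] = series_mk
        if self.cfg.k_breaks >= 1 and means.size >= (self.cfg.k_breaks + 1) * self.cfg.min_seg:
            model = trend.breakpoint_search(means, self.cfg.k_breaks, self.cfg.min_seg)
            out["breakpoints"] = model
            (self.out / "breakpoints.json").write_text(json.dumps(
                {"breaks": model.breakpoints, "J": model.cost,
                 "degenerate": model.degenerate, "segments": model.segments},
                indent=1))
        slope, z, classes = trend.trend_raster(annual_stack, z_sig=self.cfg.z_sig,
                                               z_strong=self.cfg.z_strong)
        write_grid(slope, self.out / "trend_slope.tif")
        write_grid(z, self.out / "trend_z.tif")
        write_grid(classes.astype(float), self.out / "trend_classes.tif")
        frac = {lbl: float((classes == i).mean())
                for i, lbl in enumerate(trend.TREND_CLASS_LABELS)}
        series_summary = {
            "annual_means": [float(m) for m in means],
            "sen_slope": series_mk.slope, "Z": series_mk.Z, "p": series_mk.p,
            "class_fractions": frac,
        }
        (self.out / "trend_summary.json").write_text(json.dumps(series_summary, indent=1))
        self._record("trend", {"z_sig": self.cfg.z_sig, "z_strong": self.cfg.z_strong,
                               "k_breaks": self.cfg.k_breaks},
                     ["trend_summary.json"])
        out["classes"] = classes
        self._cache["trend"] = out
        return out

    def run_moran(self) -> dict:
        if "moran" in self._cache:
            return self._cache["moran"]
        r = self.run_rsei()
        mean_rsei = _nanmean_grid(r["annual_stack"].values)
        points = spatial.fishnet_sample(mean_rsei, float(self.cfg.moran_spacing_px))
        weights = spatial.build_weights(points, self.cfg.weights_scheme)
        result = spatial.lisa_classify(points["value"].to_numpy(), weights,
                                       n_permutations=self.cfg.moran_permutations,
                                       alpha=self.cfg.lisa_alpha,
                                       seed=self.cfg.stage_seed("moran"))
        table = spatial.lisa_table(points, result)
        table.to_csv(self.out / "lisa.csv", index=False)
        (self.out / "moran_global.json").write_text(json.dumps(
            {"I": result.I, "expected": result.expected, "p_sim": result.p_sim,
             "n": result.n, "scheme": self.cfg.weights_scheme,
             "permutations": result.permutations}, indent=1))
        self._record("moran", {"spacing_px": self.cfg.moran_spacing_px,
                               "scheme": self.cfg.weights_scheme,
                               "permutations": self.cfg.moran_permutations,
                               "alpha": self.cfg.lisa_alpha,
                               "stage_seed": self.cfg.stage_seed("moran")},
                     ["lisa.csv", "moran_global.json"])
        out = {"points": points, "weights": weights, "result": result}
        self._cache["moran"] = out
        return out

    def run_geodetect(self) -> dict:
        if "detector" in self._cache:
            return self._cache["detector"]
        scene = self.simulate()
        r = self.run_rsei()
        mean_rsei = _nanmean_grid(r["annual_stack"].values)
        res = detector_report(mean_rsei, scene["drivers"],
                              bin_method=self.cfg.detector_bins,
                              k=self.cfg.detector_k,
                              permutations=self.cfg.detector_permutations,
                              seed=self.cfg.stage_seed("geodetect"),
                              sample_step=self.cfg.detector_sample_step)
        res.factors.to_csv(self.out / "detector.csv", index=False)
        res.interaction.to_csv(self.out / "interactions.csv")
        res.categories.to_csv(self.out / "interaction_categories.csv")
        self._record("geodetect", {"bins": self.cfg.detector_bins,
                                   "k": self.cfg.detector_k,
                                   "permutations": self.cfg.detector_permutations,
                                   "stage_seed": self.cfg.stage_seed("geodetect")},
                     ["detector.csv", "interactions.csv", "interaction_categories.csv"])
        self._cache["detector"] = res
        return res

    def run_transitions(self) -> dict:
        if "transitions" in self._cache:
            return self._cache["transitions"]
        scene = self.simulate()
        lc1 = scene["truth"].landcover
        rng = np.random.default_rng(self.cfg.stage_seed("transitions"))
        lc2 = evolve_landcover(lc1, self.cfg.conversions, rng)
        tm = landcover.transition_matrix(lc1, lc2, CLASS_NAMES)
        tm.counts.to_csv(self.out / "transition_counts.csv")
        props = {"t1": landcover.class_proportions(lc1, CLASS_NAMES),
                 "t2": landcover.class_proportions(lc2, CLASS_NAMES)}
        (self.out / "class_proportions.json").write_text(json.dumps(props, indent=1))
        self._record("transitions", {"conversions": self.cfg.conversions,
                                     "stage_seed": self.cfg.stage_seed("transitions")},
                     ["transition_counts.csv", "class_proportions.json"])
        out = {"matrix": tm, "proportions": props, "lc2": lc2}
        self._cache["transitions"] = out
        return out

    # -- orchestration --------------------------------------------------
    def run_all(self) -> dict:
        for stage in STAGES:
            log.info("stage %s", stage)
            getattr(self, "run_" + stage if stage != "simulate" else stage)()
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=1,
                                                           sort_keys=True))
        return self.manifest

    def _record(self, stage: str, params: dict, outputs: list[str]) -> None:
        entry = {"params": params, "outputs": {}}
        for name in outputs:
            p = self.out / name
            if p.exists():
                entry["outputs"][name] = _sha256(p)
        self.manifest["stages"][stage] = entry


def run(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    return PipelineRunner(config, output_dir).run_all()
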