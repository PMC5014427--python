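"""End-to-end orchestration: generate → measure → fit → report.

A :class:`PipelineConfig` is loaded from YAML (unknown keys rejected, all
fields defaulted), drives a seeded run of the enabled stages in dependency
order, and produces a :class:`RunReport` whose JSON/CSV serialization is
byte-identical for identical seed + config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomass as bm
from . import fitting, kinetics, morphometry
from .errors import ConfigError, MycomorphError, UndefinedRatioError
from .fitting import GammaParams, GaussianParams, TipRateMixture
from .network import GridSpec, Point3D, VoxelStack
from .raster import rasterize
from .simulate import (BRANCH_LENGTH_LAWS_FIGURE_AGES, BRANCH_LENGTH_LAWS_TABLE_AGES,
                       GrowthConfig, grow)

__all__ = ["PipelineConfig", "RunReport", "load_config", "run_pipeline", "write_report"]


def _from_dict(cls, data: dict, path: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"{path}.{key}: unknown key")
        sub = _SECTIONS.get((cls, key))
        kwargs[key] = _from_dict(sub, value, f"{path}.{key}") if sub else value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from None


@dataclass(frozen=True)
class GeneratorSection:
    n_initial_hyphae: int = 5
    duration_hours: float = 408.0
    snapshot_hours: tuple[float, ...] = (72, 96, 120, 168, 240, 288, 336, 408)
    lag_hours: float = 120.0
    k_active_lag: float = 0.72
    k_active_exp: float = 0.70
    k_lag: float = 0.2
    lb_ab_ratio: float = 4.5
    diameter_um: float = 3.0
    tilt_sd_deg: float = 5.0
    tilt_max_deg: float = 30.0
    direction_noise_sd_deg: float = 3.0
    dt_hours: float = 1.0
    resample_hours: float = 24.0
    max_tips: int | None = 600
    angle_mu_deg: float = 77.6
    angle_sigma_deg: float = 12.3
    length_alpha: float = 1.32
    length_beta: float = 0.022
    rate_alpha: float = 1.51
    rate_beta: float = 0.09
    rate_baseline: float = 4.65e-6
    rate_max: float = 80.0
    branch_length_age_preset: str | None = None  # "table", "figure" or None

    def growth_config(self, seed: int) -> GrowthConfig:
        presets = {None: None, "table": BRANCH_LENGTH_LAWS_TABLE_AGES,
                   "figure": BRANCH_LENGTH_LAWS_FIGURE_AGES}
        if self.branch_length_age_preset not in presets:
            raise ConfigError(
                f"branch_length_age_preset must be 'table', 'figure' or null, "
                f"got {self.branch_length_age_preset!r}")
        return GrowthConfig(
            seed=seed,
            n_initial_hyphae=self.n_initial_hyphae,
            duration_hours=self.duration_hours,
            snapshot_hours=tuple(self.snapshot_hours),
            lag_hours=self.lag_hours,
            k_active_lag=self.k_active_lag,
            k_active_exp=self.k_active_exp,
            k_lag=self.k_lag,
            lb_ab_ratio=self.lb_ab_ratio,
            diameter_um=self.diameter_um,
            tilt_sd_deg=self.tilt_sd_deg,
            tilt_max_deg=self.tilt_max_deg,
            direction_noise_sd_deg=self.direction_noise_sd_deg,
            dt_hours=self.dt_hours,
            resample_hours=self.resample_hours,
            max_tips=self.max_tips,
            branch_angle_law=GaussianParams(self.angle_mu_deg, self.angle_sigma_deg),
            branch_length_law=GammaParams(self.length_alpha, self.length_beta),
            branch_length_laws_by_age=presets[self.branch_length_age_preset],
            tip_rate_law=TipRateMixture(GammaParams(self.rate_alpha, self.rate_beta),
                                        self.rate_baseline, self.rate_max),
        )


@dataclass(frozen=True)
class StagesSection:
    kinetics: bool = True
    morphometry: bool = True
    biomass: bool = True
    fitting: bool = True


@dataclass(frozen=True)
class BinningSection:
    angle_deg: float = 5.0
    length_um: float = 10.0
    rate_um_per_h: float = 2.5


@dataclass(frozen=True)
class BiomassSection:
    voxel_xy_um: float = 20.0
    voxel_z_um: float = 20.0
    stack_depth_um: float = 200.0
    noise_sd: float = 5.0
    outer_radius_um: float | None = None  # default: colony extent at final snapshot


@dataclass(frozen=True)
class MorphometrySection:
    window_um: float = 20.0


@dataclass(frozen=True)
class KineticsSection:
    tolerance_um: float = 1.25


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    generator: GeneratorSection = field(default_factory=GeneratorSection)
    stages: StagesSection = field(default_factory=StagesSection)
    binning: BinningSection = field(default_factory=BinningSection)
    biomass: BiomassSection = field(default_factory=BiomassSection)
    morphometry: MorphometrySection = field(default_factory=MorphometrySection)
    kinetics: KineticsSection = field(default_factory=KineticsSection)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SECTIONS = {
    (PipelineConfig, "generator"): GeneratorSection,
    (PipelineConfig, "stages"): StagesSection,
    (PipelineConfig, "binning"): BinningSection,
    (PipelineConfig, "biomass"): BiomassSection,
    (PipelineConfig, "morphometry"): MorphometrySection,
    (PipelineConfig, "kinetics"): KineticsSection,
}


def load_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; ``seed`` overrides the file's."""
    if path is None:
        cfg = PipelineConfig()
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text())
        cfg = _from_dict(PipelineConfig, data or {}, "config")
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    return cfg


@dataclass
class RunReport:
    """All stage outputs of one pipeline run, JSON/CSV serializable."""

    config_hash: str
    seed: int
    kinetics_table: pd.DataFrame | None = None
    branch_records: pd.DataFrame | None = None
    morphometry_summary: dict | None = None
    fit_results: dict | None = None
    biomass_table: pd.DataFrame | None = None
    age_map: dict | None = None

    def summary_dict(self) -> dict:
        out = {"config_hash": self.config_hash, "seed": self.seed,
               "morphometry": self.morphometry_summary,
               "fits": self.fit_results, "age_map": self.age_map}
        if self.kinetics_table is not None:
            out["kinetics"] = json.loads(
                self.kinetics_table.to_json(orient="records", double_precision=12))
        return out


def _fit_report(result: fitting.FitResult) -> dict:
    return {"family": result.family, "params": result.params, "rss": result.rss,
            "seed": result.seed, "generations": result.generations,
            "population": result.population}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute enabled stages in dependency order; deterministic per seed.

    Stage failures are re-raised as :class:`MycomorphError` naming the stage;
    outputs of completed stages are retained on the report.
    """
    report = RunReport(config_hash=config.hash(), seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    gen_seed, fit_seed, raster_seed = (int(s.generate_state(1)[0]) for s in ss.spawn(3))

    series, log = _stage("simulate", lambda: grow(config.generator.growth_config(gen_seed)))

    if config.stages.kinetics:
        report.kinetics_table = _stage("kinetics", lambda: kinetics.summarize_series(
            series, tolerance=config.kinetics.tolerance_um))

    angles = lengths = None
    if config.stages.morphometry:
        def _morpho():
            records, summary = morphometry.measure_branches(
                series[-1], window=config.morphometry.window_um)
            df = pd.DataFrame(
                [{"site_id": r.site_id, "x": r.position[0], "y": r.position[1],
                  "z": r.position[2], "type": r.kind, "angle_deg": r.angle_deg}
                 for r in records])
            try:
                ratio = summary.ratio
            except UndefinedRatioError:
                ratio = None
            return df, summary, ratio
        df, summary, ratio = _stage("morphometry", _morpho)
        report.branch_records = df
        report.morphometry_summary = {
            "n_lbs": summary.n_lbs, "n_abs": summary.n_abs,
            "n_unclassifiable": summary.n_unclassifiable,
            "lb_ab_ratio": ratio, "n_branching_lengths": int(len(summary.lengths)),
        }
        angles = df["angle_deg"].to_numpy() if len(df) else None
        lengths = summary.lengths

    if config.stages.fitting:
        def _fits():
            out: dict[str, dict] = {}
            if angles is not None and len(angles) >= 20:
                hist = fitting.histogram_density(angles, config.binning.angle_deg)
                out["branch_angle_gaussian"] = _fit_report(
                    fitting.fit_distribution(hist, "gaussian", seed=fit_seed))
            if lengths is not None and len(lengths) >= 20:
                hist = fitting.histogram_density(lengths, config.binning.length_um)
                out["branching_length_gamma"] = _fit_report(
                    fitting.fit_distribution(hist, "gamma", seed=fit_seed))
                wcdf = fitting.weighted_cdf(hist)
                out["branching_length_weighted_cdf_end"] = float(wcdf.values[-1])
            rates = log.sampled_rates(active_only=True)
            if len(rates) >= 50:
                hist = fitting.histogram_density(rates, config.binning.rate_um_per_h)
                out["tip_rate_mixture"] = _fit_report(fitting.fit_distribution(
                    hist, "mixture", seed=fit_seed,
                    r_max=config.generator.rate_max))
            return out
        report.fit_results = _stage("fitting", _fits)

    if config.stages.biomass:
        def _biomass():
            bcfg = config.biomass
            extent = max(
                float(np.abs(np.vstack([p for p in series[-1].iter_polylines()])[:, :2]).max()),
                10 * bcfg.voxel_xy_um)
            half = extent + 5 * bcfg.voxel_xy_um
            n_xy = int(np.ceil(2 * half / bcfg.voxel_xy_um))
            nz = max(int(np.ceil(bcfg.stack_depth_um / bcfg.voxel_z_um)), 1)
            grid = GridSpec(dx=bcfg.voxel_xy_um, dy=bcfg.voxel_xy_um, dz=bcfg.voxel_z_um,
                            nx=n_xy, ny=n_xy, nz=nz,
                            origin=Point3D(-half, -half, -nz * bcfg.voxel_z_um / 2.0))
            rng = np.random.default_rng(raster_seed)
            masks = []
            for snap in series:
                gray = rasterize(snap, grid, diameter=config.generator.diameter_um,
                                 mode="grayscale", noise_sd=bcfg.noise_sd, rng=rng)
                mask, _ = bm.threshold_triangle(gray)
                masks.append(VoxelStack(grid, mask))
            days = [s.time / 24.0 for s in series]
            whole = bm.voxel_biomass(masks, days)
            outer = bcfg.outer_radius_um or extent
            spec = bm.RegionSpec(outer_radius=outer)
            regional = bm.regional_biomass(masks, days, spec)
            table = pd.DataFrame({"day": days, "colony_voxels": whole.counts})
            for name, curve in regional.items():
                table[f"{name}_normalized"] = curve.counts
            try:
                age_map = bm.align_ages(regional).to_dict()
            except MycomorphError:
                age_map = None
            return table, age_map
        report.biomass_table, report.age_map = _stage("biomass", _biomass)

    return report


def _stage(name: str, fn):
    try:
        return fn()
    except MycomorphError as exc:
        raise MycomorphError(f"stage '{name}' failed: {exc}") from exc


def write_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write the report as JSON + CSV tables with stable names; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame | None, name: str) -> None:
        if df is not None:
            p = out / name
            df.to_csv(p, index=False, float_format="%.10g")
            written.append(p)

    summary = out / "report.json"
    summary.write_text(json.dumps(report.summary_dict(), indent=1, sort_keys=True,
                                  default=float))
    written.append(summary)
    _csv(report.kinetics_table, "kinetics.csv")
    _csv(report.branch_records, "branch_records.csv")
    _csv(report.biomass_table, "biomass.csv")
    return written
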