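"""End-to-end synthetic validation experiment.

Generates (or loads) a breath trace, builds the analytic airway flow field
and the xenon concentration front, simulates the dynamic PC-MRI series,
resamples the truth field into the same voxels per retained dynamic, and
produces the voxel-wise agreement report — every stage deterministic under
the master seed, every intermediate written to disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import breath as breath_mod
from .acquisition import AcquisitionParams, PCMRISeries, acquire_series
from .breath import BreathTrace, detect_triggers, per_dynamic_flow, synthetic_inhalation_trace
from .gases import AIR, XENON, chapman_enskog_diffusion, get_gas
from .grids import DynamicWindow, GridGeometry, sagittal_slab_grid
from .phantom import AnalyticFlowField, TubePhantom, solve_concentration
from .resampling import VoxelVelocityMap, resample_to_voxels
from .stats import ComparisonReport, build_report

__all__ = ["ExperimentConfig", "run_synthetic_validation", "generate_fixtures"]

log = logging.getLogger("xepcv.pipeline")

_DEFAULT_PHANTOM = {
    "radius_m": 7.5e-3,
    "length_m": 0.20,
    "z_low_m": -0.10,
    "constriction_depth": 0.0,
    "constriction_center_m": 0.10,
    "constriction_width_m": 0.02,
}

_DEFAULT_TRACE = {
    "total_duration_s": 20.0,
    "inhale_duration_s": 13.0,
    "peak_flow_mls": 80.0,
    "ramp_s": 1.5,
    "n_dynamics": 5,
    "dynamic_duration_s": 3.1,
    "first_trigger_s": 0.5,
    "sample_rate_hz": 200.0,
    "exhale_flow_mls": -150.0,
    "noise_mls": 0.0,
}

_DEFAULT_GRID = {
    "fov_ap_mm": 30.0,
    "fov_fh_mm": 160.0,
    "in_plane_mm": 1.25,
    "slab_mm": 10.0,
}

_DEFAULT_COMPARISON = {
    "erosion_iterations": 1,
    "downsample": False,
    "block": [3, 3],
    "min_count": 5,
}


@dataclass
class ExperimentConfig:
    """Everything needed to run one synthetic validation experiment.

    Nested dictionaries carry explicit unit suffixes in their key names
    (``radius_m``, ``peak_flow_mls`` ...).  ``trace`` may instead contain a
    single ``file`` entry pointing at a breath-trace CSV.  The master
    ``seed`` fixes every stochastic stage.
    """

    seed: int = 0
    output_dir: str = "xepcv_out"
    gas: str = "xenon"
    mode: str = "oscillatory"
    n_harmonics: int = 5
    diffusion_cm2s: float | None = None  # default: Chapman-Enskog Xe-air, 310 K
    phantom: dict = field(default_factory=dict)
    trace: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    comparison: dict = field(default_factory=dict)
    save_plots: bool = False

    def __post_init__(self) -> None:
        self.phantom = {**_DEFAULT_PHANTOM, **self.phantom}
        if "file" not in self.trace:
            self.trace = {**_DEFAULT_TRACE, **self.trace}
        self.grid = {**_DEFAULT_GRID, **self.grid}
        self.comparison = {**_DEFAULT_COMPARISON, **self.comparison}
        self._validate()

    def _validate(self) -> None:
        if self.mode not in ("steady", "oscillatory"):
            raise ValueError("mode must be 'steady' or 'oscillatory'")
        unknown = set(self.phantom) - set(_DEFAULT_PHANTOM)
        if unknown:
            raise ValueError(f"unknown phantom keys: {sorted(unknown)}")
        if "file" not in self.trace:
            unknown = set(self.trace) - set(_DEFAULT_TRACE)
            if unknown:
                raise ValueError(f"unknown trace keys: {sorted(unknown)}")
        unknown = set(self.grid) - set(_DEFAULT_GRID)
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        unknown = set(self.comparison) - set(_DEFAULT_COMPARISON)
        if unknown:
            raise ValueError(f"unknown comparison keys: {sorted(unknown)}")
        get_gas(self.gas)  # raises on unknown gas

    # -- stage builders -----------------------------------------------------
    def build_trace(self) -> BreathTrace:
        if "file" in self.trace:
            return BreathTrace.from_csv(self.trace["file"])
        p = self.trace
        return synthetic_inhalation_trace(
            total_duration=p["total_duration_s"],
            inhale_duration=p["inhale_duration_s"],
            peak_flow=p["peak_flow_mls"],
            ramp=p["ramp_s"],
            n_dynamics=p["n_dynamics"],
            dynamic_duration=p["dynamic_duration_s"],
            first_trigger=p["first_trigger_s"],
            sample_rate=p["sample_rate_hz"],
            exhale_flow=p["exhale_flow_mls"],
            noise_sigma=p["noise_mls"],
            seed=self.seed,
        )

    def build_phantom(self) -> TubePhantom:
        p = self.phantom
        return TubePhantom(
            radius=p["radius_m"],
            length=p["length_m"],
            z_low=p["z_low_m"],
            gas=get_gas(self.gas),
            constriction_depth=p["constriction_depth"],
            constriction_center=p["constriction_center_m"],
            constriction_width=p["constriction_width_m"],
        )

    def build_field(self, phantom: TubePhantom, trace: BreathTrace) -> AnalyticFlowField:
        return AnalyticFlowField(phantom, trace, mode=self.mode, n_harmonics=self.n_harmonics)

    def build_grid(self) -> GridGeometry:
        g = self.grid
        return sagittal_slab_grid(
            fov_ap_mm=g["fov_ap_mm"],
            fov_fh_mm=g["fov_fh_mm"],
            in_plane_mm=g["in_plane_mm"],
            slab_mm=g["slab_mm"],
        )

    def build_acquisition_params(self) -> AcquisitionParams:
        base = dict(
            in_plane_mm=self.grid["in_plane_mm"],
            slab_mm=self.grid["slab_mm"],
            seed=self.seed,
        )
        if "file" not in self.trace:
            base["dynamic_duration"] = self.trace["dynamic_duration_s"]
            base["n_dynamics"] = self.trace["n_dynamics"]
        base.update(self.acquisition)
        return AcquisitionParams(**base)

    def diffusion(self) -> float:
        if self.diffusion_cm2s is not None:
            return self.diffusion_cm2s
        return chapman_enskog_diffusion(XENON, AIR)

    # -- (de)serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_synthetic_validation(
    config: ExperimentConfig, write_outputs: bool = True
) -> ComparisonReport:
    """Run the full experiment defined by ``config`` and return the report.

    Stages: breath trace → trigger sync → flow field + xenon front →
    simulated PC-MRI series → per-dynamic voxel-averaged reference →
    agreement statistics.  Exhalation dynamics are excluded from comparison.
    Identical config + seed gives bit-identical outputs.
    """
    out = Path(config.output_dir)
    provenance: dict = {"config_hash": _hash(dataclasses.asdict(config)), "stages": {}}

    log.info("stage trace: building breath trace")
    trace = config.build_trace()
    params = config.build_acquisition_params()
    triggers = detect_triggers(trace)
    if len(triggers) == 0:
        raise RuntimeError("stage sync failed: no trigger pulses found in trace")
    triggers = triggers[: params.n_dynamics]
    summary = per_dynamic_flow(trace, triggers, params.dynamic_duration)
    provenance["stages"]["sync"] = {
        "n_triggers": len(triggers),
        "retained": summary.retained.tolist(),
    }

    log.info("stage field: phantom + analytic flow + concentration front")
    phantom = config.build_phantom()
    fieldf = config.build_field(phantom, trace)
    t_end = float(triggers[-1] + params.dynamic_duration)
    conc = solve_concentration(
        phantom, trace, config.diffusion(), t_end=t_end, t_start=trace.support[0]
    )

    log.info("stage simulate: dynamic PC-MRI acquisition")
    series = acquire_series(fieldf, conc, params, config.build_grid(), triggers)

    log.info("stage resample: voxel-averaged reference per retained dynamic")
    refs: dict[int, VoxelVelocityMap] = {}
    for k in summary.retained:
        if k >= series.n_dynamics:
            continue
        refs[int(k)] = resample_to_voxels(
            fieldf,
            series.grid,
            series.window(int(k)),
            supersampling=params.supersampling,
            slab_supersampling=params.slab_supersampling,
            n_time=params.n_time,
            mask_threshold=params.mask_threshold,
        )
    if not refs:
        raise RuntimeError("stage resample failed: no retained (inhalation) dynamics")

    log.info("stage compare: voxel-wise agreement statistics")
    comp = config.comparison
    report = build_report(
        series,
        refs,
        erosion_iterations=comp["erosion_iterations"],
        downsample=comp["downsample"],
        block=tuple(comp["block"]),
        min_count=comp["min_count"],
    )

    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        trace.to_csv(out / "trace.csv")
        summary.to_frame().to_csv(out / "flow_summary.csv", index=False)
        series.to_nifti(out / "series")
        for k, ref in refs.items():
            ref.to_nifti(out / f"ref_dyn{k}")
        report.to_json(out / "report.json")
        report.to_csv(out / "report.csv")
        provenance["stages"]["inputs"] = {
            "trace_hash": _hash(trace.flow_rate.tolist()),
            "params": dataclasses.asdict(params),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        if config.save_plots:
            from . import plots

            plots.report_figures(report, out)
    return report


def generate_fixtures(kind: str, out_dir: str | Path, seed: int = 0, **params):
    """Write deterministic synthetic fixtures: ``trace``, ``phantom`` or ``series``.

    ``trace`` — a slow-inhalation breath CSV with trigger pulses;
    ``phantom`` — a phantom + experiment YAML config;
    ``series`` — a small pre-simulated PC-MRI NIfTI series with sidecar.
    Identical seed and parameters give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "trace":
        trace = synthetic_inhalation_trace(seed=seed, **params)
        path = out_dir / "trace.csv"
        trace.to_csv(path)
        return [path]
    if kind == "phantom":
        cfg = ExperimentConfig(seed=seed, **params)
        path = out_dir / "phantom.yaml"
        cfg.to_yaml(path)
        return [path]
    if kind == "series":
        cfg = ExperimentConfig(seed=seed, **params)
        trace = cfg.build_trace()
        acq = cfg.build_acquisition_params()
        phantom = cfg.build_phantom()
        fieldf = cfg.build_field(phantom, trace)
        triggers = detect_triggers(trace)[: acq.n_dynamics]
        conc = solve_concentration(
            phantom,
            trace,
            cfg.diffusion(),
            t_end=float(triggers[-1] + acq.dynamic_duration),
            t_start=trace.support[0],
        )
        series = acquire_series(fieldf, conc, acq, cfg.build_grid(), triggers)
        series.to_nifti(out_dir / "series")
        return sorted(out_dir.glob("series*"))
    raise ValueError(f"unknown fixture kind {kind!r}; use trace, phantom or series")
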