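"""Structured run configuration and the end-to-end pipeline.

A run is described by a YAML file with optional sections (``phantom``,
``array``, ``simulation``, ``workspace``, ``sampling``, ``split``,
``surrogate``, ``modulation``, ``evaluation``, ``mbtrap``); every key has a
default matching the study conditions (1 MHz, 8 elements of 3.7 mm with
0.5 mm gaps, pose 30 deg, theta = 1000 Pa, 74.5/13/12.5 split, sampling at
one target per wavelength).  Unknown keys are rejected.

:func:`run_pipeline` executes phantom -> collect -> split -> train ->
modulate -> field -> evaluate -> mbtrap, writing every artifact plus a
manifest (versions, seeds, SHA-256 hashes) into a flat run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

import sonotrap
from sonotrap import dataset as ds_mod
from sonotrap import mbtrap as mb_mod
from sonotrap import modulation as mod_mod
from sonotrap import surrogate as sur_mod
from sonotrap import trapeval as te_mod
from sonotrap import phantom as ph_mod
from sonotrap import wavesim as ws_mod

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, path: str):
    names = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigError(f"unknown key '{path}.{unknown[0]}'")
    return cls(**data)


@dataclass
class PhantomSpec:
    layers: list | None = None          # None -> default water+tissue stack
    cell_size_mm: float = 0.18
    extent_mm: tuple[float, float] = (120.0, 110.0)

    def build(self, frequency_mhz: float) -> ph_mod.TissueMap:
        layers = self.layers if self.layers is not None \
            else ph_mod.DEFAULT_PHANTOM_LAYERS
        return ph_mod.build_layered_phantom(
            layers, self.cell_size_mm, tuple(self.extent_mm),
            frequency_mhz=frequency_mhz)


@dataclass
class ArraySpec:
    n: int = 8
    element_diameter_mm: float = 3.7
    gap_mm: float = 0.5
    anchor_mm: tuple[float, float] = (78.0, 10.0)
    pose_angle_deg: float = 30.0

    def build(self, tissue_map: ph_mod.TissueMap) -> ph_mod.ArrayGeometry:
        return ph_mod.place_array(tissue_map, self.n, self.element_diameter_mm,
                                  self.gap_mm, self.anchor_mm,
                                  self.pose_angle_deg)


@dataclass
class SimulationSpec:
    frequency_mhz: float = 1.0
    c_water_mps: float = 1500.0
    spreading_exponent: float = 0.5
    reference_radius_mm: float = 1.0
    source_amplitude_pa: float = 1000.0

    def build(self) -> ws_mod.SimulationConfig:
        return ws_mod.SimulationConfig(
            frequency=self.frequency_mhz, c_water=self.c_water_mps,
            spreading_exponent=self.spreading_exponent,
            reference_radius=self.reference_radius_mm,
            source_amplitude=self.source_amplitude_pa)


@dataclass
class WorkspaceSpec:
    half_angle_deg: float | None = None   # None -> -6 dB root of Eq (1)
    depth_range_mm: tuple[float, float] = (24.0, 62.0)

    def build(self, array: ph_mod.ArrayGeometry,
              cfg: ws_mod.SimulationConfig) -> ph_mod.Workspace:
        sigma = self.half_angle_deg
        if sigma is None:
            sigma = ph_mod.solve_spread_half_angle(
                array.element_radius, cfg.wavelength_water)
        return ph_mod.workspace_bounds(array, sigma, tuple(self.depth_range_mm))


@dataclass
class SamplingSpec:
    density_per_mm: float | None = None   # None -> 1/lambda

    def build(self, ws: ph_mod.Workspace,
              cfg: ws_mod.SimulationConfig) -> ph_mod.SamplingPlan:
        density = self.density_per_mm
        if density is None:
            density = 1.0 / cfg.wavelength_water
        return ph_mod.plan_samples(ws, density)


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = ds_mod.DEFAULT_FRACTIONS
    seed: int = 0
    mode: str = "random"

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError(
                f"split fractions must sum to 1, got {sum(self.fractions)}")


@dataclass
class SurrogateSpec:
    tof_layout: tuple[int, ...] = sur_mod.DEFAULT_LAYOUTS["tof"]
    amplitude_layout: tuple[int, ...] = sur_mod.DEFAULT_LAYOUTS["amplitude"]
    seed: int = 0
    batch_size: int = 1
    max_epochs: int = 400
    patience: int = 60
    learning_rate: float = 2e-3


@dataclass
class ModulationSpec:
    trap: str = "focal"
    am: bool = True
    theta_pa: float = 1000.0
    target_mm: tuple[float, float] | None = None  # None -> mid-workspace

    def default_target(self, ws: ph_mod.Workspace) -> np.ndarray:
        mid = 0.5 * (ws.depth_range[0] + ws.depth_range[1])
        return ws.array.anchor + mid * ws.array.normal


@dataclass
class EvaluationSpec:
    window_mm: float = 40.0
    cell_mm: float = 0.25
    fwhm_span_wavelengths: float = 3.5


@dataclass
class MbtrapSpec:
    enabled: bool = True
    vmin_mms: float = 0.5
    vmax_mms: float = 1.54
    period_s: float = 1.0
    vessel_diameter_um: float = 40.0
    viscosity_pas: float = 1.0e-3
    n_bubbles: int = 10
    radius_um: float = 10.0
    shell_thickness_um: float = 0.05
    dt_s: float = 1.0e-4
    t_end_s: float = 0.2
    field_max_pa: float = 15000.0
    seed: int = 0

    def flow(self) -> mb_mod.FlowModel:
        return mb_mod.FlowModel(vmin=self.vmin_mms, vmax=self.vmax_mms,
                                period=self.period_s,
                                vessel_diameter=self.vessel_diameter_um,
                                viscosity=self.viscosity_pas)


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    array: ArraySpec = field(default_factory=ArraySpec)
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    workspace: WorkspaceSpec = field(default_factory=WorkspaceSpec)
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)
    modulation: ModulationSpec = field(default_factory=ModulationSpec)
    evaluation: EvaluationSpec = field(default_factory=EvaluationSpec)
    mbtrap: MbtrapSpec = field(default_factory=MbtrapSpec)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        section_types = {f.name: f.default_factory for f in fields(cls)}
        unknown = sorted(set(data) - set(section_types))
        if unknown:
            raise ConfigError(f"unknown section '{unknown[0]}'")
        kwargs = {}
        for name, factory in section_types.items():
            if name in data:
                sub = data[name]
                if not isinstance(sub, dict):
                    raise ConfigError(f"section '{name}' must be a mapping")
                kwargs[name] = _from_dict(factory, sub, name)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            return obj
        return {f.name: clean(getattr(self, f.name)) for f in fields(self)}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, defaults filled in."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir, seed: int | None = None) -> Path:
    """Execute the full workflow and write artifacts + manifest.

    ``seed`` overrides the split/surrogate/mbtrap seeds in one go.  Any
    stage failure raises ``RuntimeError`` naming the stage; artifacts from
    completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg.split.seed = seed
        cfg.surrogate.seed = seed
        cfg.mbtrap.seed = seed
    manifest: dict = {"package_version": sonotrap.__version__,
                      "seeds": {"split": cfg.split.seed,
                                "surrogate": cfg.surrogate.seed,
                                "mbtrap": cfg.mbtrap.seed},
                      "stages": [], "hashes": {}}
    state: dict = {}

    def stage(name):
        def deco(fn):
            def run():
                try:
                    fn()
                except Exception as exc:
                    _write_manifest(manifest, out)
                    raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
                manifest["stages"].append(name)
            return run
        return deco

    @stage("phantom")
    def do_phantom():
        sim = cfg.simulation.build()
        tmap = cfg.phantom.build(sim.frequency)
        array = cfg.array.build(tmap)
        ws = cfg.workspace.build(array, sim)
        plan = cfg.sampling.build(ws, sim)
        ph_mod.save_tissue_map(tmap, out / "phantom.npz")
        state.update(sim=sim, tmap=tmap, array=array, ws=ws, plan=plan)

    @stage("collect")
    def do_collect():
        ds = ds_mod.build_dataset(state["tmap"], state["array"],
                                  state["plan"], state["sim"])
        state["ds_raw"] = ds

    @stage("split")
    def do_split():
        ds = ds_mod.split_dataset(state["ds_raw"], cfg.split.fractions,
                                  seed=cfg.split.seed, mode=cfg.split.mode)
        ds_mod.write_dataset(ds, out / "dataset.csv")
        state["ds"] = ds

    @stage("train")
    def do_train():
        ds = state["ds"]
        for kind, layout in (("tof", cfg.surrogate.tof_layout),
                             ("amplitude", cfg.surrogate.amplitude_layout)):
            model = sur_mod.build_model(kind, ds.n, layout,
                                        seed=cfg.surrogate.seed)
            sur_mod.train(model, ds, batch_size=cfg.surrogate.batch_size,
                          max_epochs=cfg.surrogate.max_epochs,
                          patience=cfg.surrogate.patience,
                          learning_rate_init=cfg.surrogate.learning_rate)
            sur_mod.save_model(model, out / f"model_{kind}.npz")
            report = sur_mod.evaluate(model, ds)
            state[f"model_{kind}"] = model
            state[f"report_{kind}"] = report

    @stage("modulate")
    def do_modulate():
        ws = state["ws"]
        target = cfg.modulation.target_mm
        target = (np.asarray(target, float) if target is not None
                  else cfg.modulation.default_target(ws))
        tof = sur_mod.predict(state["model_tof"], target)
        amp = sur_mod.predict(state["model_amplitude"], target)
        pats = mod_mod.modulation_patterns(
            tof, amp, period=state["sim"].period, trap=cfg.modulation.trap,
            am=cfg.modulation.am, theta=cfg.modulation.theta_pa)
        np.savetxt(out / "psi.csv",
                   np.column_stack([np.arange(1, len(pats.psi) + 1),
                                    np.abs(pats.psi), np.angle(pats.psi) % (2 * np.pi)]),
                   delimiter=",", header="element,magnitude_pa,phase_rad",
                   comments="", fmt=["%d", "%.17g", "%.17g"])
        state["patterns"] = pats
        state["target"] = target

    @stage("field")
    def do_field():
        synth = ws_mod.FieldSynthesizer(state["tmap"], state["array"],
                                        state["sim"])
        w = cfg.evaluation.window_mm / 2.0
        t = state["target"]
        region = (t[0] - w, t[0] + w, t[1] - w, t[1] + w)
        fld = synth.field(state["patterns"].psi, region=region,
                          cell_size=cfg.evaluation.cell_mm)
        ws_mod.save_field(fld, out / "field.npz")
        state["synth"] = synth
        state["field"] = fld

    @stage("evaluate")
    def do_evaluate():
        sim, fld, t = state["sim"], state["field"], state["target"]
        lam = sim.wavelength_water
        metrics = te_mod.TrapMetrics()
        metrics.peak_position = tuple(te_mod.peak_position(fld))
        metrics.localization_error = te_mod.localization_error(fld, t)
        lateral = state["array"].axis
        try:
            metrics.fwhm_lateral = te_mod.lateral_fwhm(
                fld, t, span=cfg.evaluation.fwhm_span_wavelengths * lam,
                direction=lateral)
        except ValueError:
            pass
        if cfg.modulation.trap == "twin":
            try:
                pts, contrast = te_mod.twin_structure(fld, t, lam,
                                                      direction=lateral)
                metrics.twin_control_points = [tuple(p) for p in pts]
                metrics.twin_contrast = contrast
            except ValueError:
                pass
        rep_t, rep_a = state["report_tof"], state["report_amplitude"]
        payload = metrics.as_dict()
        payload.update({
            "tof_nonoutlier_min_us": rep_t.nonoutlier_min,
            "tof_nonoutlier_max_us": rep_t.nonoutlier_max,
            "tof_outliers": rep_t.n_outliers,
            "tof_predictions": rep_t.n_predictions,
            "amp_max_abs_mean_error_pct":
                float(np.max(np.abs(rep_a.per_element_mean))),
        })
        (out / "metrics.json").write_text(json.dumps(payload, indent=2))

    @stage("mbtrap")
    def do_mbtrap():
        if not cfg.mbtrap.enabled:
            return
        sim, t = state["sim"], state["target"]
        lam = sim.wavelength_water
        # twin actuation at the target from exact ToF (trapping demo)
        sample = ws_mod.collect_sample(state["tmap"], state["array"], t, sim)
        pats = mod_mod.modulation_patterns(sample.tof, sample.amplitude,
                                           period=sim.period, trap="twin",
                                           am=cfg.modulation.am)
        synth = state.get("synth") or ws_mod.FieldSynthesizer(
            state["tmap"], state["array"], sim)
        span = 4.0 * lam
        region = (t[0] - span, t[0] + span, t[1] - lam, t[1] + lam)
        fld = synth.field(pats.psi, region=region, cell_size=lam / 30.0)
        scale = cfg.mbtrap.field_max_pa / np.abs(fld.complex_pressure).max()
        fld = ws_mod.PressureField(fld.complex_pressure * scale,
                                   fld.cell_size, fld.origin)
        flow = cfg.mbtrap.flow()
        result = mb_mod.simulate_trapping(
            fld, flow, cfg.mbtrap.n_bubbles, dt=cfg.mbtrap.dt_s,
            t_end=cfg.mbtrap.t_end_s, seed=cfg.mbtrap.seed,
            vessel_y=t[1], x_range=(t[0] - 2.0 * lam, t[0] + 2.0 * lam),
            frequency_mhz=sim.frequency,
            radius_um=cfg.mbtrap.radius_um,
            shell_thickness_um=cfg.mbtrap.shell_thickness_um)
        result.to_dataframe().to_csv(out / "trajectories.csv", index=False)

    for step in (do_phantom, do_collect, do_split, do_train, do_modulate,
                 do_field, do_evaluate, do_mbtrap):
        step()
    for f_ in sorted(out.glob("*")):
        if f_.name != "manifest.json":
            manifest["hashes"][f_.name] = _sha256(f_)
    _write_manifest(manifest, out)
    return out


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
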