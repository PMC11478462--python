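"""Reproduction experiments on the default study conditions.

Each function runs one self-contained study on the default phantom/array
geometry (1 MHz, 8 x 3.7 mm elements, 0.5 mm gaps, 30 degree pose,
sampling wedge bounded by the -6 dB beam spread, ~950 targets at one
sample per wavelength) and returns plain numbers.  They are what the
command-line tool's validation workflow and the acceptance script execute.
"""

from __future__ import annotations

from dataclasses import replace
from types import SimpleNamespace

import numpy as np

from sonotrap.config import RunConfig
from sonotrap.dataset import (TrainingDataset, build_dataset, split_dataset,
                              subsample_density)
from sonotrap.modulation import modulation_patterns
from sonotrap.surrogate import build_model, evaluate, train
from sonotrap.trapeval import (increment_uniformity, lateral_fwhm,
                               peak_position)
from sonotrap.wavesim import (FieldSynthesizer, PressureField, collect_sample)
from sonotrap import mbtrap as mb
from sonotrap.phantom import build_layered_phantom, place_array

__all__ = [
    "default_study",
    "run_surrogate_study",
    "increment_experiment",
    "density_degradation_experiment",
    "refocusing_experiment",
    "twin_structure_experiment",
    "fwhm_pair_experiment",
    "trapping_experiment",
]


def default_study(cfg: RunConfig | None = None) -> SimpleNamespace:
    """Build the default study geometry (phantom, array, workspace, plan)."""
    cfg = cfg or RunConfig()
    sim = cfg.simulation.build()
    tmap = cfg.phantom.build(sim.frequency)
    array = cfg.array.build(tmap)
    ws = cfg.workspace.build(array, sim)
    plan = cfg.sampling.build(ws, sim)
    return SimpleNamespace(cfg=cfg, sim=sim, tmap=tmap, array=array, ws=ws,
                           plan=plan, lam=sim.wavelength_water)


def run_surrogate_study(seed: int, study: SimpleNamespace | None = None,
                        kinds=("tof", "amplitude"),
                        max_epochs: int | None = None) -> SimpleNamespace:
    """Collect the full 1/lambda dataset, split it and train the surrogates.

    ``seed`` drives both the split shuffle and the network initialization/
    sample ordering.  Returns the dataset, trained models and hold-out
    error reports.
    """
    study = study or default_study()
    ds = build_dataset(study.tmap, study.array, study.plan, study.sim)
    ds = split_dataset(ds, seed=seed)
    models = {}
    reports = {}
    for kind in kinds:
        model = build_model(kind, ds.n, seed=seed)
        kwargs = {} if max_epochs is None else {"max_epochs": max_epochs}
        train(model, ds, **kwargs)
        models[kind] = model
        reports[kind] = evaluate(model, ds)
    return SimpleNamespace(study=study, ds=ds, models=models, reports=reports)


def increment_experiment(homogeneous: bool = False,
                         study: SimpleNamespace | None = None,
                         synth: FieldSynthesizer | None = None,
                         target=None, am: bool = True) -> np.ndarray:
    """Sequential-activation wavefront-uniformity test.

    Baseline elements {2,3,4,7,8} active; e1, e5, e6 added in turn; returns
    the three rises in |p(target)| normalized by the all-8-active value.
    With amplitude modulation every rise should equal 1/8.
    """
    if homogeneous:
        tmap = build_layered_phantom([("water", 110.0, 1500.0, 1000.0, 0.0)],
                                     0.3, (120.0, 110.0), frequency_mhz=None)
        cfg = RunConfig()
        array = place_array(tmap, cfg.array.n, cfg.array.element_diameter_mm,
                            cfg.array.gap_mm, cfg.array.anchor_mm,
                            cfg.array.pose_angle_deg)
        sim = cfg.simulation.build()
        synth = FieldSynthesizer(tmap, array, sim)
        study = SimpleNamespace(tmap=tmap, array=array, sim=sim,
                                ws=cfg.workspace.build(array, sim))
    else:
        study = study or default_study()
        synth = synth or FieldSynthesizer(study.tmap, study.array, study.sim)
    if target is None:
        mid = 0.5 * (study.ws.depth_range[0] + study.ws.depth_range[1])
        target = study.array.anchor + mid * study.array.normal
    smp = collect_sample(study.tmap, study.array, target, study.sim,
                         element_tof_maps=synth.element_tof_maps)
    pats = modulation_patterns(smp.tof, smp.amplitude,
                               period=study.sim.period, am=am)
    return increment_uniformity(synth, pats.psi, target,
                                baseline=[2, 3, 4, 7, 8], added=[1, 5, 6])


def density_degradation_experiment(seed: int,
                                   study: SimpleNamespace | None = None,
                                   ds: TrainingDataset | None = None,
                                   max_epochs: int = 150) -> list[float]:
    """Median hold-out |ToF error| when training at 1/lambda .. 1/4 lambda.

    The hold-out set of the full-density split is kept fixed; for each
    decimation factor k the training pool is the every-k-th-grid-point
    subset minus hold-out targets, split 90/10 into train/validation.
    """
    study = study or default_study()
    if ds is None:
        ds = build_dataset(study.tmap, study.array, study.plan, study.sim)
        ds = split_dataset(ds, seed=seed)
    hold = ds.subset("holdout")
    hold_keys = {tuple(np.round(s.target, 6)) for s in hold.samples}
    medians = []
    for k in (1, 2, 3, 4):
        sub = subsample_density(ds, k)
        pool = [s for s in sub.samples
                if tuple(np.round(s.target, 6)) not in hold_keys]
        rng = np.random.default_rng(seed + k)
        order = rng.permutation(len(pool))
        n_val = max(2, int(round(0.1 * len(pool))))
        samples = [replace(pool[i],
                           split_label="validation" if j < n_val else "train")
                   for j, i in enumerate(order)]
        ds_k = TrainingDataset(samples=samples + hold.samples,
                               density=sub.density,
                               element_positions=ds.element_positions,
                               frequency_mhz=ds.frequency_mhz)
        model = build_model("tof", ds.n, seed=seed)
        train(model, ds_k, max_epochs=max_epochs, patience=max_epochs)
        medians.append(evaluate(model, ds_k).median_abs_error)
    return medians


def _random_workspace_targets(study, n_targets, seed, lat_limit=None,
                              depth_range=None):
    rng = np.random.default_rng(seed)
    ws = study.ws
    lo, hi = depth_range or ws.depth_range
    max_lat = lat_limit if lat_limit is not None else (
        study.array.aperture_span / 2
        + hi * np.tan(np.radians(ws.half_angle)) + 2.0)
    out = []
    while len(out) < n_targets:
        d = rng.uniform(lo, hi)
        s = rng.uniform(-max_lat, max_lat)
        tgt = study.array.anchor + d * study.array.normal + s * study.array.axis
        if ws.contains(tgt):
            out.append(tgt)
    return out


def refocusing_experiment(n_targets: int = 20, seed: int = 7,
                          study: SimpleNamespace | None = None,
                          synth: FieldSynthesizer | None = None,
                          am: bool = True, window: float = 12.0,
                          lat_limit: float | None = None,
                          depth_range=None) -> SimpleNamespace:
    """Exact-ToF modulation refocusing: field-peak offsets from the target.

    For random workspace targets, collects exact per-element ToF/amplitude,
    builds the (phase or phase-amplitude) actuation, synthesizes the field
    on a window around the target, and measures the peak offset, decomposed
    into components along the beam axis (axial) and the array line
    (lateral).
    """
    study = study or default_study()
    synth = synth or FieldSynthesizer(study.tmap, study.array, study.sim)
    targets = _random_workspace_targets(study, n_targets, seed,
                                        lat_limit=lat_limit,
                                        depth_range=depth_range)
    euclid, axial, lateral = [], [], []
    for tgt in targets:
        smp = collect_sample(study.tmap, study.array, tgt, study.sim,
                             element_tof_maps=synth.element_tof_maps)
        pats = modulation_patterns(smp.tof, smp.amplitude,
                                   period=study.sim.period, am=am)
        fld = synth.field(pats.psi,
                          region=(tgt[0] - window, tgt[0] + window,
                                  tgt[1] - window, tgt[1] + window),
                          cell_size=0.15)
        pk = peak_position(fld)
        euclid.append(float(np.linalg.norm(pk - tgt)))
        axial.append(float(abs((pk - tgt) @ study.array.normal)))
        lateral.append(float(abs((pk - tgt) @ study.array.axis)))
    return SimpleNamespace(euclid=np.array(euclid), axial=np.array(axial),
                           lateral=np.array(lateral), targets=targets)


def twin_structure_experiment(depths=(40.0, 43.0, 46.0),
                              study: SimpleNamespace | None = None,
                              synth: FieldSynthesizer | None = None
                              ) -> list[SimpleNamespace]:
    """Twin-trap structure at vessel-representative depths on the axis."""
    from sonotrap.trapeval import twin_structure

    study = study or default_study()
    synth = synth or FieldSynthesizer(study.tmap, study.array, study.sim)
    lam = study.lam
    out = []
    for depth in depths:
        tgt = study.array.anchor + depth * study.array.normal
        smp = collect_sample(study.tmap, study.array, tgt, study.sim,
                             element_tof_maps=synth.element_tof_maps)
        pats = modulation_patterns(smp.tof, smp.amplitude,
                                   period=study.sim.period, trap="twin",
                                   am=True)
        fld = synth.field(pats.psi,
                          region=(tgt[0] - 8, tgt[0] + 8,
                                  tgt[1] - 8, tgt[1] + 8), cell_size=0.1)
        pts, contrast = twin_structure(fld, tgt, lam,
                                       direction=study.array.axis)
        out.append(SimpleNamespace(
            depth=depth, target=tgt, control_points=pts, contrast=contrast,
            separation=float(np.linalg.norm(pts[0] - pts[1])),
            midpoint_offset=float(np.linalg.norm(pts.mean(axis=0) - tgt))))
    return out


def fwhm_pair_experiment(n_targets: int = 12, seed: int = 7,
                         study: SimpleNamespace | None = None,
                         synth: FieldSynthesizer | None = None
                         ) -> np.ndarray:
    """(AM-on, AM-off) lateral FWHM pairs at random core-region targets."""
    study = study or default_study()
    synth = synth or FieldSynthesizer(study.tmap, study.array, study.sim)
    lam = study.lam
    targets = _random_workspace_targets(study, n_targets, seed, lat_limit=14.0,
                                        depth_range=(28.0, 58.0))
    pairs = []
    for tgt in targets:
        smp = collect_sample(study.tmap, study.array, tgt, study.sim,
                             element_tof_maps=synth.element_tof_maps)
        widths = []
        for am in (True, False):
            pats = modulation_patterns(smp.tof, smp.amplitude,
                                       period=study.sim.period, am=am)
            fld = synth.field(pats.psi,
                              region=(tgt[0] - 8, tgt[0] + 8,
                                      tgt[1] - 8, tgt[1] + 8), cell_size=0.1)
            widths.append(lateral_fwhm(fld, tgt, span=3.5 * lam,
                                       direction=study.array.axis))
        pairs.append(widths)
    return np.asarray(pairs)   # column 0: AM on, column 1: AM off


def trapping_experiment(seed: int = 0, field_max_pa: float = 15000.0,
                        t_end: float = 0.2, n_bubbles: int = 10
                        ) -> SimpleNamespace:
    """Microbubble capture by a twin trap in the pulsatile microvessel.

    Uses a broadside (pose 0) array so the vessel runs parallel to the
    array plane through the target; the twin field is scaled to the demo
    working pressure.  Returns initial/final mean distances to the nearest
    antinode along the vessel centreline.
    """
    cfg = RunConfig()
    sim = cfg.simulation.build()
    tmap = cfg.phantom.build(sim.frequency)
    lam = sim.wavelength_water
    array = place_array(tmap, cfg.array.n, cfg.array.element_diameter_mm,
                        cfg.array.gap_mm, (60.0, 10.0), 0.0)
    target = np.array([60.0, 53.0])
    synth = FieldSynthesizer(tmap, array, sim)
    smp = collect_sample(tmap, array, target, sim,
                         element_tof_maps=synth.element_tof_maps)
    pats = modulation_patterns(smp.tof, smp.amplitude, period=sim.period,
                               trap="twin", am=True)
    fld = synth.field(pats.psi,
                      region=(target[0] - 4 * lam, target[0] + 4 * lam,
                              target[1] - lam, target[1] + lam),
                      cell_size=lam / 30.0)
    fld = PressureField(fld.complex_pressure
                        * (field_max_pa / np.abs(fld.complex_pressure).max()),
                        fld.cell_size, fld.origin)
    antinodes = mb.vessel_antinodes(fld, target[1])
    flow = mb.FlowModel()
    result = mb.simulate_trapping(
        fld, flow, n_bubbles, dt=1e-4, t_end=t_end, seed=seed,
        vessel_y=target[1], frequency_mhz=sim.frequency,
        x_range=(target[0] - 2 * lam, target[0] + 2 * lam))

    def mean_distance(pos):
        return float(np.abs(pos[:, 0][:, None]
                            - antinodes[:, 0][None, :]).min(axis=1).mean())

    return SimpleNamespace(
        result=result, antinodes=antinodes,
        initial_distance=mean_distance(result.positions[0]),
        final_distance=mean_distance(result.positions[-1]))
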