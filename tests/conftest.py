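"""Shared fixtures: the default study geometry and (expensive) trained models.

Heavy objects are session-scoped so the full-size dataset is collected once
and the two surrogates are trained once for all tests that need them.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from sonotrap.config import RunConfig
from sonotrap.dataset import build_dataset, split_dataset
from sonotrap.phantom import build_layered_phantom
from sonotrap.surrogate import build_model, evaluate, train
from sonotrap.wavesim import FieldSynthesizer


@pytest.fixture(scope="session")
def study():
    """Default study geometry: phantom, array, workspace, sampling plan."""
    cfg = RunConfig()
    sim = cfg.simulation.build()
    tmap = cfg.phantom.build(sim.frequency)
    array = cfg.array.build(tmap)
    ws = cfg.workspace.build(array, sim)
    plan = cfg.sampling.build(ws, sim)
    return SimpleNamespace(cfg=cfg, sim=sim, tmap=tmap, array=array,
                           ws=ws, plan=plan,
                           lam=sim.wavelength_water)


@pytest.fixture(scope="session")
def study_dataset(study):
    """Full time-reversal dataset at one sample per wavelength, split."""
    ds = build_dataset(study.tmap, study.array, study.plan, study.sim)
    return split_dataset(ds, seed=1)


@pytest.fixture(scope="session")
def trained_models(study_dataset):
    """Both surrogates trained on the study dataset, with error reports."""
    models = {}
    reports = {}
    for kind in ("tof", "amplitude"):
        model = build_model(kind, study_dataset.n, seed=1)
        train(model, study_dataset)
        models[kind] = model
        reports[kind] = evaluate(model, study_dataset)
    return SimpleNamespace(models=models, reports=reports, ds=study_dataset)


@pytest.fixture(scope="session")
def synthesizer(study):
    """Field synthesizer for the study geometry (8 eikonal solves, cached)."""
    return FieldSynthesizer(study.tmap, study.array, study.sim)


@pytest.fixture()
def water_map():
    """Small homogeneous water map (resolution check relaxed)."""
    return build_layered_phantom([("water", 60.0, 1500.0, 1000.0, 0.0)],
                                 cell_size=0.3, extent=(60.0, 60.0),
                                 frequency_mhz=None)
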