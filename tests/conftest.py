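"""Shared fixtures.

The heavy end-to-end objects (phantom, noiseless signal, fitted model field,
reconstructed pathway) are session-scoped so the acceptance checks and the
module tests share a single computation.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from somatotract import (
    InterpConfig,
    TrackingConfig,
    fit_ball_stick,
    make_default_geometry,
    make_default_scheme,
    rasterize_bundles,
    reconstruct_pathway,
    simulate_signal,
)
from somatotract.phantom import SUBDIVISIONS
from somatotract.pipeline import _slice_levels
from somatotract.somatotopy import envelope, extract_fascicles


@pytest.fixture(scope="session")
def scheme():
    return make_default_scheme(90, (1000.0, 2000.0, 3000.0), 6, seed=0)


@pytest.fixture(scope="session")
def phantom():
    bundles, params = make_default_geometry()
    truth = rasterize_bundles(bundles, params)
    return SimpleNamespace(bundles=bundles, params=params, truth=truth)


@pytest.fixture(scope="session")
def noiseless_dwi(phantom, scheme):
    return simulate_signal(phantom.truth, scheme, snr=np.inf, seed=0)


@pytest.fixture(scope="session")
def model_field(noiseless_dwi, phantom):
    return fit_ball_stick(noiseless_dwi, phantom.truth.brain_mask, seed=0)


@pytest.fixture(scope="session")
def pathway(model_field, phantom):
    truth = phantom.truth
    return reconstruct_pathway(
        model_field,
        truth.roi_m1_labels > 0,
        truth.roi_ic,
        truth.roi_stn,
        truth.brain_mask,
        InterpConfig(),
        TrackingConfig(rng_seed=0),
    )


@pytest.fixture(scope="session")
def somato(pathway, phantom):
    """Fascicles, envelopes and the axial analysis levels of the phantom run."""
    truth = phantom.truth
    fset = extract_fascicles(pathway, truth.roi_m1_labels)
    envs = {
        name: envelope(fset[name], truth.grid_shape, truth.affine, name=name)
        for name in SUBDIVISIONS
    }
    levels = _slice_levels(truth, phantom.params)
    return SimpleNamespace(fset=fset, envelopes=envs, levels=levels)


@pytest.fixture(scope="session")
def reduced_runs(tmp_path_factory):
    """Two reduced-pipeline runs with the same seed, written to two dirs."""
    from somatotract.pipeline import PipelineConfig, run_pipeline

    outs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"reduced_{tag}")
        cfg = PipelineConfig(seed=3, out_dir=str(out)).reduced()
        summary = run_pipeline(cfg)
        outs.append(SimpleNamespace(out=out, summary=summary))
    return outs
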