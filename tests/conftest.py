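"""Shared fixtures: the default montage/paradigm and reusable simulated subjects."""

import numpy as np
import pytest
from hypothesis import settings

import nirsfeed as nf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def layout():
    return nf.default_layout()


@pytest.fixture(scope="session")
def paradigm():
    return nf.default_paradigm()


@pytest.fixture(scope="session")
def short_paradigm():
    """A tiny block design for fast I/O and epoching tests."""
    return nf.Paradigm(baseline_s=10.0, n_trials=2, task_s=5.0, rest_s=5.0)


@pytest.fixture(scope="session")
def responder_subject():
    """One default-condition responder: recording plus ground truth."""
    rec, truth = nf.simulate_subject(nf.SimulationConfig(seed=1234))
    return rec, truth


@pytest.fixture(scope="session")
def null_subject():
    cfg = nf.SimulationConfig(seed=4321, neural_amplitude=0.0)
    rec, truth = nf.simulate_subject(cfg)
    return rec, truth


@pytest.fixture(scope="session")
def responder_hemo(responder_subject):
    rec, _ = responder_subject
    return nf.preprocess_recording(rec)


@pytest.fixture(scope="session")
def noiseless_subject():
    """No noise, no confounds: neural signal only, for exact identities."""
    cfg = nf.SimulationConfig(
        seed=7, noise_sd=0.0, scalp_walk_sd=0.0, scalp_coupling=0.0,
        mayer_amplitude=0.0, breathing_amplitude=0.0, cardiac_amplitude=0.0,
        drift_slope=0.0,
    )
    rec, truth = nf.simulate_subject(cfg)
    return rec, truth


@pytest.fixture(scope="session")
def short_recording(layout, short_paradigm):
    """A small strictly positive recording for container round trips."""
    rng = np.random.default_rng(0)
    n = short_paradigm.n_samples(nf.probe_paradigm.DEFAULT_FS)
    inten = 1.0 + 0.05 * rng.random((len(layout.channels), 2, n))
    return nf.RawRecording(layout=layout, fs=nf.probe_paradigm.DEFAULT_FS,
                           intensities=inten, paradigm=short_paradigm,
                           meta={"subject_id": "t01"})
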