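"""Synthetic continuous-wave fNIRS generator with known ground truth.

A simulated subject's per-channel ΔHbO2 is the sum of

* a neural response — HRF-convolved 30-s task boxcars on the active
  channels, with ΔHbR = −hbr_ratio·ΔHbO2;
* a scalp process shared by every channel: a slow (<0.05 Hz) smoothed
  random walk plus sinusoidal physiological oscillations (Mayer waves
  0.09–0.1 Hz, breathing 0.2–0.5 Hz, cardiac 1–1.3 Hz) with per-subject
  random phases and log-normal amplitude jitter.  Long channels receive it
  with gain `scalp_coupling`; the 8-mm short channels see it exclusively;
* a linear drift on long channels.

Concentrations are pushed through the forward modified Beer–Lambert law to
optical density, Gaussian OD measurement noise is added, and intensities
are exponentiated around `baseline_intensity` — so the generator's output
is raw light intensity, exactly what the acquisition device would stream.

Cohort scenarios: ``responder`` (true neural activation on the 4 NF
channels), ``scalp_false_positive`` (no neural signal, but a task-locked
ingredient added to the scalp process so superficial blood flow mimics
activation — the confound short-channel regression exists to remove) and
``null`` (no neural signal, task-independent scalp).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal

from .glm import HrfModel, canonical_hrf, task_regressor
from .preprocess import DEFAULT_DPF, MbllConstants
from .probe_paradigm import (
    Paradigm,
    ProbeLayout,
    RawRecording,
    default_layout,
    default_paradigm,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "hemodynamic_truth",
    "simulate_subject",
    "simulate_cohort",
    "SCENARIOS",
]

SCENARIOS = ("responder", "scalp_false_positive", "null")

# task-locked scalp amplitude used by the scalp_false_positive scenario when
# the base config leaves it at 0 (µM peak, same normalisation as neural)
FALSE_POSITIVE_SCALP_AMPLITUDE = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs; frequencies must sit in their physiological bands."""

    seed: int = 0
    neural_amplitude: float = 0.5      # µM peak ΔHbO2 per active trial
    hbr_ratio: float = 0.25            # ΔHbR = −hbr_ratio · ΔHbO2
    active_channels: tuple[str, ...] | None = None  # default: the 4 NF channels
    active_trials: tuple[int, ...] | None = None    # 1-based; default: all
    scalp_coupling: float = 1.0        # long-channel gain of the scalp component
    scalp_task_amplitude: float = 0.0  # task-locked scalp ingredient (µM peak)
    scalp_walk_sd: float = 0.3         # sd of the slow scalp process (µM)
    scalp_hbr_ratio: float = 0.2       # scalp ΔHbR = ratio · scalp ΔHbO2
    mayer_freq: float = 0.095          # Hz, in [0.09, 0.1]
    breathing_freq: float = 0.3        # Hz, in [0.2, 0.5]
    cardiac_freq: float = 1.1          # Hz, in [1.0, 1.3]
    mayer_amplitude: float = 0.2       # µM-equivalent oscillation amplitudes
    breathing_amplitude: float = 0.1
    cardiac_amplitude: float = 0.2
    drift_slope: float = 2e-4          # µM/s linear drift on long channels
    noise_sd: float = 0.002            # Gaussian noise on optical density
    dpf: float = DEFAULT_DPF
    baseline_intensity: float = 1.0    # arbitrary units
    jitter_frequencies: bool = True    # cohorts: per-subject rates within the bands

    def __post_init__(self) -> None:
        if not 0.09 <= self.mayer_freq <= 0.1:
            raise ValueError("mayer_freq outside [0.09, 0.1] Hz")
        if not 0.2 <= self.breathing_freq <= 0.5:
            raise ValueError("breathing_freq outside [0.2, 0.5] Hz")
        if not 1.0 <= self.cardiac_freq <= 1.3:
            raise ValueError("cardiac_freq outside [1.0, 1.3] Hz")
        if self.scalp_coupling < 0 or self.noise_sd < 0:
            raise ValueError("scalp_coupling and noise_sd must be nonnegative")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")


@dataclass
class GroundTruth:
    """Noiseless constituents of a simulated recording, at the recording rate."""

    neural_hbo2: np.ndarray   # (n_channels, n_times)
    neural_hbr: np.ndarray
    scalp: np.ndarray         # (n_times,) shared scalp ΔHbO2 component
    active_trials: np.ndarray  # (n_trials,) bool
    active_channels: tuple[str, ...]
    fs: float


def _resolve_active(config: SimulationConfig, layout: ProbeLayout,
                    paradigm: Paradigm) -> tuple[list[str], list[int]]:
    channels = list(config.active_channels) if config.active_channels is not None else [
        c.name for c in layout.roi_channels("nf_dlpfc")]
    trials = list(config.active_trials) if config.active_trials is not None else list(
        range(1, paradigm.n_trials + 1))
    if any(t < 1 or t > paradigm.n_trials for t in trials):
        raise ValueError(f"active_trials outside 1..{paradigm.n_trials}")
    return channels, trials


def hemodynamic_truth(
    config: SimulationConfig,
    paradigm: Paradigm,
    hrf: HrfModel,
    layout: ProbeLayout | None = None,
) -> GroundTruth:
    """Noiseless neural ΔHbO2/ΔHbR per channel (active channels only non-zero)."""
    layout = layout or default_layout()
    fs = hrf.fs
    n = paradigm.n_samples(fs)
    channels, trials = _resolve_active(config, layout, paradigm)
    onsets = paradigm.onsets[[t - 1 for t in trials]]
    response = config.neural_amplitude * task_regressor(onsets, paradigm.task_s, hrf, n)
    n_ch = len(layout.channels)
    hbo2 = np.zeros((n_ch, n))
    for name in channels:
        hbo2[layout.index_of(name)] = response
    hbr = -config.hbr_ratio * hbo2
    active = np.zeros(paradigm.n_trials, dtype=bool)
    active[[t - 1 for t in trials]] = config.neural_amplitude != 0
    return GroundTruth(neural_hbo2=hbo2, neural_hbr=hbr,
                       scalp=np.zeros(n), active_trials=active,
                       active_channels=tuple(channels) if config.neural_amplitude != 0 else (),
                       fs=fs)


@lru_cache(maxsize=8)
def _walk_scale(n: int, fs: float) -> float:
    """Expected std of the demeaned low-passed walk (fixed-seed Monte Carlo).

    A deterministic scale keeps the process Gaussian; normalising each
    realisation by its own std would put every subject on a unit shell.
    """
    sos = signal.butter(2, 0.05, btype="lowpass", fs=fs, output="sos")
    ref = np.random.default_rng(1234567)
    stds = []
    for _ in range(8):
        w = signal.sosfiltfilt(sos, np.cumsum(ref.standard_normal(n)))
        stds.append((w - w.mean()).std())
    return float(np.mean(stds))


def _slow_walk(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Random walk low-passed below 0.05 Hz, scaled so its expected sd is `sd`."""
    if sd == 0:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    sos = signal.butter(2, 0.05, btype="lowpass", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, walk)
    slow = slow - slow.mean()
    return slow * (sd / _walk_scale(n, fs))


def _scalp_process(config: SimulationConfig, rng: np.random.Generator,
                   paradigm: Paradigm, hrf: HrfModel, n: int) -> np.ndarray:
    fs = hrf.fs
    t = np.arange(n) / fs
    scalp = _slow_walk(rng, n, fs, config.scalp_walk_sd)
    for freq, amp in ((config.mayer_freq, config.mayer_amplitude),
                      (config.breathing_freq, config.breathing_amplitude),
                      (config.cardiac_freq, config.cardiac_amplitude)):
        phase = rng.uniform(0, 2 * np.pi)
        jitter = float(np.exp(0.3 * rng.standard_normal()))
        scalp += amp * jitter * np.sin(2 * np.pi * freq * t + phase)
    if config.scalp_task_amplitude:
        scalp += config.scalp_task_amplitude * task_regressor(
            paradigm.onsets, paradigm.task_s, hrf, n)
    return scalp


def simulate_subject(
    config: SimulationConfig,
    layout: ProbeLayout | None = None,
    paradigm: Paradigm | None = None,
    fs: float | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Generate one subject's raw recording; identical seeds give identical output."""
    from .probe_paradigm import DEFAULT_FS

    layout = layout or default_layout()
    paradigm = paradigm or default_paradigm()
    fs = fs or DEFAULT_FS
    rng = np.random.default_rng(config.seed)
    hrf = canonical_hrf(fs)
    truth = hemodynamic_truth(config, paradigm, hrf, layout)
    n = truth.neural_hbo2.shape[1]
    t = np.arange(n) / fs

    scalp = _scalp_process(config, rng, paradigm, hrf, n)
    truth.scalp = scalp

    n_ch = len(layout.channels)
    hbo2 = np.empty((n_ch, n))
    hbr = np.empty((n_ch, n))
    for i, ch in enumerate(layout.channels):
        if ch.kind == "long":
            hbo2[i] = truth.neural_hbo2[i] + config.scalp_coupling * scalp \
                + config.drift_slope * t
            hbr[i] = truth.neural_hbr[i] + config.scalp_hbr_ratio \
                * (config.scalp_coupling * scalp)
        else:
            hbo2[i] = scalp
            hbr[i] = config.scalp_hbr_ratio * scalp

    from .preprocess import forward_mbll

    constants = MbllConstants.for_layout(layout, dpf=config.dpf)
    od = forward_mbll(hbo2, hbr, constants)
    if config.noise_sd > 0:
        od = od + rng.normal(0.0, config.noise_sd, size=od.shape)
    intensities = config.baseline_intensity * np.power(10.0, -od)
    if not np.all(np.isfinite(intensities)):
        raise ValueError("simulated intensities are non-finite; check amplitudes")
    rec = RawRecording(layout=layout, fs=fs, intensities=intensities,
                       paradigm=paradigm, meta={"seed": config.seed})
    return rec, truth


def _child_seed(base_seed: int, i: int) -> int:
    return int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_subjects: int,
    scenario: str,
    base_config: SimulationConfig | None = None,
    layout: ProbeLayout | None = None,
    paradigm: Paradigm | None = None,
) -> list[tuple[RawRecording, GroundTruth]]:
    """Simulate a cohort under one scenario with deterministic per-subject seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    base = base_config or SimulationConfig()
    out = []
    for i in range(n_subjects):
        cfg = replace(base, seed=_child_seed(base.seed, i))
        if base.jitter_frequencies:
            # physiological rates differ across people; draw each subject's
            # from the population band (deterministic per subject seed)
            frng = np.random.default_rng(_child_seed(base.seed, 10_000 + i))
            cfg = replace(
                cfg,
                mayer_freq=frng.uniform(0.09, 0.1),
                breathing_freq=frng.uniform(0.2, 0.5),
                cardiac_freq=frng.uniform(1.0, 1.3),
            )
        if scenario == "responder":
            cfg = replace(cfg, scalp_task_amplitude=0.0)
        elif scenario == "scalp_false_positive":
            amp = base.scalp_task_amplitude or FALSE_POSITIVE_SCALP_AMPLITUDE
            cfg = replace(cfg, neural_amplitude=0.0, scalp_task_amplitude=amp)
        else:  # null
            cfg = replace(cfg, neural_amplitude=0.0, scalp_task_amplitude=0.0)
        out.append(simulate_subject(cfg, layout, paradigm))
    return out
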