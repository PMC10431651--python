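"""Optical-density conversion, band-pass filtering, resampling and the MBLL.

Offline pipeline order (fixed): raw intensity → optical density → order-3
Butterworth band-pass (either 0.01–0.09 Hz or 0.01–0.2 Hz) → polyphase
resampling to 4 Hz → modified Beer–Lambert law (MBLL) giving ΔHbO2/ΔHbR in
µM.  The MBLL is linear, so it commutes with the filtering; the chosen order
matches how the analysis is run.

Optical density is defined against the per-channel, per-wavelength mean
intensity over the whole recording: OD(t) = −log10(I(t)/Ī).  Concentration
changes are therefore relative to the recording mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .probe_paradigm import Channel, ProbeLayout, RawRecording, ValidationError

__all__ = [
    "OpticalDensity",
    "HemoTimeSeries",
    "MbllConstants",
    "DEFAULT_DPF",
    "EXTINCTION_UM_CM",
    "intensity_to_od",
    "bandpass",
    "resample_4hz",
    "mbll",
    "forward_mbll",
    "preprocess_recording",
    "BANDS",
]

ANALYSIS_FS = 4.0  # Hz, offline analysis rate
BANDS = {"narrow": (0.01, 0.09), "wide": (0.01, 0.2)}  # Hz
FILTER_ORDER = 3
DEFAULT_DPF = 6.0  # differential pathlength factor, both wavelengths

# Molar extinction coefficients (base-10) of HbO2 / HbR at 760 and 850 nm,
# from the compiled Gratzer–Kollias tabulation widely used for CW-NIRS,
# converted to µM⁻¹·cm⁻¹.  Rows: wavelength (760, 850); cols: (HbO2, HbR).
EXTINCTION_UM_CM = np.array(
    [
        [1486.5865e-6, 3843.707e-6],
        [2526.391e-6, 1798.643e-6],
    ]
)


@dataclass
class OpticalDensity:
    """Dimensionless OD, (n_channels, 2, n_times)."""

    values: np.ndarray
    fs: float
    provenance: str = "whole-recording mean intensity reference"

    @property
    def n_times(self) -> int:
        return self.values.shape[2]


@dataclass
class MbllConstants:
    """Extinction matrix (2×2, µM⁻¹·cm⁻¹), per-wavelength DPF, per-channel distance (cm)."""

    extinction: np.ndarray
    dpf: tuple[float, float]
    distances_cm: np.ndarray

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        self.distances_cm = np.atleast_1d(np.asarray(self.distances_cm, dtype=float))
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2 (wavelength x chromophore)")
        if np.linalg.cond(self.extinction) >= 1e4:
            raise ValueError("extinction matrix is ill-conditioned (cond >= 1e4)")

    @classmethod
    def for_layout(cls, layout: ProbeLayout, dpf: float = DEFAULT_DPF) -> "MbllConstants":
        dist = np.array([c.distance_mm / 10.0 for c in layout.channels])
        return cls(EXTINCTION_UM_CM.copy(), (dpf, dpf), dist)

    @classmethod
    def for_channels(cls, channels: Sequence[Channel], dpf: float = DEFAULT_DPF) -> "MbllConstants":
        dist = np.array([c.distance_mm / 10.0 for c in channels])
        return cls(EXTINCTION_UM_CM.copy(), (dpf, dpf), dist)


@dataclass
class HemoTimeSeries:
    """ΔHbO2/ΔHbR per channel (µM), at the analysis rate."""

    hbo2: np.ndarray  # (n_channels, n_times)
    hbr: np.ndarray
    fs: float
    filter_band: tuple[float, float] | None
    channels: tuple[Channel, ...]
    filter_fs: float | None = None  # rate at which the band-pass was applied

    def __post_init__(self) -> None:
        if self.hbo2.shape != self.hbr.shape:
            raise ValueError("hbo2 and hbr must share shape")
        if len(self.channels) != self.hbo2.shape[0]:
            raise ValueError("channel list does not match array shape")

    @property
    def n_times(self) -> int:
        return self.hbo2.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(name)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def intensity_to_od(rec: RawRecording) -> OpticalDensity:
    """OD(t) = −log10(I(t)/Ī), Ī the whole-recording mean per channel/wavelength."""
    I = rec.intensities
    if np.any(I <= 0):
        raise ValidationError("intensities must be strictly positive")
    ref = I.mean(axis=2, keepdims=True)
    od = -np.log10(I / ref)
    return OpticalDensity(values=od, fs=rec.fs)


def _butter_sos(band: tuple[float, float], fs: float) -> np.ndarray:
    low, high = band
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz at or above Nyquist ({nyq} Hz)")
    if low <= 0 or low >= high:
        raise ValueError(f"invalid band {band}")
    return signal.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    mode: str = "zero_phase",
) -> np.ndarray:
    """Order-3 Butterworth band-pass along the last axis.

    ``zero_phase`` runs the filter forward and backward (no phase lag,
    effective order 6) with reflect padding; ``causal`` is a single forward
    pass with zero initial state, as a real-time system would apply it.
    """
    sos = _butter_sos(band, fs)
    x = np.asarray(x, dtype=float)
    if mode == "zero_phase":
        # pad by one filter length — a full period of the low cutoff — so the
        # long high-pass transient never leaks into the record
        padlen = min(int(round(fs / band[0])), x.shape[-1] - 1)
        return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
    if mode == "causal":
        return signal.sosfilt(sos, x, axis=-1)
    raise ValueError(f"unknown mode {mode!r}")


def resample_4hz(x: np.ndarray, fs_in: float) -> tuple[np.ndarray, float]:
    """Polyphase rational resampling to 4 Hz with the built-in anti-alias FIR."""
    if fs_in <= 0:
        raise ValueError("fs_in must be positive")
    if fs_in == ANALYSIS_FS:
        return np.asarray(x, dtype=float), ANALYSIS_FS
    frac = Fraction(ANALYSIS_FS).limit_denominator(10**6) / Fraction(fs_in).limit_denominator(10**6)
    y = signal.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator,
                             axis=-1, padtype="line")
    return y, ANALYSIS_FS


def mbll(od: OpticalDensity, constants: MbllConstants) -> HemoTimeSeries:
    """Invert the MBLL: solve ΔOD_λ = (ε·ΔHb)·d·DPF_λ for (ΔHbO2, ΔHbR) per sample."""
    raise_if_wrong = od.values.shape[0] != constants.distances_cm.size
    if raise_if_wrong:
        raise ValueError("constants.distances_cm does not match channel count")
    return _mbll_arrays(od.values, od.fs, constants, channels=None)


def _mbll_arrays(od_values, fs, constants, channels):
    n_ch = od_values.shape[0]
    einv = np.linalg.inv(constants.extinction)
    dpf = np.asarray(constants.dpf)
    hbo2 = np.empty((n_ch, od_values.shape[2]))
    hbr = np.empty_like(hbo2)
    for i in range(n_ch):
        L = constants.distances_cm[i] * dpf  # per-wavelength effective pathlength (cm)
        od_per_path = od_values[i] / L[:, None]
        conc = einv @ od_per_path
        hbo2[i], hbr[i] = conc[0], conc[1]
    return HemoTimeSeries(
        hbo2=hbo2, hbr=hbr, fs=fs, filter_band=None,
        channels=tuple(channels) if channels is not None else tuple(
            Channel(f"S{i+1}", "Dx", "long", constants.distances_cm[i] * 10, "other_frontal")
            for i in range(n_ch)
        ),
    )


def forward_mbll(
    hbo2: np.ndarray,
    hbr: np.ndarray,
    constants: MbllConstants,
) -> np.ndarray:
    """Exact linear forward map: concentrations (µM) → ΔOD (n_ch, 2, n_t)."""
    hbo2 = np.atleast_2d(np.asarray(hbo2, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    n_ch, n_t = hbo2.shape
    dpf = np.asarray(constants.dpf)
    od = np.empty((n_ch, 2, n_t))
    for i in range(n_ch):
        conc = np.vstack([hbo2[i], hbr[i]])  # (2, n_t)
        L = constants.distances_cm[i] * dpf
        od[i] = (constants.extinction @ conc) * L[:, None]
    return od


def preprocess_recording(
    rec: RawRecording,
    band: tuple[float, float] | None = BANDS["narrow"],
    mode: str = "zero_phase",
    dpf: float = DEFAULT_DPF,
    resample: bool = True,
) -> HemoTimeSeries:
    """Full offline chain: OD → band-pass → 4 Hz resample → MBLL.

    ``band=None`` / ``resample=False`` disable the corresponding stage (used
    by diagnostics and by forward/inverse consistency checks).
    """
    od = intensity_to_od(rec)
    values, fs = od.values, od.fs
    if band is not None:
        values = bandpass(values, fs, band, mode=mode)
    if resample:
        values, fs = resample_4hz(values, fs)
    constants = MbllConstants.for_layout(rec.layout, dpf=dpf)
    hemo = _mbll_arrays(values, fs, constants, channels=rec.layout.channels)
    hemo.filter_band = band
    hemo.filter_fs = od.fs if band is not None else None
    return hemo
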