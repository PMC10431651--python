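"""Causal, streaming computation of the neurofeedback signal and gauge.

The online chain mirrors what the acquisition loop can actually do, sample
by sample, on the four DL-PFC neurofeedback channels:

1. optical density against a running-mean intensity reference (causal: the
   reference at sample t is the mean of samples 0..t),
2. MBLL conversion to ΔHbO2 with the same pinned constants as offline,
3. causal order-3 Butterworth band-pass 0.01–0.2 Hz,
4. 2-s moving average,
5. mean over the 4 NF channels, minus the trial baseline — the mean of the
   5 s preceding the current task onset, recomputed at every onset.

The feedback value is mapped to gauge height through a smooth saturating
tanh: height = 0.5 + 0.5·tanh(v/v0), so no concentration change shows the
gauge at half height, positive changes fill the top half, and the ends
compress rather than saturate.  Streaming output is chunking-invariant:
replaying a recording in any chunk sizes reproduces the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .preprocess import MbllConstants
from .probe_paradigm import Paradigm, ProbeLayout, RawRecording

__all__ = [
    "gauge_map",
    "FeedbackSample",
    "OnlineProcessor",
    "replay",
]

ONLINE_BAND = (0.01, 0.2)  # Hz
ONLINE_FILTER_ORDER = 3
MA_WINDOW_S = 2.0
BASELINE_WINDOW_S = 5.0
DEFAULT_V0 = 1.0  # µM, gauge compression scale


def gauge_map(v, v0: float = DEFAULT_V0):
    """Feedback value (µM) → gauge height in (0, 1); 0 maps to half height."""
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    return 0.5 + 0.5 * np.tanh(np.asarray(v, dtype=float) / v0)


@dataclass(frozen=True)
class FeedbackSample:
    t: float          # s from recording start
    value: float      # baseline-subtracted mean NF-channel ΔHbO2 (µM)
    height: float     # gauge height in (0, 1)
    phase: str        # baseline | task | rest
    displayed: bool   # gauge is shown to the participant only during task


class OnlineProcessor:
    """Stateful streaming processor for the online neurofeedback signal.

    Feed raw dual-wavelength intensities of the NF channels in time order via
    :meth:`step`; chunk boundaries do not affect the output.
    """

    def __init__(
        self,
        layout: ProbeLayout,
        paradigm: Paradigm,
        fs: float,
        channels: Sequence[str] | None = None,
        v0: float = DEFAULT_V0,
        dpf: float | None = None,
    ) -> None:
        self.layout = layout
        self.paradigm = paradigm
        self.fs = fs
        names = list(channels) if channels is not None else [
            c.name for c in layout.roi_channels("nf_dlpfc")]
        self.channel_names = names
        self.channel_idx = [layout.index_of(n) for n in names]
        chans = [layout.channels[i] for i in self.channel_idx]
        self.constants = MbllConstants.for_channels(
            chans, **({"dpf": dpf} if dpf is not None else {}))
        self._einv = np.linalg.inv(self.constants.extinction)
        self._pathlen = self.constants.distances_cm[:, None] * np.asarray(self.constants.dpf)

        self.v0 = v0
        n_ch = len(names)
        self._sos = signal.butter(ONLINE_FILTER_ORDER, ONLINE_BAND, btype="bandpass",
                                  fs=fs, output="sos")
        self._zi = np.zeros((n_ch, self._sos.shape[0], 2))
        ma_len = max(int(round(MA_WINDOW_S * fs)), 1)
        self._ma_b = np.full(ma_len, 1.0 / ma_len)
        self._ma_zi = np.zeros((n_ch, ma_len - 1))

        self._count = 0                      # samples consumed
        self._isum = np.zeros((n_ch, 2))     # running intensity sums
        self._base_len = int(round(BASELINE_WINDOW_S * fs))
        self._recent = np.zeros(self._base_len)  # ring buffer of combined signal
        self._recent_n = 0
        self._baseline = 0.0
        self._onset_samples = set(int(np.ceil(t * fs)) for t in paradigm.onsets)

    def step(self, samples: np.ndarray, timestamps: np.ndarray | None = None) -> list[FeedbackSample]:
        """Process a chunk of raw intensities, shape (n_nf_channels, 2, n_new).

        `timestamps`, if given, must continue the sample clock; a repeated or
        earlier timestamp raises.
        """
        x = np.asarray(samples, dtype=float)
        if x.ndim == 2:
            x = x[:, :, None]
        n_ch = len(self.channel_idx)
        if x.shape[0] != n_ch or x.shape[1] != 2:
            raise ValueError(f"expected shape ({n_ch}, 2, n), got {x.shape}")
        n_new = x.shape[2]
        if timestamps is not None:
            ts = np.atleast_1d(np.asarray(timestamps, dtype=float))
            expected = (self._count + np.arange(n_new)) / self.fs
            if np.any(np.diff(ts) <= 0) or (self._count > 0 and ts[0] <= (self._count - 1) / self.fs):
                raise ValueError("out-of-order timestamps")
            if not np.allclose(ts, expected, atol=0.5 / self.fs):
                raise ValueError("timestamps do not follow the sample clock")

        out: list[FeedbackSample] = []
        for j in range(n_new):
            i_t = x[:, :, j]
            if np.any(i_t <= 0):
                raise ValueError("non-positive intensity sample")
            self._isum += i_t
            self._count += 1
            ref = self._isum / self._count
            od = -np.log10(i_t / ref)               # (n_ch, 2)
            od_per_path = od / self._pathlen
            hbo2 = (self._einv @ od_per_path.T)[0]  # µM per channel

            filt = np.empty(len(hbo2))
            for c in range(len(hbo2)):
                y, self._zi[c] = signal.sosfilt(self._sos, hbo2[c: c + 1], zi=self._zi[c])
                filt[c] = y[0]
                y2, self._ma_zi[c] = signal.lfilter(self._ma_b, [1.0], filt[c: c + 1],
                                                    zi=self._ma_zi[c])
                filt[c] = y2[0]
            combined = float(filt.mean())

            k = self._count - 1  # 0-based index of this sample
            if k in self._onset_samples and self._recent_n >= 1:
                m = min(self._recent_n, self._base_len)
                self._baseline = float(self._recent[-m:].mean()) if m else 0.0
            # push AFTER the onset check: baseline covers samples strictly before onset
            self._recent = np.roll(self._recent, -1)
            self._recent[-1] = combined
            self._recent_n += 1

            t = k / self.fs
            phase = self.paradigm.phase_at(t)
            v = combined - self._baseline
            out.append(FeedbackSample(t=t, value=v, height=float(gauge_map(v, self.v0)),
                                      phase=phase, displayed=phase == "task"))
        return out


def replay(
    rec: RawRecording,
    channels: Sequence[str] | None = None,
    chunk: int = 64,
    v0: float = DEFAULT_V0,
):
    """Replay a recording through the online chain; returns a DataFrame log."""
    import pandas as pd

    proc = OnlineProcessor(rec.layout, rec.paradigm, rec.fs, channels=channels, v0=v0)
    x = rec.intensities[proc.channel_idx]
    rows = []
    for start in range(0, x.shape[2], chunk):
        for s in proc.step(x[:, :, start: start + chunk]):
            rows.append((s.t, s.value, s.height, s.phase, s.displayed))
    return pd.DataFrame(rows, columns=["t", "value", "height", "phase", "displayed"])
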