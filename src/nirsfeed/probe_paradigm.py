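"""Probe geometry, task paradigm and file I/O for continuous-wave fNIRS.

The montage modelled here is an 8-source / 8-detector prefrontal cap:
sixteen long channels over the frontal lobe (four of which, S1-D1, S1-D2,
S7-D5 and S7-D7, cover the bilateral dorsolateral prefrontal cortex and
drive the neurofeedback gauge), one long channel over the motor cortex as a
control region, and eight 8-mm short channels — one per source, all
terminating on detector D8 — that see only scalp hemodynamics.

Recordings are stored either in SNIRF (the community HDF5 container for
NIRS) or in a plain CSV dialect: one CSV of intensities with a
``<stem>.meta.json`` sidecar carrying layout, paradigm and metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

__all__ = [
    "Channel",
    "ProbeLayout",
    "Paradigm",
    "RawRecording",
    "FormatError",
    "ValidationError",
    "ROIS",
    "default_layout",
    "default_paradigm",
    "read_recording",
    "write_recording",
]

DEFAULT_FS = 7.8125  # Hz, NIRScout XP sample rate
DEFAULT_WAVELENGTHS = (760.0, 850.0)  # nm

ROIS = ("nf_dlpfc", "other_frontal", "motor", "scalp")

SHORT_DISTANCE_MM = 8.0
LONG_DISTANCE_RANGE_MM = (30.0, 42.0)


class FormatError(ValueError):
    """A container file is malformed or missing a required field."""


class ValidationError(ValueError):
    """Data violate a domain invariant (e.g. non-positive intensity)."""


@dataclass(frozen=True)
class Channel:
    """A source-detector pair with its geometry and region label."""

    source: str
    detector: str
    kind: str  # "long" | "short"
    distance_mm: float
    roi: str

    @property
    def name(self) -> str:
        return f"{self.source}-{self.detector}"


@dataclass(frozen=True)
class ProbeLayout:
    sources: tuple[str, ...]
    detectors: tuple[str, ...]
    channels: tuple[Channel, ...]
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        longs = [c for c in self.channels if c.kind == "long"]
        shorts = [c for c in self.channels if c.kind == "short"]
        if len(longs) != 17:
            raise ValidationError(f"expected 17 long channels, got {len(longs)}")
        if len(shorts) != 8:
            raise ValidationError(f"expected 8 short channels, got {len(shorts)}")
        lo, hi = LONG_DISTANCE_RANGE_MM
        for c in longs:
            if not lo <= c.distance_mm <= hi:
                raise ValidationError(
                    f"long channel {c.name} distance {c.distance_mm} mm outside [{lo}, {hi}]"
                )
            if c.roi not in ("nf_dlpfc", "other_frontal", "motor"):
                raise ValidationError(f"long channel {c.name} has roi {c.roi!r}")
        for c in shorts:
            if c.distance_mm != SHORT_DISTANCE_MM:
                raise ValidationError(
                    f"short channel {c.name} distance must be {SHORT_DISTANCE_MM} mm"
                )
            if c.roi != "scalp":
                raise ValidationError(f"short channel {c.name} has roi {c.roi!r}")
        nf = {c.name for c in longs if c.roi == "nf_dlpfc"}
        if nf != {"S1-D1", "S1-D2", "S7-D5", "S7-D7"}:
            raise ValidationError(f"nf_dlpfc ROI must be the 4 NF channels, got {nf}")
        if sum(c.roi == "other_frontal" for c in longs) != 12:
            raise ValidationError("other_frontal ROI must have 12 channels")
        if sum(c.roi == "motor" for c in longs) != 1:
            raise ValidationError("motor ROI must have 1 channel")
        short_sources = sorted(c.source for c in shorts)
        if short_sources != sorted(set(short_sources)) or set(short_sources) != set(self.sources):
            raise ValidationError("each source must have exactly one short channel")

    # -- convenience --------------------------------------------------------
    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def long_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.kind == "long"]

    def short_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.kind == "short"]

    def roi_channels(self, roi: str) -> list[Channel]:
        if roi not in ROIS:
            raise ValueError(f"unknown roi {roi!r}; expected one of {ROIS}")
        return [c for c in self.channels if c.roi == roi]

    def index_of(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(name)

    def short_for_source(self, source: str) -> Channel:
        """The scalp (short) channel sharing `source` — the nuisance partner."""
        for c in self.channels:
            if c.kind == "short" and c.source == source:
                return c
        raise KeyError(source)


def default_layout() -> ProbeLayout:
    """The study montage: 16 frontal + 1 motor long channels, 8 short channels.

    Exact per-channel distances are not part of the montage definition beyond
    the 30-42 mm long-channel range; all long channels default to 30 mm.
    """
    nf = ["S1-D1", "S1-D2", "S7-D5", "S7-D7"]
    other_frontal = [
        "S2-D1", "S2-D2", "S2-D3", "S3-D2", "S3-D3", "S4-D3",
        "S4-D4", "S5-D4", "S5-D5", "S6-D5", "S6-D6", "S6-D7",
    ]
    motor = ["S8-D6"]
    channels: list[Channel] = []
    for name in nf + other_frontal + motor:
        s, d = name.split("-")
        roi = "nf_dlpfc" if name in nf else ("motor" if name in motor else "other_frontal")
        channels.append(Channel(s, d, "long", 30.0, roi))
    for i in range(1, 9):
        channels.append(Channel(f"S{i}", "D8", "short", SHORT_DISTANCE_MM, "scalp"))
    return ProbeLayout(
        sources=tuple(f"S{i}" for i in range(1, 9)),
        detectors=tuple(f"D{i}" for i in range(1, 9)),
        channels=tuple(channels),
    )


@dataclass(frozen=True)
class Paradigm:
    """Block design: an initial rest baseline, then alternating task/rest trials."""

    baseline_s: float = 120.0
    n_trials: int = 15
    task_s: float = 30.0
    rest_s: float = 30.0

    @property
    def onsets(self) -> np.ndarray:
        """Task onset times (s), one per trial."""
        return self.baseline_s + np.arange(self.n_trials) * (self.task_s + self.rest_s)

    @property
    def rest_onsets(self) -> np.ndarray:
        return self.onsets + self.task_s

    def total_duration(self) -> float:
        return self.baseline_s + self.n_trials * (self.task_s + self.rest_s)

    def n_samples(self, fs: float) -> int:
        return int(np.ceil(self.total_duration() * fs))

    def phase_at(self, t: float) -> str:
        """'baseline', 'task' or 'rest' at time t (s from recording start)."""
        if t < self.baseline_s:
            return "baseline"
        cycle = (t - self.baseline_s) % (self.task_s + self.rest_s)
        if (t - self.baseline_s) >= self.n_trials * (self.task_s + self.rest_s):
            return "rest"
        return "task" if cycle < self.task_s else "rest"


def default_paradigm() -> Paradigm:
    """120 s baseline then 15 trials of 30 s task + 30 s rest (1020 s total)."""
    return Paradigm()


@dataclass
class RawRecording:
    """Raw dual-wavelength intensities, (n_channels, 2, n_times), arbitrary units."""

    layout: ProbeLayout
    fs: float
    intensities: np.ndarray
    paradigm: Paradigm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_ch = len(self.layout.channels)
        if self.intensities.ndim != 3 or self.intensities.shape[:2] != (n_ch, 2):
            raise ValidationError(
                f"intensities must have shape ({n_ch}, 2, n_times), got {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")
        if np.any(self.intensities <= 0):
            raise ValidationError("intensities must be strictly positive")
        if self.intensities.shape[2] < self.paradigm.total_duration() * self.fs - 1:
            raise ValidationError("recording shorter than the paradigm")

    @property
    def n_times(self) -> int:
        return self.intensities.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------

def _layout_to_dict(layout: ProbeLayout) -> dict:
    return {
        "sources": list(layout.sources),
        "detectors": list(layout.detectors),
        "wavelengths": list(layout.wavelengths),
        "channels": [
            {"source": c.source, "detector": c.detector, "kind": c.kind,
             "distance_mm": c.distance_mm, "roi": c.roi}
            for c in layout.channels
        ],
    }


def _layout_from_dict(d: Mapping) -> ProbeLayout:
    try:
        channels = tuple(
            Channel(c["source"], c["detector"], c["kind"], float(c["distance_mm"]), c["roi"])
            for c in d["channels"]
        )
        return ProbeLayout(
            sources=tuple(d["sources"]),
            detectors=tuple(d["detectors"]),
            channels=channels,
            wavelengths=tuple(float(w) for w in d["wavelengths"]),
        )
    except KeyError as e:
        raise FormatError(f"layout description missing field {e.args[0]!r}") from e


def _paradigm_to_dict(p: Paradigm) -> dict:
    return {"baseline_s": p.baseline_s, "n_trials": p.n_trials,
            "task_s": p.task_s, "rest_s": p.rest_s}


def _paradigm_from_dict(d: Mapping) -> Paradigm:
    try:
        return Paradigm(float(d["baseline_s"]), int(d["n_trials"]),
                        float(d["task_s"]), float(d["rest_s"]))
    except KeyError as e:
        raise FormatError(f"paradigm description missing field {e.args[0]!r}") from e


# ---------------------------------------------------------------------------
# SNIRF container (continuous-wave subset, HDF5 via h5py)
# ---------------------------------------------------------------------------

def _write_snirf(rec: RawRecording, path: Path) -> None:
    n_ch = len(rec.layout.channels)
    n_t = rec.n_times
    src_index = {s: i + 1 for i, s in enumerate(rec.layout.sources)}
    det_index = {d: i + 1 for i, d in enumerate(rec.layout.detectors)}
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        tags = nirs.create_group("metaDataTags")
        tags.create_dataset("SubjectID", data=str(rec.meta.get("subject_id", "sim")))
        tags.create_dataset("MeasurementDate", data="unknown")
        tags.create_dataset("MeasurementTime", data="unknown")
        tags.create_dataset("LengthUnit", data="mm")
        tags.create_dataset("TimeUnit", data="s")
        tags.create_dataset("FrequencyUnit", data="Hz")
        tags.create_dataset("channelTableJson", data=json.dumps(_layout_to_dict(rec.layout)))
        tags.create_dataset("paradigmJson", data=json.dumps(_paradigm_to_dict(rec.paradigm)))
        tags.create_dataset("metaJson", data=json.dumps(rec.meta, default=str))

        data = nirs.create_group("data1")
        # measurement order: channel-major, wavelength-minor
        series = rec.intensities.reshape(n_ch * 2, n_t).T
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.array([0.0, 1.0 / rec.fs]))  # start, step
        for m in range(n_ch * 2):
            ch = rec.layout.channels[m // 2]
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=src_index[ch.source])
            ml.create_dataset("detectorIndex", data=det_index[ch.detector])
            ml.create_dataset("wavelengthIndex", data=(m % 2) + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.layout.wavelengths))
        probe.create_dataset("sourceLabels", data=list(rec.layout.sources))
        probe.create_dataset("detectorLabels", data=list(rec.layout.detectors))
        # schematic 2-D positions (mm); geometry of record lives in the channel table
        probe.create_dataset(
            "sourcePos2D",
            data=np.array([[30.0 * i, 0.0] for i in range(len(rec.layout.sources))]),
        )
        probe.create_dataset(
            "detectorPos2D",
            data=np.array([[30.0 * i, 30.0] for i in range(len(rec.layout.detectors))]),
        )

        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="task")
        stim.create_dataset(
            "data",
            data=np.column_stack([
                rec.paradigm.onsets,
                np.full(rec.paradigm.n_trials, rec.paradigm.task_s),
                np.ones(rec.paradigm.n_trials),
            ]),
        )


def _require(group: h5py.Group, key: str) -> h5py.Dataset | h5py.Group:
    if key not in group:
        raise FormatError(f"SNIRF file missing required field {group.name}/{key}")
    return group[key]


def _read_str(ds: h5py.Dataset) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_snirf(path: Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs")
        probe = _require(nirs, "probe")
        _require(probe, "wavelengths")  # wavelength table is mandatory
        data = _require(nirs, "data1")
        series = np.asarray(_require(data, "dataTimeSeries"))
        time = np.asarray(_require(data, "time"))
        if time.size == 2:
            fs = 1.0 / (time[1] - time[0])
        else:
            fs = 1.0 / float(np.median(np.diff(time)))
        tags = _require(nirs, "metaDataTags")
        layout = _layout_from_dict(json.loads(_read_str(_require(tags, "channelTableJson"))))
        paradigm = _paradigm_from_dict(json.loads(_read_str(_require(tags, "paradigmJson"))))
        meta = json.loads(_read_str(tags["metaJson"])) if "metaJson" in tags else {}
        n_ch = len(layout.channels)
        if series.shape[1] != n_ch * 2:
            raise FormatError(
                f"dataTimeSeries has {series.shape[1]} measurements, expected {n_ch * 2}"
            )
        intensities = series.T.reshape(n_ch, 2, -1)
    return RawRecording(layout=layout, fs=fs, intensities=intensities,
                        paradigm=paradigm, meta=meta)


# ---------------------------------------------------------------------------
# CSV dialect: <stem>.csv intensities + <stem>.meta.json sidecar
# ---------------------------------------------------------------------------

def _write_csv(rec: RawRecording, path: Path) -> None:
    import pandas as pd

    cols = {}
    for i, ch in enumerate(rec.layout.channels):
        for w, wl in enumerate(rec.layout.wavelengths):
            cols[f"{ch.name}@{wl:g}"] = rec.intensities[i, w]
    df = pd.DataFrame(cols, index=rec.times)
    df.index.name = "time_s"
    df.to_csv(path, float_format="%.17g")
    sidecar = {
        "fs": rec.fs,
        "layout": _layout_to_dict(rec.layout),
        "paradigm": _paradigm_to_dict(rec.paradigm),
        "meta": rec.meta,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, default=str))


def _read_csv(path: Path) -> RawRecording:
    import pandas as pd

    sidecar_file = path.with_suffix(".meta.json")
    if not sidecar_file.exists():
        raise FormatError(f"CSV sidecar {sidecar_file} not found")
    sidecar = json.loads(sidecar_file.read_text())
    for key in ("fs", "layout", "paradigm"):
        if key not in sidecar:
            raise FormatError(f"CSV sidecar missing field {key!r}")
    layout = _layout_from_dict(sidecar["layout"])
    paradigm = _paradigm_from_dict(sidecar["paradigm"])
    df = pd.read_csv(path, index_col=0)
    n_ch = len(layout.channels)
    intensities = np.empty((n_ch, 2, len(df)))
    for i, ch in enumerate(layout.channels):
        for w, wl in enumerate(layout.wavelengths):
            col = f"{ch.name}@{wl:g}"
            if col not in df.columns:
                raise FormatError(f"CSV missing intensity column {col!r}")
            intensities[i, w] = df[col].to_numpy()
    return RawRecording(layout=layout, fs=float(sidecar["fs"]), intensities=intensities,
                        paradigm=paradigm, meta=sidecar.get("meta", {}))


def _infer_format(path: Path) -> str:
    return "snirf" if path.suffix.lower() == ".snirf" else "csv"


def write_recording(rec: RawRecording, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        _write_snirf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        return _read_snirf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")
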