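"""Domain containers for continuous-wave fNIRS recordings.

A recording moves through three stages — raw light intensity, optical
density (OD), and chromophore concentration (HbO/HbR, micromolar) — and
every stage shares one container shape so each pipeline step can be
serialized and restarted.  Two on-disk dialects are supported: a minimal
SNIRF (HDF5) subset and a plain ``csv_bundle`` directory (``data.csv`` +
``layout.json`` + ``stim.json``) that needs no HDF5 tooling.

Conventions (asserted at boundaries): coordinates in mm, time in seconds
from recording start, wavelength order (760, 850) nm, chromophore order
(HbO, HbR), channel identity is the ordered (source, detector) pair.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

WAVELENGTHS = (760.0, 850.0)
CHROMOPHORES = ("HbO", "HbR")

STAGE_INTENSITY = "intensity"
STAGE_OD = "optical_density"
STAGE_CONCENTRATION = "concentration"
_STAGE_ORDER = (STAGE_INTENSITY, STAGE_OD, STAGE_CONCENTRATION)

#: maximum tolerated relative jitter of the sampling interval on read
MAX_TIMESTAMP_JITTER = 0.01


class LayoutError(ValueError):
    """Raised when probe geometry is missing or inconsistent."""


@dataclass(frozen=True)
class ProbeLayout:
    """Optode montage: source/detector positions (mm) and channel pairs.

    A channel is *short-separation* iff its source–detector Euclidean
    distance is below ``short_threshold_mm`` (default 15 mm); short
    channels sample scalp hemodynamics only and are used as nuisance
    regressors, never as data channels of interest.
    """

    source_positions: np.ndarray
    detector_positions: np.ndarray
    channels: tuple[tuple[int, int], ...]
    short_threshold_mm: float = 15.0

    def __post_init__(self) -> None:
        src = np.asarray(self.source_positions, dtype=float).reshape(-1, 3)
        det = np.asarray(self.detector_positions, dtype=float).reshape(-1, 3)
        chans = tuple((int(s), int(d)) for s, d in self.channels)
        object.__setattr__(self, "source_positions", src)
        object.__setattr__(self, "detector_positions", det)
        object.__setattr__(self, "channels", chans)
        if not chans:
            raise LayoutError("layout defines no channels")
        for s, d in chans:
            if not (0 <= s < len(src)) or not (0 <= d < len(det)):
                raise LayoutError(
                    f"channel ({s},{d}) indexes outside the optode lists "
                    f"({len(src)} sources, {len(det)} detectors)"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_distances_mm(self) -> np.ndarray:
        s_idx = np.array([s for s, _ in self.channels])
        d_idx = np.array([d for _, d in self.channels])
        diff = self.source_positions[s_idx] - self.detector_positions[d_idx]
        return np.linalg.norm(diff, axis=1)

    @property
    def short_channel_flags(self) -> np.ndarray:
        return self.channel_distances_mm < self.short_threshold_mm

    @property
    def long_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.short_channel_flags)

    @property
    def short_indices(self) -> np.ndarray:
        return np.flatnonzero(self.short_channel_flags)

    def channel_names(self) -> list[str]:
        return [f"S{s + 1}D{d + 1}" for s, d in self.channels]

    def channel_midpoints(self) -> np.ndarray:
        s_idx = np.array([s for s, _ in self.channels])
        d_idx = np.array([d for _, d in self.channels])
        return 0.5 * (self.source_positions[s_idx] + self.detector_positions[d_idx])

    def to_dict(self) -> dict:
        return {
            "source_positions": self.source_positions.tolist(),
            "detector_positions": self.detector_positions.tolist(),
            "channels": [list(c) for c in self.channels],
            "short_threshold_mm": self.short_threshold_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeLayout":
        return cls(
            source_positions=np.asarray(d["source_positions"], dtype=float),
            detector_positions=np.asarray(d["detector_positions"], dtype=float),
            channels=tuple(tuple(c) for c in d["channels"]),
            short_threshold_mm=float(d.get("short_threshold_mm", 15.0)),
        )


@dataclass(frozen=True)
class StimDesign:
    """Block-design stimulus timing: task-block onsets/durations in seconds.

    Sessions start with a rest block (``rest_duration``, default 120 s)
    and alternate task/rest; only the task blocks are listed here.
    """

    onsets: np.ndarray
    durations: np.ndarray
    labels: tuple[str, ...] = ()
    rest_duration: float = 120.0

    def __post_init__(self) -> None:
        on = np.atleast_1d(np.asarray(self.onsets, dtype=float))
        du = np.atleast_1d(np.asarray(self.durations, dtype=float))
        if on.shape != du.shape:
            raise ValueError("onsets and durations must have equal length")
        if on.size and np.any(np.diff(on) <= 0):
            raise ValueError("block onsets must be strictly increasing")
        if on.size and np.any(on[:-1] + du[:-1] > on[1:] + 1e-9):
            raise ValueError("task blocks must not overlap")
        labels = tuple(self.labels) if self.labels else tuple("task" for _ in on)
        if len(labels) != on.size:
            raise ValueError("one label per block required")
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "durations", du)
        object.__setattr__(self, "labels", labels)

    @property
    def n_blocks(self) -> int:
        return int(self.onsets.size)

    def end_time(self) -> float:
        if self.onsets.size == 0:
            return 0.0
        return float(self.onsets[-1] + self.durations[-1])

    def to_dict(self) -> dict:
        return {
            "onsets": self.onsets.tolist(),
            "durations": self.durations.tolist(),
            "labels": list(self.labels),
            "rest_duration": self.rest_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimDesign":
        return cls(
            onsets=np.asarray(d["onsets"], dtype=float),
            durations=np.asarray(d["durations"], dtype=float),
            labels=tuple(d.get("labels") or ()),
            rest_duration=float(d.get("rest_duration", 120.0)),
        )


@dataclass
class Recording:
    """Multichannel time series at one processing stage.

    ``data`` has shape (n_channels, 2, n_times); axis 1 is the wavelength
    pair (760, 850) nm for intensity/OD stages and the chromophore pair
    (HbO, HbR) in μM for the concentration stage.
    """

    sample_rate: float
    data: np.ndarray
    stage: str
    layout: ProbeLayout
    stim: StimDesign | None = None
    timestamps: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("data must have shape (n_channels, 2, n_times)")
        if self.stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but layout has "
                f"{self.layout.n_channels}"
            )
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.size != self.data.shape[2]:
                raise ValueError("timestamps length must match the time axis")
        if self.stage == STAGE_INTENSITY and np.any(self.data <= 0):
            ch, wl, t = np.unravel_index(np.argmin(self.data), self.data.shape)
            raise ValueError(
                f"intensity must be strictly positive; offending sample: "
                f"channel {ch}, wavelength {WAVELENGTHS[wl]:g} nm, sample {t}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_times / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        if self.timestamps is not None:
            return self.timestamps
        return np.arange(self.n_times) / self.sample_rate

    @property
    def component_labels(self) -> tuple[str, str]:
        if self.stage == STAGE_CONCENTRATION:
            return CHROMOPHORES
        return (f"{WAVELENGTHS[0]:g}", f"{WAVELENGTHS[1]:g}")

    def with_data(self, data: np.ndarray, stage: str | None = None) -> "Recording":
        """Copy with new data, enforcing the stage-order invariant."""
        new_stage = self.stage if stage is None else stage
        if _STAGE_ORDER.index(new_stage) < _STAGE_ORDER.index(self.stage):
            raise ValueError(
                f"stage may only advance {' -> '.join(_STAGE_ORDER)}; "
                f"got {self.stage} -> {new_stage}"
            )
        return Recording(
            sample_rate=self.sample_rate,
            data=data,
            stage=new_stage,
            layout=self.layout,
            stim=self.stim,
            timestamps=self.timestamps,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Session schedule (block-design training study)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSpec:
    session_index: int  # 1-based
    repetitions: int
    block_duration_min: float


#: (first_session, last_session, repetitions, block_duration_min) — the
#: 15-session training schedule: 3×10-min, then 5×5-min, then 7×3-min blocks.
DEFAULT_SCHEDULE_BANDS: tuple[tuple[int, int, int, float], ...] = (
    (1, 5, 3, 10.0),
    (6, 10, 5, 5.0),
    (11, 15, 7, 3.0),
)


def session_schedule(
    bands: Sequence[tuple[int, int, int, float]] = DEFAULT_SCHEDULE_BANDS,
) -> list[SessionSpec]:
    """Expand schedule bands into one :class:`SessionSpec` per session.

    The default expands to 15 sessions and 75 total task repetitions.
    """
    out: list[SessionSpec] = []
    for first, last, reps, block_min in bands:
        if reps <= 0:
            raise ValueError(f"repetition count must be positive, got {reps}")
        if block_min <= 0:
            raise ValueError(f"block duration must be positive, got {block_min}")
        for s in range(int(first), int(last) + 1):
            out.append(SessionSpec(s, int(reps), float(block_min)))
    out.sort(key=lambda s: s.session_index)
    idx = [s.session_index for s in out]
    if len(set(idx)) != len(idx):
        raise ValueError("schedule bands overlap")
    return out


def session_stim(
    spec: SessionSpec,
    rest_duration_s: float = 120.0,
    block_duration_s: float | None = None,
) -> tuple[StimDesign, float]:
    """Stimulus timing and total duration for one training session.

    Sessions alternate rest/task starting and ending with a rest block:
    rest, (task, rest) × repetitions.
    """
    block_s = (
        spec.block_duration_min * 60.0 if block_duration_s is None else block_duration_s
    )
    onsets = rest_duration_s + np.arange(spec.repetitions) * (block_s + rest_duration_s)
    durations = np.full(spec.repetitions, block_s)
    stim = StimDesign(onsets=onsets, durations=durations, rest_duration=rest_duration_s)
    total = rest_duration_s + spec.repetitions * (block_s + rest_duration_s)
    return stim, total


# ---------------------------------------------------------------------------
# I/O — csv_bundle dialect
# ---------------------------------------------------------------------------

def _column_names(rec: Recording) -> list[str]:
    names = rec.layout.channel_names()
    comps = rec.component_labels
    return [f"{n}:{c}" for n in names for c in comps]


def _write_csv_bundle(rec: Recording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    n_ch, _, n_t = rec.data.shape
    flat = rec.data.reshape(n_ch * 2, n_t).T  # time × (channel*component)
    df = pd.DataFrame(flat, columns=_column_names(rec))
    df.insert(0, "time", rec.times)
    df.to_csv(path / "data.csv", index=False, float_format="%.10g")
    layout_doc = rec.layout.to_dict()
    layout_doc["meta"] = {
        "stage": rec.stage,
        "sample_rate": rec.sample_rate,
        "wavelengths": list(WAVELENGTHS),
        **rec.meta,
    }
    (path / "layout.json").write_text(json.dumps(layout_doc, indent=1))
    if rec.stim is not None:
        (path / "stim.json").write_text(json.dumps(rec.stim.to_dict(), indent=1))


def _read_csv_bundle(path: Path) -> Recording:
    layout_file = path / "layout.json"
    if not layout_file.exists():
        raise LayoutError(f"no layout: {layout_file} is missing")
    layout_doc = json.loads(layout_file.read_text())
    meta = dict(layout_doc.pop("meta", {}))
    layout = ProbeLayout.from_dict(layout_doc)
    df = pd.read_csv(path / "data.csv")
    t = df.pop("time").to_numpy()
    _check_uniform(t, float(meta.get("sample_rate", 0.0)) or None)
    fs = float(meta.pop("sample_rate"))
    stage = meta.pop("stage")
    meta.pop("wavelengths", None)
    n_t = len(df)
    data = df.to_numpy().T.reshape(layout.n_channels, 2, n_t)
    stim = None
    stim_file = path / "stim.json"
    if stim_file.exists():
        stim = StimDesign.from_dict(json.loads(stim_file.read_text()))
    return Recording(
        sample_rate=fs, data=data, stage=stage, layout=layout, stim=stim, meta=meta
    )


def _check_uniform(t: np.ndarray, fs: float | None) -> None:
    if t.size < 2:
        return
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    med = np.median(dt)
    if np.max(np.abs(dt - med)) > MAX_TIMESTAMP_JITTER * med:
        raise ValueError(
            "non-uniform sampling beyond 1% jitter; resample explicitly "
            "before loading"
        )
    if fs is not None and abs(med - 1.0 / fs) > MAX_TIMESTAMP_JITTER / fs:
        raise ValueError("timestamps disagree with the declared sample rate")


# ---------------------------------------------------------------------------
# I/O — minimal SNIRF (HDF5) subset
# ---------------------------------------------------------------------------

_SNIRF_DATATYPE_CW = 1
_SNIRF_DATATYPE_PROCESSED = 99999
_STAGE_TO_LABELS = {
    STAGE_OD: ("dOD", "dOD"),
    STAGE_CONCENTRATION: ("HbO", "HbR"),
}


def _write_snirf(rec: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.1")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("fnirs_skill_stage", data=rec.stage)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(WAVELENGTHS))
        probe.create_dataset("sourcePos3D", data=rec.layout.source_positions)
        probe.create_dataset("detectorPos3D", data=rec.layout.detector_positions)
        data1 = nirs.create_group("data1")
        n_ch, _, n_t = rec.data.shape
        data1.create_dataset(
            "dataTimeSeries", data=rec.data.reshape(n_ch * 2, n_t).T
        )
        data1.create_dataset("time", data=rec.times)
        m = 0
        for ci, (s, d) in enumerate(rec.layout.channels):
            for wi in range(2):
                m += 1
                ml = data1.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=s + 1)
                ml.create_dataset("detectorIndex", data=d + 1)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                if rec.stage == STAGE_INTENSITY:
                    ml.create_dataset("dataType", data=_SNIRF_DATATYPE_CW)
                else:
                    ml.create_dataset("dataType", data=_SNIRF_DATATYPE_PROCESSED)
                    ml.create_dataset(
                        "dataTypeLabel", data=_STAGE_TO_LABELS[rec.stage][wi]
                    )
        if rec.stim is not None:
            stim = nirs.create_group("stim1")
            stim.create_dataset("name", data=rec.stim.labels[0] if rec.stim.labels else "task")
            cols = np.column_stack(
                [rec.stim.onsets, rec.stim.durations, np.ones(rec.stim.n_blocks)]
            )
            stim.create_dataset("data", data=cols)
            stim.attrs["rest_duration"] = rec.stim.rest_duration


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_snirf(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        if "probe" not in nirs:
            raise LayoutError(f"no layout: {path} has no /nirs/probe group")
        probe = nirs["probe"]
        src = np.asarray(probe["sourcePos3D"])
        det = np.asarray(probe["detectorPos3D"])
        data1 = nirs["data1"]
        series = np.asarray(data1["dataTimeSeries"])
        t = np.asarray(data1["time"])
        _check_uniform(t, None)
        fs = 1.0 / float(np.median(np.diff(t)))
        n_meas = series.shape[1]
        pairs: list[tuple[int, int]] = []
        order = np.empty(n_meas, dtype=int)
        stage = STAGE_INTENSITY
        for m in range(1, n_meas + 1):
            ml = data1[f"measurementList{m}"]
            s = int(ml["sourceIndex"][()]) - 1
            d = int(ml["detectorIndex"][()]) - 1
            wi = int(ml["wavelengthIndex"][()]) - 1
            if (s, d) not in pairs:
                pairs.append((s, d))
            ci = pairs.index((s, d))
            order[m - 1] = ci * 2 + wi
            if int(ml["dataType"][()]) == _SNIRF_DATATYPE_PROCESSED:
                label = _read_str(ml["dataTypeLabel"])
                stage = STAGE_CONCENTRATION if label in CHROMOPHORES else STAGE_OD
        stage_ds = nirs.get("metaDataTags/fnirs_skill_stage")
        if stage_ds is not None:
            stage = _read_str(stage_ds)
        data = np.empty((len(pairs) * 2, series.shape[0]))
        data[order] = series.T
        data = data.reshape(len(pairs), 2, -1)
        stim = None
        if "stim1" in nirs:
            sdata = np.atleast_2d(np.asarray(nirs["stim1"]["data"]))
            rest = float(nirs["stim1"].attrs.get("rest_duration", 120.0))
            stim = StimDesign(
                onsets=sdata[:, 0], durations=sdata[:, 1], rest_duration=rest
            )
        layout = ProbeLayout(src, det, tuple(pairs))
    return Recording(
        sample_rate=fs, data=data, stage=stage, layout=layout, stim=stim
    )


# ---------------------------------------------------------------------------
# Public read/write dispatch
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "snirf" if str(path).endswith(".snirf") else "csv_bundle"


def write_recording(rec: Recording, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a recording as SNIRF or csv_bundle; lossless for data/layout/stim."""
    if rec.n_channels == 0 or rec.n_times == 0:
        raise ValueError("refusing to write an empty recording")
    p = Path(path)
    fmt = _infer_format(p, format)
    if fmt == "snirf":
        _write_snirf(rec, p)
    elif fmt == "csv_bundle":
        _write_csv_bundle(rec, p)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return p


def read_recording(path: str | os.PathLike, format: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = _infer_format(p, format)
    if fmt == "snirf":
        return _read_snirf(p)
    if fmt == "csv_bundle":
        return _read_csv_bundle(p)
    raise ValueError(f"unknown format {fmt!r}")
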