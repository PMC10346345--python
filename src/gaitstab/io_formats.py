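"""Readers and writers for the file formats the pipeline touches.

EEG travels as BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``), gait
kinematics (heel-marker height, vertical ground reaction force) as plain
delimited text, and cycle-level feature matrices as TSV.  All readers
reject malformed input instead of silently truncating; every writer
round-trips through its reader.

Conventions: time is seconds from trial start, sample indices are 0-based,
intervals are half-open ``[start, end)``, and EEG amplitudes are µV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "MotionSeries",
    "FeatureTable",
    "ColumnSpec",
    "read_brainvision",
    "write_brainvision",
    "read_timeseries_csv",
    "write_timeseries_tsv",
    "read_feature_table",
    "write_feature_table",
]

METADATA_COLUMNS = ("subject", "condition", "cycle_index")


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is (channels, samples) in µV."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"channel label count {len(self.channel_labels)} does not "
                f"match channel count {self.data.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(),
            self.sampling_rate,
            list(self.channel_labels),
            self.start_time,
            json.loads(json.dumps(self.metadata)) if self.metadata else {},
        )


@dataclass
class MotionSeries:
    """Uniformly sampled gait signal: heel height (mm) or vertical GRF (N)."""

    time: np.ndarray
    values: np.ndarray
    side: str
    kind: str  # "marker" | "force"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.time.shape != self.values.shape or self.time.ndim != 1:
            raise ValueError("time and values must be matching 1-D arrays")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.kind not in ("marker", "force"):
            raise ValueError(f"kind must be 'marker' or 'force', got {self.kind!r}")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            step = np.median(dt)
            if np.max(np.abs(dt - step)) > 0.01 * step:
                raise ValueError("time grid is not uniform (deviation > 1% of step)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def sampling_rate(self) -> float:
        if len(self.time) < 2:
            raise ValueError("need at least 2 samples to infer a sampling rate")
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class FeatureTable:
    """Cycle-level feature matrix.

    One row per gait cycle; columns ``subject``, ``condition``,
    ``cycle_index`` followed by ``<channel>__<feature>`` columns.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if cols[: len(METADATA_COLUMNS)] != list(METADATA_COLUMNS):
            raise ValueError(
                f"feature table must start with columns {METADATA_COLUMNS}"
            )
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate column names: {dupes}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in METADATA_COLUMNS]

    @property
    def values(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=np.float64)

    @property
    def conditions(self) -> np.ndarray:
        return self.frame["condition"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# BrainVision triplet
# ---------------------------------------------------------------------------

_BV_DTYPES = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}


def write_brainvision(rec: EEGRecording, basepath: str | Path) -> tuple[Path, Path, Path]:
    """Write ``rec`` as a BrainVision triplet (multiplexed IEEE_FLOAT_32).

    ``basepath`` is the path without extension; returns the three paths
    written (.vhdr, .vmrk, .eeg).
    """
    if rec.n_channels == 0:
        raise ValueError("cannot write a recording with 0 channels")
    base = Path(basepath)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    sampling_interval_us = 1e6 / rec.sampling_rate

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by gaitstab",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    markers = rec.metadata.get("markers", [])
    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for j, mk in enumerate(markers, start=2):
        mlines.append(
            f"Mk{j}={mk.get('type', 'Stimulus')},{mk.get('description', '')},"
            f"{int(mk['position']) + 1},{int(mk.get('size', 1))},"
            f"{int(mk.get('channel', 0))}"
        )
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, _, val = line.partition("=")
            current[key.strip()] = val.strip()
    return sections


def read_brainvision(header_path: str | Path) -> EEGRecording:
    """Read a BrainVision triplet referenced by its ``.vhdr`` header.

    Supports MULTIPLEXED orientation with INT_16 (per-channel resolution
    scaling) or IEEE_FLOAT_32 binary formats; returns data in µV.
    """
    vhdr = Path(header_path)
    if not vhdr.exists():
        raise FileNotFoundError(f"header file not found: {vhdr}")
    sections = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    chinfo = sections.get("Channel Infos", {})

    fmt = common.get("DataFormat", "BINARY")
    if fmt != "BINARY":
        raise ValueError(f"unsupported DataFormat keyword: {fmt!r}")
    orientation = common.get("DataOrientation", "MULTIPLEXED")
    if orientation != "MULTIPLEXED":
        raise ValueError(f"unsupported DataOrientation keyword: {orientation!r}")
    binfmt = binary.get("BinaryFormat", "IEEE_FLOAT_32")
    if binfmt not in _BV_DTYPES:
        raise ValueError(f"unsupported BinaryFormat keyword: {binfmt!r}")

    n_channels = int(common["NumberOfChannels"])
    sampling_rate = 1e6 / float(common["SamplingInterval"])

    labels, resolutions = [], []
    for i in range(1, n_channels + 1):
        entry = chinfo.get(f"Ch{i}")
        if entry is None:
            raise ValueError(f"missing Channel Infos entry Ch{i}")
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] != "" else "1"
        resolutions.append(float(res))

    eeg_path = vhdr.parent / common["DataFile"]
    if not eeg_path.exists():
        raise FileNotFoundError(f"referenced data file not found: {eeg_path}")
    raw = np.fromfile(eeg_path, dtype=_BV_DTYPES[binfmt])
    if raw.size % n_channels != 0:
        raise ValueError(
            f"data file length {raw.size} is not a multiple of channel "
            f"count {n_channels}"
        )
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    metadata: dict = {}
    marker_name = common.get("MarkerFile")
    if marker_name:
        vmrk = vhdr.parent / marker_name
        if vmrk.exists():
            metadata["markers"] = _read_markers(vmrk)
    return EEGRecording(data, sampling_rate, labels, metadata=metadata)


def _read_markers(vmrk: Path) -> list[dict]:
    sections = _parse_ini(vmrk.read_text(encoding="utf-8"))
    markers = []
    infos = sections.get("Marker Infos", {})
    for key in sorted(infos, key=lambda k: int(k[2:])):
        parts = infos[key].split(",")
        if parts[0] == "New Segment":
            continue
        markers.append(
            {
                "type": parts[0],
                "description": parts[1],
                "position": int(parts[2]) - 1,
                "size": int(parts[3]) if len(parts) > 3 else 1,
                "channel": int(parts[4]) if len(parts) > 4 else 0,
            }
        )
    return markers


# ---------------------------------------------------------------------------
# Delimited gait time series
# ---------------------------------------------------------------------------


@dataclass
class ColumnSpec:
    """Which columns of a delimited file hold the gait series."""

    time_column: str = "time"
    value_column: str = "value"
    side: str = "right"
    kind: str = "marker"
    delimiter: str | None = None  # None = infer from extension


def read_timeseries_csv(path: str | Path, spec: ColumnSpec) -> MotionSeries:
    """Read a heel-marker or GRF series from a delimited file with header."""
    path = Path(path)
    delim = spec.delimiter or ("\t" if path.suffix.lower() == ".tsv" else ",")
    frame = pd.read_csv(path, sep=delim)
    for col in (spec.time_column, spec.value_column):
        if col not in frame.columns:
            raise ValueError(f"missing column {col!r} in {path.name}")
    time = frame[spec.time_column].to_numpy(dtype=float)
    if len(time) > 1 and np.any(np.diff(time) <= 0):
        raise ValueError("time column is not strictly increasing")
    return MotionSeries(
        time=time,
        values=frame[spec.value_column].to_numpy(dtype=float),
        side=spec.side,
        kind=spec.kind,
    )


def write_timeseries_tsv(series: MotionSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time": series.time, "value": series.values}).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )
    return path


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as TSV, lossless at 12 significant digits."""
    path = Path(path)
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names in {path.name}: {dupes}")
    frame = pd.read_csv(path, sep="\t")
    return FeatureTable(frame)
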