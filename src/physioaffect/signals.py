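"""Signal containers and plain-text channel file I/O.

A recording is one (subject, condition) pair with three channels: ECG in
millivolts, skin temperature (SKT) in degrees Celsius and electrodermal
activity (EDA) in microsiemens. Channels are stored one per file as a
single column of samples preceded by a header line of the form::

    # channel=ECG fs=1000 units=mV

with a ``recording.json`` sidecar carrying subject id, condition and the
channel file names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CHANNELS = ("ECG", "SKT", "EDA")
CONDITIONS = ("basic", "negative")

_DEFAULT_UNITS = {"ECG": "mV", "SKT": "degC", "EDA": "uS"}


@dataclass
class SignalRecord:
    """One channel's samples with its sampling rate and provenance."""

    channel: str
    fs: float
    samples: np.ndarray
    units: str = ""
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.units:
            self.units = _DEFAULT_UNITS[self.channel]
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class Recording:
    """All channels of one (subject, condition) session."""

    subject_id: str
    condition: str
    channels: dict[str, SignalRecord] = field(default_factory=dict)

    def __getitem__(self, channel: str) -> SignalRecord:
        return self.channels[channel]

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels


def write_channel(record: SignalRecord, path: str | Path) -> None:
    path = Path(path)
    header = f"# channel={record.channel} fs={record.fs:g} units={record.units}"
    np.savetxt(path, record.samples, fmt="%.6g", header=header, comments="")


def read_channel(path: str | Path, subject_id: str = "", condition: str = "") -> SignalRecord:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing '# channel=... fs=... units=...' header")
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    samples = np.loadtxt(path, skiprows=1)
    return SignalRecord(
        channel=meta["channel"],
        fs=float(meta["fs"]),
        samples=np.atleast_1d(samples),
        units=meta.get("units", ""),
        subject_id=subject_id,
        condition=condition,
    )


def write_recording(rec: Recording, out_dir: str | Path) -> Path:
    """Write each channel file plus the recording.json sidecar; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, record in rec.channels.items():
        fname = f"{rec.subject_id}_{rec.condition}_{name}.txt"
        write_channel(record, out_dir / fname)
        files[name] = fname
    sidecar = out_dir / f"{rec.subject_id}_{rec.condition}_recording.json"
    sidecar.write_text(
        json.dumps(
            {"subject_id": rec.subject_id, "condition": rec.condition, "channels": files},
            indent=2,
        )
    )
    return sidecar


def read_recording(sidecar: str | Path) -> Recording:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    rec = Recording(subject_id=meta["subject_id"], condition=meta["condition"])
    for name, fname in meta["channels"].items():
        rec.channels[name] = read_channel(
            sidecar.parent / fname, subject_id=rec.subject_id, condition=rec.condition
        )
    return rec
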