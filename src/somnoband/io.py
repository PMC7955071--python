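"""Reading EEG recordings, epoch segmentation, and epoch-set persistence.

Recordings come from EDF files (via :mod:`mne`) or plain CSV sample tables
(one column per channel).  The classification unit is a fixed-length,
non-overlapping epoch; an epoch takes the label of the annotated event
covering at least half of it, otherwise it is normal breathing (NB).
Epoch sets round-trip through a CSV file plus a JSON sidecar.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventLabel",
    "Recording",
    "EpochSet",
    "read_recording",
    "segment_epochs",
    "write_epochs",
    "read_epochs",
]

DEFAULT_CHANNELS = ("C3-A2", "C4-A1")
DEFAULT_FS = 100.0
DEFAULT_EPOCH_LEN_S = 30.0


class EventLabel(str, Enum):
    """The three-class event alphabet."""

    OSA = "OSA"  # obstructive sleep apnea
    CSA = "CSA"  # central sleep apnea
    NB = "NB"  # normal breathing

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LABELS: tuple[str, ...] = tuple(l.value for l in EventLabel)


def _canon(name: str) -> str:
    """Canonical channel key: uppercase alphanumerics only.

    Makes "C3-A2", "C3A2", "EEG C3-A2" and "c3-a2" all comparable.
    """
    return re.sub(r"[^A-Z0-9]", "", name.upper())


def _match_channel(wanted: str, available: list[str]) -> str | None:
    key = _canon(wanted)
    for ch in available:
        ck = _canon(ch)
        if ck == key or ck.endswith(key) or key.endswith(ck):
            return ch
    return None


@dataclass
class Recording:
    """A continuous multi-channel EEG recording.

    Attributes
    ----------
    channels : list of str
        Channel names, in storage order.
    fs : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Signal values (microvolts by convention; never used quantitatively).
    annotations : list of (start_s, duration_s, label)
        Event marks in seconds from recording start.
    """

    channels: list[str]
    fs: float
    samples: np.ndarray
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("samples rows must match number of channels")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class EpochSet:
    """Labeled fixed-length epochs, the pipeline's raw input.

    ``epochs`` has shape (n_epochs, n_channels, epoch_len_samples); labels
    are strings from the {OSA, CSA, NB} alphabet.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    epoch_len_s: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal number of epochs")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")
        expected = int(round(self.epoch_len_s * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples inconsistent "
                f"with epoch_len_s={self.epoch_len_s} at fs={self.fs}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def read_recording(
    path: str | Path,
    format: str | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    fs: float | None = None,
) -> Recording:
    """Read an EEG recording from an EDF or CSV file.

    Only the configured ``channels`` are kept.  Channel name matching is
    case-insensitive and tolerant of dialects like "C3A2" or "EEG C3-A2".

    For CSV, the file must have a header row naming the channels; the
    sampling rate comes from ``fs`` (default 100 Hz) or a JSON sidecar
    ``<path>.json`` with an ``"fs"`` entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return _read_edf(path, channels)
    if format == "csv":
        return _read_csv(path, channels, fs)
    raise ValueError(f"unknown recording format {format!r}")


def _read_edf(path: Path, channels: tuple[str, ...]) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "EDF support requires the 'mne' package (pip install somnoband[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    picked, names = [], []
    for want in channels:
        got = _match_channel(want, available)
        if got is None:
            raise KeyError(
                f"channel {want!r} not found in {path.name}; "
                f"available channels: {available}"
            )
        picked.append(got)
        names.append(want)
    data = raw.get_data(picks=picked) * 1e6  # mne stores volts
    annotations = [
        (float(a["onset"]), float(a["duration"]), str(a["description"]))
        for a in raw.annotations
    ]
    return Recording(
        channels=names,
        fs=float(raw.info["sfreq"]),
        samples=np.asarray(data, dtype=float),
        annotations=annotations,
    )


def _read_csv(path: Path, channels: tuple[str, ...], fs: float | None) -> Recording:
    df = pd.read_csv(path)
    if fs is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            fs = float(json.loads(sidecar.read_text())["fs"])
        else:
            fs = DEFAULT_FS
    cols, names = [], []
    for want in channels:
        got = _match_channel(want, list(df.columns))
        if got is None:
            raise KeyError(
                f"channel {want!r} not found in {path.name}; "
                f"available channels: {list(df.columns)}"
            )
        cols.append(got)
        names.append(want)
    samples = df[cols].to_numpy(dtype=float).T
    return Recording(channels=names, fs=float(fs), samples=samples)


def segment_epochs(
    rec: Recording,
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
    min_overlap: float = 0.5,
) -> EpochSet:
    """Cut a recording into non-overlapping consecutive labeled epochs.

    An epoch's label is the annotated event covering at least
    ``min_overlap`` of it (largest overlap wins), otherwise NB.  The
    trailing partial epoch is dropped.
    """
    if rec.samples.shape[1] == 0:
        raise ValueError("empty recording")
    epoch_len = int(round(epoch_len_s * rec.fs))
    n_epochs = rec.samples.shape[1] // epoch_len
    if n_epochs == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s shorter than one "
            f"{epoch_len_s} s epoch"
        )
    epochs = np.stack(
        [rec.samples[:, i * epoch_len : (i + 1) * epoch_len] for i in range(n_epochs)]
    )
    labels = np.array(
        [
            _label_for_window(rec.annotations, i * epoch_len_s, epoch_len_s, min_overlap)
            for i in range(n_epochs)
        ],
        dtype=object,
    )
    return EpochSet(
        epochs=epochs,
        labels=labels,
        fs=rec.fs,
        channel_names=tuple(rec.channels),
        epoch_len_s=epoch_len_s,
    )


def _label_for_window(
    annotations: list[tuple[float, float, str]],
    start_s: float,
    len_s: float,
    min_overlap: float,
) -> str:
    end_s = start_s + len_s
    best_label, best_ov = EventLabel.NB.value, 0.0
    for a_start, a_dur, label in annotations:
        if label not in LABELS:
            continue
        ov = min(end_s, a_start + a_dur) - max(start_s, a_start)
        if ov > best_ov:
            best_ov, best_label = ov, label
    if best_ov / len_s >= min_overlap:
        return best_label
    return EventLabel.NB.value


def write_epochs(es: EpochSet, out_dir: str | Path) -> Path:
    """Write an EpochSet as ``epochs.csv`` + ``epochs.json`` sidecar.

    The CSV holds one row per sample with columns
    (epoch, <channel>, ...); the sidecar carries fs, epoch length,
    channel names and per-epoch labels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_epochs, n_ch, n_samp = es.epochs.shape
    flat = es.epochs.transpose(0, 2, 1).reshape(n_epochs * n_samp, n_ch)
    df = pd.DataFrame(flat, columns=list(es.channel_names))
    df.insert(0, "epoch", np.repeat(np.arange(n_epochs), n_samp))
    csv_path = out_dir / "epochs.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "fs": es.fs,
        "epoch_len_s": es.epoch_len_s,
        "channel_names": list(es.channel_names),
        "labels": [str(l) for l in es.labels],
    }
    (out_dir / "epochs.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_epochs(in_dir: str | Path) -> EpochSet:
    """Inverse of :func:`write_epochs`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "epochs.json").read_text())
    df = pd.read_csv(in_dir / "epochs.csv")
    channel_names = tuple(meta["channel_names"])
    labels = np.array(meta["labels"], dtype=object)
    n_epochs = len(labels)
    n_samp = int(round(meta["epoch_len_s"] * meta["fs"]))
    flat = df[list(channel_names)].to_numpy(dtype=float)
    epochs = flat.reshape(n_epochs, n_samp, len(channel_names)).transpose(0, 2, 1)
    return EpochSet(
        epochs=epochs,
        labels=labels,
        fs=float(meta["fs"]),
        channel_names=channel_names,
        epoch_len_s=float(meta["epoch_len_s"]),
    )
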