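"""Reading, writing and containers for multichannel EEG.

EDF reading goes through MNE; a minimal 16-bit EDF writer is provided so
synthetic recordings can be exported and round-tripped.  Arrays travel as
microvolts throughout the package.  An HDF5 container mirrors the EDF
content for fast chunked access (datasets ``/data`` channels x samples
float32 µV, ``/labels``, ``/fs``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Recording",
    "read_edf",
    "write_edf",
    "normalize_channel_label",
    "save_recording_h5",
    "load_recording_h5",
    "save_spectrograms_h5",
    "load_spectrograms_h5",
    "save_embeddings_h5",
    "load_embeddings_h5",
]


@dataclass
class Recording:
    """A labelled multichannel EEG time series.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    channel_labels : list of str
        Unique electrode names, one per row of ``data``.
    sample_rate : float
        Sampling rate in Hz, strictly positive.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    center_id : str, optional
        Clinical-center identifier for center-level cross-validation.
    """

    patient_id: str
    channel_labels: list[str]
    sample_rate: float
    data: np.ndarray
    center_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]


def normalize_channel_label(label: str) -> str:
    """Map EDF label dialects onto bare upper-case electrode names.

    Strips an ``EEG `` prefix and ``-REF``/``-LE`` reference suffixes,
    case-insensitively: ``"EEG F3-Ref"`` -> ``"F3"``.
    """
    lab = label.strip()
    if lab.upper().startswith("EEG "):
        lab = lab[4:]
    for suffix in ("-REF", "-LE"):
        if lab.upper().endswith(suffix):
            lab = lab[: -len(suffix)]
    return lab.strip().upper()


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (data in µV).

    Channel labels are normalized to upper-case electrode names.  The
    file stem is used as ``patient_id``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt files
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE holds Volts
    labels = [normalize_channel_label(ch) for ch in raw.ch_names]
    return Recording(
        patient_id=path.stem,
        channel_labels=labels,
        sample_rate=float(raw.info["sfreq"]),
        data=data_uv,
    )


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a :class:`Recording` as a minimal 16-bit EDF file.

    One data record per second; the sampling rate must therefore be a
    positive integer.  Physical range is set per channel from the data.
    """
    fs = rec.sample_rate
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_sig = rec.n_channels
    n_records = rec.n_samples // fs
    if n_records * fs != rec.n_samples:
        raise ValueError("recording length must be a whole number of seconds")

    def _field(value: str, width: int) -> bytes:
        b = value.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    # round the physical range to what the 8-char header fields hold, so
    # the reader's rescaling matches the writer's exactly
    phys_min = np.floor(np.minimum(rec.data.min(axis=1), -1.0) * 100) / 100
    phys_max = np.ceil(np.maximum(rec.data.max(axis=1), 1.0) * 100) / 100
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(rec.patient_id, 80))
        f.write(_field("neuromap", 80))
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(str(256 * (1 + n_sig)), 8))
        f.write(_field("", 44))
        f.write(_field(str(n_records), 8))
        f.write(_field("1", 8))  # record duration, seconds
        f.write(_field(str(n_sig), 4))
        for lab in rec.channel_labels:
            f.write(_field(lab, 16))
        for _ in range(n_sig):
            f.write(_field("", 80))  # transducer
        for _ in range(n_sig):
            f.write(_field("uV", 8))
        for v in phys_min:
            f.write(_field(f"{v:.2f}", 8))
        for v in phys_max:
            f.write(_field(f"{v:.2f}", 8))
        for _ in range(n_sig):
            f.write(_field(str(dig_min), 8))
        for _ in range(n_sig):
            f.write(_field(str(dig_max), 8))
        for _ in range(n_sig):
            f.write(_field("", 80))  # prefiltering
        for _ in range(n_sig):
            f.write(_field(str(fs), 8))
        for _ in range(n_sig):
            f.write(_field("", 32))
        scale = (dig_max - dig_min) / (phys_max - phys_min)
        for r in range(n_records):
            block = rec.data[:, r * fs : (r + 1) * fs]
            dig = np.rint((block - phys_min[:, None]) * scale[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            f.write(dig.tobytes())


def save_recording_h5(path: str | Path, rec: Recording) -> None:
    """Persist a recording to the package's HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("labels", data=np.array(rec.channel_labels, dtype="S"))
        f.create_dataset("fs", data=float(rec.sample_rate))
        f.attrs["patient_id"] = rec.patient_id
        if rec.center_id is not None:
            f.attrs["center_id"] = rec.center_id


def load_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            patient_id=str(f.attrs.get("patient_id", Path(path).stem)),
            channel_labels=[s.decode() for s in f["labels"][()]],
            sample_rate=float(f["fs"][()]),
            data=f["data"][()].astype(float),
            center_id=str(f.attrs["center_id"]) if "center_id" in f.attrs else None,
        )


def save_spectrograms_h5(path: str | Path, spects) -> None:
    """Persist SpectroSegments: /spect (N,4,F,T), /freqs, /times, ids, labels."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spect", data=np.stack([s.spect for s in spects]).astype(np.float32))
        f.create_dataset("freqs", data=spects[0].freqs)
        f.create_dataset("times", data=spects[0].times)
        f.create_dataset("patient_id", data=np.array([s.patient_id for s in spects], dtype="S"))
        f.create_dataset("start_time", data=np.array([s.start_time for s in spects]))
        f.create_dataset(
            "label", data=np.array([s.label or "" for s in spects], dtype="S")
        )


def load_spectrograms_h5(path: str | Path):
    from neuromap.preprocess import SpectroSegment

    with h5py.File(path, "r") as f:
        spect = f["spect"][()].astype(float)
        freqs = f["freqs"][()]
        times = f["times"][()]
        pids = [s.decode() for s in f["patient_id"][()]]
        starts = f["start_time"][()]
        labels = [s.decode() or None for s in f["label"][()]]
    return [
        SpectroSegment(
            patient_id=pid, start_time=float(t0), spect=sp, freqs=freqs, times=times, label=lab
        )
        for sp, pid, t0, lab in zip(spect, pids, starts, labels)
    ]


def save_embeddings_h5(path: str | Path, embs) -> None:
    """Persist embeddings: /emb (N,dim) float32 plus provenance vectors."""
    with h5py.File(path, "w") as f:
        f.create_dataset("emb", data=np.stack([e.vector for e in embs]).astype(np.float32))
        f.create_dataset("patient_id", data=np.array([e.patient_id for e in embs], dtype="S"))
        f.create_dataset("start_time", data=np.array([e.start_time for e in embs]))
        f.create_dataset(
            "label", data=np.array([e.source_label or "" for e in embs], dtype="S")
        )


def load_embeddings_h5(path: str | Path):
    from neuromap.embedding import Embedding

    with h5py.File(path, "r") as f:
        vecs = f["emb"][()].astype(float)
        pids = [s.decode() for s in f["patient_id"][()]]
        starts = f["start_time"][()]
        labels = [s.decode() or None for s in f["label"][()]]
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)  # restore unit norm after float32
    return [
        Embedding(vector=v, patient_id=pid, start_time=float(t0), source_label=lab)
        for v, pid, t0, lab in zip(vecs, pids, starts, labels)
    ]
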