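"""Core data containers, EEG I/O, baseline correction, averaging and the
scaled-MAD outlier rule used for subject screening.

Time convention: milliseconds relative to TMS onset at all interfaces;
every window is half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .montage import ChannelMontage, default_montage

__all__ = [
    "Cell",
    "EpochedEEG",
    "EvokedResponse",
    "baseline_correct",
    "average_epochs",
    "mad_outlier_flags",
    "read_eeg",
    "write_eeg",
    "MAD_SCALE",
]

#: Consistency constant relating the MAD to the normal standard deviation.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class Cell:
    """Design-cell identity of a recording."""

    subject: str
    session: str  # "active" | "sham"
    time: str  # "pre" | "post"
    intensity: str = "na"  # "sub" | "supra" | "resting" | "na"

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "session": self.session,
            "time": self.time,
            "intensity": self.intensity,
        }


def _times_ms(n_samples: int, srate: float, t0_index: int) -> np.ndarray:
    return (np.arange(n_samples) - t0_index) / srate * 1000.0


@dataclass(frozen=True)
class EpochedEEG:
    """Epoched potentials in microvolts, ``channel x sample x trial``."""

    data: np.ndarray = field(repr=False)
    srate: float
    t0_index: int
    montage: ChannelMontage
    cell: Cell | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 2:
            data = data[:, :, None]
        if data.ndim != 3:
            raise ValueError("data must be channel x sample x trial")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if data.shape[2] < 1:
            raise ValueError("at least one trial is required")
        if data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{data.shape[0]} data channels vs "
                f"{self.montage.n_channels} montage labels"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to TMS onset."""
        return _times_ms(self.n_samples, self.srate, self.t0_index)

    def sample_index(self, t_ms: float) -> int:
        """Index of the first sample with time >= t_ms."""
        idx = int(np.ceil(t_ms / 1000.0 * self.srate + self.t0_index - 1e-9))
        return idx

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Half-open sample slice covering ``[start_ms, end_ms)``."""
        t = self.times_ms
        if start_ms >= end_ms:
            raise ValueError("window start must precede end")
        if start_ms < t[0] - 1e-9 or end_ms > t[-1] + 1000.0 / self.srate + 1e-9:
            raise ValueError(
                f"window ({start_ms}, {end_ms}) ms outside epoch span "
                f"[{t[0]:.3f}, {t[-1]:.3f}] ms"
            )
        lo = self.sample_index(start_ms)
        hi = self.sample_index(end_ms)
        if hi <= lo:
            raise ValueError(f"window ({start_ms}, {end_ms}) ms contains no samples")
        return slice(lo, hi)


@dataclass(frozen=True)
class EvokedResponse:
    """Trial-averaged potentials, ``channel x sample``."""

    data: np.ndarray = field(repr=False)
    srate: float
    t0_index: int
    montage: ChannelMontage
    cell: Cell | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 and data.ndim != 2:
            raise ValueError("data must be channel x sample")
        if data.ndim == 3:
            data = data[:, :, 0]
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return _times_ms(self.n_samples, self.srate, self.t0_index)

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        probe = EpochedEEG(self.data[:, :, None], self.srate, self.t0_index,
                           self.montage, self.cell)
        return probe.window_slice(start_ms, end_ms)


# ---------------------------------------------------------------------------
# operations


def baseline_correct(epochs: EpochedEEG,
                     window: tuple[float, float]) -> EpochedEEG:
    """Subtract, per channel and trial, the mean over ``[start, end)`` ms."""
    sl = epochs.window_slice(*window)
    base = epochs.data[:, sl, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def average_epochs(epochs: EpochedEEG) -> EvokedResponse:
    """Arithmetic mean over trials."""
    return EvokedResponse(epochs.data.mean(axis=2), epochs.srate,
                          epochs.t0_index, epochs.montage, epochs.cell)


def mad_outlier_flags(values, factor: float = 3.0) -> np.ndarray:
    """Flag values more than ``factor`` scaled MADs from the median.

    With MAD = 0 but non-constant data every value different from the
    median is flagged (convention; the threshold would otherwise be zero).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D list of at least 3 values")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if mad == 0.0:
        return dev > 0.0
    return dev > factor * MAD_SCALE * mad


def screen_subjects(bin_counts: Mapping[str, int], max_flagged: int) -> list[str]:
    """Subjects whose flagged-bin count exceeds the configured limit."""
    return [s for s, c in bin_counts.items() if c > max_flagged]


# ---------------------------------------------------------------------------
# internal container I/O
#
# One recording = a float64 little-endian matrix file (.dat) plus a JSON
# sidecar (.json) carrying labels, srate, t0_index, shape and cell metadata.
# Chosen so fixtures need no third-party reader and round-trip losslessly.

_MAGIC = b"TMEK"


def write_eeg(eeg: EpochedEEG | EvokedResponse, path: str) -> None:
    """Write a recording to the internal container at ``path`` (no suffix)."""
    base, _ = os.path.splitext(path)
    data = eeg.data if eeg.data.ndim == 3 else eeg.data[:, :, None]
    meta = {
        "labels": list(eeg.montage.names),
        "positions": eeg.montage.positions.tolist(),
        "srate": eeg.srate,
        "t0_index": eeg.t0_index,
        "shape": list(data.shape),
        "cell": eeg.cell.as_dict() if eeg.cell is not None else None,
        "evoked": isinstance(eeg, EvokedResponse),
    }
    with open(base + ".json", "w") as fh:
        json.dump(meta, fh)
    with open(base + ".dat", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(np.ascontiguousarray(data, dtype="<f8").tobytes())


def _read_internal(path: str) -> EpochedEEG | EvokedResponse:
    base, _ = os.path.splitext(path)
    with open(base + ".json") as fh:
        meta = json.load(fh)
    with open(base + ".dat", "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"{base}.dat is not an internal-container file")
        raw = np.frombuffer(fh.read(), dtype="<f8")
    shape = tuple(meta["shape"])
    data = raw.reshape(shape)
    montage = ChannelMontage(tuple(meta["labels"]), np.array(meta["positions"]))
    cell = Cell(**meta["cell"]) if meta.get("cell") else None
    if meta.get("evoked"):
        return EvokedResponse(data[:, :, 0], meta["srate"], meta["t0_index"],
                              montage, cell)
    return EpochedEEG(data, meta["srate"], meta["t0_index"], montage, cell)


# ---------------------------------------------------------------------------
# external formats (optional ingestion path)


def _read_brainvision(vhdr_path: str) -> EpochedEEG:
    """Minimal BrainVision reader: multiplexed binary .eeg + .vhdr header.

    Supports IEEE_FLOAT_32 and INT_16 with per-channel resolution, the
    variants produced by BrainVision recorders.  Epoch markers are not
    parsed; the file is returned as a single continuous "trial".
    """
    import configparser

    with open(vhdr_path, encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    # headers start with a non-INI banner line
    body = text[text.index("["):]
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str  # keep case
    cp.read_string(body)
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    srate = 1e6 / float(common["SamplingInterval"])
    fmt = cp["Binary Infos"]["BinaryFormat"].upper()
    labels, resolutions = [], []
    for i in range(1, n_ch + 1):
        parts = cp["Channel Infos"][f"Ch{i}"].split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    eeg_file = os.path.join(os.path.dirname(vhdr_path), common["DataFile"])
    raw = open(eeg_file, "rb").read()
    if fmt == "IEEE_FLOAT_32":
        arr = np.frombuffer(raw, dtype="<f4").astype(float)
    elif fmt == "INT_16":
        arr = np.frombuffer(raw, dtype="<i2").astype(float)
    else:
        raise ValueError(f"unsupported BinaryFormat {fmt}")
    arr = arr.reshape(-1, n_ch).T * np.array(resolutions)[:, None]
    try:
        montage = default_montage(tuple(labels))
    except ValueError as err:
        raise ValueError(f"channel labels do not fit the 10-10 template: {err}")
    return EpochedEEG(arr[:, :, None], srate, 0, montage)


def _read_edf(path: str) -> EpochedEEG:
    """Minimal EDF/EDF+ reader (continuous signals, uniform rate)."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        n_bytes_hdr = int(hdr[184:192])
        n_records = int(hdr[236:244])
        dur = float(hdr[244:252])
        n_sig = int(hdr[252:256])
        sig_hdr = fh.read(n_bytes_hdr - 256)

        # field layout: label16, transducer80, dim8, physmin8, physmax8,
        # digmin8, digmax8, prefilter80, n_samples8, reserved32
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        offsets = np.cumsum([0] + widths[:-1])

        def field_at(k):
            o, w = offsets[k], widths[k]
            base = o * n_sig
            return [sig_hdr[base + i * w: base + (i + 1) * w]
                    .decode("ascii").strip() for i in range(n_sig)]

        labels = field_at(0)
        phys_min = np.array([float(v) for v in field_at(3)])
        phys_max = np.array([float(v) for v in field_at(4)])
        dig_min = np.array([float(v) for v in field_at(5)])
        dig_max = np.array([float(v) for v in field_at(6)])
        ns = np.array([int(v) for v in field_at(8)])
        if len(set(ns)) != 1:
            raise ValueError("mixed per-signal sampling rates are unsupported")
        data = np.frombuffer(fh.read(), dtype="<i2").astype(float)
    per_rec = int(ns.sum())
    data = data[: n_records * per_rec].reshape(n_records, n_sig, ns[0])
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    phys = (data - dig_min[None, :, None]) * gain[None, :, None] \
        + phys_min[None, :, None]
    cont = np.concatenate([phys[r] for r in range(n_records)], axis=1)
    srate = ns[0] / dur
    labels = [lbl.split()[-1] if " " in lbl else lbl for lbl in labels]
    return EpochedEEG(cont[:, :, None], srate, 0, default_montage(tuple(labels)))


def read_eeg(path: str, format: str = "internal") -> EpochedEEG | EvokedResponse:
    """Read a recording; ``format`` is one of brainvision, edf, internal."""
    if format not in ("internal", "brainvision", "edf"):
        raise ValueError(f"unknown EEG format {format!r}")
    if not os.path.exists(path) and format != "internal":
        raise FileNotFoundError(path)
    if format == "internal":
        return _read_internal(path)
    if format == "brainvision":
        return _read_brainvision(path)
    return _read_edf(path)
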