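"""Reading, filtering, and windowing of multichannel EEG recordings.

A recording is a channels x timepoints matrix of amplitudes (microvolts)
with a sampling rate, a subject identifier, and a two-state label
(``normal`` / ``fatigue``).  Recordings are cut into non-overlapping
single-channel windows ("units"), the atomic classification instance of
the pipeline.

On-disk format: a delimited text matrix (one channel per row,
whitespace or comma separated) plus a sidecar ``<name>.meta`` key-value
file carrying ``fs``, ``subject_id``, ``state`` and optionally
``channel_names``.  EDF reading is available when :mod:`mne` is
installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "Epoch",
    "STATE_LABELS",
    "state_to_sign",
    "read_recording",
    "write_recording",
    "bandpass_filter",
    "window_epochs",
    "assemble_dataset",
]

#: Canonical class labels.  Internally normal -> +1, fatigue -> -1.
STATE_LABELS = ("normal", "fatigue")
_STATE_SIGN = {"normal": 1, "fatigue": -1}


def state_to_sign(state: str) -> int:
    """Map a state label to its numeric class, ``normal=+1``, ``fatigue=-1``."""
    try:
        return _STATE_SIGN[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}; expected one of {STATE_LABELS}")


@dataclass
class EEGRecording:
    """A multichannel EEG recording with metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_timepoints)
        Amplitudes in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz; must be positive.
    subject_id : str
        Opaque subject identifier.
    state : str
        One of ``"normal"`` or ``"fatigue"``.
    channel_names : list of str, optional
        Defaults to ``ch00, ch01, ...``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    state: str
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x timepoints matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        state_to_sign(self.state)  # validates
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_timepoints / self.fs


@dataclass
class Epoch:
    """One single-channel window of ``L`` amplitudes — a classification unit."""

    values: np.ndarray
    subject_id: str
    channel: str
    state: str
    epoch_index: int

    @property
    def label(self) -> int:
        return state_to_sign(self.state)


# ---------------------------------------------------------------------------
# I/O: delimited matrix + sidecar metadata, optional EDF
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def _parse_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def read_recording(
    path: str | Path,
    format: str = "delimited",
    meta: dict | None = None,
) -> EEGRecording:
    """Read a recording from disk.

    ``meta`` overrides/provides ``fs``, ``subject_id``, ``state`` and
    ``channel_names``; for the delimited format any key missing from
    ``meta`` is looked up in the ``<path>.meta`` sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = dict(meta or {})

    if format == "delimited":
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            file_meta = _parse_sidecar(sidecar)
            for key, value in file_meta.items():
                meta.setdefault(key, value)
        samples = _read_delimited_matrix(path)
    elif format == "edf":
        samples, fs_edf, names = _read_edf(path)
        meta.setdefault("fs", fs_edf)
        meta.setdefault("channel_names", names)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'delimited' or 'edf'")

    if "fs" not in meta:
        raise ValueError(f"missing sampling rate 'fs' for {path}")
    channel_names = meta.get("channel_names", [])
    if isinstance(channel_names, str):
        channel_names = [c.strip() for c in channel_names.split(",") if c.strip()]
    return EEGRecording(
        samples=samples,
        fs=float(meta["fs"]),
        subject_id=str(meta.get("subject_id", path.stem)),
        state=str(meta.get("state", "normal")),
        channel_names=list(channel_names),
    )


def _read_delimited_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.replace(",", " ").split()
        row = []
        for col, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {lineno}, column {col + 1}: {cell!r}"
                ) from None
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    return np.array(rows, dtype=float)


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - capability gate
        raise ImportError(
            "EDF reading requires the optional 'mne' dependency "
            "(install eegfatigue[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def write_recording(rec: EEGRecording, path: str | Path, fmt: str = "%.17g") -> Path:
    """Write a recording as a delimited matrix plus sidecar metadata.

    ``%.17g`` round-trips IEEE doubles bit-exactly through text.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.samples, fmt=fmt)
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        f"fs = {rec.fs!r}\n"
        f"subject_id = {rec.subject_id}\n"
        f"state = {rec.state}\n"
        f"channel_names = {', '.join(rec.channel_names)}\n"
    )
    return path


# ---------------------------------------------------------------------------
# Filtering and windowing
# ---------------------------------------------------------------------------

def bandpass_filter(
    rec: EEGRecording,
    low_hz: float = 0.15,
    high_hz: float = 45.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied forward-backward per channel.

    Realized as a cascade of a low-pass of the requested ``order`` and
    an order-2 high-pass: a monolithic band-pass with a sub-Hz low
    corner is numerically ill-conditioned at EEG sampling rates, while
    the cascade stays well behaved.  The high-pass is padded over
    several of its (slow) time constants so its startup transient
    decays inside the padding; an edge transient of roughly
    ``1 / low_hz`` seconds is still inherent to any zero-phase drift
    removal, so very short recordings are filtered best-effort.

    The default 0.15-45 Hz band is the conventional broadband EEG range.
    """
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyq} Hz"
        )
    sos_lp = sps.butter(order, high_hz, btype="lowpass", fs=rec.fs, output="sos")
    sos_hp = sps.butter(2, low_hz, btype="highpass", fs=rec.fs, output="sos")
    pad = min(rec.n_timepoints - 1, int(round(3.0 * rec.fs / low_hz)))
    filtered = sps.sosfiltfilt(sos_lp, rec.samples, axis=1)
    filtered = sps.sosfiltfilt(sos_hp, filtered, axis=1, padlen=pad)
    return EEGRecording(
        samples=filtered,
        fs=rec.fs,
        subject_id=rec.subject_id,
        state=rec.state,
        channel_names=list(rec.channel_names),
    )


def window_epochs(rec: EEGRecording, window_s: float = 1.0) -> list[Epoch]:
    """Cut a recording into non-overlapping windows of ``window_s`` seconds.

    Each channel is sectioned independently into half-open sample ranges
    ``[k*L, (k+1)*L)`` with ``L = round(fs * window_s)``; a trailing
    partial window is discarded.  A recording shorter than one window
    yields an empty list with a warning.
    """
    L = int(round(rec.fs * window_s))
    if L < 1:
        raise ValueError("window_s too short for this sampling rate")
    n_epochs = rec.n_timepoints // L
    if n_epochs == 0:
        warnings.warn(
            f"recording of {rec.n_timepoints} samples is shorter than one "
            f"{window_s}-s window ({L} samples); no epochs produced",
            stacklevel=2,
        )
        return []
    epochs: list[Epoch] = []
    for ch_idx, ch_name in enumerate(rec.channel_names):
        row = rec.samples[ch_idx]
        for k in range(n_epochs):
            epochs.append(
                Epoch(
                    values=row[k * L : (k + 1) * L],
                    subject_id=rec.subject_id,
                    channel=ch_name,
                    state=rec.state,
                    epoch_index=k,
                )
            )
    return epochs


def assemble_dataset(
    recordings: Iterable[EEGRecording], window_s: float = 1.0
) -> list[Epoch]:
    """Window every recording and concatenate the units in deterministic order.

    Raises on duplicated ``(subject, state, channel, epoch_index)`` keys,
    which would silently double-count units downstream.
    """
    epochs: list[Epoch] = []
    seen: set[tuple] = set()
    for rec in recordings:
        for ep in window_epochs(rec, window_s):
            key = (ep.subject_id, ep.state, ep.channel, ep.epoch_index)
            if key in seen:
                raise ValueError(f"duplicate unit key {key}")
            seen.add(key)
            epochs.append(ep)
    return epochs


def class_counts(epochs: Sequence[Epoch]) -> dict[str, int]:
    """Number of units per state label."""
    counts = {s: 0 for s in STATE_LABELS}
    for ep in epochs:
        counts[ep.state] += 1
    return counts
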