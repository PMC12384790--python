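"""Recording I/O, the preprocessing chain, epoching and sliding windows.

The preprocessing chain mirrors common practice for microstate studies:
band-pass filter -> integer-factor downsampling -> common-average
re-reference, applied to a continuous multichannel recording, followed by
extraction of fixed-length epochs ending at each trigger (the pre-event
preparation period, by default the 3 s before the trigger).

Two on-disk formats are supported: EDF (read via :mod:`mne`) and a plain
CSV matrix (rows = channels, first column = channel label, with the
sampling rate carried in a ``# fs=...`` header line).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "Epoch",
    "WindowSpec",
    "read_recording",
    "write_recording",
    "bandpass_filter",
    "downsample",
    "rereference_average",
    "epoch_prefire",
    "sliding_windows",
]


@dataclass
class EEGRecording:
    """A continuous multichannel recording.

    data : (n_channels, n_samples) array in microvolts.
    fs : sampling rate in Hz.
    channel_labels : unique channel names, one per row.
    reference : 'raw' or 'average'.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.reference not in ("raw", "average"):
            raise ValueError("reference must be 'raw' or 'average'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A fixed-length data segment cut around a trigger.

    t0_offset is the epoch start relative to the trigger in seconds
    (negative for pre-trigger data; the default prefire epoch has
    t0_offset = -3.0).
    """

    data: np.ndarray
    fs: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class WindowSpec:
    """Sliding-window geometry in seconds (default 1 s windows, 0.2 s step)."""

    length: float = 1.0
    step: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.length):
            raise ValueError("need 0 < step <= length")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_recording(path, fmt: str | None = None) -> EEGRecording:
    """Read an EDF or CSV-matrix recording from disk.

    ``fmt`` ('edf' or 'csv') is inferred from the extension when omitted.
    The returned recording is marked reference='raw'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: EEGRecording, path) -> None:
    """Write a recording as a CSV matrix (or EDF when the path ends .edf)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
        return
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs} reference={rec.reference}\n")
        for label, row in zip(rec.channel_labels, rec.data):
            fh.write(label + "," + ",".join(format(v, ".17g") for v in row) + "\n")


def _read_csv(path: Path) -> EEGRecording:
    fs = None
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("fs="):
                        fs = float(token[3:])
                continue
            cells = line.split(",")
            labels.append(cells[0])
            try:
                rows.append(np.array([float(c) for c in cells[1:]]))
            except ValueError as err:
                raise ValueError(f"{path}: non-numeric cell on line {lineno}: {err}") from None
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header line")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged rows (lengths {sorted(lengths)})")
    return EEGRecording(data=np.vstack(rows), fs=fs, channel_labels=labels, reference="raw")


def _read_edf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data, fs=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names),
        reference="raw",
    )


def _write_edf(rec: EEGRecording, path: Path) -> None:
    try:
        import mne
        info = mne.create_info(rec.channel_labels, rec.fs, ch_types="eeg")
        raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
        mne.export.export_raw(path, raw, fmt="edf", overwrite=True, verbose="error")
    except ImportError as err:  # pragma: no cover
        raise ImportError(f"writing EDF requires mne plus an EDF export backend: {err}")


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------

def bandpass_filter(rec: EEGRecording, lo_hz: float, hi_hz: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward, no phase lag).

    ``lo_hz = 0`` degenerates to a pure low-pass.  Passband gain is within
    5% at mid-band and stopband attenuation exceeds 20 dB one octave above
    ``hi_hz`` for the default order.
    """
    if not (0 <= lo_hz < hi_hz):
        raise ValueError("need 0 <= lo_hz < hi_hz")
    nyq = rec.fs / 2
    if hi_hz >= nyq:
        raise ValueError(f"hi_hz={hi_hz} must be below the Nyquist frequency {nyq}")
    if lo_hz == 0:
        sos = sps.butter(order, hi_hz, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    logger.info("bandpass %.3g-%.3g Hz (order %d, zero-phase)", lo_hz, hi_hz, order)
    return EEGRecording(filtered, rec.fs, rec.channel_labels, rec.reference)


def downsample(rec: EEGRecording, factor: int) -> EEGRecording:
    """Anti-aliased integer decimation: fs -> fs/factor, n -> floor(n/factor)."""
    if factor != int(factor) or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return rec
    new_fs = rec.fs / factor
    sos = sps.butter(8, 0.8 * new_fs / 2, btype="lowpass", fs=rec.fs, output="sos")
    smoothed = sps.sosfiltfilt(sos, rec.data, axis=1)
    n_out = rec.n_samples // factor
    out = smoothed[:, : n_out * factor : factor]
    logger.info("downsampled x%d: %.6g -> %.6g Hz", factor, rec.fs, new_fs)
    return EEGRecording(out, new_fs, rec.channel_labels, rec.reference)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Common average reference: subtract the per-sample channel mean."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, rec.fs, rec.channel_labels, reference="average")


def epoch_prefire(
    rec: EEGRecording,
    trigger_times,
    span: tuple[float, float] = (-3.0, 0.0),
) -> list[Epoch]:
    """Cut one epoch per trigger over ``[t + span[0], t + span[1])`` seconds.

    Sample indices follow the half-open convention; triggers whose span
    falls outside the recording are dropped with a warning.
    """
    t0, t1 = span
    if not t0 < t1:
        raise ValueError("span must have positive length")
    epochs: list[Epoch] = []
    n_len = round((t1 - t0) * rec.fs)
    for t in trigger_times:
        start = round((t + t0) * rec.fs)
        stop = start + n_len
        if start < 0 or stop > rec.n_samples:
            warnings.warn(f"trigger at {t} s: span exceeds recording; epoch dropped")
            continue
        epochs.append(Epoch(data=rec.data[:, start:stop], fs=rec.fs, t0_offset=t0))
    return epochs


def sliding_windows(epoch: Epoch, spec: WindowSpec | None = None) -> list[tuple[float, float, Epoch]]:
    """Slice an epoch into overlapping windows.

    Window i (1-based) spans [(i-1)*step, (i-1)*step + length] seconds
    relative to the epoch start; windows that would run past the end of
    the epoch are not emitted.  Returns (start_s, end_s, sub_epoch)
    triples, with times relative to the epoch start.
    """
    if spec is None:
        spec = WindowSpec()
    dur = epoch.duration
    if spec.length > dur + 1e-9:
        raise ValueError("window longer than epoch")
    n_win = int(np.floor((dur - spec.length) / spec.step + 1e-9)) + 1
    out = []
    for i in range(n_win):
        start_s = i * spec.step
        a = round(start_s * epoch.fs)
        b = a + round(spec.length * epoch.fs)
        sub = Epoch(
            data=epoch.data[:, a:b], fs=epoch.fs, t0_offset=epoch.t0_offset + start_s
        )
        out.append((start_s, start_s + spec.length, sub))
    return out
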