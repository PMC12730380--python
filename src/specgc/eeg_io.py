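"""Reading recordings, band-pass filtering, and epoch extraction.

Conventions: time in seconds, 0-based samples, half-open sample windows
``[start, end)``. Band-pass filtering is zero-phase (forward-backward
Butterworth): a phase-distorting filter shifts channels by different group
delays and can fabricate spurious lead-lag structure, which a
direction-sensitive measure would mistake for causality — hence zero-phase
is not configurable.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .containers import MultiTrialSegment

__all__ = [
    "EpochSpec",
    "read_recording",
    "write_csv",
    "write_edf",
    "bandpass",
    "extract_epochs",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochSpec:
    """An analysis window relative to the reference point (e.g. seizure onset).

    ``start_offset`` is in seconds, negative = before the reference;
    ``duration`` in seconds, > 0.
    """

    label: str
    start_offset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"epoch {self.label!r}: duration must be positive")


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _read_csv(path: Path, fs: float | None) -> MultiTrialSegment:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    if cols and cols[0].lower() in ("time_s", "time", "t"):
        t = df[cols[0]].to_numpy(dtype=float)
        if fs is None:
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise ValueError("time column is not increasing")
            fs = 1.0 / dt
        df = df.drop(columns=cols[0])
    if fs is None:
        raise ValueError(
            "CSV has no time column; pass the sampling rate explicitly (fs=...)"
        )
    data = df.to_numpy(dtype=float).T  # (channels, samples)
    return MultiTrialSegment(data[None], fs=float(fs), labels=tuple(df.columns))


def _read_edf(path: Path) -> MultiTrialSegment:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    # mne stores EEG in volts; report microvolts, the native EEG unit
    data = raw.get_data() * 1e6
    return MultiTrialSegment(data[None], fs=fs, labels=tuple(raw.ch_names))


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    channels: list[str] | None = None,
    fs: float | None = None,
) -> MultiTrialSegment:
    """Read a recording as a single-trial segment.

    ``fmt`` is ``"edf"`` or ``"csv"``; inferred from the suffix when omitted.
    ``channels`` restricts and *orders* the output channels. For CSV, the
    first column may be a time axis (``time_s``) from which the sampling
    rate is inferred; otherwise pass ``fs``. EDF channel data are returned
    in microvolts. Sample ``i`` is at time ``i / fs`` seconds from file start.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in ("csv", "tsv", "txt"):
        seg = _read_csv(path, fs)
    elif fmt == "edf":
        seg = _read_edf(path)
    else:
        raise ValueError(f"unknown recording format {fmt!r} (expected edf or csv)")
    if channels is not None:
        seg = seg.select(channels)
    return seg


def write_csv(path: str | Path, segment: MultiTrialSegment) -> None:
    """Write a single-trial segment as CSV with a leading time_s column."""
    if segment.n_trials != 1:
        raise ValueError("CSV export is defined for single-trial segments")
    df = pd.DataFrame(segment.data[0].T, columns=list(segment.labels))
    df.insert(0, "time_s", np.arange(segment.n_samples) / segment.fs)
    df.to_csv(path, index=False)


def write_edf(path: str | Path, segment: MultiTrialSegment, phys_dim: str = "uV") -> None:
    """Write a single-trial segment as a minimal 16-bit EDF file.

    Standard 256-byte header plus one 256-byte block per signal; one data
    record per second, so the sampling rate must be a positive integer and
    the segment is zero-padded to a whole number of seconds. Intended for
    fixtures and round-trips, not for clinical interchange metadata.
    """
    if segment.n_trials != 1:
        raise ValueError("EDF export is defined for single-trial segments")
    fs = segment.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per 1-second record
    data = segment.data[0]
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    pmin = np.minimum(padded.min(axis=1), -1e-6)
    pmax = np.maximum(padded.max(axis=1), 1e-6)
    dmin, dmax = -32768, 32767

    def f(x, width):  # fixed-width ascii field
        s = str(x)[:width]
        return s.ljust(width).encode("ascii")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate X X X X", 80),
            f(now.strftime("%d.%m.%y"), 8),
            f(now.strftime("%H.%M.%S"), 8),
            f(256 * (1 + n_ch), 8),
            f("", 44),
            f(n_rec, 8),
            f("1", 8),
            f(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(f(lab, 16) for lab in segment.labels),
            b"".join(f("", 80) for _ in range(n_ch)),
            b"".join(f(phys_dim, 8) for _ in range(n_ch)),
            b"".join(f(f"{pmin[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(f(f"{pmax[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(f(dmin, 8) for _ in range(n_ch)),
            b"".join(f(dmax, 8) for _ in range(n_ch)),
            b"".join(f("", 80) for _ in range(n_ch)),
            b"".join(f(spr, 8) for _ in range(n_ch)),
            b"".join(f("", 32) for _ in range(n_ch)),
        ]
    )
    # physical values are re-read from the truncated ascii fields so that
    # digital quantization round-trips exactly against the written header
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    gain = (dmax - dmin) / (pmax_r - pmin_r)
    digital = np.rint((padded - pmin_r[:, None]) * gain[:, None] + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass(
    segment: MultiTrialSegment, lo_hz: float, hi_hz: float, order: int = 4
) -> MultiTrialSegment:
    """Zero-phase Butterworth band-pass (forward-backward, effective order 2x).

    ``hi_hz`` equal to the Nyquist frequency is clipped to 0.99x Nyquist with
    a logged warning, so the 80-500 Hz band is expressible at a 1 kHz rate.
    """
    nyq = segment.fs / 2
    if not 0 < lo_hz < hi_hz:
        raise ValueError(f"need 0 < lo < hi, got ({lo_hz}, {hi_hz})")
    if lo_hz >= nyq:
        raise ValueError(f"low edge {lo_hz} Hz at or above Nyquist {nyq} Hz")
    if hi_hz > nyq:
        raise ValueError(f"high edge {hi_hz} Hz above Nyquist {nyq} Hz")
    if hi_hz == nyq:
        hi_hz = 0.99 * nyq
        logger.warning("band high edge at Nyquist; clipped to %.6g Hz", hi_hz)
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=segment.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, segment.data, axis=-1)
    return MultiTrialSegment(
        filtered, fs=segment.fs, labels=segment.labels,
        epoch_tag=segment.epoch_tag, t0=segment.t0,
    )


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------

def extract_epochs(
    segment: MultiTrialSegment,
    reference_time_s: float,
    specs: list[EpochSpec],
    trial_split: float | None = None,
) -> list[MultiTrialSegment]:
    """Cut analysis epochs out of a single-trial recording.

    Windows are half-open in samples: ``[round((ref+offset)*fs),
    start + round(duration*fs))``, so adjacent epochs neither lose nor
    duplicate samples. With ``trial_split`` (seconds) each epoch is chopped
    into consecutive non-overlapping sub-windows forming the trial axis for
    multitaper averaging; a fractional leftover shorter than one sub-window
    is dropped. The output ``t0`` is relative to the reference point.
    """
    if segment.n_trials != 1:
        raise ValueError("extract_epochs expects a single-trial recording")
    n = segment.n_samples
    fs = segment.fs
    out = []
    for spec in specs:
        start = int(round((reference_time_s + spec.start_offset) * fs))
        length = int(round(spec.duration * fs))
        end = start + length
        if start < 0:
            raise ValueError(
                f"epoch {spec.label!r} starts {-start / fs:.3f} s before the recording"
            )
        if end > n:
            raise ValueError(
                f"epoch {spec.label!r} overruns the recording by {(end - n) / fs:.3f} s"
            )
        chunk = segment.data[:, :, start:end]
        if trial_split is not None:
            spt = int(round(trial_split * fs))
            n_tr = length // spt
            if n_tr < 1:
                raise ValueError(
                    f"epoch {spec.label!r}: trial_split {trial_split} s longer than epoch"
                )
            chunk = chunk[0, :, : n_tr * spt].reshape(
                segment.n_channels, n_tr, spt
            ).transpose(1, 0, 2)
        out.append(
            MultiTrialSegment(
                chunk,
                fs=fs,
                labels=segment.labels,
                epoch_tag=spec.label,
                t0=start / fs - reference_time_s,
            )
        )
    return out
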