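"""Recording containers, session I/O, filtering, epoching, and the inclusion gate.

The raw unit of analysis is a :class:`SessionRecording`: simultaneously
recorded multichannel LFP from the basolateral amygdala (BLA) and ventral
hippocampus (vHPC) during one phase of a social interaction test, together
with the timestamps at which the animal entered the interaction zone.

Sessions are stored one directory per session: ``signal.h5`` (or a
``signal.csv`` fallback) holding a channels x samples matrix per region,
``meta.json`` with group/phase/subject and event times, and optionally
``behavior.json``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

try:
    import h5py

    _HAVE_H5PY = True
except ImportError:  # pragma: no cover - h5py is a hard dependency in practice
    _HAVE_H5PY = False

REGIONS = ("BLA", "vHPC")

#: Acquisition band of the recording system (Hz).
ACQUISITION_BAND = (0.5, 250.0)

#: Event-locked analysis window relative to zone entry (s).
DEFAULT_WINDOW_S = (-3.0, 3.0)


class InclusionStatus(Enum):
    """Outcome of the social-interaction-ratio gate for stressed animals."""

    SUSCEPTIBLE_INCLUDED = "susceptible_included"
    RESILIENT_EXCLUDED = "resilient_excluded"


@dataclass
class SessionRecording:
    """Two-region multichannel LFP recording for one subject and phase.

    Parameters
    ----------
    signals
        Mapping region name -> (n_channels, n_samples) float array, in
        arbitrary LFP units.
    sampling_rate_hz
        Sampling rate; must exceed twice the highest analysis frequency
        (90 Hz).
    events_s
        Strictly increasing zone-entry times in seconds, recording start = 0.
    meta
        Free-form metadata; by convention holds ``subject``, ``group`` and
        ``phase``.
    """

    signals: Mapping[str, np.ndarray]
    sampling_rate_hz: float
    events_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = {r: np.asarray(s, dtype=float) for r, s in self.signals.items()}
        self.events_s = np.asarray(self.events_s, dtype=float)
        if self.sampling_rate_hz <= 2 * 90.0:
            raise ValueError(
                "sampling_rate_hz must exceed 180 Hz (twice the 90 Hz analysis limit)"
            )
        lengths = set()
        for region, sig in self.signals.items():
            if sig.ndim != 2:
                raise ValueError(f"region {region!r}: signals must be channels x samples")
            lengths.add(sig.shape[1])
        if len(lengths) > 1:
            raise ValueError("all regions must have the same number of samples")
        if self.events_s.size:
            if np.any(np.diff(self.events_s) <= 0):
                raise ValueError("events_s must be strictly increasing")
            if self.events_s[0] < 0 or self.events_s[-1] > self.duration_s:
                raise ValueError("events_s must lie within [0, duration]")

    @property
    def n_samples(self) -> int:
        return next(iter(self.signals.values())).shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.signals)


@dataclass
class Epoch:
    """Channel-averaged signal in a window around one zone-entry event.

    ``window_s`` is relative to the event; the window is half-open
    ``[start, end)`` so an epoch of (-3, +3) s at 2 kHz has exactly 12000
    samples and contains the event at relative time 0.
    """

    region: str
    data: np.ndarray
    window_s: tuple[float, float]
    event_time_s: float
    epoch_id: str
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        start, end = self.window_s
        expected = int(round((end - start) * self.sampling_rate_hz))
        if self.data.size != expected:
            raise ValueError(
                f"epoch {self.epoch_id}: expected {expected} samples, got {self.data.size}"
            )
        if not (start <= 0.0 < end):
            raise ValueError("epoch window must contain the event time 0")


def bandpass_filter(
    x: np.ndarray, low_hz: float, high_hz: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    Forward-backward (``sosfiltfilt``) filtering, so no phase distortion of
    event-locked features. A 4th-order Butterworth run both ways gives a
    monotone passband and >40 dB attenuation one octave outside the band.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for Nyquist {fs / 2} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def average_channels(signals: np.ndarray) -> np.ndarray:
    """Arithmetic mean across channels (axis 0) of a channels x samples array."""
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 1:
        signals = signals[None, :]
    if signals.shape[0] == 0:
        raise ValueError("cannot average zero channels")
    return signals.mean(axis=0)


def extract_epochs(
    recording: SessionRecording,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
) -> tuple[list[Epoch], int]:
    """Cut channel-averaged, event-locked epochs from a recording.

    One epoch per region per event whose full window lies inside the
    recording; boundary events are skipped (never zero-padded) and counted.

    Returns
    -------
    epochs, n_skipped
        ``n_skipped`` counts skipped *events*; per region,
        ``len(epochs per region) + n_skipped == len(events)``.
    """
    start, end = window_s
    fs = recording.sampling_rate_hz
    n_win = int(round((end - start) * fs))
    n = recording.n_samples
    averaged = {r: average_channels(sig) for r, sig in recording.signals.items()}

    epochs: list[Epoch] = []
    n_skipped = 0
    for i, t in enumerate(recording.events_s):
        i0 = int(round((t + start) * fs))
        i1 = i0 + n_win
        if i0 < 0 or i1 > n:
            n_skipped += 1
            continue
        for region, trace in averaged.items():
            epochs.append(
                Epoch(
                    region=region,
                    data=trace[i0:i1],
                    window_s=(start, end),
                    event_time_s=float(t),
                    epoch_id=f"{recording.meta.get('subject', 'subject')}:ev{i}:{region}",
                    sampling_rate_hz=fs,
                )
            )
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} event(s) with truncated windows", stacklevel=2
        )
    return epochs, n_skipped


def include_subject(behavior) -> InclusionStatus:
    """Apply the susceptibility gate: SI ratio < 1 is included for the
    oscillation analysis; SI >= 1 is labelled resilient and excluded from the
    susceptible-vs-control contrasts."""
    ratio = behavior.si_ratio if hasattr(behavior, "si_ratio") else float(behavior)
    if ratio is None or not np.isfinite(ratio):
        raise ValueError("SI ratio undefined (zero time in zone without the target?)")
    if ratio < 1.0:
        return InclusionStatus.SUSCEPTIBLE_INCLUDED
    return InclusionStatus.RESILIENT_EXCLUDED


# ---------------------------------------------------------------------------
# Session directory I/O


def write_session(recording: SessionRecording, directory: str | Path,
                  behavior: dict | None = None, use_hdf5: bool = True) -> Path:
    """Write a session directory: ``signal.h5`` (or ``signal.csv``),
    ``meta.json`` and optionally ``behavior.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if use_hdf5 and _HAVE_H5PY:
        with h5py.File(directory / "signal.h5", "w") as f:
            f.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
            for region, sig in recording.signals.items():
                # track_times=False keeps equal recordings byte-identical
                f.create_dataset(region, data=sig, track_times=False)
    else:
        _write_signal_csv(recording, directory / "signal.csv")
    meta = dict(recording.meta)
    meta["events_s"] = [float(t) for t in recording.events_s]
    meta["sampling_rate_hz"] = recording.sampling_rate_hz
    meta["regions"] = list(recording.signals)
    with open(directory / "meta.json", "w") as f:
        json.dump(meta, f, indent=1, sort_keys=True)
    if behavior is not None:
        with open(directory / "behavior.json", "w") as f:
            json.dump(behavior, f, indent=1, sort_keys=True)
    return directory


def read_session(directory: str | Path) -> SessionRecording:
    """Read a session directory written by :func:`write_session` (HDF5 or the
    plain-CSV fallback with ``region:channel`` column headers)."""
    directory = Path(directory)
    with open(directory / "meta.json") as f:
        meta = json.load(f)
    events = np.asarray(meta.pop("events_s", []), dtype=float)
    fs = float(meta.pop("sampling_rate_hz"))
    meta.pop("regions", None)
    h5path = directory / "signal.h5"
    if h5path.exists() and _HAVE_H5PY:
        signals = {}
        with h5py.File(h5path, "r") as f:
            for region in f:
                signals[region] = f[region][()]
    else:
        signals = _read_signal_csv(directory / "signal.csv")
    return SessionRecording(signals=signals, sampling_rate_hz=fs,
                            events_s=events, meta=meta)


def _write_signal_csv(recording: SessionRecording, path: Path) -> None:
    headers: list[str] = []
    columns: list[np.ndarray] = []
    for region, sig in recording.signals.items():
        for ch in range(sig.shape[0]):
            headers.append(f"{region}:{ch}")
            columns.append(sig[ch])
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(headers)
        for row in zip(*columns):
            writer.writerow([repr(float(v)) for v in row])


def _read_signal_csv(path: Path) -> dict[str, np.ndarray]:
    with open(path) as f:
        reader = csv.reader(f)
        headers = next(reader)
        data = np.array([[float(v) for v in row] for row in reader])
    signals: dict[str, list[np.ndarray]] = {}
    for j, head in enumerate(headers):
        region = head.split(":")[0]
        signals.setdefault(region, []).append(data[:, j])
    return {r: np.vstack(chs) for r, chs in signals.items()}


def read_behavior(directory: str | Path) -> dict:
    with open(Path(directory) / "behavior.json") as f:
        return json.load(f)
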