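"""STFT power spectral density, band powers per stage, and the PSD-change
statistic.

The spectral estimate follows the recording-analysis convention used for
event-locked LFP: a short-time Fourier transform with a 1 s Hamming window on
a 0.5 Hz frequency grid (the 1 s window is zero-padded to 2 s to reach 0.5 Hz
resolution), hop 0.1 s, density scaling (signal-units^2/Hz). Band powers are
means of the PSD over five canonical bands; the 12-13 Hz gap between the
printed theta and beta bands is kept verbatim, so frequencies in [12, 13) Hz
belong to neither.

The headline statistic is the change in PSD between test phases:
``delta PSD = PSD(With CD1) - PSD(No CD1)`` for a matching band, stage
(pre-entry -3-0 s vs post-entry 0-3 s) and region.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

from .io import Epoch

#: The five analysis bands (Hz), closed-open intervals [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 12.0),
    "beta": (13.0, 30.0),
    "lowgamma": (30.0, 60.0),
    "highgamma": (60.0, 90.0),
}

BAND_ORDER = tuple(BANDS)

FREQ_MIN_HZ = 0.5
FREQ_MAX_HZ = 90.0
FREQ_STEP_HZ = 0.5
WINDOW_LEN_S = 1.0
HOP_S = 0.1


class Stage(str, Enum):
    PRE = "PRE"    # -3-0 s before zone entry
    POST = "POST"  # 0-3 s after zone entry
    FULL = "FULL"  # whole epoch


@dataclass
class Spectrogram:
    """STFT power on the fixed 0.5-90 Hz / 0.5 Hz grid.

    ``times_s`` are window-center times relative to the event (epoch time 0);
    edge windows whose support would leave the epoch are dropped, never
    padded.
    """

    freqs_hz: np.ndarray
    times_s: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), signal-units^2/Hz
    window_len_s: float = WINDOW_LEN_S
    window_type: str = "hamming"

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD must be nonnegative")
        steps = np.diff(self.freqs_hz)
        if steps.size and not np.allclose(steps, FREQ_STEP_HZ):
            raise ValueError("frequency grid step must be exactly 0.5 Hz")


@dataclass
class BandPower:
    band: str
    stage: Stage
    region: str
    value: float
    phase: str | None = None

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.value < 0:
            raise ValueError("band power must be nonnegative")


def stft_psd(epoch: Epoch, hop_s: float = HOP_S) -> Spectrogram:
    """Short-time Fourier PSD of one channel-averaged epoch.

    Hamming window of 1 s, zero-padded to 2 s NFFT so the grid step is
    exactly 0.5 Hz at any sampling rate, density scaling. Requires
    ``fs >= 2 * 90`` Hz and an epoch at least one window long.
    """
    fs = epoch.sampling_rate_hz
    nperseg = int(round(WINDOW_LEN_S * fs))
    if epoch.data.size < nperseg:
        raise ValueError(
            f"epoch of {epoch.data.size} samples shorter than the "
            f"{nperseg}-sample analysis window"
        )
    hop = max(int(round(hop_s * fs)), 1)
    freqs, times, power = sps.spectrogram(
        epoch.data,
        fs=fs,
        window=sps.get_window("hamming", nperseg),
        nperseg=nperseg,
        noverlap=nperseg - hop,
        nfft=2 * nperseg,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    keep = (freqs >= FREQ_MIN_HZ - 1e-9) & (freqs <= FREQ_MAX_HZ + 1e-9)
    return Spectrogram(
        freqs_hz=freqs[keep],
        times_s=times + epoch.window_s[0],
        power=power[keep, :],
    )


def _stage_columns(spec: Spectrogram, stage: Stage) -> np.ndarray:
    if stage is Stage.FULL:
        return np.ones_like(spec.times_s, dtype=bool)
    lo, hi = (-3.0, 0.0) if stage is Stage.PRE else (0.0, 3.0)
    return (spec.times_s >= lo) & (spec.times_s < hi)


def band_power(spec: Spectrogram, band: str, stage: Stage | str = Stage.FULL,
               region: str = "", phase: str | None = None) -> BandPower:
    """Mean PSD over a band's frequency rows and a stage's time columns.

    Stage membership is by window-center time, half-open [start, end); band
    intervals are closed-open [lo, hi).
    """
    stage = Stage(stage)
    lo, hi = BANDS[band]
    rows = (spec.freqs_hz >= lo - 1e-9) & (spec.freqs_hz < hi - 1e-9)
    cols = _stage_columns(spec, stage)
    if not rows.any() or not cols.any():
        raise ValueError(f"empty selection for band {band!r}, stage {stage.value}")
    value = float(spec.power[np.ix_(rows, cols)].mean())
    return BandPower(band=band, stage=stage, region=region, value=value, phase=phase)


def dominant_band(spec: Spectrogram) -> str:
    """Band with maximal full-epoch mean PSD; ties resolved toward the lower
    band (deterministic)."""
    if not np.any(spec.power > 0):
        raise ValueError("all-zero spectrogram has no dominant band")
    values = [band_power(spec, b, Stage.FULL).value for b in BAND_ORDER]
    return BAND_ORDER[int(np.argmax(values))]  # argmax takes the first maximum


def psd_change(with_cd1: BandPower, no_cd1: BandPower) -> float:
    """PSD change between phases: With-CD1 value minus No-CD1 value for a
    matching band, stage and region. The sign is preserved (post-entry
    changes are typically negative)."""
    for attr in ("band", "stage", "region"):
        if getattr(with_cd1, attr) != getattr(no_cd1, attr):
            raise ValueError(
                f"mismatched {attr}: {getattr(with_cd1, attr)!r} vs "
                f"{getattr(no_cd1, attr)!r}"
            )
    return with_cd1.value - no_cd1.value


def epoch_band_powers(epochs: list[Epoch], phase: str | None = None,
                      hop_s: float = HOP_S) -> "pandas.DataFrame":
    """Tidy per-epoch band/stage PSD table (one row per epoch x band x
    stage), the common currency of the group statistics and the decoder."""
    import pandas as pd

    rows = []
    for ep in epochs:
        spec = stft_psd(ep, hop_s=hop_s)
        for band in BAND_ORDER:
            for stage in (Stage.PRE, Stage.POST, Stage.FULL):
                bp = band_power(spec, band, stage, region=ep.region, phase=phase)
                rows.append({
                    "epoch_id": ep.epoch_id,
                    "region": ep.region,
                    "band": band,
                    "stage": stage.value,
                    "phase": phase,
                    "value": bp.value,
                })
    return pd.DataFrame(rows)
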