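"""Synthetic two-region LFP sessions with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: theta-dominant (4-12 Hz) oscillations riding on 1/f background noise
in BLA and vHPC, directed BLA->vHPC amplitude coupling at a fixed lag,
anticipatory theta elevation in the With-CD1 phase, a multiplicative theta
change in the 0-3 s window after each zone entry, and group presets that
reproduce the reported stress effects (susceptible mice: BLA theta up, vHPC
theta down, weaker BLA->vHPC coupling, a larger-magnitude post-entry theta
drop; ketamine: each effect moved back toward control).

Theta is generated as Gaussian noise band-passed around the theta center
frequency, not as a pure sinusoid: transfer entropy between amplitude
envelopes is degenerate when the envelope is constant, so realistic envelope
fluctuations are essential ground truth. Coupling is imposed on envelopes
(the vHPC theta carrier is re-modulated by a mixture of its own envelope and
the delayed BLA envelope), matching the amplitude-based connectivity measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from enum import Enum
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy import signal as sps
from scipy import stats

from .io import SessionRecording, bandpass_filter


class Phase(str, Enum):
    """Social-interaction-test phase: target cage empty vs CD1 aggressor present."""

    NO_CD1 = "NO_CD1"
    WITH_CD1 = "WITH_CD1"


class Group(str, Enum):
    CON = "CON"
    RSDS_SUSCEPTIBLE = "RSDS_SUSCEPTIBLE"
    RSDS_RESILIENT = "RSDS_RESILIENT"
    SALINE = "SALINE"
    KETAMINE = "KETAMINE"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session.

    Amplitudes are in arbitrary LFP units; the theta oscillator in each
    region has unit RMS before scaling by ``theta_amp_*``, and the 1/f
    background has RMS ``noise_scale`` within the 0.5-250 Hz acquisition
    band. ``post_entry_theta_factor`` multiplies the theta amplitude in the
    0-3 s window after each zone entry, per phase; ``theta_gain_with_cd1``
    scales theta throughout the With-CD1 phase (anticipatory elevation), so
    the With-minus-No PSD change can be positive before entry and negative
    after it, as observed.
    """

    sampling_rate_hz: float = 2000.0
    duration_s: float = 90.0
    theta_center_hz: float = 8.0
    theta_bandwidth_hz: float = 8.0  # full 4-12 Hz theta band
    theta_amp_bla: float = 1.0
    theta_amp_vhpc: float = 1.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    coupling_gain: float = 0.6
    coupling_lag_s: float = 0.1
    event_rate_per_min: float = 15.0
    post_entry_theta_factor: Mapping[str, float] = field(
        default_factory=lambda: {"NO_CD1": 1.0, "WITH_CD1": 0.85}
    )
    theta_gain_with_cd1: float = 1.10
    n_channels_per_region: int = 8
    channel_noise_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if not (4.0 <= self.theta_center_hz <= 12.0):
            raise ValueError("theta_center_hz must lie in the 4-12 Hz theta band")
        if self.theta_bandwidth_hz <= 0:
            raise ValueError("theta_bandwidth_hz must be positive")
        for name in ("theta_amp_bla", "theta_amp_vhpc", "noise_scale",
                     "channel_noise_scale"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if not (0.0 <= self.coupling_gain <= 1.0):
            raise ValueError("coupling_gain must lie in [0, 1]")
        if self.coupling_lag_s < 0 or self.coupling_lag_s >= self.duration_s:
            raise ValueError("coupling_lag_s must be in [0, duration_s)")
        if self.event_rate_per_min <= 0:
            raise ValueError("event_rate_per_min must be positive")
        if self.n_channels_per_region < 1:
            raise ValueError("need at least one channel per region")
        for v in self.post_entry_theta_factor.values():
            if v <= 0:
                raise ValueError("post_entry_theta_factor values must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["post_entry_theta_factor"] = dict(self.post_entry_theta_factor)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**d)


@dataclass(frozen=True)
class GroupPreset:
    """Named set of SimConfig overrides defining a study group."""

    name: Group
    overrides: Mapping[str, object] = field(default_factory=dict)

    def apply(self, config: SimConfig) -> SimConfig:
        return replace(config, **dict(self.overrides))


# Group presets: directions follow the reported effects (susceptible stress:
# BLA theta power up, vHPC theta power down, weaker BLA->vHPC coupling, a
# larger-magnitude post-entry theta change in the With-CD1 phase; ketamine
# moves every one of these strictly back toward control). Magnitudes are free
# parameters of the generator, chosen once to give clear but not degenerate
# effects at n = 8 subjects per group.
PRESETS: dict[Group, GroupPreset] = {
    Group.CON: GroupPreset(Group.CON, {
        "theta_amp_bla": 1.0, "theta_amp_vhpc": 1.0, "coupling_gain": 0.6,
        "theta_gain_with_cd1": 1.10,
        "post_entry_theta_factor": {"NO_CD1": 1.0, "WITH_CD1": 0.85},
    }),
    Group.RSDS_SUSCEPTIBLE: GroupPreset(Group.RSDS_SUSCEPTIBLE, {
        "theta_amp_bla": 1.4, "theta_amp_vhpc": 0.7, "coupling_gain": 0.25,
        "theta_gain_with_cd1": 1.20,
        # post-entry factor chosen so the group ratio of post-entry PSD
        # change magnitudes matches the ~2.6x reported contrast
        "post_entry_theta_factor": {"NO_CD1": 1.0, "WITH_CD1": 0.55},
    }),
    Group.RSDS_RESILIENT: GroupPreset(Group.RSDS_RESILIENT, {
        "theta_amp_bla": 1.1, "theta_amp_vhpc": 0.9, "coupling_gain": 0.5,
        "theta_gain_with_cd1": 1.12,
        "post_entry_theta_factor": {"NO_CD1": 1.0, "WITH_CD1": 0.80},
    }),
    Group.SALINE: GroupPreset(Group.SALINE, {
        "theta_amp_bla": 1.4, "theta_amp_vhpc": 0.7, "coupling_gain": 0.25,
        "theta_gain_with_cd1": 1.20,
        "post_entry_theta_factor": {"NO_CD1": 1.0, "WITH_CD1": 0.55},
    }),
    Group.KETAMINE: GroupPreset(Group.KETAMINE, {
        "theta_amp_bla": 1.15, "theta_amp_vhpc": 0.88, "coupling_gain": 0.45,
        "theta_gain_with_cd1": 1.14,
        "post_entry_theta_factor": {"NO_CD1": 1.0, "WITH_CD1": 0.76},
    }),
}


# ---------------------------------------------------------------------------
# Behavior generator


@dataclass(frozen=True)
class GroupBehavior:
    """Mean and SD (derived from the printed SEM, SD = SEM * sqrt(n)) of the
    behavioral measures for one group."""

    time_zone_no_cd1_mean_s: float
    time_zone_no_cd1_sd_s: float
    time_zone_with_cd1_mean_s: float
    time_zone_with_cd1_sd_s: float
    tst_immobility_mean_s: float
    tst_immobility_sd_s: float
    n: int = 8


def _sd(sem: float, n: int = 8) -> float:
    return sem * math.sqrt(n)


#: Default behavioral parameters: reported group means +/- SEM at n = 8.
#: Stressed mice avoid the interaction zone when the CD1 aggressor is present
#: (91 s vs 277 s in controls out of 600 s) and hang immobile longer in the
#: tail suspension test; drug groups mirror control (ketamine) or stressed
#: (saline) behavior.
DEFAULT_BEHAVIOR: dict[Group, GroupBehavior] = {
    Group.CON: GroupBehavior(195.9, _sd(15.81), 277.3, _sd(31.83), 102.2, _sd(6.050)),
    Group.RSDS_SUSCEPTIBLE: GroupBehavior(
        239.8, _sd(16.46), 91.12, _sd(18.98), 184.4, _sd(6.339)
    ),
    Group.RSDS_RESILIENT: GroupBehavior(
        200.0, _sd(16.0), 250.0, _sd(30.0), 120.0, _sd(8.0)
    ),
    Group.SALINE: GroupBehavior(
        239.8, _sd(16.46), 91.12, _sd(18.98), 184.4, _sd(6.339)
    ),
    Group.KETAMINE: GroupBehavior(
        220.0, _sd(16.0), 240.0, _sd(28.0), 120.0, _sd(7.0)
    ),
}

BehaviorGenParams = dict  # group -> GroupBehavior mapping


@lru_cache(maxsize=None)
def _truncnorm_location(target_mean: float, sd: float) -> float:
    """Location of a zero-truncated normal (scale ``sd``) whose *truncated*
    mean equals ``target_mean``.

    A naive truncation at zero shifts the mean upward (by ~6% when
    mean/sd ~ 1.7), so the location is solved such that
    E[X | X > 0] = target_mean.
    """
    if target_mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")

    def trunc_mean(mu: float) -> float:
        a = -mu / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)

    if trunc_mean(target_mean) <= target_mean:  # truncation negligible
        return target_mean
    return optimize.brentq(lambda m: trunc_mean(m) - target_mean,
                           target_mean - 6 * sd, target_mean, xtol=1e-10)


def _truncnorm_mean_matched(target_mean: float, sd: float, rng: np.random.Generator,
                            size: int | None = None):
    """Draw from the mean-matched zero-truncated normal."""
    mu = _truncnorm_location(target_mean, sd)
    a = -mu / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd,
                               size=size, random_state=rng)


def simulate_behavior(group: Group, seed: int,
                      params: Mapping[Group, GroupBehavior] | None = None) -> dict:
    """Draw one subject's behavioral record for ``group``.

    Zone times and immobility are drawn from mean-matched zero-truncated
    normals; the SI ratio is *not* stored (it is derived downstream as
    time-with-CD1 / time-no-CD1).
    """
    params = params if params is not None else DEFAULT_BEHAVIOR
    group = Group(group)
    if group not in params:
        raise KeyError(f"unknown group {group!r}")
    p = params[group]
    rng = np.random.default_rng(seed)
    return {
        "group": group.value,
        "time_zone_no_cd1_s": float(
            _truncnorm_mean_matched(p.time_zone_no_cd1_mean_s, p.time_zone_no_cd1_sd_s, rng)
        ),
        "time_zone_with_cd1_s": float(
            _truncnorm_mean_matched(p.time_zone_with_cd1_mean_s, p.time_zone_with_cd1_sd_s, rng)
        ),
        "tst_immobility_s": float(
            _truncnorm_mean_matched(p.tst_immobility_mean_s, p.tst_immobility_sd_s, rng)
        ),
    }


# ---------------------------------------------------------------------------
# LFP generator


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                center: float, bandwidth: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to center +/- bandwidth/2."""
    white = rng.standard_normal(n)
    lo = max(center - bandwidth / 2, 0.1)
    hi = min(center + bandwidth / 2, fs / 2 - 1)
    nb = bandpass_filter(white, lo, hi, fs)
    return nb / np.sqrt(np.mean(nb**2))


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float,
                scale: float, band: tuple[float, float] = (0.5, 250.0)) -> np.ndarray:
    """Band-limited 1/f^exponent noise with RMS ``scale``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs <= min(band[1], fs / 2))
    shaping[inband] = freqs[inband] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms) if rms > 0 else x


def _envelope(x: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    return np.maximum(np.abs(sps.hilbert(x)), floor)


def _delay(x: np.ndarray, lag_samples: int) -> np.ndarray:
    if lag_samples == 0:
        return x
    out = np.empty_like(x)
    out[lag_samples:] = x[:-lag_samples]
    out[:lag_samples] = x[0]
    return out


def _draw_events(rng: np.random.Generator, duration_s: float,
                 rate_per_min: float, margin_s: float = 3.0,
                 min_gap_s: float = 6.0) -> np.ndarray:
    """Homogeneous event process thinned so every event keeps a full +/-3 s
    window inside the recording and post-entry windows never overlap."""
    if duration_s < 2 * margin_s:
        raise ValueError(
            f"duration {duration_s} s too short for any valid event; "
            f"minimum is {2 * margin_s} s"
        )
    n_cand = rng.poisson(rate_per_min * duration_s / 60.0)
    cand = np.sort(rng.uniform(margin_s, duration_s - margin_s, size=n_cand))
    kept: list[float] = []
    for t in cand:
        if not kept or t - kept[-1] >= min_gap_s:
            kept.append(float(t))
    return np.asarray(kept)


def _session_rng(config: SimConfig, group: Group, phase: Phase,
                 subject: int) -> np.random.Generator:
    codes = {g: i for i, g in enumerate(Group)}
    ss = np.random.SeedSequence(
        entropy=config.seed,
        spawn_key=(codes[group], 0 if phase is Phase.NO_CD1 else 1, subject),
    )
    return np.random.default_rng(ss)


def simulate_session(config: SimConfig, group: Group | GroupPreset,
                     phase: Phase, subject: int = 0) -> SessionRecording:
    """Simulate one session (one subject, one phase) of two-region LFP.

    Each region's trace is a theta-band oscillator plus 1/f background. The
    vHPC theta amplitude envelope is a (1-g, g) mixture of its own envelope
    and the BLA envelope delayed by ``coupling_lag_s``, giving directed
    BLA->vHPC amplitude coupling. In the 0-3 s window after each zone entry
    the theta amplitude of both regions is multiplied by the phase's
    ``post_entry_theta_factor``. Channels within a region share the region
    signal plus independent white noise.
    """
    if isinstance(group, GroupPreset):
        preset = group
    else:
        preset = PRESETS[Group(group)]
    cfg = preset.apply(config)
    phase = Phase(phase)
    fs = cfg.sampling_rate_hz
    n = int(round(cfg.duration_s * fs))
    rng = _session_rng(cfg, preset.name, phase, subject)

    events = _draw_events(rng, cfg.duration_s, cfg.event_rate_per_min)

    # region theta carriers and envelopes
    bla_nb = _narrowband(rng, n, fs, cfg.theta_center_hz, cfg.theta_bandwidth_hz)
    vhpc_nb = _narrowband(rng, n, fs, cfg.theta_center_hz, cfg.theta_bandwidth_hz)
    env_bla = _envelope(bla_nb)
    env_vhpc = _envelope(vhpc_nb)
    carrier_vhpc = vhpc_nb / env_vhpc

    lag_samples = int(round(cfg.coupling_lag_s * fs))
    g = cfg.coupling_gain
    mixed_env = (1.0 - g) * env_vhpc + g * _delay(env_bla, lag_samples)

    theta_bla = cfg.theta_amp_bla * bla_nb
    theta_vhpc = cfg.theta_amp_vhpc * mixed_env * carrier_vhpc

    phase_gain = cfg.theta_gain_with_cd1 if phase is Phase.WITH_CD1 else 1.0
    theta_bla = theta_bla * phase_gain
    theta_vhpc = theta_vhpc * phase_gain

    post_factor = cfg.post_entry_theta_factor.get(phase.value, 1.0)
    if post_factor != 1.0:
        gain = np.ones(n)
        for t in events:
            i0 = int(round(t * fs))
            i1 = min(int(round((t + 3.0) * fs)), n)
            gain[i0:i1] = post_factor
        theta_bla = theta_bla * gain
        theta_vhpc = theta_vhpc * gain

    signals: dict[str, np.ndarray] = {}
    for region, theta in (("BLA", theta_bla), ("vHPC", theta_vhpc)):
        background = _one_over_f(rng, n, fs, cfg.noise_exponent, cfg.noise_scale)
        region_sig = theta + background
        chan_noise = cfg.channel_noise_scale * rng.standard_normal(
            (cfg.n_channels_per_region, n)
        )
        signals[region] = region_sig[None, :] + chan_noise

    return SessionRecording(
        signals=signals,
        sampling_rate_hz=fs,
        events_s=events,
        meta={
            "subject": f"{preset.name.value}_{subject:02d}",
            "group": preset.name.value,
            "phase": phase.value,
        },
    )


def simulate_envelope_pair(
    n_samples: int,
    coupling_gain: float,
    coupling_lag_s: float,
    fs_env: float = 100.0,
    env_bandwidth_hz: float = 8.0,
    depth: float = 0.35,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly generate a coupled pair of theta amplitude envelopes at the
    envelope sampling rate (ground truth for the transfer-entropy stage,
    bypassing carrier synthesis and envelope extraction).

    Each own-envelope is 1 + depth * low-passed white noise (cutoff
    ``env_bandwidth_hz``), floored at 0.05; the target is the (1-g, g)
    mixture of its own envelope and the source delayed by an integer number
    of envelope samples.
    """
    rng = np.random.default_rng(seed)
    sos = sps.butter(4, env_bandwidth_hz, btype="low", fs=fs_env, output="sos")

    def own() -> np.ndarray:
        slow = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
        slow = slow / np.std(slow)
        return np.maximum(1.0 + depth * slow, 0.05)

    src = own()
    tgt_own = own()
    lag_samples = int(round(coupling_lag_s * fs_env))
    tgt = (1.0 - coupling_gain) * tgt_own + coupling_gain * _delay(src, lag_samples)
    return src, tgt
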