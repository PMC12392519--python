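"""Directed amplitude transfer entropy (ATE) between theta envelopes.

Transfer entropy quantifies directed information flow from a source series X
to a target series Y: the reduction in uncertainty about the next target
sample given the source's past, beyond what the target's own past provides,

    TE(X -> Y) = sum p(y_{t+1}, y_t^(k), x^(l)) *
                 log2 [ p(y_{t+1} | y_t^(k), x^(l)) / p(y_{t+1} | y_t^(k)) ]

in bits, where y_t^(k) is the k-sample target history and x^(l) the l-sample
source history ending at x_{t+1-lag}. With this lag convention a pure copy
process y_{t+1} = x_t yields exactly 1 bit at lag 1, and a generator that
delays the source envelope by L samples puts the ATE peak at lag = L.

Amplitude transfer entropy applies this to the amplitude envelopes of
band-limited LFP (here the 4-12 Hz theta band), capturing how the theta
amplitude in BLA drives the theta amplitude in vHPC. The estimator is the
plug-in (histogram) estimate after equal-occupancy (quantile) discretization
— robust at the few-thousand-sample scale of concatenated 3 s post-entry
stages and exactly checkable against a brute-force enumeration of the joint
histogram. The plug-in estimate of a conditional mutual information is
nonnegative by construction; ``te_bits`` additionally clips at 0 as a guard
and the unclipped value is kept in ``te_raw``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import SessionRecording, average_channels, bandpass_filter

THETA_BAND = (4.0, 12.0)
DEFAULT_FS_ENV = 100.0
DEFAULT_LAGS_S = np.round(np.arange(0.0, 0.5 + 1e-9, 0.01), 10)


@dataclass
class EnvelopePair:
    """Source/target amplitude envelopes on a common envelope-rate grid.

    ``segments`` lists half-open (start, stop) index ranges of independent
    stretches (e.g. one per post-entry window); no embedding vector used by
    the estimator ever crosses a segment boundary.
    """

    source_env: np.ndarray
    target_env: np.ndarray
    fs_env: float
    band: tuple[float, float] = THETA_BAND
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.source_env = np.asarray(self.source_env, dtype=float)
        self.target_env = np.asarray(self.target_env, dtype=float)
        if self.source_env.shape != self.target_env.shape:
            raise ValueError("source and target envelopes must have equal length")
        for env in (self.source_env, self.target_env):
            if not np.all(np.isfinite(env)):
                raise ValueError("envelopes must be finite")
            if np.any(env < 0):
                raise ValueError("amplitude envelopes must be nonnegative")
        if not self.segments:
            self.segments = [(0, self.source_env.size)]

    def swapped(self) -> "EnvelopePair":
        """The reverse direction (target -> source), for direction controls."""
        return EnvelopePair(self.target_env, self.source_env, self.fs_env,
                            self.band, list(self.segments))


@dataclass
class AteCurve:
    """Transfer entropy over a lag sweep, with peak and AUC summaries."""

    lags_s: np.ndarray
    te_bits: np.ndarray
    te_raw: np.ndarray
    peak: float
    peak_lag_s: float
    auc: float  # trapezoidal integral of te_bits over lags_s (bits * s)


def amplitude_envelope(
    x: np.ndarray,
    band: tuple[float, float] = THETA_BAND,
    fs: float = 2000.0,
    fs_env: float = DEFAULT_FS_ENV,
) -> np.ndarray:
    """Theta amplitude envelope: zero-phase band-pass, analytic-signal
    magnitude, edge-trimmed, decimated to the envelope rate."""
    env, _ = _amplitude_envelope_t0(x, band, fs, fs_env)
    return env


def _amplitude_envelope_t0(x, band, fs, fs_env):
    x = np.asarray(x, dtype=float)
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} invalid for Nyquist {fs / 2} Hz")
    q = fs / fs_env
    if abs(q - round(q)) > 1e-9:
        raise ValueError("fs must be an integer multiple of fs_env")
    q = int(round(q))
    flen = int(round(fs / low))  # ~one cycle of the low band edge
    if x.size < 2 * flen:
        raise ValueError(
            f"signal of {x.size} samples shorter than twice the filter "
            f"length ({2 * flen} samples)"
        )
    nb = bandpass_filter(x, low, high, fs)
    env = np.abs(sps.hilbert(nb))
    trim = flen // 2
    env = env[trim:-trim] if trim else env
    env = sps.resample_poly(env, 1, q)
    return np.maximum(env, 0.0), trim / fs


def _quantile_discretize(x: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Equal-occupancy discretization; returns codes and the effective number
    of occupied states (duplicated quantile edges collapse)."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    codes = np.searchsorted(edges, x, side="right")
    return codes, int(np.unique(codes).size)


def _valid_predict_times(segments, n, k, l, lag):
    """Indices t such that (y_{t+1}, y_t^(k), x_{t+1-lag}^(l)) lies wholly
    within one segment."""
    ts = []
    for s, e in segments:
        lo = max(s + k - 1, s + lag + l - 2, s)
        hi = e - 2
        if hi >= lo:
            ts.append(np.arange(lo, hi + 1))
    return np.concatenate(ts) if ts else np.empty(0, dtype=int)


def transfer_entropy(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 1,
    l: int = 1,
    lag: int = 1,
    bins: int = 4,
    segments: list[tuple[int, int]] | None = None,
) -> float:
    """Plug-in transfer entropy TE(X -> Y) in bits at an integer sample lag.

    ``lag`` positions the most recent source sample at x_{t+1-lag} when
    predicting y_{t+1}; lag=1 means the source sample simultaneous with the
    last target-history sample. Equal-occupancy discretization into ``bins``
    states per variable; defaults k = l = 1, bins = 4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if k < 1 or l < 1 or lag < 0:
        raise ValueError("k, l >= 1 and lag >= 0 required")
    n = x.size
    if n <= lag + max(k, l) + 1:
        raise ValueError("series too short for the requested embedding/lag")
    segments = segments or [(0, n)]

    xc, x_states = _quantile_discretize(x, bins)
    yc, y_states = _quantile_discretize(y, bins)
    if x_states < 2 or y_states < 2:
        warnings.warn("degenerate (constant) input: transfer entropy is 0",
                      stacklevel=2)
        return 0.0

    t = _valid_predict_times(segments, n, k, l, lag)
    if t.size == 0:
        raise ValueError("no valid samples given segments, embedding and lag")

    b = int(max(xc.max(), yc.max())) + 1
    # encode (a = y_{t+1}; bhist = y-history; chist = x-history) as integers
    a = yc[t + 1]
    bhist = np.zeros_like(a)
    for j in range(k):
        bhist = bhist * b + yc[t - j]
    chist = np.zeros_like(a)
    for j in range(l):
        chist = chist * b + xc[t + 1 - lag - j]

    n_b = b**k
    n_c = b**l
    code = (a * n_b + bhist) * n_c + chist
    counts = np.bincount(code, minlength=b * n_b * n_c).reshape(b, n_b, n_c)

    n_abc = counts.astype(float)
    n_bc = n_abc.sum(axis=0, keepdims=True)
    n_ab = n_abc.sum(axis=2, keepdims=True)
    n_bv = n_abc.sum(axis=(0, 2), keepdims=True)
    total = n_abc.sum()

    mask = n_abc > 0
    te = np.sum(
        n_abc[mask] / total
        * np.log2(
            (n_abc * np.broadcast_to(n_bv, n_abc.shape))[mask]
            / (np.broadcast_to(n_bc, n_abc.shape)
               * np.broadcast_to(n_ab, n_abc.shape))[mask]
        )
    )
    return float(te)


def ate_curve(
    pair: EnvelopePair,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    k: int = 1,
    l: int = 1,
    bins: int = 4,
) -> AteCurve:
    """Transfer entropy of the envelope pair over a sweep of lags (seconds),
    summarized by the peak, its lag, and the trapezoidal area under the
    curve."""
    lags_s = np.asarray(lags_s, dtype=float)
    lag_samples = np.round(lags_s * pair.fs_env).astype(int)
    max_lag = int(lag_samples.max(initial=0))
    n_valid = _valid_predict_times(pair.segments, pair.source_env.size,
                                   k, l, max_lag).size
    if n_valid < 50 * bins**2:
        raise ValueError(
            f"only {n_valid} valid samples after boundary exclusion; need at "
            f"least {50 * bins**2} — provide more epochs"
        )
    te_raw = np.array([
        transfer_entropy(pair.source_env, pair.target_env, k=k, l=l,
                         lag=int(lg), bins=bins, segments=pair.segments)
        for lg in lag_samples
    ])
    te_bits = np.maximum(te_raw, 0.0)
    i_peak = int(np.argmax(te_bits))
    return AteCurve(
        lags_s=lags_s,
        te_bits=te_bits,
        te_raw=te_raw,
        peak=float(te_bits[i_peak]),
        peak_lag_s=float(lags_s[i_peak]),
        auc=float(np.trapezoid(te_bits, lags_s)),
    )


def ate_null(
    pair: EnvelopePair,
    lags_s: np.ndarray = DEFAULT_LAGS_S,
    n_surrogates: int = 99,
    seed: int | None = None,
    k: int = 1,
    l: int = 1,
    bins: int = 4,
) -> dict[str, np.ndarray]:
    """Circular-shift surrogate null for the ATE peak and AUC.

    Each surrogate circularly shifts the source envelope by a uniform shift
    of at least the maximum lag, destroying the directed dependence while
    preserving both marginals and autocorrelations.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a p <= 0.05 gate")
    lags_s = np.asarray(lags_s, dtype=float)
    max_lag = int(np.round(lags_s.max() * pair.fs_env))
    n = pair.source_env.size
    min_shift = max(max_lag, 1)
    if n <= 2 * min_shift:
        raise ValueError("envelope shorter than twice the maximum shift")
    rng = np.random.default_rng(seed)
    peaks = np.empty(n_surrogates)
    aucs = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shift = int(rng.integers(min_shift, n - min_shift))
        surrogate = EnvelopePair(
            np.roll(pair.source_env, shift), pair.target_env,
            pair.fs_env, pair.band, list(pair.segments),
        )
        curve = ate_curve(surrogate, lags_s, k=k, l=l, bins=bins)
        peaks[i] = curve.peak
        aucs[i] = curve.auc
    return {"peak": peaks, "auc": aucs}


def post_entry_envelope_pair(
    recording: SessionRecording,
    band: tuple[float, float] = THETA_BAND,
    stage_window_s: tuple[float, float] = (0.0, 3.0),
    fs_env: float = DEFAULT_FS_ENV,
    source_region: str = "BLA",
    target_region: str = "vHPC",
) -> EnvelopePair:
    """Build the ATE input from a recording: theta envelopes of the
    channel-averaged signals, restricted to the post-entry stage of every
    event and concatenated with segment boundaries preserved."""
    envs = {}
    t0 = 0.0
    for region in (source_region, target_region):
        trace = average_channels(recording.signals[region])
        envs[region], t0 = _amplitude_envelope_t0(
            trace, band, recording.sampling_rate_hz, fs_env
        )
    n_env = envs[source_region].size
    src_parts, tgt_parts, segments = [], [], []
    pos = 0
    for t in recording.events_s:
        i0 = int(round((t + stage_window_s[0] - t0) * fs_env))
        i1 = int(round((t + stage_window_s[1] - t0) * fs_env))
        if i0 < 0 or i1 > n_env:
            continue
        src_parts.append(envs[source_region][i0:i1])
        tgt_parts.append(envs[target_region][i0:i1])
        segments.append((pos, pos + (i1 - i0)))
        pos += i1 - i0
    if not src_parts:
        raise ValueError("no complete post-entry stages inside the recording")
    return EnvelopePair(
        np.concatenate(src_parts), np.concatenate(tgt_parts),
        fs_env, band, segments,
    )
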