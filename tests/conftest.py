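import numpy as np
import pytest
from hypothesis import settings

from thetadefeat.io import Epoch

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_epoch(data, fs=2000.0, window=(-3.0, 3.0), region="BLA"):
    return Epoch(region=region, data=np.asarray(data, dtype=float),
                 window_s=window, event_time_s=10.0, epoch_id="test:ev0",
                 sampling_rate_hz=fs)


def sine_epoch(freq_hz, fs=2000.0, window=(-3.0, 3.0), amp=1.0):
    t = np.arange(int(round((window[1] - window[0]) * fs))) / fs + window[0]
    return make_epoch(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs, window=window)


# --- independent brute-force transfer-entropy oracle -----------------------
# Explicit probability tables via dictionary loops; shares only the
# discretization *convention* (equal-occupancy, right-closed edges) with the
# implementation, nothing else.

def te_bruteforce(x, y, k=1, l=1, lag=1, bins=4):
    import math

    def discretize(v):
        qs = np.quantile(np.asarray(v, dtype=float),
                         np.linspace(0, 1, bins + 1)[1:-1])
        edges = sorted(set(qs.tolist()))
        return [sum(1 for e in edges if val >= e) for val in v]

    xd = discretize(x)
    yd = discretize(y)
    n = len(x)
    joint = {}
    for t in range(n - 1):
        if t - k + 1 < 0 or t + 1 - lag - l + 1 < 0:
            continue
        a = yd[t + 1]
        b = tuple(yd[t - j] for j in range(k))
        c = tuple(xd[t + 1 - lag - j] for j in range(l))
        joint[(a, b, c)] = joint.get((a, b, c), 0) + 1
    total = sum(joint.values())
    p_abc = {key: cnt / total for key, cnt in joint.items()}
    p_bc, p_ab, p_b = {}, {}, {}
    for (a, b, c), p in p_abc.items():
        p_bc[(b, c)] = p_bc.get((b, c), 0.0) + p
        p_ab[(a, b)] = p_ab.get((a, b), 0.0) + p
        p_b[b] = p_b.get(b, 0.0) + p
    te = 0.0
    for (a, b, c), p in p_abc.items():
        te += p * math.log2((p * p_b[b]) / (p_bc[(b, c)] * p_ab[(a, b)]))
    return te
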