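# thetadefeat

Event-locked theta-band analysis of two-region local field potentials (LFP)
in the social-defeat paradigm: band-power spectra around zone-entry events,
the between-phase PSD change, directed amplitude transfer entropy from the
basolateral amygdala (BLA) to the ventral hippocampus (vHPC), and
shuffle-controlled SVM decoding of stress group — together with a synthetic
recording generator so that every stage can be verified against known
ground truth.

## Who this is for

Systems-neuroscience analysts working with chronic multi-electrode LFP
recordings from behaving mice (social interaction test with a CD1
aggressor, repeated-social-defeat stress groups), and methodologists who
want an exactly-testable reference implementation of histogram
transfer entropy between amplitude envelopes.

## The analysis

A recording session is one subject in one phase of the social interaction
test (`NO_CD1`: target cage empty; `WITH_CD1`: aggressor present), sampled
at 2 kHz and acquisition-filtered 0.5–250 Hz, with timestamps of every
entry into the interaction zone. The pipeline:

1. **Behavior gate.** The social interaction ratio
   `SI = t_zone(With CD1) / t_zone(No CD1)`; animals with SI < 1 are
   susceptible and enter the oscillation analysis, SI ≥ 1 are resilient
   and excluded from the susceptible-vs-control contrasts.
2. **Spectra.** Channel-averaged ±3 s epochs around each zone entry;
   short-time Fourier PSD (1 s Hamming window, 0.5 Hz grid, hop 0.1 s);
   band means over δ 0.5–4, θ 4–12, β 13–30, low-γ 30–60, high-γ 60–90 Hz,
   split into pre-entry (−3–0 s) and post-entry (0–3 s) stages. The
   headline statistic is the PSD change
   `ΔPSD = PSD(With CD1) − PSD(No CD1)` per band, stage and region.
3. **Directed connectivity.** Theta amplitude envelopes (zero-phase
   band-pass, Hilbert magnitude, decimated to 100 Hz) over the post-entry
   stages; plug-in transfer entropy

   `TE(X→Y) = Σ p(y_{t+1}, y_t^{(k)}, x^{(l)}) log₂ [ p(y_{t+1} | y_t^{(k)}, x^{(l)}) / p(y_{t+1} | y_t^{(k)}) ]`

   after equal-occupancy discretization (k = l = 1, 4 bins), swept over
   lags 0–0.5 s and summarized by its peak and area under the curve, with
   circular-shift surrogates as the significance gate.
4. **Decoding.** RBF-kernel SVM on the five band powers per region (ten
   when BLA and vHPC are fused), repeated stratified subject-level 80/20
   splits, each matched with a label-permuted null run; accuracy,
   precision, F1 and AUC as mean ± SEM in percent.

The synthetic generator produces sessions with exactly this structure —
theta-band noise oscillators over 1/f background, envelope-level BLA→vHPC
coupling at a fixed delay, event-locked theta modulation, and group presets
reproducing the reported stress effects (BLA theta ↑, vHPC theta ↓,
coupling ↓, deeper post-entry theta drop; ketamine partially reversing
each). See `docs/methods.md` for the model and every numerical choice.

## Worked example

```python
import numpy as np
from thetadefeat import (SimConfig, Group, Phase, simulate_session,
                         extract_epochs, stft_psd, band_power, Stage,
                         post_entry_envelope_pair, ate_curve)
from thetadefeat.pipeline import cohort_theta_ate_stats

cfg = SimConfig(seed=42)                       # 90 s session, 2 kHz, theta 4-12 Hz
rec = simulate_session(cfg, Group.CON, Phase.WITH_CD1, subject=0)
epochs, skipped = extract_epochs(rec)          # channel-averaged +/-3 s epochs
print(f"events: {len(rec.events_s)}, epochs kept: {len(epochs) // 2}, skipped: {skipped}")

ep = next(e for e in epochs if e.region == "BLA")
spec = stft_psd(ep)
for stage in (Stage.PRE, Stage.POST):
    bp = band_power(spec, "theta", stage)
    print(f"BLA theta PSD, {stage.value}: {bp.value:.3f} units^2/Hz")

curve = ate_curve(post_entry_envelope_pair(rec))
print(f"ATE peak {curve.peak:.4f} bits at lag {curve.peak_lag_s:.2f} s, "
      f"AUC {curve.auc:.5f} bits*s")

con = cohort_theta_ate_stats(Group.CON, seed=42)
rsds = cohort_theta_ate_stats(Group.RSDS_SUSCEPTIBLE, seed=42)
print(f"cohort BLA theta: CON {con['bla_theta']:.3f} vs RSDS {rsds['bla_theta']:.3f}")
print(f"cohort vHPC theta: CON {con['vhpc_theta']:.3f} vs RSDS {rsds['vhpc_theta']:.3f}")
print(f"cohort ATE peak:  CON {con['ate_peak']:.4f} vs RSDS {rsds['ate_peak']:.4f}")
```

prints

```
events: 8, epochs kept: 8, skipped: 0
BLA theta PSD, PRE: 0.314 units^2/Hz
BLA theta PSD, POST: 0.161 units^2/Hz
ATE peak 0.0107 bits at lag 0.08 s, AUC 0.00310 bits*s
cohort BLA theta: CON 0.144 vs RSDS 0.239
cohort vHPC theta: CON 0.124 vs RSDS 0.072
cohort ATE peak:  CON 0.0136 vs RSDS 0.0091
```

Reading the numbers: in the aggressor-present phase theta power drops after
the animal enters the interaction zone (0.161 vs 0.314 units²/Hz — the
post-entry modulation the ΔPSD statistic quantifies); the single-subject
ATE curve peaks near the generator's 0.1 s coupling delay; and at cohort
level (n = 8 per group) the stressed preset shows higher BLA theta, lower
vHPC theta, and weaker BLA→vHPC information transfer than control — the
three electrophysiological signatures of social defeat this package
measures.

## Command line

```
thetadefeat simulate --preset rsds_susceptible --n-subjects 8 --seed 7 --out sessions/
thetadefeat psd    --sessions sessions/ --out psd.csv
thetadefeat ate    --sessions sessions/ --lags 0 0.5 0.01 --surrogates 99 --out ate.json
thetadefeat decode --features psd.csv --featureset fused --repetitions 1000 --seed 7 --out decode.json
thetadefeat run    --seed 7 --out run/        # full pipeline + tables + figures
```

`run` writes `config.yaml`, tidy CSV tables (behavior, per-epoch band
powers, ΔPSD, ATE summaries, decoder report), `results.json`, and
figure panels; re-running with the same config reproduces `results.json`
byte for byte.

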