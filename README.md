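# eegstc — space–time complexity analysis of EEG

`eegstc` is a tested, reusable pipeline for quantifying the *space–time
complexity* of multichannel EEG, built for studies that combine
**microstate analysis** (the spatial level: which quasi-stable scalp
topography is active at each moment) with **complexity metrics** (the
temporal level: how unpredictable the resulting dynamics are).  It is
aimed at cognitive / sports neurophysiology work on short pre-event
epochs — e.g. the seconds of motor preparation before a trigger — under
several within-subject conditions.

## What it computes

**Microstate segmentation** (`eegstc.microstate`)

1. Global field power, GFP(t) = √( Σᵢ (uᵢ − ū)² / N ) — the spatial SD
   across electrodes at each sample.
2. Topographies at GFP local maxima are clustered with polarity-invariant
   **AAHC** (atomize-and-agglomerate hierarchical clustering).
3. The template count K is chosen by the **elbow of the SSE curve**
   (maximum discrete second difference over K = 1..10), restricted to K
   whose **global explained variance** GEV = Σₙ GFPₙ²·Corr(xₙ, a_{lₙ})² / Σₙ GFPₙ²
   reaches 0.65.
4. **Back-fitting** labels every sample with its max-|corr| template,
   giving a symbolic sequence, plus the conventional parameters
   (coverage, mean duration, occurrence, transition probabilities).

**Sequence complexity** (`eegstc.seq_complexity`): Ms-LZC (Lempel–Ziv
dictionary size over the native K-letter alphabet, normalised by shuffled
copies), Ms-MIG (mean information gain −Σ pᵢⱼ log₂ p_{i→j}), Ms-FC
(fluctuation complexity Σ pᵢⱼ (log₂ pᵢ/pⱼ)²), Ms-SE (Shannon entropy),
and Ms-ER / Ms-EE (entropy rate and excess entropy from the linear fit
H_k ≈ h·k + E of block entropies).

**Signal complexity** (`eegstc.sig_complexity`): LZC (median-binarised,
C(N)·log₂N/N), SampEn (m = 2, r = 0.15·SD), PeEn (m = 5, τ = 1,
normalised to [0,1]), Higuchi fractal dimension (kmax = 10 with a
stability rule), Wiener entropy / spectral flatness, and SSV (variance of
windowed flatness) — each also available as a sliding-window profile
(default 1 s windows, 0.2 s step).

**Statistics** (`eegstc.stats`): Lilliefors/Levene assumption checks,
one-way repeated-measures ANOVA, Benjamini–Hochberg FDR across metrics,
Scheffé post hoc contrasts on the repeated-measures error term, Cohen's d
and Pearson-r bands, and a noncentral-F power computation for the minimum
subject count of a within-subjects design.

**Synthetic ground truth** (`eegstc.synthgen`): K latent topographies, a
first-order Markov label chain (~80 ms dwell at 250 Hz by default),
positive per-sample amplitudes and 1/f^α channel noise at a controlled
SNR, up to full multi-subject, multi-condition studies — so every stage
of the pipeline is testable without any recorded data.

## Worked example

```python
import numpy as np
from eegstc import synthgen as sg, microstate as ms
from eegstc.seq_complexity import sequence_metrics

cfg = sg.SynthConfig(n_channels=30, K=5, fs=250.0, duration=120.0,
                     snr_db=20.0, seed=1)
templates = sg.generate_templates(30, 5, seed=1)
truth = sg.generate_label_sequence(cfg)
rec = sg.generate_eeg(templates, truth, cfg)

chosen, k, _ = ms.fit_microstates(rec.data, rec.fs)
seq = ms.backfit(chosen, rec.data, fs=rec.fs)
print(k, round(chosen.gev_total, 3))
print({m: round(v, 3) for m, v in sequence_metrics(seq, seed=1).items()})
```

prints

```
5 0.992
{'ms_lzc': 0.17, 'ms_mig': 0.381, 'ms_fc': 0.0, 'ms_se': 2.321,
 'ms_er': 0.379, 'ms_ee': 1.943}
```

The elbow method recovers the true five templates, which explain 99% of
the GFP-weighted variance at 20 dB SNR.  The back-fitted sequence is far
more compressible than its shuffles (Ms-LZC ≈ 0.17) and carries ≈ 0.38
bits of surprisal per sample — the signature of long ~80 ms dwells — while
its state distribution is near-uniform (Ms-SE ≈ log₂5 ≈ 2.32, Ms-FC ≈ 0).
The low entropy rate with a large intercept (Ms-ER ≈ 0.38, Ms-EE ≈ 1.9)
says most of the marginal entropy is structure, not innovation.

A command-line interface covers the same flow
(`eegstc synth / preprocess / fit-microstates / backfit / complexity / stats`);
run `eegstc --help`.

## Layout

- `src/eegstc/synthgen.py` — ground-truth generator
- `src/eegstc/io_preprocess.py` — I/O, filtering, epoching, windows
- `src/eegstc/microstate.py` — GFP, AAHC, GEV/SSE, elbow, back-fit
- `src/eegstc/seq_complexity.py` — six sequence metrics
- `src/eegstc/sig_complexity.py` — six signal metrics + windows
- `src/eegstc/stats.py` — RM-ANOVA, FDR, Scheffé, effect sizes, power
- `docs/methods.md` — model assumptions, parameter choices, limitations
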