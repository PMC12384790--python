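# Methods

This note documents the models, estimators and numerical choices behind
`eegstc`, what the synthetic-data generator does and does not emulate,
and the known limitations of the pipeline.

## The generative model the pipeline assumes

Microstate analysis models multichannel EEG as a piecewise-constant
spatial process: at any instant one of K fixed scalp topographies is
active, scaled by a time-varying amplitude, and the active topography
switches every few tens of milliseconds.  `eegstc.synthgen` makes this
model literal:

- **Topographies** are zero-mean (average-referenced), unit-norm channel
  vectors drawn by rejection sampling so that every pair has absolute
  spatial correlation ≤ 0.5.  Real microstate maps are smooth dipolar
  fields; random vectors share their algebraic properties (quasi-
  orthogonality in channel space) but not their spatial smoothness.
- **Switching** follows a first-order Markov chain on {1..K}.  The
  diagonal of the transition matrix sets dwell time: self-transition
  probability 0.95 at 250 Hz gives geometric dwells with mean 20 samples
  = 80 ms, the canonical microstate duration.  Condition effects are
  expressed as overrides of the chain (dwell scale, stationary skew).
- **Amplitudes** are |N(1, 0.1²)| per sample, keeping GFP peaks well
  defined and polarity positive on average (back-fitting is
  polarity-invariant, so the sign convention is immaterial).
- **Noise** is spatially independent 1/f^α noise per channel (α = 1 by
  default), the standard broadband EEG background assumption.  Noise is
  rescaled so the realised signal-to-noise power ratio equals `snr_db`
  exactly.  There is no volume conduction, no forward head model, and no
  artifact simulation (blinks, EMG); passing tests therefore demonstrate
  algorithmic correctness under the assumed generative model, not
  robustness to the full physics of scalp EEG.
- All randomness descends from one seed through named child streams
  (templates / sequence / amplitudes / noise), so runs are bitwise
  reproducible.

Study-level generation stacks subjects × conditions × trials of 3 s
epochs at 250 Hz (the pre-trigger preparation window this kind of design
analyses) and records the per-condition true chain parameters.

## Segmentation choices

- **GFP peaks** are strict interior local maxima.  GFP-peak maps are
  highly redundant, so `fit_microstates` subsamples to 2000 maps
  (seeded) before clustering; the modified-AAHC cost is O(n²·channels)
  and the subsample leaves selection results unchanged in practice.
- **AAHC** starts from singleton clusters and repeatedly dissolves the
  cluster contributing least GFP²-weighted explained variance (GEV),
  re-assigning members by maximal |spatial correlation|.  The cluster
  centroid is the leading right singular vector of the member maps — the
  polarity-invariant analogue of the mean.  The procedure is
  deterministic given input order; order-permutation changes GEV by
  < 0.01 on default synthetic data (tested).
- **SSE** assigns each sample map to its max-|corr| template and
  accumulates ‖x − a·t‖² with the least-squares amplitude a = ⟨x, t⟩.
  The signed amplitude keeps the distance polarity-consistent; an
  unscaled distance would contradict the polarity invariance of the
  clustering itself.
- **Model order** is the K maximising the discrete second difference of
  SSE over a contiguous K range (default 1–10), restricted to K with
  GEV ≥ 0.65; ties break to the smaller K, and a curvature-free SSE
  curve falls back to the smallest admissible K with a warning.  The
  0.65 floor is treated as a selection constraint, not merely a
  reporting convention.
- **Back-fitting** uses max |corr| with ties to the lowest template
  index; zero-variance samples inherit the previous label (label 1 at
  the start) and are logged.  No temporal smoothing or minimum-duration
  constraint is applied by default — smoothing would bias exactly the
  dwell-time-sensitive complexity metrics this pipeline exists to
  compute.

## Sequence metrics

Transition statistics are counted at the **sample level including
self-transitions** by default: microstate sequences spend most samples
inside a dwell, and dwell time is a physiologically meaningful signal
that run-level counting would discard.  Run-level counting is available
(`include_self=False`).  The conditional p_{i→j} is the joint pair
probability normalised by the pair-origin marginal, so rows sum to 1
exactly; 0·log 0 := 0 and 0/0 := 0 throughout.

- **Ms-LZC** uses LZ76 exhaustive-history parsing over the native
  K-letter alphabet (no binarisation), normalised by the mean phrase
  count of 20 seeded uniform permutations of the same symbols.  A
  constant sequence scores exactly 1 (every permutation is itself).
- **Ms-ER / Ms-EE** fit H_k ≈ h·k + E by OLS over k = 1..6.  Plug-in
  block entropies need support: k is capped adaptively so the number of
  blocks stays ≥ 10·K^k (never below 2, keeping slope and intercept
  identifiable), with a warning when capping occurs.  A 3 s, 250 Hz
  sequence over 5 states typically supports k ≤ 2–4.  The slope is
  floored at 0 (a negative fitted rate is an estimation artifact).

## Signal metrics

- **LZC** binarises at the median (robust, threshold-free) before LZ76
  parsing and normalises by N/log₂N.
- **SampEn** interprets r as a fraction of the signal SD (field
  convention); an absolute-r mode exists.  A zero-SD signal receives a
  1e-12 tolerance floor so constants score 0.  When no matches exist the
  value is *undefined* and returned as NaN — never coerced to a number.
- **PeEn** is normalised by log₂(m!), which pins it to [0, 1]; ordinal
  ties are broken by temporal order (stable sort).
- **Higuchi FD** is the slope of ln L(k) against ln(1/k) with the
  standard offset-averaged normalisation, clipped to [1, 2] with a
  warning.  The kmax-stability rule scans candidates (6, 8, …, 16) and
  returns the first k with |D(k+2) − D(k)| < 0.02, defaulting to 10.
- **Wiener entropy** is geometric-over-arithmetic mean of the PSD with
  the DC bin excluded and a 1e-300 power floor.  The PSD is a Welch
  estimate (Hann, 50% overlap, segments of ~1/8 the signal for long
  inputs) rather than a single periodogram: a raw periodogram's bin
  statistics are exponential, which drags the flatness of genuinely
  white noise down to exp(−γ) ≈ 0.56 regardless of length, while
  segment averaging restores the interpretable near-1 reading for flat
  spectra.  Flatness is scale-free, so no further normalisation enters.
- **SSV** is the population variance of Wiener entropy over 0.5 s
  subwindows with 50% overlap (both configurable).

All six are invariant under positive linear rescaling of the input
(tested), so µV calibration does not matter.

## Statistics

- Normality is checked per condition with the Lilliefors-corrected KS
  test (parameters are estimated from the sample, so the plain KS null
  would be anti-conservative); homogeneity with Levene.  Both are
  advisory: the ANOVA runs regardless, with a warning.
- The one-way repeated-measures ANOVA is the classical partition
  F = MS_condition / MS_(condition×subject) with df (c−1, (c−1)(s−1)),
  implemented directly and cross-checked against an independent
  implementation in the test suite.
- BH-FDR is applied across the metric family to the omnibus p-values;
  Scheffé pairwise contrasts (referred to (c−1)·F_{c−1,df_err} on the
  repeated-measures error term) are reported uncorrected, as post hoc
  qualifiers of an already-corrected omnibus result.
- Effect-size bands: |d| < 0.2 small, < 0.8 moderate, else large;
  |r| < 0.3 low, < 0.6 moderate, else strong.
- The sample-size computation finds the smallest n whose noncentral-F
  power reaches the target, with noncentrality λ = n·m·f²/(1−ρ) and
  df ((m−1)ε, (n−1)(m−1)ε) — the within-factors convention of standard
  power software.  The reference design (f = 0.25, α = 0.05,
  power = 0.8, m = 3, ρ = 0.5, ε = 1) yields n = 28.

## Problem sizes used in validation

The test suite and the acceptance script validate at sizes chosen to
make the statistics decisive while staying desk-scale: template-count
recovery uses 20 replicates of 120 s, 30-channel, 20 dB recordings
(GFP-peak maps subsampled to 2000); type-I calibration uses 500 null
replicate studies of 10 subjects × 2 identical conditions × 2 trials of
3 s epochs, pooling the six-metric family; oracle equivalence uses 50
random short inputs per metric against naive definitional
implementations (tolerance 1e-10, or 3 Monte-Carlo SE for the
shuffle-normalised Ms-LZC).

## Known limitations

- Random topographies lack spatial smoothness; recovery results say
  nothing about anatomical interpretability of real templates.
- Plug-in block entropies are biased downward at small samples; Ms-ER /
  Ms-EE from 3 s epochs are comparative measures, not absolute rates.
  No bias-corrected (e.g. Miller–Madow) estimators are offered.
- AAHC with GEV-based atomisation can extinguish a genuinely low-power
  state when amplitude is confounded with state identity; this is a
  property of the algorithm, not of the implementation.
- Sphericity is taken as given (ε supplied, default 1); no
  Greenhouse–Geisser estimation.
- Source localisation is out of scope: per-region time series are
  consumed as plain signals, never produced.
- EDF export needs an optional backend; CSV is the always-available
  interchange format.
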