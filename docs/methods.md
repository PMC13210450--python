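# Methods

## Design and processing model

The package analyzes block-design fNIRS recordings with two conditions
(OOC, SOC) presented as counterbalanced contiguous blocks of 10 trials.
Trial timing is fixed: 0.5 s introduction, 24 s task split into three
8 s selection screens, 35 s rest, so one condition block spans
10 × 59.5 s = 595 s. Sessions carry a 5 s lead-in and tail so that the
first epoch has its 1 s pre-onset baseline and the last epoch its full
61 s window.

Processing follows the standard chain for slow hemodynamic phase
coupling:

1. **MBLL.** ΔOD(λ, t) = −log10(I/I₀); [ΔHbO, ΔHbR] solve the 2×2
   system ΔOD = ε·c·d·DPF per sample. Defaults: 780/850 nm, literature
   extinction coefficients (μM⁻¹cm⁻¹), DPF 6.0, d = 3 cm; all
   overridable. Because the generator's forward model is the exact
   algebraic inverse, round-trips are machine-precision identities.
2. **Resampling** 8.138 → 2 Hz via polyphase anti-aliased conversion at
   the rational ratio 1000/4069 (Kaiser window). The polyphase DC gain
   ripples at ~5·10⁻⁵ relative; tests allow for it.
3. **Band-pass** 0.005–0.05 Hz, 3rd-order Butterworth, forward–backward
   (zero phase, magnitude response applied twice), odd-reflection
   padding of 3×(1/f_low) seconds capped at the record length.
4. **Epoching** on the half-open window [−1, 61) s → exactly 124
   samples at 2 Hz; the onset sample is the first sample at or after
   the marker; baseline is the arithmetic mean over −1 ≤ t ≤ 0.
   Filtering always acts on the continuous record, never per epoch.
5. **PLV** from Hilbert phases of the filtered record over each
   condition's contiguous block, trimming 50 s per end against analytic
   -signal edge transients (one cycle at 0.02 Hz); segments shorter
   than 400 s (two cycles of the lowest band frequency) are rejected,
   and concatenation across blocks is never allowed because phase
   continuity requires unbroken time. A trial-wise PLV variant
   (consistency across epochs at each latency) exists for
   comparability; the continuous-segment definition is primary.
6. **ROI aggregation**: mean PLV over all channel pairs linking two of
   the seven ROIs; the singleton seed ROI4's diagonal is set to 1 by
   convention and diagonals never enter statistics. The seed profile
   S1..S6 is ROI4's row against (ROI1, ROI2, ROI3, ROI5, ROI6, ROI7).
7. **Network metrics** on the 7×7 weighted matrix (diagonal zeroed,
   never thresholded): lengths L = 1/W, Dijkstra distances, global
   efficiency = mean 1/d over ordered pairs, nodal strength, Onnela
   clustering (ŵ = W/max W), local efficiency = efficiency of each
   node's neighbor-induced subgraph. The 0.7 binarization (strict '>')
   is visualization-only.
8. **Inference**: two-tailed paired t-tests with dz = mean(diff)/sd(diff),
   BH-FDR within explicitly declared families (15 channels, 105 channel
   pairs, 21 ROI pairs, 6 seed connections, 21 nodal metrics).
   Zero-variance differences report t = 0, p = 1, dz = 0 with a warning.
   The a-priori sample-size operation scans n upward until the
   noncentral-t power (ncp = dz√n, df = n−1) reaches the target; at
   dz = 0.5, α = 0.05, power = 0.90 it returns 44.
9. **Behavior**: per-participant two-sample t over the 30-vs-30
   selection RTs (the only per-subject sample structure available) plus
   a group paired t on subject mean RTs; low-price selection counts
   (0..30) contrasted by a group paired t, with a "selection-slot" mode
   pairing the 30 trial×screen slots (df = 29) for comparability with
   analyses run over slots rather than subjects.

## Synthetic generator

Each channel's ΔHbO at 8.138 Hz is the sum of:

* **Task response** — canonical double-gamma HRF (peak 6 s, undershoot
  16 s, ratio 1/6) convolved with the condition's task boxcar,
  normalized to unit peak so the amplitude parameter is the peak evoked
  ΔHbO (default 0.3 μM, ~the magnitude of typical prefrontal block
  responses).
* **Band-limited background** — unit-variance 0.005–0.05 Hz Gaussian
  process scaled to 0.3 μM, synthesized spectrally (Gaussian spectrum
  shaped by the band's Butterworth magnitude; statistically identical
  to filtering white noise and cheaper for large cohorts). Channels
  designated as coupled replace a fraction `strength` of this variance
  with a shared sinusoidal oscillator (default 0.02 Hz) with optional
  per-channel phase lags: strength 1 ⇒ downstream PLV → 1, strength 0
  ⇒ independent channels.
* **Physiological noise** — cardiac 1 Hz (0.2 μM), respiratory 0.3 Hz
  (0.1 μM), Mayer 0.1 Hz (0.1 μM) sinusoids with random phases, white
  noise (sd 0.05 μM), linear drift (0.001 μM/s), optional motion
  spikes (off by default — the analysis chain contains no motion
  correction and must not need it).

ΔHbR is emitted as −ΔHbO/3 plus independent noise, for MBLL
round-trips and reference plots only; the analysis uses ΔHbO.

**Cohort simulation** (`study.simulate_study`) draws per-subject
parameters: response amplitudes (subject/channel sd 0.05 μM), planted
coupling strengths on the ROI6–ROI4 channel pairs (base 0.35, subject
sd 0.10, split half-and-half across conditions), and behavioral
parameters. Condition effects are mean shifts of those per-subject
parameters, and their between-subject spread fixes the paired effect
size dz of the group contrast. The presets were calibrated once, by
simulation, to the effect-size regime of interest and then frozen:

* `seed_effect_study`: coupling shift 0.115 (sd 0.21) → measured S5
  dz ≈ 0.45;
* `activation_effect_study`: Ch06 amplitude shift 0.133 μM (sd 0.20)
  → measured dz ≈ 0.5;
* `null_study`: the same per-condition jitter with zero mean shift
  (conditions exchangeable — the type-I reference).

Behavioral defaults: low-price choice probability per subject is
Beta-distributed with means 7/30 (OOC) and 23/30 (SOC) and
concentrations 36/80, chosen so the between-subject count dispersion
matches the published sds (≈3.1 and 2.7 of 30); selection RTs are
normal (within-subject sd 900 ms, truncated to the 8 s screen) with a
small group mean shift (150 ms) but large between-subject heterogeneity
(sd 1200 ms), so many individuals differ strongly in either direction
while the group contrast stays non-significant.

### What the generator does and does not emulate

It reproduces the design's timing, rate, channel count, band-limited
phase structure, the dominant physiological rhythms, and realistic
effect-size regimes. It does **not** model superficial/systemic
physiology beyond additive sinusoids, photon transport (the forward
model is MBLL only), spatially correlated noise, motion artifacts by
default, or non-stationarities. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under these conditions, not
that any particular real dataset will show the same effects.

## Numerical choices

* Half-open epoch grid (124 samples) with ceil-based onset mapping —
  deterministic counts for any marker time.
* PLV matrices are symmetrized (0.5(M+Mᵀ)) and clipped to [0, 1] to
  absorb rounding; diagonal fixed at 1 (self-PLV).
* Dijkstra via `scipy.sparse.csgraph` with explicit no-edge masking;
  disconnected pairs contribute 0 (1/∞).
* BH adjusted p-values: reverse cumulative minimum of m·p₍ⱼ₎/j, capped
  at 1; rejection is adjusted p < q.
* Monte-Carlo cohort studies run in float32 with a seed-row-only PLV
  path; everything else defaults to float64.
* Channel QC (configurable, default coefficient of variation ≤ 15% at
  both wavelengths) stands in for the study's qualitative low-SNR
  exclusion rule, which has no published numeric criterion.

## Problem sizes

The test suite and acceptance script use: full 44-subject cohorts for
single-study contrasts; 100 replicates for the planted-S5 recovery
rate (500 for the type-I rate in the test suite, 200 in the acceptance
script); 100 replicates for behavioral Monte-Carlos; 200 random
graphs for the efficiency oracle; 1000 replicates at N = 1000 for the
null-PLV mean.

## Known limitations

* Whether filtering preceded or followed resampling in the original
  chain is unstated; this package resamples first (the listed order).
  At these band edges the two orders differ negligibly.
* The per-subject RT test (30 vs 30 selections) and the
  selection-slot low-price mode are reconstructions of table layouts
  whose exact test structure is not published; the subject-level paired
  test is primary.
* ROI aggregation weights all channel pairs equally; no distance or
  sensitivity weighting.
* Seed-based statistics inherit the multiple-comparison family choice
  (6 connections); changing the family changes adjusted p-values.
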