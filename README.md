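# nirsplv

Prefrontal fNIRS activation and phase-locking-value (PLV) connectivity
analysis for block-design, two-condition decision-making experiments —
plus a synthetic data generator so the entire chain is testable without
any recordings.

## The scientific problem

Wearable fNIRS probes measure changes in oxygenated hemoglobin (ΔHbO,
μM) over the prefrontal cortex while participants perform a task. In
the paradigm this package targets, participants choose products under
two purchase orientations — other-oriented (OOC, buying for someone
else) and self-oriented (SOC, buying for oneself) — in counterbalanced
blocks of 10 trials (0.5 s introduction, 24 s task shown as three 8 s
selection screens, 35 s rest), recorded from 15 channels at 8.138 Hz
with 3 cm optode separation. The analysis asks two questions:

1. **Activation** — which channels show a stronger task-evoked ΔHbO
   response under one condition (paired t-tests across participants,
   Benjamini–Hochberg FDR at q = 0.05, paired Cohen's dz)?
2. **Connectivity** — does phase synchrony between regions differ
   between conditions? Synchrony between channels a and b is the
   phase-locking value

   PLV = |(1/N) Σₜ exp(j·Δϕₜ)| ∈ [0, 1],  Δϕₜ = ϕₐ(t) − ϕ_b(t),

   with instantaneous phases ϕ(t) from the Hilbert analytic signal of
   the 0.005–0.05 Hz band-limited record, estimated over each
   condition's continuous ~10 min block. Channel matrices are averaged
   into 7 regions of interest (ROI1–ROI7); seed-based connections
   S1..S6 link the central ROI4 (medial-PFC-adjacent, channel Ch08) to
   the six other ROIs. Weighted-graph metrics (global efficiency on
   L = 1/W lengths, nodal strength, Onnela clustering, local
   efficiency) summarize the 7×7 matrix.

The processing chain is: modified Beer–Lambert law (intensity → ΔHbO),
resample 8.138 → 2 Hz, zero-phase 3rd-order Butterworth band-pass
0.005–0.05 Hz, epochs −1..61 s baseline-corrected on −1..0 s, PLV,
graph metrics, paired group statistics, behavioral contrasts (selection
response times and low-price choice frequency). An a-priori power
operation reproduces the paired-t sample-size computation
(dz = 0.5, α = 0.05, power = 0.90 → n = 44).

## Worked example

```python
import numpy as np
from nirsplv import (CouplingSpec, generate_paradigm, plv_matrix,
                     required_n_paired, simulate_hemodynamics)
from nirsplv.preprocess import preprocess

print(required_n_paired(dz=0.5, alpha=0.05, power=0.90))
# 44

sched = generate_paradigm(10, order_seed=0)     # two 595 s condition blocks
series = simulate_hemodynamics(
    sched,
    coupling=CouplingSpec(pairs=(("Ch01", "Ch02"),), frequency_hz=0.02,
                          strength=1.0),
    seed=1,
)
filtered = preprocess(series, sched)            # 2 Hz, 0.005–0.05 Hz band
m = plv_matrix(filtered, sched.condition_segment(sched.condition_order[0]))
print(round(m.loc("Ch01", "Ch02"), 4), round(np.median(m.values), 4))
# 0.9986 0.2376
```

The planted pair's PLV is ~1 (a fully shared 0.02 Hz oscillator;
residual physiological noise keeps it just below), while unrelated
channel pairs sit near the 0.24 noise floor of a 600 s segment in
this band.

A full synthetic cohort runs from one config:

```bash
nirsplv all --n-subjects 44 --seed 1 --out runs/demo
```

which writes contrast tables (activation, seed, ROI-pair,
channel-pair), per-subject network metrics, behavioral tables, mean
PLV matrices with 0.7-threshold edge lists, a channel-pair significance
heatmap and a provenance manifest. Stage-level subcommands
(`simulate`, `preprocess`, `connect`, `network`, `stats`, `behavior`,
`report`) operate on the per-subject SNIRF/TSV files instead.

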