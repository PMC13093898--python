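# patchkit

Whole-cell patch-clamp analysis for three-arm pharmacology studies:
intrinsic-excitability and passive-membrane feature extraction from
current-clamp sweeps, threshold-based spontaneous-EPSC (sEPSC) detection from
voltage-clamp sweeps, quality-control gating, and group statistics — together
with a seeded synthetic-cohort simulator so that every stage of the pipeline
can be validated by parameter recovery.

## Who this is for

Cellular electrophysiologists comparing layer-5 pyramidal-neuron physiology
across treatment groups (here: control, prenatal-alcohol-exposure + saline,
and PAE + the serotonin-2A agonist 25CN-NBOH), and anyone who needs a
transparent, scriptable replacement for point-and-click ephys analysis whose
every step is testable against known ground truth.

## The measurements at its core

From 1-s current steps (0–400 pA in 50-pA increments, 20 kHz):

- **Spike detection** — threshold at the voltage where dV/dt (central
  differences) reaches 10 mV/ms; spikes whose peak fails to reach −10 mV are
  not counted.
- **f–I curve** — firing frequency *f(I)* per step; **gain** is the OLS slope
  of *f* on *I* from 0 pA to the (lowest) current of maximum frequency;
  **total spike output** is the spike sum over the same range.
- **First-spike waveform** — threshold, peak, amplitude (peak − threshold),
  half-width at half-maximal amplitude (linearly interpolated), maximum rise
  and decay slopes of dV/dt.
- **Rheobase / latency** — smallest 2-s fine step (5–10 pA) evoking a spike;
  latency from step onset to the first threshold crossing.

From small hyperpolarizing steps (−10 to −20 pA, 20–40 sweeps):

- **R_in** = ΔV_peak / I (baseline-relative maximum deflection),
  **TC** from a single-exponential fit from step onset to the peak
  deflection, **C_in = TC / R_in**, and the **sag ratio** (peak over
  late-plateau deflection, reporting I_h).

From 30-s voltage-clamp sweeps at −70 mV (first second discarded; it carries
a −5 mV / 250 ms test pulse used to monitor R_s and R_in):

- **sEPSC detection** with the threshold detector settings *negative peak
  direction, 5-ms local maximum period, 30-ms decay search period, 8 pA
  threshold, 10-ms search period, 1-ms averaged baseline, curved baseline
  and threshold*; manual noise rejection is replaced by explicit kinetic
  criteria (rise time, decay τ, amplitude ceiling).
- **Per-sweep statistics** — frequency = events / 29 s, mean amplitude, and
  the decay time constant fitted to the peak-aligned averaged event.

QC excludes cells with resting potential above −50 mV or series resistance
above 35 MΩ (strict inequalities), and keeps putative intratelencephalic
pyramidal cells by a regular-spiking pattern plus a configurable physiology
index < 5. Groups are compared by Kruskal–Wallis plus corrected pairwise
contrasts (or normality-gated Welch/Mann–Whitney), and f–I curves by a
cell-level max-T permutation test.

## Worked example

```python
from patchkit.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(output_dir="demo_out", seed=1, cells_per_group=12)
result = run_pipeline(config)   # simulate -> extract -> detect -> QC -> compare

freq = result.summary.query("feature == 'sepsc_frequency'")
print(freq[["group_a", "group_b", "mean_a", "mean_b", "p_adjusted", "significant"]])
```

Output (seed 1):

```
       group_a     group_b    mean_a    mean_b  p_adjusted  significant
60         all         all  4.276501  4.276501    0.000037         True
61     control  PAE_saline  5.244253  2.636015    0.000028         True
62     control    PAE_NBOH  5.244253  4.949234    0.557617        False
63  PAE_saline  PAE_NBOH    2.636015  4.949234    0.000028         True
```

Reading this: the simulated PAE + saline arm has about half the control
sEPSC frequency (2.6 vs 5.2 Hz, adjusted p ≈ 3e-5), the psychedelic-treated
arm is restored to near control (4.9 Hz, not significant vs control), and
the treated arm differs significantly from the untreated PAE arm — the
qualitative pattern the cohort generator is designed to emulate. The same
`result` carries per-cell `features`, per-event `events`, `qc` decisions and
f–I permutation contrasts, all also written as CSV with a provenance header
(config hash + seed) under `demo_out/`.

A command-line interface wraps the same stages:

```bash
patchkit simulate --cells-per-group 12 --seed 1 --out cohort/
patchkit run --in cohort/ --out results/
patchkit detect-epsc --in cohort/ --events-out events.csv --sweeps-out sweeps.csv
```

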