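# Methods

This note documents the models, estimators and design choices behind
patchkit, in the order data flows through the pipeline.

## Data model

Episodic sweeps are uniformly sampled arrays (mV in current clamp, pA in
voltage clamp) with mandatory rectangular-step command metadata
(`amplitude`, `onset`, `duration`, `baseline_level`). Time is seconds from
sweep start; sample *i* lies at *i / f_s*, and command intervals are
half-open `[onset, onset + duration)`. Inferring the command from the
recorded trace is refused by design: every estimator below assumes the
commanded step is known. Units are fixed per clamp mode; there is no silent
rescaling. The portable fixture format is a JSON manifest plus an HDF5 or
CSV sample container; ABF ingestion is available when the optional `pyabf`
package is installed, and fixtures are the tested interchange format.

## Synthetic cohort

The simulator is first-class, tested code: it defines the study conditions
under which every estimator is validated.

**Current clamp.** A leaky integrate-and-fire membrane, forward Euler at the
50 µs sampling interval:

    dV/dt = (V_rest + R_m I(t) − V) / τ_m,     τ_m = R_m C_m.

The membrane is biased so the pre-step potential is −65 mV. The
integration scheme is justified by a tested property: with spiking disabled
the trace matches the closed-form RC step response to within 0.1% of the
step amplitude. An I_h-like sag is a slow state *w* relaxing toward
`sag_conductance × R_m I` (hyperpolarizing commands only) with time constant
`sag_tau`; the output V − w is then the classic two-exponential response
whose late plateau recovers exactly `sag_conductance` of the steady-state
deflection. Spikes are stereotyped piecewise-linear waveforms (threshold →
peak at the designed maximum rise slope, peak → reset at the designed decay
slope) pasted at threshold crossings, followed by an absolute refractory
hold at the reset potential. Waveform-feature ground truth (threshold, peak,
max dV/dt, triangle half-width) is therefore exact by construction rather
than emergent from channel kinetics. Measurement noise is additive i.i.d.
Gaussian on the final trace.

A second generator, `make_prescribed_fi_recording`, pastes an exact number
of spikes per current step, so a linear count sequence yields an exactly
linear f–I relation — this validates gain estimation independently of
integrate-and-fire dynamics.

**Voltage clamp.** 30-s sweeps at −70 mV holding. The first 300 ms carry a
−5 mV / 250 ms test pulse whose current response is the two-resistor
transient: peak ΔV/R_s relaxing to ΔV/(R_s + R_in) with an access time
constant (2 ms default). Synaptic events are a Poisson train (rate
`event_rate`) over the 29-s post-pulse window; each event adds a negative
bi-exponential kernel normalized to a lognormal peak amplitude (mean
`amp_mean`, CV `amp_cv`). Baseline drift is sinusoidal (amplitude
`drift_amplitude`, period `drift_period`, random phase per sweep) and noise
is i.i.d. Gaussian. Outward (inhibitory) events are not generated: at
−70 mV the chloride driving force of the emulated recordings is ≈ 0.

**Cohort defaults.** Cell parameters are drawn from lognormal distributions
loosely centred on layer-5 pyramidal values (R_m 150 MΩ, C_m 150 pF,
threshold 20 mV above rest, sEPSC rate 5 Hz, amplitude 20 pA, τ_decay 8 ms,
R_s uniform 8–20 MΩ), with modest between-cell CVs (0.1–0.2) chosen so the
documented group effects are detectable at ~12 cells/group. The three-arm
effect multipliers (control 1.0; PAE + saline: event rate × 0.6, f–I gain
× 0.7, spike half-width × 1.15; PAE + NBOH: event rate × 0.95, gain × 0.8)
are qualitative stand-ins for reported effect *directions* — the study
design they emulate publishes no numeric effect sizes — and are
config-overridable. The gain multiplier acts by scaling the
threshold-to-rest distance (in the near-linear LIF regime, f ≈ R_m I /
(τ_m ΔV_th), so gain ∝ 1/ΔV_th); the half-width multiplier scales both
waveform slopes down. All outputs are pure functions of (parameters, seed).

## Active intrinsic features

dV/dt is computed by central differences (symmetric threshold placement;
endpoints excluded), in mV/ms. A spike is an upward dV/dt crossing of
10 mV/ms followed by the first local voltage maximum, one peak per crossing;
peaks below −10 mV are not counted but are tracked for the advisory
depolarization-block flag. Features come from the first spike of a step:
threshold at the crossing sample, amplitude = peak − threshold, half-width
between the two linearly interpolated crossings of threshold + amplitude/2,
and slope extrema of dV/dt over the rise and over 10 ms of decay (truncated
at the next spike). The f–I gain regression includes the mandatory 0 pA
point; ties for maximum frequency resolve to the lowest current, making the
regression range — and hence gain and total spike output — invariant to
sweeps above it. Rheobase repetitions (steps restarting at a lower current)
are summarized by the mean of per-repetition rheobase and latency; the
combiner is a documented choice.

## Passive properties

Sweeps sharing a step amplitude are averaged point-wise *before* measurement
— averaging first suppresses the upward bias that per-sweep extrema suffer
under noise. For extremum localisation only, the averaged trace is
additionally smoothed with a 5-ms boxcar; without it, the maximum of
~20 000 noisy samples overshoots the true deflection by several percent
even after 30-sweep averaging, which would dominate the R_in error budget.
Baselines and fits use the unsmoothed average. R_in = ΔV_peak / I; TC is a
bounded least-squares single-exponential fit (τ ∈ [0.1, 200] ms) from step
onset to the peak-deflection sample; C_in = TC/R_in holds as an exact
identity in every emitted record (ms/MΩ = nF, reported in pF). The sag
ratio divides the peak deflection by the mean deflection of the last 50 ms
of the step, both relative to the 100-ms pre-step baseline, making it
invariant to constant offsets. With sag present, R_in (measured at the
early peak) and TC (fit window ending at the peak) are mildly biased; this
mirrors the estimator definitions themselves, and the parameter-recovery
bounds quoted in the tests apply to sag-free cells.

The physiology index is a pluggable weighted combination of features
(`Σ w·(x − center)/scale`); the published formula lives in prior work not
reproduced here, so the shipped single-term configuration is a placeholder
documented as non-authoritative. Only the gate contract — score < 5 means
included — is relied on downstream.

## sEPSC detection

The commercial detector whose settings the pipeline adopts does not publish
its internals; the concrete semantics here are this package's own and are
frozen by an independent brute-force oracle test (500 randomized
trace/settings combinations must agree event-for-event).

The curved baseline is a wide median filter (window = 10 × decay search
period) on a 1-ms mean-decimated copy of the trace, followed by a 100-ms
moving average and interpolation back to full resolution: it tracks
20 pA / 10 s drift to better than 1 pA while sparse events (≤ ~20% duty
cycle) cannot drag the median. Detection runs on a 1-ms boxcar-smoothed
copy of the signal (raw i.i.d. noise at 20 kHz would otherwise produce
spurious single-sample crossings; smoothing attenuates realistic event
peaks by only ~1%). Candidate peaks are below-threshold local minima of a
centred 5-ms window with a ≥ 8 pA fall from the preceding 10-ms maximum
("foot"); this peak-centric formulation handles events riding on a
predecessor's decay, which a purely crossing-anchored scan misses. Peaks
closer than the local-maximum period merge (deepest wins, earliest onset
kept). Amplitude is the baseline curve (averaged over 1 ms before onset)
minus the smoothed peak. Note one practical consequence of threshold
detection: raising the threshold almost always reduces the event count, but
pathological double-dip traces can violate strict monotonicity; the
property is tested on realistic seeded traces, not asserted universally.

The manual-inspection step of the original workflow is replaced by explicit
kinetic criteria, all configurable: 10–90% rise time within [0.1, 5] ms
(measured between foot and peak, robust to stacked events), decay τ within
[1, 50] ms from a per-event bounded exponential fit (skipped when a
following event truncates the clean decay window below 5 ms — a truncated
fit is uninformative), and amplitude ≤ 10 × threshold. Rejected events keep
machine-readable reasons so the surrogate can be audited.

Per-sweep summaries follow the frequency = count/29 s convention; the decay
time constant fits the peak-aligned (2 ms pre-peak to 30 ms post-peak),
baseline-subtracted averaged event, starting 0.5 ms past the averaged peak
because the rounded bi-exponential top otherwise biases τ upward by ~8%.
Two-to-three sweeps per cell combine by the mean of per-sweep summaries.
Test-pulse monitoring uses R_s = |ΔV|/|I_peak| and R_in = |ΔV|/|I_ss| − R_s
with the steady state from the last 50 ms of the pulse, all
baseline-relative.

## QC and classification

Gates are strict inequalities per their stated wording (−50 mV, 35 MΩ):
equality passes. "Regular spiking" has no formal published definition in
the emulated workflow; the surrogate is the absence of an initial doublet
(first ISI ≥ 0.5 × median ISI on a suprathreshold step) and no
depolarization-block flag, both configurable. Every cell receives exactly
one QC record with the full failure list; excluded cells appear in the
audit table and nowhere downstream.

## Group statistics

Scalar features: Kruskal–Wallis omnibus plus all three pairwise contrasts.
Pairwise tests follow the configured policy — `auto` gates Welch's t on
Shapiro–Wilk normality in both groups and otherwise uses Mann–Whitney U —
with Holm (default) or Dunn's rank-based post hoc as the multiplicity
correction. Holm is the default because it is assumption-free and
conservative; the emulated study names Kruskal–Wallis "with corrections"
without specifying the exact post hoc. f–I curves are compared by a
cell-level permutation test on the maximum absolute pointwise difference of
group mean frequencies (max-T): the curve-level test of the original
workflow is unnamed, and the permutation approach needs neither normality
nor sphericity. Permutation p-values use the add-one estimator and a
configured seed; all stochastic procedures are bit-reproducible. Degenerate
inputs (all-identical groups) return p = 1 with an explicit flag. Animal-level
nesting is not modelled; cell IDs are the experimental unit.

## Problem sizes and numerical choices

Validation scenarios use: 50 cells × 30 sweeps for passive recovery; 500 ×
2-s micro-traces for detector-oracle equivalence; 20 × 29-s sweeps at 5 Hz
for detection quality; 2 000 simulated repetitions at n = 15/group for
type-I calibration; and 12 cells/group for the end-to-end cohort — sizes
chosen to keep Monte-Carlo error comfortably below the tested tolerances.
Exponential fits are bounded (τ ∈ [0.1, 200] ms membrane, [0.01, 500] ms
synaptic) with data-derived initial values (1/e return time); fit failures
raise explicit diagnostics rather than returning defaults. Ties in argmin /
argmax resolve to the first sample throughout, in both the implementation
and the oracles.

## Known limitations

- The simulator's noise is white; real recordings have 1/f and line
  components, so passing recovery tests bounds estimator error under ideal
  noise, not instrument-specific artifacts.
- Pasted stereotype spikes have no rate adaptation or after-potentials;
  adaptation indices are out of scope.
- sEPSC amplitudes are not corrected for series-resistance filtering.
- The physiology-index placeholder is not the published composite score.
- Boundary QC behaviour is exact only on the supplied measurements; a
  measured R_s estimate near 35 MΩ inherits the test-pulse estimator's ~2%
  discretization bias.
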