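"""Active intrinsic excitability: spike detection, waveform features, f-I curve, rheobase.

Spike detection uses the dV/dt criterion: a spike threshold is the first
sample in the rising phase where dV/dt (central differences, mV/ms) reaches
10 mV/ms, and candidates whose peak voltage fails to reach -10 mV are not
counted.  The f-I curve summarises 1-s current steps: firing frequency per
step, gain as the ordinary-least-squares slope of frequency on current from
0 pA up to the (lowest) current at which the maximum frequency is attained,
and total spike output as the spike sum over the same range.  Rheobase is the
smallest 2-s step current that evokes at least one spike; latency runs from
step onset to the first threshold crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .recording import ClampMode, Recording, Sweep

__all__ = [
    "SpikeDetectionSettings",
    "DetectedSpike",
    "SpikeFeatures",
    "FICurve",
    "RheobaseResult",
    "detect_spikes",
    "first_spike_features",
    "compute_fi_curve",
    "rheobase_and_latency",
]


@dataclass(frozen=True)
class SpikeDetectionSettings:
    dvdt_threshold: float = 10.0  # mV/ms
    peak_floor: float = -10.0  # mV; peaks below this are not counted


@dataclass(frozen=True)
class DetectedSpike:
    threshold_time: float  # s
    peak_time: float  # s
    peak_value: float  # mV
    threshold_index: int
    peak_index: int


@dataclass(frozen=True)
class SpikeFeatures:
    threshold: float  # mV
    threshold_time: float  # s
    peak: float  # mV
    amplitude: float  # mV, peak - threshold
    half_width: float  # ms
    max_rise_slope: float  # mV/ms
    max_decay_slope: float  # mV/ms


@dataclass(frozen=True)
class FICurve:
    currents: np.ndarray  # pA
    frequencies: np.ndarray  # Hz (spikes per 1-s step)
    gain: float  # Hz/pA
    max_frequency: float
    current_at_max: float
    total_spike_output: int
    block_detected: bool


@dataclass(frozen=True)
class RheobaseResult:
    rheobase: float | None  # pA; None when no step evoked a spike
    latency: float | None  # ms from step onset to first threshold crossing

    @property
    def reached(self) -> bool:
        return self.rheobase is not None


def _dvdt(samples: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference dV/dt in mV/ms; endpoints are zero (never crossings)."""
    dt_ms = 1e3 / rate
    out = np.zeros_like(samples)
    out[1:-1] = (samples[2:] - samples[:-2]) / (2.0 * dt_ms)
    return out


def _scan_spikes(
    samples: np.ndarray, rate: float, settings: SpikeDetectionSettings
) -> tuple[list[DetectedSpike], int]:
    """Crossing-then-peak scan.  Returns (counted spikes, sub-floor candidate count)."""
    v = samples
    n = v.size
    dvdt = _dvdt(v, rate)
    thr = settings.dvdt_threshold
    above = dvdt >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1

    spikes: list[DetectedSpike] = []
    n_subfloor = 0
    last_peak = -1
    for c in crossings:
        if c <= last_peak:
            continue  # crossing inside the previous spike's rise
        j = int(c)
        while j + 1 < n and v[j + 1] > v[j]:
            j += 1
        if j == last_peak:
            continue  # one peak per threshold crossing
        last_peak = j
        if v[j] < settings.peak_floor:
            n_subfloor += 1
            continue
        spikes.append(
            DetectedSpike(
                threshold_time=c / rate,
                peak_time=j / rate,
                peak_value=float(v[j]),
                threshold_index=int(c),
                peak_index=j,
            )
        )
    return spikes, n_subfloor


def detect_spikes(
    sweep: Sweep,
    settings: SpikeDetectionSettings | None = None,
    *,
    clamp_mode: ClampMode | None = None,
) -> list[DetectedSpike]:
    """Detect action potentials in a current-clamp sweep.

    Candidates are local maxima preceded by an upward crossing of the dV/dt
    threshold; each crossing is assigned to exactly one peak, and peaks below
    ``settings.peak_floor`` are discarded.
    """
    if clamp_mode is ClampMode.VOLTAGE_CLAMP:
        raise ValueError("spike detection requires a current-clamp sweep")
    settings = settings or SpikeDetectionSettings()
    spikes, _ = _scan_spikes(sweep.samples, sweep.sampling_rate, settings)
    return spikes


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def first_spike_features(
    sweep: Sweep,
    spikes: Sequence[DetectedSpike],
    settings: SpikeDetectionSettings | None = None,
) -> SpikeFeatures | None:
    """Waveform features of the first detected spike; ``None`` when no spike.

    Threshold is the voltage at the first rising-phase sample where dV/dt
    reaches the detection criterion; amplitude is peak minus threshold;
    half-width is the time between the two crossings of
    ``threshold + amplitude / 2``, linearly interpolated between samples;
    the maximum rise and decay slopes are the extremes of central-difference
    dV/dt over the spike.
    """
    if not spikes:
        return None
    settings = settings or SpikeDetectionSettings()
    v = sweep.samples
    rate = sweep.sampling_rate
    dt = 1.0 / rate
    spk = spikes[0]
    i_thr, i_peak = spk.threshold_index, spk.peak_index

    threshold = float(v[i_thr])
    peak = float(v[i_peak])
    amplitude = peak - threshold
    half_level = threshold + 0.5 * amplitude

    # decay window: to the next spike's threshold or 10 ms past the peak
    i_end = min(
        v.size - 1,
        i_peak + int(round(0.010 * rate)),
        spikes[1].threshold_index if len(spikes) > 1 else v.size - 1,
    )

    # rising crossing of the half-maximal level
    t_up = None
    for i in range(i_thr, i_peak + 1):
        if v[i] >= half_level:
            t_up = (
                _interp_crossing((i - 1) * dt, i * dt, v[i - 1], v[i], half_level)
                if i > i_thr
                else i * dt
            )
            break
    # falling crossing
    t_down = None
    for i in range(i_peak, i_end + 1):
        if v[i] <= half_level:
            t_down = _interp_crossing((i - 1) * dt, i * dt, v[i - 1], v[i], half_level)
            break
    if t_up is None or t_down is None:
        t_up = t_up if t_up is not None else i_thr * dt
        t_down = t_down if t_down is not None else i_end * dt
    half_width = (t_down - t_up) * 1e3  # ms

    dvdt = _dvdt(v, rate)
    max_rise = float(np.max(dvdt[i_thr : i_peak + 1]))
    max_decay = float(np.min(dvdt[i_peak : i_end + 1]))

    return SpikeFeatures(
        threshold=threshold,
        threshold_time=spk.threshold_time,
        peak=peak,
        amplitude=amplitude,
        half_width=half_width,
        max_rise_slope=max_rise,
        max_decay_slope=max_decay,
    )


def compute_fi_curve(
    recording: Recording, settings: SpikeDetectionSettings | None = None
) -> FICurve:
    """f-I curve with gain, maximum frequency, and total spike output.

    Ties for the maximum frequency resolve to the lowest current attaining
    it; the regression range runs from the mandatory 0 pA step to that
    current inclusive, and appending sweeps above it cannot change the gain
    or the total spike output.
    """
    if recording.clamp_mode is not ClampMode.CURRENT_CLAMP:
        raise ValueError("f-I analysis requires a current-clamp recording")
    settings = settings or SpikeDetectionSettings()

    order = np.argsort([s.command.amplitude for s in recording.sweeps], kind="stable")
    sweeps = [recording.sweeps[i] for i in order]
    currents = np.array([s.command.amplitude for s in sweeps])
    if not np.any(currents == 0.0):
        raise ValueError("f-I regression range undefined: no 0 pA sweep present")

    counts = np.empty(len(sweeps), dtype=int)
    subfloor = np.empty(len(sweeps), dtype=int)
    for i, s in enumerate(sweeps):
        spk, n_sub = _scan_spikes(s.samples, s.sampling_rate, settings)
        counts[i] = len(spk)
        subfloor[i] = n_sub
    durations = np.array([s.command.duration for s in sweeps])
    freqs = counts / durations

    i_max = int(np.argmax(freqs))  # argmax returns the lowest index on ties
    current_at_max = float(currents[i_max])
    max_frequency = float(freqs[i_max])
    in_range = currents <= current_at_max
    if in_range.sum() >= 2:
        gain = float(np.polyfit(currents[in_range], freqs[in_range], 1)[0])
    else:
        gain = 0.0
    total = int(counts[in_range].sum())
    block = bool(
        np.any((currents > current_at_max) & (freqs < max_frequency) & (subfloor > 0))
    )
    return FICurve(
        currents=currents,
        frequencies=freqs,
        gain=gain,
        max_frequency=max_frequency,
        current_at_max=current_at_max,
        total_spike_output=total,
        block_detected=block,
    )


def _split_repetitions(sweeps: list[Sweep]) -> list[list[Sweep]]:
    """Split an ordered sweep list into repetitions of strictly increasing steps."""
    reps: list[list[Sweep]] = [[]]
    prev = -math.inf
    for s in sweeps:
        if s.command.amplitude <= prev and reps[-1]:
            reps.append([])
            prev = -math.inf
        reps[-1].append(s)
        prev = s.command.amplitude
    return [r for r in reps if r]


def rheobase_and_latency(
    recording: Recording, settings: SpikeDetectionSettings | None = None
) -> RheobaseResult:
    """Rheobase and latency from fine (5-10 pA) 2-s depolarizing steps.

    Within each repetition the rheobase is the smallest step amplitude whose
    sweep contains at least one spike, and the latency is measured on that
    sweep from the command onset to the first threshold crossing.
    Repetitions are combined by averaging.  Returns a result with
    ``rheobase=None`` when no sweep spiked.
    """
    if recording.clamp_mode is not ClampMode.CURRENT_CLAMP:
        raise ValueError("rheobase analysis requires a current-clamp recording")
    settings = settings or SpikeDetectionSettings()

    rheos: list[float] = []
    lats: list[float] = []
    for rep in _split_repetitions(list(recording.sweeps)):
        for s in rep:
            spikes = detect_spikes(s, settings)
            in_step = [
                k
                for k in spikes
                if s.command.onset
                <= k.threshold_time
                < s.command.onset + s.command.duration
            ]
            if in_step:
                rheos.append(s.command.amplitude)
                lats.append((in_step[0].threshold_time - s.command.onset) * 1e3)
                break
    if not rheos:
        return RheobaseResult(rheobase=None, latency=None)
    return RheobaseResult(rheobase=float(np.mean(rheos)), latency=float(np.mean(lats)))
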