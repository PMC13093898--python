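"""Seeded synthetic patch-clamp recordings with known ground truth.

The generator emulates the three-arm study design (control, prenatal-alcohol
exposure + saline, PAE + 25CN-NBOH) so every downstream stage — passive and
active intrinsic feature extraction, spontaneous-EPSC detection, QC gating and
group statistics — can be validated by parameter recovery rather than against
non-deposited animal recordings.

Current clamp
    A leaky integrate-and-fire membrane integrated by forward Euler at the
    sampling interval.  The membrane is biased so the pre-step potential sits
    at -65 mV.  An Ih-like sag is modelled as a slow relaxation that recovers
    a fraction ``sag_conductance`` of the steady-state hyperpolarizing
    deflection with time constant ``sag_tau``, giving the classic
    two-exponential step response.  Spikes are stereotyped piecewise-linear
    waveforms pasted at threshold crossings, so waveform-feature ground truth
    (threshold, peak, maximum dV/dt, half-width) is designed, not emergent.

Voltage clamp
    30-s sweeps at a -70 mV holding potential.  Each sweep starts with a
    -5 mV / 250 ms test pulse whose current response is the standard
    two-resistor (series + input) transient.  Spontaneous EPSCs are a Poisson
    train of negative bi-exponential kernels with lognormal amplitudes, on a
    slowly drifting sinusoidal baseline plus Gaussian noise.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .recording import (
    ClampMode,
    GroupLabel,
    ProtocolTag,
    Recording,
    StepCommand,
    Sweep,
)

__all__ = [
    "MembraneParams",
    "SynapseParams",
    "GroupEffects",
    "CohortDesign",
    "CellGroundTruth",
    "CohortGroundTruth",
    "StepProtocol",
    "fi_protocol",
    "rheobase_protocol",
    "hyperpolarizing_protocol",
    "simulate_current_clamp",
    "simulate_sepsc_sweeps",
    "generate_cohort",
    "make_spike_waveform",
    "make_prescribed_fi_recording",
    "DEFAULT_GROUP_EFFECTS",
]

SAMPLING_RATE = 20_000.0  # Hz, matching the acquisition rate of the study design


@dataclass(frozen=True)
class MembraneParams:
    """Ground-truth passive and spiking parameters of one simulated cell.

    Units: resistances MΩ, capacitance pF, potentials mV, times ms,
    slopes mV/ms.  ``tau_m`` (ms) is ``R_m * C_m / 1000``.
    """

    R_m: float = 150.0
    C_m: float = 150.0
    E_L: float = -65.0
    spike_threshold: float = -45.0
    reset: float = -55.0
    refractory: float = 2.5
    sag_conductance: float = 0.0
    sag_tau: float = 45.0
    noise_sd: float = 0.2
    # stereotyped spike waveform design
    ap_peak: float = 15.0
    max_rise_slope: float = 350.0
    max_decay_slope: float = -110.0

    def __post_init__(self) -> None:
        if self.R_m <= 0 or self.C_m <= 0:
            raise ValueError("R_m and C_m must be positive")
        if not (0.0 <= self.sag_conductance < 1.0):
            raise ValueError("sag_conductance must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms."""
        return self.R_m * self.C_m * 1e-3

    def rheobase_analytic(self, rest: float = -65.0) -> float:
        """Asymptotic (long-step) rheobase in pA from Ohm's law."""
        return (self.spike_threshold - rest) / self.R_m * 1e3


@dataclass(frozen=True)
class SynapseParams:
    """Ground truth for spontaneous-EPSC sweeps.

    ``event_rate`` is the Poisson rate (Hz) over the 29-s post-pulse window;
    amplitudes are lognormal with mean ``amp_mean`` (pA) and coefficient of
    variation ``amp_cv``; kernels are bi-exponential with rise/decay time
    constants in ms.  ``r_s`` / ``r_in`` (MΩ) shape the test-pulse response.
    """

    event_rate: float = 5.0
    amp_mean: float = 20.0
    amp_cv: float = 0.3
    tau_rise: float = 0.5
    tau_decay: float = 8.0
    noise_sd: float = 2.0
    drift_amplitude: float = 10.0
    drift_period: float = 10.0
    r_s: float = 12.0
    r_in: float = 150.0
    access_tau: float = 2.0  # ms, test-pulse transient relaxation

    def __post_init__(self) -> None:
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.amp_mean <= 0:
            raise ValueError("amp_mean must be positive")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")


@dataclass(frozen=True)
class GroupEffects:
    """Per-group multipliers applied to cell-level base parameters."""

    event_rate: float = 1.0
    amp_mean: float = 1.0
    fi_gain: float = 1.0
    half_width: float = 1.0

    def __post_init__(self) -> None:
        for name in ("event_rate", "amp_mean", "fi_gain", "half_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} multiplier must be positive")


#: Default effect multipliers.  The study design they emulate reports
#: directions, not magnitudes: PAE+saline lowers f-I gain, broadens spikes and
#: lowers sEPSC frequency relative to control; the psychedelic treatment
#: restores sEPSC frequency close to control while gain remains reduced.
DEFAULT_GROUP_EFFECTS: dict[GroupLabel, GroupEffects] = {
    GroupLabel.CONTROL: GroupEffects(),
    GroupLabel.PAE_SALINE: GroupEffects(event_rate=0.6, fi_gain=0.7, half_width=1.15),
    GroupLabel.PAE_NBOH: GroupEffects(event_rate=0.95, fi_gain=0.8),
}


@dataclass(frozen=True)
class CohortDesign:
    cells_per_group: int = 12
    seed: int = 0
    group_effects: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    sepsc_sweeps: int = 3
    hyperpol_sweeps: int = 30

    def __post_init__(self) -> None:
        if self.cells_per_group < 1:
            raise ValueError("cells_per_group must be >= 1")


@dataclass(frozen=True)
class CellGroundTruth:
    cell_id: str
    group_label: GroupLabel
    membrane: MembraneParams
    synapse: SynapseParams
    seed: int

    @property
    def r_in_true(self) -> float:
        return self.membrane.R_m

    @property
    def tau_true(self) -> float:
        return self.membrane.tau_m

    @property
    def c_in_true(self) -> float:
        return self.membrane.C_m


@dataclass
class CohortGroundTruth:
    cells: list[CellGroundTruth]
    seed: int

    def __len__(self) -> int:
        return len(self.cells)

    def by_id(self, cell_id: str) -> CellGroundTruth:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


# ---------------------------------------------------------------------------
# Protocols


@dataclass(frozen=True)
class StepProtocol:
    """A family of rectangular current steps sharing timing."""

    amplitudes: tuple[float, ...]
    step_duration: float  # s
    pre_baseline: float = 0.25  # s
    post_baseline: float = 0.25  # s
    tag: ProtocolTag = ProtocolTag.FI_STEPS

    def __post_init__(self) -> None:
        if self.step_duration <= 0:
            raise ValueError("step duration must be positive")
        if self.pre_baseline < 0.2:
            raise ValueError("protocol needs >= 200 ms of pre-step baseline")

    @property
    def sweep_duration(self) -> float:
        return self.pre_baseline + self.step_duration + self.post_baseline


def fi_protocol(max_current: float = 400.0, step: float = 50.0, duration: float = 1.0) -> StepProtocol:
    """1-s current steps from 0 pA up to ``max_current`` in ``step`` pA increments."""
    amps = tuple(np.arange(0.0, max_current + 0.5 * step, step))
    return StepProtocol(amps, duration, tag=ProtocolTag.FI_STEPS)


def rheobase_protocol(
    start: float, stop: float, step: float = 5.0, duration: float = 2.0
) -> StepProtocol:
    """2-s fine steps (5-10 pA) bracketing the expected rheobase."""
    amps = tuple(np.arange(start, stop + 0.5 * step, step))
    return StepProtocol(amps, duration, tag=ProtocolTag.RHEOBASE_STEPS)


def hyperpolarizing_protocol(
    amplitude: float = -20.0, n_sweeps: int = 30, duration: float = 1.0
) -> StepProtocol:
    """Repeated small hyperpolarizing steps for Rin / tau / sag estimation."""
    if amplitude >= 0:
        raise ValueError("hyperpolarizing step amplitude must be negative")
    return StepProtocol(
        (amplitude,) * n_sweeps,
        duration,
        pre_baseline=0.3,
        post_baseline=0.2,
        tag=ProtocolTag.HYPERPOLARIZING_STEPS,
    )


# ---------------------------------------------------------------------------
# Spike waveform


def make_spike_waveform(
    threshold: float,
    peak: float,
    rise_slope: float,
    decay_slope: float,
    end_level: float,
    dt_ms: float,
) -> np.ndarray:
    """Piecewise-linear stereotype spike sampled at ``dt_ms``.

    Rises from ``threshold`` to ``peak`` at ``rise_slope`` (mV/ms), falls at
    ``decay_slope`` (negative) to ``end_level``.  Maximum dV/dt equals the
    designed slopes exactly in continuous time; on the sampled grid they hold
    to within one sample interval.
    """
    if peak <= threshold:
        raise ValueError("peak must exceed threshold")
    if rise_slope <= 0 or decay_slope >= 0:
        raise ValueError("rise_slope must be > 0 and decay_slope < 0")
    t_peak = (peak - threshold) / rise_slope
    t_end = t_peak + (peak - end_level) / -decay_slope
    t = np.arange(0.0, t_end + dt_ms, dt_ms)
    rising = threshold + rise_slope * t
    falling = peak + decay_slope * (t - t_peak)
    wave = np.where(t <= t_peak, rising, falling)
    return np.clip(wave, end_level, peak)


# ---------------------------------------------------------------------------
# Current clamp

_SPIKES_OFF = math.inf


@njit(cache=False)
def _lif_core(
    i_cmd: np.ndarray,
    dt_ms: float,
    tau_ms: float,
    r_mohm: float,
    v_rest: float,
    v_th: float,
    v_reset: float,
    hold_samples: int,
    sag_c: float,
    sag_tau_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler LIF with an Ih-like sag state; returns (trace, spike indices)."""
    n = i_cmd.size
    out = np.empty(n)
    spike_idx = np.empty(n, dtype=np.int64)
    n_spikes = 0
    v = v_rest
    w = 0.0
    hold = 0
    a_v = dt_ms / tau_ms
    a_w = dt_ms / sag_tau_ms if sag_tau_ms > 0 else 0.0
    for i in range(n):
        if hold > 0:
            v = v_reset
            hold -= 1
            out[i] = v
            continue
        v_out = v - w
        out[i] = v_out
        if v_out >= v_th:
            spike_idx[n_spikes] = i
            n_spikes += 1
            v = v_reset
            hold = hold_samples
            continue
        drive = v_rest + r_mohm * i_cmd[i] * 1e-3
        v += a_v * (drive - v)
        if sag_c > 0.0:
            w_inf = sag_c * r_mohm * i_cmd[i] * 1e-3 if i_cmd[i] < 0.0 else 0.0
            w += a_w * (w_inf - w)
    return out, spike_idx[:n_spikes]


def _command_array(protocol: StepProtocol, amplitude: float, rate: float) -> np.ndarray:
    n = int(round(protocol.sweep_duration * rate))
    i_cmd = np.zeros(n)
    i0 = int(round(protocol.pre_baseline * rate))
    i1 = int(round((protocol.pre_baseline + protocol.step_duration) * rate))
    i_cmd[i0:i1] = amplitude
    return i_cmd


def simulate_current_clamp(
    params: MembraneParams,
    protocol: StepProtocol,
    seed: int,
    *,
    bias_to: float | None = -65.0,
    sampling_rate: float = SAMPLING_RATE,
    cell_id: str = "sim",
    group_label: GroupLabel = GroupLabel.CONTROL,
    return_spike_times: bool = False,
):
    """Simulate one current-clamp recording for ``protocol``.

    The membrane is biased so its pre-step potential equals ``bias_to``
    (default -65 mV); pass ``bias_to=None`` to rest at ``params.E_L``.  With
    ``spike_threshold = +inf`` the dynamics are purely passive and match the
    closed-form RC (or two-exponential, with sag) step response to within the
    Euler discretization error.

    Returns the :class:`Recording`, or ``(Recording, spike_times)`` with the
    per-sweep list of pasted-spike threshold times (seconds) when
    ``return_spike_times`` is set.
    """
    rng = np.random.default_rng(seed)
    dt_ms = 1e3 / sampling_rate
    rest = params.E_L if bias_to is None else bias_to

    spiking = math.isfinite(params.spike_threshold)
    if spiking:
        wave = make_spike_waveform(
            params.spike_threshold,
            params.ap_peak,
            params.max_rise_slope,
            params.max_decay_slope,
            params.reset,
            dt_ms,
        )
        hold = wave.size + int(round(params.refractory / dt_ms))
        v_th = params.spike_threshold
    else:
        wave = np.empty(0)
        hold = 0
        v_th = 1e30  # effectively disables spiking inside the jit kernel

    sweeps: list[Sweep] = []
    spike_times: list[np.ndarray] = []
    for k, amp in enumerate(protocol.amplitudes):
        i_cmd = _command_array(protocol, amp, sampling_rate)
        trace, idx = _lif_core(
            i_cmd,
            dt_ms,
            params.tau_m,
            params.R_m,
            rest,
            v_th,
            params.reset,
            hold,
            params.sag_conductance,
            params.sag_tau,
        )
        for i in idx:
            seg = wave[: trace.size - i]
            trace[i : i + seg.size] = seg
        if params.noise_sd > 0:
            trace = trace + rng.normal(0.0, params.noise_sd, trace.size)
        sweeps.append(
            Sweep(
                samples=trace,
                sampling_rate=sampling_rate,
                command=StepCommand(
                    amplitude=float(amp),
                    onset=protocol.pre_baseline,
                    duration=protocol.step_duration,
                ),
                sweep_index=k,
            )
        )
        spike_times.append(idx / sampling_rate)

    rec = Recording(
        sweeps=sweeps,
        clamp_mode=ClampMode.CURRENT_CLAMP,
        cell_id=cell_id,
        group_label=group_label,
        protocol_tag=protocol.tag,
        holding_level=rest,
    )
    if return_spike_times:
        return rec, spike_times
    return rec


def make_prescribed_fi_recording(
    counts: Sequence[int],
    currents: Sequence[float],
    params: MembraneParams | None = None,
    seed: int = 0,
    *,
    sampling_rate: float = SAMPLING_RATE,
    cell_id: str = "sim-fi",
) -> Recording:
    """Build an f-I recording with an exact, prescribed spike count per step.

    Spikes are pasted at regular intervals within each 1-s step on a flat
    -65 mV baseline (plus the passive step deflection and optional noise), so
    the true firing-rate-versus-current relation is known by construction —
    e.g. a linear count sequence yields an exactly linear f-I curve.  Used to
    validate gain estimation independently of integrate-and-fire dynamics.
    """
    if len(counts) != len(currents):
        raise ValueError("counts and currents must have equal length")
    params = params or MembraneParams()
    proto = StepProtocol(tuple(currents), 1.0, tag=ProtocolTag.FI_STEPS)
    dt_ms = 1e3 / sampling_rate
    wave = make_spike_waveform(
        params.spike_threshold,
        params.ap_peak,
        params.max_rise_slope,
        params.max_decay_slope,
        params.reset,
        dt_ms,
    )
    rng = np.random.default_rng(seed)
    sweeps = []
    for k, (n_spk, amp) in enumerate(zip(counts, currents)):
        i_cmd = _command_array(proto, amp, sampling_rate)
        trace, _ = _lif_core(
            i_cmd, dt_ms, params.tau_m, params.R_m, -65.0, 1e30, params.reset, 0, 0.0, 1.0
        )
        i0 = int(round(proto.pre_baseline * sampling_rate))
        i1 = int(round((proto.pre_baseline + proto.step_duration) * sampling_rate))
        if n_spk > 0:
            at = np.linspace(i0 + 200, i1 - wave.size - 200, n_spk).astype(int)
            for i in at:
                trace[i : i + wave.size] = wave
        if params.noise_sd > 0:
            trace = trace + rng.normal(0.0, params.noise_sd, trace.size)
        sweeps.append(
            Sweep(
                trace,
                sampling_rate,
                StepCommand(float(amp), proto.pre_baseline, proto.step_duration),
                k,
            )
        )
    return Recording(
        sweeps=sweeps,
        clamp_mode=ClampMode.CURRENT_CLAMP,
        cell_id=cell_id,
        group_label=GroupLabel.CONTROL,
        protocol_tag=ProtocolTag.FI_STEPS,
        holding_level=-65.0,
    )


# ---------------------------------------------------------------------------
# Voltage clamp / sEPSC


@dataclass(frozen=True)
class TrueEvent:
    sweep_index: int
    onset_time: float  # s, kernel onset within the sweep
    amplitude: float  # pA, designed peak magnitude
    peak_time: float  # s


SEPSC_SWEEP_S = 30.0
TEST_PULSE_ONSET_S = 0.025
TEST_PULSE_DURATION_S = 0.25
TEST_PULSE_MV = -5.0
ANALYSIS_START_S = 1.0  # first second discarded: it contains the test pulse


def _biexp_kernel(tau_rise: float, tau_decay: float, dt_ms: float) -> tuple[np.ndarray, float]:
    """Unit-peak bi-exponential kernel and its continuous-time peak latency (ms)."""
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    support = t_peak + 10.0 * tau_decay
    t = np.arange(0.0, support, dt_ms)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    k /= math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return k, t_peak


def _test_pulse_current(n: int, rate: float, p: SynapseParams) -> np.ndarray:
    """Whole-sweep current response (pA) to the -5 mV / 250 ms test pulse."""
    t = np.arange(n) / rate
    i0, i1 = TEST_PULSE_ONSET_S, TEST_PULSE_ONSET_S + TEST_PULSE_DURATION_S
    tau_s = p.access_tau * 1e-3
    i_ss = TEST_PULSE_MV / (p.r_s + p.r_in) * 1e3  # pA
    i_pk = TEST_PULSE_MV / p.r_s * 1e3
    out = np.zeros(n)
    on = (t >= i0) & (t < i1)
    out[on] = i_ss + (i_pk - i_ss) * np.exp(-(t[on] - i0) / tau_s)
    off = t >= i1
    out[off] = -(i_pk - i_ss) * np.exp(-(t[off] - i1) / tau_s)
    return out


def simulate_sepsc_sweeps(
    params: SynapseParams,
    n_sweeps: int,
    seed: int,
    *,
    sampling_rate: float = SAMPLING_RATE,
    cell_id: str = "sim",
    group_label: GroupLabel = GroupLabel.CONTROL,
) -> tuple[Recording, list[TrueEvent]]:
    """Simulate 30-s voltage-clamp sweeps and return the true-event list.

    Event onsets are Poisson with rate ``params.event_rate`` over the 29-s
    post-pulse window; each event adds a negative bi-exponential kernel with a
    lognormally distributed peak amplitude.  The returned events are sorted by
    (sweep, onset) and their count per sweep equals the number of kernels
    added to that sweep.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    dt_ms = 1e3 / sampling_rate
    n = int(round(SEPSC_SWEEP_S * sampling_rate))
    kernel, t_peak_ms = _biexp_kernel(params.tau_rise, params.tau_decay, dt_ms)
    pulse = _test_pulse_current(n, sampling_rate, params)

    if params.amp_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.amp_cv**2))
        mu = math.log(params.amp_mean) - 0.5 * sigma**2
    else:
        sigma = 0.0
        mu = math.log(params.amp_mean)

    window = SEPSC_SWEEP_S - ANALYSIS_START_S
    sweeps = []
    events: list[TrueEvent] = []
    for k in range(n_sweeps):
        trace = pulse.copy()
        if params.drift_amplitude > 0:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            t = np.arange(n) / sampling_rate
            trace += params.drift_amplitude * np.sin(
                2.0 * math.pi * t / params.drift_period + phase
            )
        n_events = rng.poisson(params.event_rate * window)
        onsets = np.sort(rng.uniform(ANALYSIS_START_S, SEPSC_SWEEP_S, n_events))
        amps = np.exp(rng.normal(mu, sigma, n_events)) if sigma > 0 else np.full(
            n_events, params.amp_mean
        )
        for onset, amp in zip(onsets, amps):
            i0 = int(round(onset * sampling_rate))
            seg = kernel[: n - i0]
            trace[i0 : i0 + seg.size] -= amp * seg
            events.append(
                TrueEvent(
                    sweep_index=k,
                    onset_time=i0 / sampling_rate,
                    amplitude=float(amp),
                    peak_time=i0 / sampling_rate + t_peak_ms * 1e-3,
                )
            )
        if params.noise_sd > 0:
            trace += rng.normal(0.0, params.noise_sd, n)
        sweeps.append(
            Sweep(
                samples=trace,
                sampling_rate=sampling_rate,
                command=StepCommand(
                    amplitude=TEST_PULSE_MV,
                    onset=TEST_PULSE_ONSET_S,
                    duration=TEST_PULSE_DURATION_S,
                    baseline_level=-70.0,
                ),
                sweep_index=k,
            )
        )

    rec = Recording(
        sweeps=sweeps,
        clamp_mode=ClampMode.VOLTAGE_CLAMP,
        cell_id=cell_id,
        group_label=group_label,
        protocol_tag=ProtocolTag.SEPSC,
        holding_level=-70.0,
    )
    return rec, events


# ---------------------------------------------------------------------------
# Cohort


def _draw_lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma = math.sqrt(math.log(1.0 + cv**2))
    mu = math.log(mean) - 0.5 * sigma**2
    return float(np.exp(rng.normal(mu, sigma)))


def _draw_cell_params(
    rng: np.random.Generator, effects: GroupEffects
) -> tuple[MembraneParams, SynapseParams]:
    """Cell-level base distributions, loosely centred on layer-5 pyramidal values.

    The between-cell coefficients of variation (0.15-0.2) are deliberately
    modest so that the documented group-effect multipliers are detectable at
    the study's per-group sample sizes.
    """
    r_m = _draw_lognormal(rng, 150.0, 0.2)
    c_m = _draw_lognormal(rng, 150.0, 0.2)
    dv_th = _draw_lognormal(rng, 20.0, 0.1) / effects.fi_gain
    slope_scale = 1.0 / effects.half_width
    membrane = MembraneParams(
        R_m=r_m,
        C_m=c_m,
        E_L=-65.0,
        spike_threshold=-65.0 + dv_th,
        reset=-55.0,
        refractory=2.5,
        sag_conductance=float(rng.uniform(0.05, 0.15)),
        sag_tau=45.0,
        noise_sd=0.2,
        ap_peak=15.0,
        max_rise_slope=350.0 * slope_scale,
        max_decay_slope=-110.0 * slope_scale,
    )
    synapse = SynapseParams(
        event_rate=_draw_lognormal(rng, 5.0, 0.2) * effects.event_rate,
        amp_mean=_draw_lognormal(rng, 20.0, 0.15) * effects.amp_mean,
        amp_cv=0.3,
        tau_rise=0.5,
        tau_decay=_draw_lognormal(rng, 8.0, 0.1),
        noise_sd=2.0,
        drift_amplitude=10.0,
        drift_period=10.0,
        r_s=float(rng.uniform(8.0, 20.0)),
        r_in=r_m,
    )
    return membrane, synapse


def generate_cohort(
    design: CohortDesign,
) -> tuple[dict[str, dict[str, Recording]], CohortGroundTruth]:
    """Generate the full three-arm cohort.

    Returns ``(recordings, truth)`` where ``recordings[cell_id]`` maps
    protocol tag values (``fi_steps``, ``rheobase_steps``,
    ``hyperpolarizing_steps``, ``sepsc``) to :class:`Recording` objects, and
    ``truth`` carries each cell's generating parameters.  Deterministic given
    ``design.seed``.
    """
    root = np.random.SeedSequence(design.seed)
    groups = [GroupLabel.CONTROL, GroupLabel.PAE_SALINE, GroupLabel.PAE_NBOH]
    children = root.spawn(len(groups) * design.cells_per_group)

    recordings: dict[str, dict[str, Recording]] = {}
    cells: list[CellGroundTruth] = []
    k = 0
    for group in groups:
        effects = design.group_effects.get(group, GroupEffects())
        if not isinstance(effects, GroupEffects):
            effects = GroupEffects(**effects)
        for j in range(design.cells_per_group):
            ss = children[k]
            k += 1
            rng = np.random.default_rng(ss)
            cell_seed = int(rng.integers(0, 2**31 - 1))
            membrane, synapse = _draw_cell_params(rng, effects)
            cell_id = f"{group.value}_{j:03d}"
            cells.append(CellGroundTruth(cell_id, group, membrane, synapse, cell_seed))

            i_rheo = membrane.rheobase_analytic()
            rheo_proto = rheobase_protocol(
                start=max(10.0, 10.0 * math.floor(0.07 * i_rheo)),
                stop=10.0 * math.ceil(0.135 * i_rheo),
                step=10.0,
            )
            recordings[cell_id] = {
                "fi_steps": simulate_current_clamp(
                    membrane, fi_protocol(), cell_seed, cell_id=cell_id, group_label=group
                ),
                "rheobase_steps": simulate_current_clamp(
                    membrane, rheo_proto, cell_seed + 1, cell_id=cell_id, group_label=group
                ),
                "hyperpolarizing_steps": simulate_current_clamp(
                    membrane,
                    hyperpolarizing_protocol(n_sweeps=design.hyperpol_sweeps),
                    cell_seed + 2,
                    cell_id=cell_id,
                    group_label=group,
                ),
                "sepsc": simulate_sepsc_sweeps(
                    synapse,
                    design.sepsc_sweeps,
                    cell_seed + 3,
                    cell_id=cell_id,
                    group_label=group,
                )[0],
            }
    return recordings, CohortGroundTruth(cells=cells, seed=design.seed)
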