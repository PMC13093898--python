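"""Passive membrane properties from small hyperpolarizing current steps.

Input resistance is the voltage difference between the maximum response
during the step and the 100-ms pre-step baseline, divided by the injected
current; the membrane time constant is a single-exponential fit from step
onset to the peak deflection; input capacitance follows from the identity
Cin = TC / Rin; and the sag ratio is the peak deflection over the mean
deflection of the last 50 ms of the step, both baseline-relative.

Sweeps at the same step amplitude are averaged point-wise before any
measurement, which suppresses the extremum bias that single-sweep maxima
suffer under noise; a short (5 ms) boxcar additionally smooths the averaged
trace for extremum localisation only — fits and baselines use the unsmoothed
average.  Multiple step amplitudes are combined by averaging the
per-amplitude estimates.

The physiology index is a configurable weighted combination of features used
only as a classification gate (score < 5); the formula published for it
lives in cited prior work, so the shipped default configuration is a
documented placeholder, not an authoritative reimplementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.ndimage import uniform_filter1d

from .recording import ClampMode, Recording, Sweep

__all__ = [
    "PassiveProperties",
    "FitFailure",
    "resting_membrane_potential",
    "input_resistance",
    "membrane_time_constant",
    "input_capacitance",
    "sag_ratio",
    "compute_passive_properties",
    "physiology_index",
    "PLACEHOLDER_INDEX_CONFIG",
]

BASELINE_WINDOW_S = 0.100  # mean of the 100 ms immediately preceding the step
SAG_PLATEAU_S = 0.050  # mean of the last 50 ms of the step
_SMOOTH_S = 0.005  # boxcar used only to localise the response extremum


class FitFailure(RuntimeError):
    """Exponential fit did not converge; carries diagnostics in ``args``."""


@dataclass(frozen=True)
class PassiveProperties:
    rmp: float  # mV
    r_in: float  # MOhm
    tc: float  # ms
    c_in: float  # pF, always exactly tc / r_in * 1000
    sag_ratio: float


def resting_membrane_potential(sweep: Sweep) -> float:
    """Mean voltage over the 100 ms immediately preceding the command onset."""
    rate = sweep.sampling_rate
    i_on = int(round(sweep.command.onset * rate))
    n_base = int(round(BASELINE_WINDOW_S * rate))
    if i_on < n_base:
        raise ValueError(
            f"insufficient pre-step baseline: {i_on / rate * 1e3:.0f} ms available, "
            f"{BASELINE_WINDOW_S * 1e3:.0f} ms required"
        )
    return float(np.mean(sweep.samples[i_on - n_base : i_on]))


def _grouped_averages(recording: Recording) -> dict[float, Sweep]:
    """Point-wise average of sweeps sharing a step amplitude."""
    groups: dict[float, list[Sweep]] = {}
    for s in recording.sweeps:
        groups.setdefault(s.command.amplitude, []).append(s)
    out = {}
    for amp, sweeps in groups.items():
        n = min(s.n_samples for s in sweeps)
        mean = np.mean([s.samples[:n] for s in sweeps], axis=0)
        out[amp] = Sweep(mean, sweeps[0].sampling_rate, sweeps[0].command, sweeps[0].sweep_index)
    return out


def _step_response(avg: Sweep) -> tuple[float, int, int, np.ndarray]:
    """(baseline mV, onset index, offset index, smoothed trace) of an averaged sweep."""
    rate = avg.sampling_rate
    i_on = int(round(avg.command.onset * rate))
    i_off = int(round((avg.command.onset + avg.command.duration) * rate))
    baseline = resting_membrane_potential(avg)
    k = max(1, int(round(_SMOOTH_S * rate)))
    smoothed = uniform_filter1d(avg.samples, size=k, mode="nearest")
    return baseline, i_on, min(i_off, avg.n_samples), smoothed


def _peak_index(avg: Sweep) -> int:
    """Index of the maximum (hyperpolarizing) response during the step."""
    baseline, i_on, i_off, smoothed = _step_response(avg)
    return i_on + int(np.argmax(np.abs(smoothed[i_on:i_off] - baseline)))


def input_resistance(recording: Recording) -> float:
    """Input resistance (MΩ) from hyperpolarizing steps.

    Per step amplitude, sweeps are averaged, the maximum baseline-relative
    deflection during the step is taken, and Rin = ΔV / I; amplitudes are
    combined by the mean of per-amplitude estimates.
    """
    if recording.clamp_mode is not ClampMode.CURRENT_CLAMP:
        raise ValueError("input resistance requires current-clamp sweeps")
    values = []
    for amp, avg in _grouped_averages(recording).items():
        if amp == 0.0:
            raise ValueError("zero-amplitude step: Rin undefined")
        baseline, i_on, i_off, smoothed = _step_response(avg)
        i_peak = _peak_index(avg)
        dv = smoothed[i_peak] - baseline  # mV
        values.append(dv / amp * 1e3)  # mV/pA = GΩ; x1000 -> MΩ
    return float(np.mean(values))


def membrane_time_constant(recording: Recording) -> float:
    """Membrane time constant (ms): exponential fit from step onset to peak deflection."""
    if recording.clamp_mode is not ClampMode.CURRENT_CLAMP:
        raise ValueError("time constant requires current-clamp sweeps")
    taus = []
    for amp, avg in _grouped_averages(recording).items():
        if amp == 0.0:
            raise ValueError("zero-amplitude step: time constant undefined")
        baseline, i_on, _, _ = _step_response(avg)
        i_peak = _peak_index(avg)
        if i_peak - i_on < 5:
            raise FitFailure("fit window too short", {"onset": i_on, "peak": i_peak})
        rate = avg.sampling_rate
        t_ms = (np.arange(i_on, i_peak + 1) - i_on) / rate * 1e3
        y = avg.samples[i_on : i_peak + 1]

        v_inf_guess = y[-1]
        tau_guess = max(0.5, min(200.0, 0.63 * t_ms[-1] / 3.0))

        def model(t, v_inf, dv, tau):
            return v_inf + dv * np.exp(-t / tau)

        try:
            popt, _ = curve_fit(
                model,
                t_ms,
                y,
                p0=(v_inf_guess, baseline - v_inf_guess, tau_guess),
                bounds=([-200.0, -100.0, 0.1], [50.0, 100.0, 200.0]),
                maxfev=10_000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitFailure(
                "exponential fit failed to converge",
                {"amplitude": amp, "window_ms": float(t_ms[-1]), "error": str(exc)},
            ) from exc
        taus.append(popt[2])
    return float(np.mean(taus))


def input_capacitance(tc: float, r_in: float) -> float:
    """Cin (pF) from the identity Cin = TC / Rin (ms / MΩ = nF, reported in pF)."""
    if tc <= 0 or r_in <= 0:
        raise ValueError("tc and r_in must be positive")
    return tc / r_in * 1e3


def sag_ratio(recording: Recording) -> float:
    """Peak deflection over the mean deflection of the last 50 ms of the step.

    Both amplitudes are baseline-relative (mean of the 100 ms pre-step), so
    the ratio is invariant to any constant offset of the whole sweep.
    """
    values = []
    for amp, avg in _grouped_averages(recording).items():
        if avg.command.duration < 0.150:
            raise ValueError("step too short for sag: need >= 150 ms")
        baseline, i_on, i_off, smoothed = _step_response(avg)
        i_peak = _peak_index(avg)
        n_plateau = int(round(SAG_PLATEAU_S * avg.sampling_rate))
        peak_amp = abs(smoothed[i_peak] - baseline)
        plateau_amp = abs(np.mean(avg.samples[i_off - n_plateau : i_off]) - baseline)
        values.append(peak_amp / plateau_amp)
    return float(np.mean(values))


def compute_passive_properties(recording: Recording) -> PassiveProperties:
    """All passive properties of one hyperpolarizing-steps recording."""
    rmp = float(
        np.mean([resting_membrane_potential(s) for s in recording.sweeps])
    )
    r_in = input_resistance(recording)
    tc = membrane_time_constant(recording)
    return PassiveProperties(
        rmp=rmp,
        r_in=r_in,
        tc=tc,
        c_in=input_capacitance(tc, r_in),
        sag_ratio=sag_ratio(recording),
    )


# ---------------------------------------------------------------------------
# Physiology index

#: Placeholder gate configuration.  The published index formula is defined in
#: prior work not reproduced here; this default scores the sag ratio alone so
#: that typical regular-spiking pyramidal cells fall well under the gate
#: (score < 5).  Replace with a calibrated configuration for real use.
PLACEHOLDER_INDEX_CONFIG: list[dict] = [
    {"feature": "sag_ratio", "weight": 1.0, "center": 1.0, "scale": 0.25}
]


def physiology_index(
    features: Mapping[str, float], index_config: Sequence[Mapping] | None = None
) -> float:
    """Configurable weighted feature combination used by the inclusion gate.

    Each configuration term contributes ``weight * (x - center) / scale``
    for feature ``x``; a term naming a feature absent from ``features``
    raises.  Only the gate contract (score < 5 means included) is relied on
    downstream.
    """
    config = PLACEHOLDER_INDEX_CONFIG if index_config is None else index_config
    score = 0.0
    for term in config:
        name = term["feature"]
        if name not in features or features[name] is None or (
            isinstance(features[name], float) and math.isnan(features[name])
        ):
            raise KeyError(f"physiology index term references missing feature {name!r}")
        center = term.get("center", 0.0)
        scale = term.get("scale", 1.0)
        score += term["weight"] * (features[name] - center) / scale
    return score
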