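import math

import numpy as np
import pytest

from oracles import oracle_detect_events
from patchkit.epsc import (
    DetectionSettings,
    KineticCriteria,
    Segment,
    detect_events,
    estimate_curved_baseline,
    reject_noise_events,
    strip_test_pulse,
    summarize_sweep,
    test_pulse_monitor,
)
from patchkit.recording import StepCommand
from patchkit.synthetic import _biexp_kernel

RATE = 20_000.0


def _segment(samples, t0=1.0):
    return Segment(np.asarray(samples, float), RATE, t0)


def _kernel_trace(onsets_s, amps, n_seconds=29.0, tau_rise=0.5, tau_decay=8.0):
    n = int(n_seconds * RATE)
    s = np.zeros(n)
    kernel, t_peak_ms = _biexp_kernel(tau_rise, tau_decay, 1e3 / RATE)
    for onset, amp in zip(onsets_s, amps):
        i0 = int(round(onset * RATE))
        seg = kernel[: n - i0]
        s[i0 : i0 + seg.size] -= amp * seg
    return s, t_peak_ms


# ---------------------------------------------------------------------------
# strip_test_pulse


def test_strip_test_pulse_sample_counts(noisy_sepsc_sweep):
    analysis, pulse = strip_test_pulse(noisy_sepsc_sweep["sweep"])
    assert analysis.samples.size == 580_000
    assert analysis.t0 == 1.0
    # conservation: analysis + pulse + discarded gap = whole sweep
    gap = noisy_sepsc_sweep["sweep"].n_samples - analysis.samples.size - pulse.samples.size
    assert gap >= 0
    assert analysis.samples.size + pulse.samples.size + gap == 600_000


def test_strip_test_pulse_rejects_short_sweeps():
    from patchkit.recording import Sweep

    sweep = Sweep(np.zeros(int(1.2 * RATE)), RATE, StepCommand(-5.0, 0.025, 0.25), 0)
    with pytest.raises(ValueError, match="short"):
        strip_test_pulse(sweep)


# ---------------------------------------------------------------------------
# curved baseline


def test_baseline_flat_zero_trace():
    seg = _segment(np.zeros(int(29 * RATE)))
    base = estimate_curved_baseline(seg, DetectionSettings())
    assert np.max(np.abs(base)) < 0.1


def test_baseline_tracks_slow_sinusoidal_drift():
    t = np.arange(int(29 * RATE)) / RATE
    drift = 20.0 * np.sin(2 * math.pi * t / 10.0)
    base = estimate_curved_baseline(_segment(drift), DetectionSettings())
    interior = slice(int(1 * RATE), int(28 * RATE))
    assert np.max(np.abs(base[interior] - drift[interior])) < 1.0


def test_baseline_not_dragged_by_sparse_events():
    t = np.arange(int(29 * RATE)) / RATE
    drift = 20.0 * np.sin(2 * math.pi * t / 10.0)
    rng = np.random.default_rng(3)
    onsets = np.sort(rng.uniform(0.5, 28.0, 100))
    events, _ = _kernel_trace(onsets, np.full(100, 20.0))
    trace = drift + events
    base = estimate_curved_baseline(_segment(trace), DetectionSettings())
    event_free = events == 0.0
    interior = np.zeros_like(event_free)
    interior[int(1 * RATE) : int(28 * RATE)] = True
    err = np.abs(base - drift)[event_free & interior]
    assert err.max() < 2.0


def test_baseline_requires_segment_longer_than_filter_window():
    seg = _segment(np.zeros(1000))
    with pytest.raises(ValueError, match="filter window"):
        estimate_curved_baseline(seg, DetectionSettings())


# ---------------------------------------------------------------------------
# detect_events


def test_detect_nothing_on_flat_trace():
    seg = _segment(np.zeros(int(29 * RATE)))
    base = np.zeros(seg.samples.size)
    assert detect_events(seg, base, DetectionSettings()) == []


def test_detect_well_separated_noiseless_kernels():
    rng = np.random.default_rng(1)
    onsets = np.sort(rng.uniform(0.5, 28.0, 10))
    while np.any(np.diff(onsets) < 0.2):
        onsets = np.sort(rng.uniform(0.5, 28.0, 10))
    trace, t_peak_ms = _kernel_trace(onsets, np.full(10, 20.0))
    seg = _segment(trace)
    base = np.zeros(trace.size)
    events = detect_events(seg, base, DetectionSettings())
    assert len(events) == 10
    for ev, onset in zip(events, onsets):
        assert abs((ev.onset_time - seg.t0) - onset) < 1e-3
        assert ev.amplitude == pytest.approx(20.0, abs=0.5)


def test_two_close_kernels_merge_to_single_deeper_event():
    """Kernels 3 ms apart (< local max period) yield one event, deepest peak wins."""
    trace, _ = _kernel_trace([5.0, 5.003], [15.0, 25.0])
    seg = _segment(trace)
    events = detect_events(seg, np.zeros(trace.size), DetectionSettings())
    assert len(events) == 1
    smoothed_min = trace.min()  # the stacked pair's deepest point
    assert events[0].amplitude == pytest.approx(-smoothed_min, rel=0.05)


def test_detector_matches_bruteforce_oracle_on_random_micro_traces():
    rng = np.random.default_rng(10)
    for _ in range(40):
        n = int(2.0 * RATE)
        s = rng.normal(0, rng.uniform(0.5, 3.0), n)
        t = np.arange(n) / RATE
        s += rng.uniform(0, 20) * np.sin(2 * math.pi * t / rng.uniform(3, 12))
        for _ in range(rng.integers(0, 20)):
            i0 = int(rng.integers(0, n - 500))
            tt = np.arange(0, min(500, n - i0)) / RATE * 1e3
            tr, td = rng.uniform(0.2, 1.0), rng.uniform(3, 15)
            k = np.exp(-tt / td) - np.exp(-tt / tr)
            s[i0 : i0 + tt.size] -= rng.uniform(5, 40) * k / k.max()
        settings = DetectionSettings(
            local_max_period=float(rng.uniform(2, 8)),
            decay_search_period=float(rng.uniform(15, 40)),
            threshold=float(rng.uniform(5, 15)),
            search_period=float(rng.uniform(5, 15)),
            baseline_average_window=float(rng.uniform(0.5, 3)),
            baseline_mode="flat",
        )
        base = np.full(n, np.median(s))
        events = detect_events(Segment(s, RATE, 0.0), base, settings)
        o_on, o_pk, o_amp = oracle_detect_events(s, base, RATE, settings)
        assert len(events) == len(o_pk)
        for ev, on, pk, amp in zip(events, o_on, o_pk, o_amp):
            assert abs(ev.onset_index - on) <= 1
            assert ev.peak_index == pk
            assert ev.amplitude == pytest.approx(amp, abs=0.01)


def test_raising_threshold_does_not_increase_event_count(noisy_sepsc_sweep):
    analysis = noisy_sepsc_sweep["analysis"]
    counts = []
    for thr in (6.0, 8.0, 12.0, 16.0):
        settings = DetectionSettings(threshold=thr)
        base = estimate_curved_baseline(analysis, settings)
        counts.append(len(detect_events(analysis, base, settings)))
    assert counts == sorted(counts, reverse=True)


def test_constant_offset_absorbed_by_curved_baseline(noisy_sepsc_sweep):
    analysis = noisy_sepsc_sweep["analysis"]
    settings = noisy_sepsc_sweep["settings"]
    base = noisy_sepsc_sweep["baseline"]
    ref = detect_events(analysis, base, settings)
    shifted = Segment(analysis.samples + 37.0, analysis.sampling_rate, analysis.t0)
    base2 = estimate_curved_baseline(shifted, settings)
    moved = detect_events(shifted, base2, settings)
    assert len(moved) == len(ref)
    amp_ref = np.array([e.amplitude for e in ref])
    amp_moved = np.array([e.amplitude for e in moved])
    assert np.max(np.abs(amp_ref - amp_moved)) < 0.1


# ---------------------------------------------------------------------------
# noise rejection


def test_generator_events_with_physiologic_kinetics_all_accepted():
    rng = np.random.default_rng(5)
    onsets = np.sort(rng.uniform(0.5, 28.0, 30))
    while np.any(np.diff(onsets) < 0.1):
        onsets = np.sort(rng.uniform(0.5, 28.0, 30))
    trace, _ = _kernel_trace(onsets, rng.uniform(12, 30, 30))
    seg = _segment(trace)
    base = np.zeros(trace.size)
    settings = DetectionSettings()
    events = reject_noise_events(detect_events(seg, base, settings), seg, base, None, settings)
    assert len(events) == 30
    assert all(e.accepted for e in events)


def test_single_sample_square_artifact_rejected_for_rise_time():
    trace = np.zeros(int(29 * RATE))
    trace[100_000] = -300.0  # 1-sample artifact; survives 1-ms smoothing at -15 pA
    seg = _segment(trace)
    base = np.zeros(trace.size)
    settings = DetectionSettings()
    events = reject_noise_events(detect_events(seg, base, settings), seg, base, None, settings)
    assert len(events) == 1
    assert not events[0].accepted
    assert events[0].rejection_reason == "rise_time"


def test_disabled_criteria_accept_everything(noisy_sepsc_sweep):
    analysis = noisy_sepsc_sweep["analysis"]
    settings = noisy_sepsc_sweep["settings"]
    base = noisy_sepsc_sweep["baseline"]
    raw = detect_events(analysis, base, settings)
    flagged = reject_noise_events(
        raw, analysis, base, KineticCriteria(enabled=False), settings
    )
    assert all(e.accepted for e in flagged)
    assert len(flagged) == len(raw)


# ---------------------------------------------------------------------------
# summaries


def test_frequency_is_count_over_29s():
    rng = np.random.default_rng(8)
    onsets = np.linspace(0.5, 28.5, 58)
    trace, _ = _kernel_trace(onsets, np.full(58, 20.0))
    seg = _segment(trace)
    base = np.zeros(trace.size)
    settings = DetectionSettings()
    events = reject_noise_events(detect_events(seg, base, settings), seg, base, None, settings)
    summary = summarize_sweep(events, seg, base, settings)
    assert summary.n_events == 58
    assert summary.frequency == pytest.approx(2.0, abs=1e-9)


def test_decay_tc_exact_for_pure_exponential_event():
    n = int(29 * RATE)
    trace = np.zeros(n)
    i0 = int(5 * RATE)
    t_ms = np.arange(n - i0) / RATE * 1e3
    trace[i0:] = -30.0 * np.exp(-t_ms / 6.0)
    seg = _segment(trace)
    base = np.zeros(n)
    settings = DetectionSettings()
    events = reject_noise_events(detect_events(seg, base, settings), seg, base, None, settings)
    summary = summarize_sweep(events, seg, base, settings)
    assert summary.decay_tc == pytest.approx(6.0, rel=0.02)


def test_zero_accepted_events_summary():
    seg = _segment(np.zeros(int(29 * RATE)))
    summary = summarize_sweep([], seg, np.zeros(seg.samples.size))
    assert summary.frequency == 0.0
    assert summary.mean_amplitude is None and summary.decay_tc is None


# ---------------------------------------------------------------------------
# test pulse


def test_test_pulse_arithmetic_on_constructed_response():
    """Peak -500 pA on -5 mV -> Rs = 10 MOhm; steady -50 pA -> Rin = 90 MOhm."""
    n = int(0.3 * RATE)
    trace = np.zeros(n)
    i_on, i_off = int(0.025 * RATE), int(0.275 * RATE)
    t = np.arange(i_off - i_on) / RATE
    trace[i_on:i_off] = -50.0 + (-500.0 + 50.0) * np.exp(-t / 0.002)
    trace[i_on] = -500.0
    seg = Segment(trace, RATE, 0.0)
    stats = test_pulse_monitor(seg, StepCommand(-5.0, 0.025, 0.25))
    assert stats.r_s == pytest.approx(10.0, rel=1e-6)
    assert stats.r_in == pytest.approx(90.0, rel=1e-3)


def test_test_pulse_recovery_from_simulated_sweep(noisy_sepsc_sweep):
    pulse = noisy_sepsc_sweep["pulse"]
    params = noisy_sepsc_sweep["params"]
    stats = test_pulse_monitor(pulse, noisy_sepsc_sweep["sweep"].command)
    assert stats.r_s == pytest.approx(params.r_s, rel=0.10)
    assert stats.r_in == pytest.approx(params.r_in, rel=0.10)


def test_test_pulse_requires_transient():
    seg = Segment(np.zeros(int(0.3 * RATE)), RATE, 0.0)
    with pytest.raises(ValueError, match="transient"):
        test_pulse_monitor(seg, StepCommand(-5.0, 0.025, 0.25))
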