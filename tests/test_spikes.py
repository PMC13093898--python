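import numpy as np
import pytest

from oracles import oracle_detect_spikes
from patchkit.recording import ClampMode, StepCommand, Sweep
from patchkit.spikes import (
    compute_fi_curve,
    detect_spikes,
    first_spike_features,
    rheobase_and_latency,
)
from patchkit.synthetic import (
    MembraneParams,
    fi_protocol,
    make_prescribed_fi_recording,
    make_spike_waveform,
    rheobase_protocol,
    simulate_current_clamp,
)

RATE = 20_000.0


def _sweep(samples, amp=0.0, onset=0.01, duration=0.05):
    return Sweep(np.asarray(samples, float), RATE, StepCommand(amp, onset, duration), 0)


def _triangle_spike_trace(threshold=-48.0, peak=12.0, rise=300.0, decay=-100.0, reset=-55.0):
    """Flat baseline, sub-criterion ramp to threshold, then a designed triangle spike."""
    dt_ms = 1e3 / RATE
    baseline = np.full(400, -65.0)
    n_ramp = int(round((threshold - (-65.0)) / 5.0 / dt_ms))  # 5 mV/ms < criterion
    ramp = -65.0 + 5.0 * dt_ms * np.arange(1, n_ramp + 1)
    wave = make_spike_waveform(threshold, peak, rise, decay, reset, dt_ms)
    tail = np.full(600, reset)
    return np.concatenate([baseline, ramp, wave, tail])


def test_flat_sweep_has_no_spikes():
    assert detect_spikes(_sweep(np.full(4000, -65.0))) == []


def test_subfloor_hump_is_not_counted():
    """A fast depolarizing hump peaking at -15 mV fails the -10 mV peak floor."""
    trace = _triangle_spike_trace(threshold=-48.0, peak=-15.0, rise=300.0)
    assert detect_spikes(_sweep(trace)) == []
    # same geometry peaking above the floor is counted
    trace2 = _triangle_spike_trace(threshold=-48.0, peak=-5.0, rise=300.0)
    assert len(detect_spikes(_sweep(trace2))) == 1


def test_voltage_clamp_sweep_is_rejected():
    with pytest.raises(ValueError, match="current-clamp"):
        detect_spikes(_sweep(np.zeros(100)), clamp_mode=ClampMode.VOLTAGE_CLAMP)


def test_simulated_step_count_matches_generator_and_oracle():
    params = MembraneParams(noise_sd=0.2)
    rec, spike_times = simulate_current_clamp(
        params, fi_protocol(), 21, return_spike_times=True
    )
    sweep = rec.sweeps[6]  # 300 pA
    detected = detect_spikes(sweep)
    assert len(detected) == len(spike_times[6])
    oracle = oracle_detect_spikes(sweep.samples, RATE)
    assert [(s.threshold_index, s.peak_index) for s in detected] == oracle


def test_detector_equals_oracle_on_randomized_sweeps():
    rng = np.random.default_rng(2)
    for _ in range(60):
        n = 3000
        trace = np.full(n, -65.0) + rng.normal(0, rng.uniform(0.1, 2.0), n)
        for _ in range(rng.integers(0, 4)):
            i0 = int(rng.integers(100, n - 200))
            wave = make_spike_waveform(
                -48.0,
                float(rng.uniform(-20.0, 20.0)),
                float(rng.uniform(50, 400)),
                float(rng.uniform(-300, -30)),
                -55.0,
                1e3 / RATE,
            )
            trace[i0 : i0 + wave.size] = wave[: n - i0]
        detected = detect_spikes(_sweep(trace))
        oracle = oracle_detect_spikes(trace, RATE)
        assert [(s.threshold_index, s.peak_index) for s in detected] == oracle


def test_first_spike_features_match_designed_waveform():
    trace = _triangle_spike_trace(threshold=-48.0, peak=12.0, rise=300.0, decay=-100.0)
    sweep = _sweep(trace)
    spikes = detect_spikes(sweep)
    feats = first_spike_features(sweep, spikes)
    dt_ms = 1e3 / RATE
    assert feats.threshold == pytest.approx(-48.0, abs=300.0 * dt_ms)
    assert feats.amplitude == pytest.approx(60.0, abs=300.0 * dt_ms)
    assert feats.max_rise_slope == pytest.approx(300.0, rel=0.05)
    assert feats.max_decay_slope == pytest.approx(-100.0, rel=0.05)
    # triangle half-width: (A/2) * (1/rise + 1/|decay|)
    expected_hw = 30.0 * (1 / 300.0 + 1 / 100.0)
    assert feats.half_width == pytest.approx(expected_hw, abs=dt_ms)


def test_halving_sampling_rate_shifts_features_by_less_than_one_coarse_sample():
    feats = {}
    for rate in (20_000.0, 10_000.0):
        dt_ms = 1e3 / rate
        baseline = np.full(int(0.02 * rate), -65.0)
        n_ramp = int(round(17.0 / 5.0 / dt_ms))
        ramp = -65.0 + 5.0 * dt_ms * np.arange(1, n_ramp + 1)
        wave = make_spike_waveform(-48.0, 12.0, 300.0, -100.0, -55.0, dt_ms)
        trace = np.concatenate([baseline, ramp, wave, np.full(int(0.03 * rate), -55.0)])
        sweep = Sweep(trace, rate, StepCommand(0.0, 0.001, 0.01), 0)
        feats[rate] = first_spike_features(sweep, detect_spikes(sweep))
    coarse_dt_ms = 0.1
    assert abs(feats[20_000.0].half_width - feats[10_000.0].half_width) < coarse_dt_ms
    assert abs(feats[20_000.0].threshold - feats[10_000.0].threshold) < 300.0 * coarse_dt_ms


def test_no_spikes_yields_explicit_none():
    sweep = _sweep(np.full(1000, -65.0))
    assert first_spike_features(sweep, []) is None


def test_fi_curve_exact_arithmetic():
    rec = make_prescribed_fi_recording(
        [0, 2, 4, 6], [0.0, 50.0, 100.0, 150.0], MembraneParams(R_m=30.0, noise_sd=0.0)
    )
    fi = compute_fi_curve(rec)
    assert fi.gain == pytest.approx(0.04, abs=1e-12)
    assert fi.total_spike_output == 12
    assert fi.max_frequency == 6.0
    assert fi.current_at_max == 150.0
    assert not fi.block_detected


def test_fi_curve_all_zero_and_missing_zero_step():
    rec = make_prescribed_fi_recording([0, 0, 0], [0.0, 50.0, 100.0], MembraneParams(R_m=30.0, noise_sd=0.0))
    fi = compute_fi_curve(rec)
    assert fi.gain == 0.0 and fi.total_spike_output == 0

    rec2 = make_prescribed_fi_recording([1, 2], [50.0, 100.0], MembraneParams(R_m=30.0, noise_sd=0.0))
    with pytest.raises(ValueError, match="0 pA"):
        compute_fi_curve(rec2)


def test_gain_invariant_to_sweeps_above_current_at_max():
    base = make_prescribed_fi_recording(
        [0, 2, 4, 6], [0.0, 50.0, 100.0, 150.0], MembraneParams(R_m=30.0, noise_sd=0.0)
    )
    extended = make_prescribed_fi_recording(
        [0, 2, 4, 6, 5, 3], [0.0, 50.0, 100.0, 150.0, 200.0, 250.0], MembraneParams(R_m=30.0, noise_sd=0.0)
    )
    fi_a, fi_b = compute_fi_curve(base), compute_fi_curve(extended)
    assert fi_a.gain == fi_b.gain
    assert fi_a.total_spike_output == fi_b.total_spike_output
    assert fi_a.current_at_max == fi_b.current_at_max


def test_prescribed_linear_fi_gain_recovered_under_noise():
    currents = list(np.arange(0.0, 401.0, 50.0))
    counts = [int(round(0.05 * c)) for c in currents]  # exactly linear, slope 0.05
    rec = make_prescribed_fi_recording(counts, currents, MembraneParams(R_m=30.0, noise_sd=0.2), seed=4)
    fi = compute_fi_curve(rec)
    assert fi.gain == pytest.approx(0.05, rel=0.05)


def test_simulated_fi_frequency_is_monotone_up_to_max():
    params = MembraneParams(noise_sd=0.0)
    rec = simulate_current_clamp(params, fi_protocol(), 0)
    fi = compute_fi_curve(rec)
    in_range = fi.currents <= fi.current_at_max
    assert np.all(np.diff(fi.frequencies[in_range]) >= 0)


def test_rheobase_analytic_and_latency_monotonicity():
    params = MembraneParams(R_m=100.0, C_m=200.0, spike_threshold=-45.0, noise_sd=0.0)
    proto = rheobase_protocol(180.0, 230.0, step=5.0)
    rec = simulate_current_clamp(params, proto, 0)
    result = rheobase_and_latency(rec)
    assert result.reached
    assert abs(result.rheobase - 200.0) <= 5.0

    latencies = []
    for sweep in rec.sweeps:
        spikes = detect_spikes(sweep)
        in_step = [s for s in spikes if s.threshold_time >= sweep.command.onset]
        if in_step:
            latencies.append(in_step[0].threshold_time - sweep.command.onset)
    assert len(latencies) >= 3
    assert np.all(np.diff(latencies) < 0)


def test_rheobase_latency_from_known_crossing_time():
    dt_ms = 1e3 / RATE
    onset = 0.25
    n = int(2.5 * RATE)
    trace = np.full(n, -65.0)
    wave = make_spike_waveform(-48.0, 12.0, 300.0, -100.0, -55.0, dt_ms)
    i0 = int((onset + 0.150) * RATE)
    trace[i0 : i0 + wave.size] = wave
    trace[i0 + wave.size :] = -55.0
    sweep = Sweep(trace, RATE, StepCommand(100.0, onset, 2.0), 0)
    from patchkit.recording import ClampMode, GroupLabel, ProtocolTag, Recording

    rec = Recording([sweep], ClampMode.CURRENT_CLAMP, "c", GroupLabel.CONTROL,
                    ProtocolTag.RHEOBASE_STEPS)
    result = rheobase_and_latency(rec)
    assert result.reached and result.rheobase == 100.0
    assert result.latency == pytest.approx(150.0, abs=0.2)


def test_all_subthreshold_sweeps_report_not_reached():
    params = MembraneParams(R_m=100.0, spike_threshold=-45.0, noise_sd=0.0)
    rec = simulate_current_clamp(params, rheobase_protocol(50.0, 100.0, 10.0), 0)
    result = rheobase_and_latency(rec)
    assert not result.reached
    assert result.rheobase is None and result.latency is None
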