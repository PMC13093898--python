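import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from patchkit.epsc import (
    DetectionSettings,
    detect_events,
    estimate_curved_baseline,
    reject_noise_events,
    strip_test_pulse,
)
from patchkit.synthetic import SynapseParams, simulate_sepsc_sweeps


def match_by_peak(true_events, detected, window_s=0.003):
    """Greedy one-to-one matching of detected to true events by peak time."""
    true_pk = np.array([e.peak_time for e in true_events])
    used = np.zeros(true_pk.size, dtype=bool)
    matched = 0
    for d in detected:
        if true_pk.size == 0:
            break
        j = int(np.argmin(np.abs(true_pk - d.peak_time)))
        if abs(true_pk[j] - d.peak_time) <= window_s and not used[j]:
            used[j] = True
            matched += 1
    return matched


@pytest.fixture(scope="session")
def noisy_sepsc_sweep():
    """One realistic 30-s voltage-clamp sweep with ground truth and analysis."""
    params = SynapseParams(
        event_rate=5.0,
        amp_mean=20.0,
        amp_cv=0.3,
        noise_sd=2.0,
        drift_amplitude=20.0,
        drift_period=10.0,
    )
    rec, truth = simulate_sepsc_sweeps(params, 1, seed=42)
    sweep = rec.sweeps[0]
    settings = DetectionSettings()
    analysis, pulse = strip_test_pulse(sweep)
    baseline = estimate_curved_baseline(analysis, settings)
    events = detect_events(analysis, baseline, settings)
    events = reject_noise_events(events, analysis, baseline, None, settings)
    return {
        "params": params,
        "sweep": sweep,
        "truth": truth,
        "analysis": analysis,
        "pulse": pulse,
        "baseline": baseline,
        "events": events,
        "settings": settings,
    }
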