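"""Independent brute-force oracles used to validate the fast implementations.

These are written directly from the documented semantics as naive per-sample
scans, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def oracle_detect_spikes(v, rate, dvdt_threshold=10.0, peak_floor=-10.0):
    """Exhaustive crossing-then-peak spike scan.

    Returns a list of (threshold_index, peak_index) for counted spikes.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    dt_ms = 1e3 / rate
    dvdt = [0.0] * n
    for i in range(1, n - 1):
        dvdt[i] = (v[i + 1] - v[i - 1]) / (2.0 * dt_ms)
    spikes = []
    last_peak = -1
    for i in range(1, n):
        if dvdt[i] >= dvdt_threshold and dvdt[i - 1] < dvdt_threshold:
            if i <= last_peak:
                continue
            j = i
            while j + 1 < n and v[j + 1] > v[j]:
                j += 1
            if j == last_peak:
                continue
            last_peak = j
            if v[j] >= peak_floor:
                spikes.append((i, j))
    return spikes


@njit(cache=False)
def _oracle_events_core(
    s_raw, baseline, rate, threshold, local_max_ms, search_ms, decay_ms, base_ms
):
    n = s_raw.size
    # 1-ms boxcar smoothing, centred with the window [i - k//2, i + k - k//2 - 1],
    # edges clamped to the first/last sample
    k = int(round(1.0e-3 * rate))
    if k < 1:
        k = 1
    s = np.empty(n)
    left = k // 2
    right = k - left - 1
    for i in range(n):
        acc = 0.0
        for j in range(i - left, i + right + 1):
            jj = j
            if jj < 0:
                jj = 0
            elif jj >= n:
                jj = n - 1
            acc += s_raw[jj]
        s[i] = acc / k

    def win(ms):
        w = int(round(ms * 1e-3 * rate))
        return w if w > 1 else 1

    w_local = win(local_max_ms)
    w_search = win(search_ms)
    w_decay = win(decay_ms)
    w_base = win(base_ms)
    half = w_local // 2

    peaks = []
    feet = []
    onsets = []
    for i in range(n):
        if not (s[i] < baseline[i] - threshold):
            continue
        lo = i - half
        if lo < 0:
            lo = 0
        hi = i + half + 1
        if hi > n:
            hi = n
        # first index achieving the window minimum
        m = lo
        for j in range(lo + 1, hi):
            if s[j] < s[m]:
                m = j
        if m != i:
            continue
        w0 = i - w_search
        if w0 < 0:
            w0 = 0
        foot = w0
        for j in range(w0 + 1, i + 1):
            if s[j] > s[foot]:
                foot = j
        if s[foot] - s[i] < threshold:
            continue
        onset = i
        for j in range(foot + 1, i + 1):
            crossed = (
                s[j] < baseline[j] - threshold
                and s[j - 1] >= baseline[j - 1] - threshold
            )
            rel = (s[foot] < baseline[foot] - threshold) and (
                s[foot] - s[j] >= threshold
            )
            if crossed or rel:
                onset = j
                break
        peaks.append(i)
        feet.append(foot)
        onsets.append(onset)

    # merge peaks closer than the local-max period
    m_on = []
    m_pk = []
    m_ft = []
    for idx in range(len(peaks)):
        if len(m_pk) > 0 and peaks[idx] - m_pk[-1] < w_local:
            if s[peaks[idx]] < s[m_pk[-1]]:
                m_pk[-1] = peaks[idx]
                m_ft[-1] = feet[idx]
        else:
            m_on.append(onsets[idx])
            m_pk.append(peaks[idx])
            m_ft.append(feet[idx])

    out_onset = np.empty(len(m_pk), dtype=np.int64)
    out_peak = np.empty(len(m_pk), dtype=np.int64)
    out_amp = np.empty(len(m_pk))
    for idx in range(len(m_pk)):
        onset = m_on[idx]
        b0 = onset - w_base
        if b0 < 0:
            b0 = 0
        if onset > b0:
            acc = 0.0
            for j in range(b0, onset):
                acc += baseline[j]
            base_i = acc / (onset - b0)
        else:
            base_i = baseline[onset]
        out_onset[idx] = onset
        out_peak[idx] = m_pk[idx]
        out_amp[idx] = base_i - s[m_pk[idx]]
    return out_onset, out_peak, out_amp


def oracle_detect_events(segment_samples, baseline, rate, settings):
    """Exhaustive event detector; returns (onset indices, peak indices, amplitudes)."""
    return _oracle_events_core(
        np.asarray(segment_samples, dtype=float),
        np.asarray(baseline, dtype=float),
        float(rate),
        float(settings.threshold),
        float(settings.local_max_period),
        float(settings.search_period),
        float(settings.decay_search_period),
        float(settings.baseline_average_window),
    )


def oracle_two_group_power(rng, n, shift_sd, reps, alpha=0.05):
    """Monte-Carlo power of Welch's t for a Gaussian mean shift (brute force)."""
    from scipy import stats as sps

    hits = 0
    for _ in range(reps):
        a = rng.standard_normal(n)
        b = rng.standard_normal(n) + shift_sd
        if sps.ttest_ind(a, b, equal_var=False).pvalue < alpha:
            hits += 1
    return hits / reps
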