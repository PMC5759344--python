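import itertools

import numpy as np
import pytest

from ratplm import (DetectionParams, MotorEvent, SignalTrace, ValidationError,
                    detect_jerks, envelope, merge_bilateral, tonic_baseline)

FS = 250.0


def _trace(samples, fs=FS):
    return SignalTrace("LegL", fs, np.asarray(samples, float))


def make_bursty_trace(burst_times, burst_dur=0.3, factor=2.5, total_s=120.0,
                      base=1.0, fs=FS):
    """Deterministic envelope-level fixture: base level with flat bursts."""
    n = int(total_s * fs)
    x = np.full(n, base)
    for t in burst_times:
        i0 = int(t * fs)
        x[i0:i0 + int(burst_dur * fs)] = factor * base
    return _trace(x, fs)


def brute_force_detect(env, base, params, fs):
    """Independent threshold-scan oracle (plain loops)."""
    above = [e >= params.amplitude_factor * b for e, b in zip(env, base)]
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]) < params.merge_gap * fs:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    tol = 0.5 / fs
    return [(s, e) for s, e in merged
            if params.min_duration - tol <= (e - s) / fs <= params.max_duration + tol]


def test_envelope_of_silence_is_zero():
    env = envelope(_trace(np.zeros(1000)))
    assert np.all(env.samples == 0)


def test_envelope_of_sinusoid_is_rms_amplitude():
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    a = 3.0
    env = envelope(SignalTrace("x", fs, a * np.sin(2 * np.pi * 50 * t)),
                   smoothing=0.1)
    mid = env.samples[int(2 * fs):int(8 * fs)]
    assert np.allclose(mid, a / np.sqrt(2), rtol=0.02)


def test_envelope_invariant_to_sign_flip(rng):
    x = rng.normal(0, 1, 5000)
    e1 = envelope(_trace(x)).samples
    e2 = envelope(_trace(-x)).samples
    np.testing.assert_allclose(e1, e2)


def test_envelope_rejects_too_short_smoothing():
    with pytest.raises(ValidationError):
        envelope(_trace(np.zeros(100), fs=10.0), smoothing=0.1)


def test_baseline_of_constant_envelope_is_constant():
    env = _trace(np.full(int(60 * FS), 2.5))
    base = tonic_baseline(env, baseline_window=20.0)
    np.testing.assert_allclose(base.samples, 2.5, rtol=1e-9)


def test_baseline_robust_to_brief_burst():
    env = make_bursty_trace([10.0], burst_dur=0.5, factor=10.0, total_s=60.0)
    base = tonic_baseline(env, baseline_window=20.0)
    assert np.all(np.abs(base.samples - 1.0) < 0.05)


def test_baseline_below_running_mean_under_bursts(rng):
    # right-skewed envelope: median-based background sits under the mean
    env_arr = np.full(int(120 * FS), 1.0)
    for t in rng.uniform(15, 105, 25):
        i0 = int(t * FS)
        env_arr[i0:i0 + int(0.4 * FS)] += rng.uniform(3, 8)
    base = tonic_baseline(_trace(env_arr), baseline_window=20.0)
    kernel = np.ones(int(20 * FS)) / int(20 * FS)
    running_mean = np.convolve(env_arr, kernel, mode="same")
    interior = slice(int(15 * FS), int(105 * FS))
    assert np.all(base.samples[interior] <= running_mean[interior] + 1e-9)


def test_flat_envelope_yields_no_events():
    env = _trace(np.full(int(60 * FS), 1.0))
    base = tonic_baseline(env)
    assert detect_jerks(env, base) == []


def test_three_bursts_detected_and_match_oracle():
    env = make_bursty_trace([30.0, 50.0, 70.0], burst_dur=0.3, factor=2.5)
    base = tonic_baseline(env)
    params = DetectionParams()
    events = detect_jerks(env, base, params)
    assert len(events) == 3
    oracle = brute_force_detect(env.samples, base.samples, params, FS)
    assert len(oracle) == 3
    for ev, (s, e) in zip(events, oracle):
        assert ev.onset == pytest.approx(s / FS)
        assert ev.offset == pytest.approx(e / FS)
    for ev in events:
        assert ev.peak_amplitude >= params.amplitude_factor * ev.baseline
        assert params.min_duration <= ev.duration <= params.max_duration


def test_duration_criterion_rejects_short_and_long():
    # a 0.1-s and a 6-s burst at 3x baseline -> no events
    env = make_bursty_trace([30.0], burst_dur=0.1, factor=3.0)
    env.samples[int(60 * FS):int(66 * FS)] = 3.0
    base = tonic_baseline(env)
    assert detect_jerks(env, base) == []


def test_random_envelopes_match_oracle_and_criteria(rng):
    params = DetectionParams()
    for _ in range(5):
        env_arr = np.full(int(90 * FS), 1.0) + rng.uniform(0, 0.1, int(90 * FS))
        for t in rng.uniform(12, 75, 8):
            i0 = int(t * FS)
            env_arr[i0:i0 + int(rng.uniform(0.05, 1.2) * FS)] += rng.uniform(1.5, 6)
        env = _trace(env_arr)
        base = tonic_baseline(env)
        events = detect_jerks(env, base, params)
        oracle = brute_force_detect(env_arr, base.samples, params, FS)
        assert [(int(round(e.onset * FS)), int(round(e.offset * FS)))
                for e in events] == [(s, e) for s, e in oracle]
        for ev in events:
            assert ev.peak_amplitude >= params.amplitude_factor * ev.baseline
            tol = 0.5 / FS
            assert params.min_duration - tol <= ev.duration <= params.max_duration + tol


def test_detection_is_scale_invariant(rng):
    raw = rng.normal(0, 1, int(120 * FS))
    for t in [20, 45, 80]:
        i0 = int(t * FS)
        raw[i0:i0 + int(0.4 * FS)] += rng.normal(0, 5, int(0.4 * FS))

    def detect(x):
        env = envelope(_trace(x))
        base = tonic_baseline(env)
        return detect_jerks(env, base)

    ev1 = detect(raw)
    ev2 = detect(raw * 37.5)
    assert len(ev1) == len(ev2) > 0
    assert [e.onset for e in ev1] == [e.onset for e in ev2]


# ---------------------------------------------------------------------------
# bilateral fusion
# ---------------------------------------------------------------------------

def _ev(onset, limb="L", dur=0.3):
    return MotorEvent(limb, onset, onset + dur, 3.0, 1.0)


def brute_force_max_matching(on_l, on_r, window):
    """Maximum bipartite matching size by exhaustive enumeration."""
    best = 0
    pairs = [(i, j) for i in range(len(on_l)) for j in range(len(on_r))
             if abs(on_l[i] - on_r[j]) < window]
    for k in range(min(len(on_l), len(on_r)), 0, -1):
        for combo in itertools.combinations(pairs, k):
            li = [i for i, _ in combo]
            rj = [j for _, j in combo]
            if len(set(li)) == k and len(set(rj)) == k:
                best = k
                break
        if best:
            break
    return best


def test_identical_events_fuse_to_one_bilateral():
    merged = merge_bilateral([_ev(10.0, "L")], [_ev(10.0, "R")])
    assert len(merged) == 1
    assert merged[0].limb == "bilateral"


def test_unilateral_events_pass_through():
    evs = [_ev(5.0, "L"), _ev(40.0, "L")]
    assert merge_bilateral(evs, []) == evs


def test_unsorted_bilateral_input_rejected():
    with pytest.raises(ValidationError):
        merge_bilateral([_ev(10.0), _ev(5.0)], [])


def test_bilateral_count_matches_matching_oracle(rng):
    window = 0.5
    for _ in range(40):
        on_l = np.sort(rng.uniform(0, 10, rng.integers(0, 5)))
        on_r = np.sort(rng.uniform(0, 10, rng.integers(0, 5)))
        merged = merge_bilateral([_ev(t, "L") for t in on_l],
                                 [_ev(t, "R") for t in on_r], window)
        n_fused = sum(1 for e in merged if e.limb == "bilateral")
        n_expected = brute_force_max_matching(list(on_l), list(on_r), window)
        # movements are never double-counted
        assert len(merged) == len(on_l) + len(on_r) - n_fused
        assert n_fused == n_expected
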