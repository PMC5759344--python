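import itertools

import numpy as np
import pytest

from ratplm import (AnalysisWindow, MotorEvent, PLMSequence, ValidationError,
                    assign_states, compute_indices, group_sequences)

from conftest import make_hypnogram

IMI_CHOICES = (10.0, 50.0, 89.0, 90.0, 91.0, 120.0)


def _events_from_imis(imis, start=100.0):
    onsets = np.concatenate([[start], start + np.cumsum(imis)])
    return [MotorEvent("L", t, t + 0.3, 3.0, 1.0) for t in onsets]


def brute_force_grouping(onsets, max_imi=90.0, min_run=4):
    """Oracle: split at gaps >= max_imi, keep runs >= min_run."""
    runs, current = [], [0]
    for i in range(1, len(onsets)):
        if onsets[i] - onsets[i - 1] < max_imi:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    runs.append(current)
    seq_idx = [i for run in runs if len(run) >= min_run for i in run]
    iso_idx = [i for run in runs if len(run) < min_run for i in run]
    return seq_idx, iso_idx


def test_four_events_under_90s_form_one_sequence():
    events = _events_from_imis([30.0, 30.0, 30.0])
    sequences, isolated = group_sequences(events)
    assert len(sequences) == 1 and len(sequences[0].events) == 4
    assert isolated == []
    np.testing.assert_allclose(sequences[0].imis, 30.0)


def test_three_events_stay_isolated():
    events = _events_from_imis([20.0, 20.0])
    sequences, isolated = group_sequences(events)
    assert sequences == []
    assert len(isolated) == 3


def test_gap_of_95s_splits_into_two_sequences():
    events = _events_from_imis([30, 30, 30, 95, 30, 30, 30])
    sequences, isolated = group_sequences(events)
    assert len(sequences) == 2
    assert [len(s.events) for s in sequences] == [4, 4]
    assert isolated == []


def test_exactly_90s_breaks_the_run():
    # strict inequality: an IMI of exactly 90 s terminates the run
    sequences, isolated = group_sequences(_events_from_imis([30, 30, 90, 30, 30]))
    assert sequences == []
    assert len(isolated) == 6
    sequences, _ = group_sequences(_events_from_imis([89.0, 89.0, 89.0]))
    assert len(sequences) == 1


def test_grouping_matches_oracle_exhaustively():
    """All IMI configurations up to 6 events, from the boundary-rich set."""
    for n_imis in range(1, 6):
        for imis in itertools.product(IMI_CHOICES, repeat=n_imis):
            events = _events_from_imis(imis)
            sequences, isolated = group_sequences(events)
            onsets = [e.onset for e in events]
            seq_idx, iso_idx = brute_force_grouping(onsets)
            got_seq = [e.onset for s in sequences for e in s.events]
            assert got_seq == [onsets[i] for i in seq_idx]
            assert [e.onset for e in isolated] == [onsets[i] for i in iso_idx]
            # partition property
            assert len(got_seq) + len(isolated) == len(events)


def test_grouping_matches_oracle_random_large(rng):
    for _ in range(300):
        n = rng.integers(7, 9)
        imis = rng.choice(IMI_CHOICES, size=n - 1)
        events = _events_from_imis(imis)
        sequences, isolated = group_sequences(events)
        onsets = [e.onset for e in events]
        seq_idx, iso_idx = brute_force_grouping(onsets)
        assert [e.onset for s in sequences for e in s.events] == \
            [onsets[i] for i in seq_idx]
        assert len(isolated) == len(iso_idx)


def test_unsorted_events_rejected():
    events = _events_from_imis([30, 30, 30])[::-1]
    with pytest.raises(ValidationError):
        group_sequences(events)


def test_plmsequence_invariants_enforced():
    with pytest.raises(ValidationError):
        PLMSequence(_events_from_imis([30, 30]))  # only 3 events
    with pytest.raises(ValidationError):
        PLMSequence(_events_from_imis([30, 95, 30]))  # an IMI >= 90 s


def test_assign_states_examples(tiny_hypnogram):
    # epochs: QW QW SWS SWS SWS REM at 10 s
    evs = [MotorEvent("L", 25.0, 25.3, 3.0, 1.0),
           MotorEvent("L", 50.0, 50.3, 3.0, 1.0)]
    out = assign_states(evs, tiny_hypnogram)
    assert out[0].stage == "SWS"
    assert out[1].stage == "REM"  # boundary onset takes the later epoch
    with pytest.raises(ValidationError):
        assign_states([MotorEvent("L", 60.0, 60.3, 3.0, 1.0)], tiny_hypnogram)


def test_assign_states_matches_per_sample_oracle(rng):
    labels = rng.choice(["AW", "QW", "SWS", "REM"], size=200)
    hyp = make_hypnogram(labels)
    onsets = rng.uniform(0, hyp.duration - 1e-6, 100)
    evs = [MotorEvent("L", t, t + 0.2, 3.0, 1.0) for t in np.sort(onsets)]
    out = assign_states(evs, hyp)
    for ev in out:
        assert ev.stage == labels[int(ev.onset // 10.0)]


def _scored_fixture():
    # 2 h: 1 h QW, 0.75 h SWS, 0.25 h REM
    labels = ["QW"] * 360 + ["SWS"] * 270 + ["REM"] * 90
    hyp = make_hypnogram(labels)
    return hyp


def test_index_arithmetic():
    hyp = _scored_fixture()
    # one 10-event train in SWS (0.75 h), 3 isolated in REM, 2 isolated in QW
    train = [MotorEvent("L", 3700 + 30 * i, 3700.3 + 30 * i, 3.0, 1.0)
             for i in range(10)]
    iso = [MotorEvent("L", t, t + 0.3, 3.0, 1.0)
           for t in (500.0, 1000.0, 6500.0, 6700.0, 6900.0)]
    events = assign_states(sorted(train + iso, key=lambda e: e.onset), hyp)
    sequences, isolated = group_sequences(events)
    rep = compute_indices(sequences, isolated, hyp)
    assert rep.counts == {"plmw": 0, "plms": 10, "ilms": 3}
    assert rep.plmsi == pytest.approx(10 / 0.75)
    assert rep.ilmsi == pytest.approx(3 / 1.0)
    assert rep.plmwi == 0.0
    # REM isolated events can be excluded from ILMS
    rep2 = compute_indices(sequences, isolated, hyp, ilms_include_rem=False)
    assert rep2.counts["ilms"] == 0


def test_zero_denominator_gives_undefined_index():
    hyp = make_hypnogram(["QW"] * 720)  # no sleep at all
    evs = assign_states([MotorEvent("L", 100.0, 100.3, 3.0, 1.0)], hyp)
    seqs, iso = group_sequences(evs)
    rep = compute_indices(seqs, iso, hyp)
    assert rep.plmsi is None and rep.ilmsi is None
    assert rep.plmwi == 0.0


def test_count_additivity_across_phase_windows(rng):
    hyp = _scored_fixture()
    onsets = np.sort(rng.uniform(0, hyp.duration - 1, 80))
    evs = assign_states(
        [MotorEvent("L", t, t + 0.3, 3.0, 1.0) for t in onsets], hyp)
    seqs, iso = group_sequences(evs)
    full = compute_indices(seqs, iso, hyp, AnalysisWindow("f", 0, 7200))
    first = compute_indices(seqs, iso, hyp, AnalysisWindow("a", 0, 3600))
    second = compute_indices(seqs, iso, hyp, AnalysisWindow("b", 3600, 7200))
    for key in ("plmw", "plms", "ilms"):
        assert full.counts[key] == first.counts[key] + second.counts[key]
    for key in ("qw", "sws", "sleep"):
        assert full.hours[key] == pytest.approx(first.hours[key] + second.hours[key])
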