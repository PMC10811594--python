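"""Scoring engine: latency, classification, per-input score, matching,
Sing-Lab crediting and session aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhythmlearn import (
    AcceptanceLevel,
    ClassifiedInput,
    InputEvent,
    classify,
    correct_latency,
    match_inputs,
    score_input,
    score_session,
    score_singlab,
    stars_for_ratio,
)
from rhythmlearn.scoring import _assign

from conftest import brute_force_assignment, make_schedule


# --- latency correction ---------------------------------------------------

def test_zero_latency_is_identity():
    events = [InputEvent(0.5), InputEvent(1.25)]
    assert correct_latency(events, 0.0) == events


def test_standard_latency_shifts_twenty_ms_earlier():
    (out,) = correct_latency([InputEvent(1.020)], 0.020)
    assert out.timestamp == pytest.approx(1.000)


def test_latency_clips_at_level_start():
    (out,) = correct_latency([InputEvent(0.010)], 0.020)
    assert out.timestamp == 0.0


def test_negative_latency_rejected():
    with pytest.raises(ValueError):
        correct_latency([InputEvent(1.0)], -0.01)


# --- classification -------------------------------------------------------

@pytest.mark.parametrize(
    "delta,expected",
    [
        (0.05, AcceptanceLevel.PERFECT),
        (-0.12, AcceptanceLevel.GOOD),
        (0.25, AcceptanceLevel.CORRECT),   # closed interval boundary
        (-0.10, AcceptanceLevel.PERFECT),  # boundaries inclusive
        (0.26, AcceptanceLevel.UNACCEPTABLE),
    ],
)
def test_classification_against_standard_windows(delta, expected, standard_profile):
    assert classify(delta, standard_profile) is expected


@given(delta=st.floats(min_value=-0.5, max_value=0.5))
def test_windows_are_nested(delta, standard_profile):
    level = classify(delta, standard_profile)
    if level is AcceptanceLevel.PERFECT:
        assert abs(delta) <= standard_profile.t_good
    if level in (AcceptanceLevel.PERFECT, AcceptanceLevel.GOOD):
        assert abs(delta) <= standard_profile.t_correct


def test_singlab_profile_cannot_be_classified(singlab_profile):
    with pytest.raises(ValueError):
        classify(0.0, singlab_profile)


# --- per-input score ------------------------------------------------------

def test_score_formula_spot_values():
    assert score_input(0.0, 0.25) == 100.0
    assert score_input(0.125, 0.25) == 50.0
    assert score_input(0.25, 0.25) == 0.0
    assert score_input(0.30, 0.25) == 0.0


def test_score_requires_positive_threshold():
    with pytest.raises(ValueError):
        score_input(0.1, 0.0)


@given(
    delta=st.floats(min_value=-1, max_value=1),
    threshold=st.floats(min_value=0.01, max_value=0.5),
)
def test_score_is_even_bounded_and_nonincreasing(delta, threshold):
    s = score_input(delta, threshold)
    assert 0.0 <= s <= 100.0
    assert s == score_input(-delta, threshold)
    # non-increasing in |delta|
    assert s >= score_input(delta * 1.5, threshold) - 1e-9


@given(threshold=st.floats(min_value=0.01, max_value=0.5))
def test_score_is_continuous_at_the_threshold(threshold):
    eps = 1e-9 * threshold
    assert score_input(threshold - eps, threshold) == pytest.approx(0.0, abs=1e-5)
    assert score_input(threshold + eps, threshold) == 0.0


# --- matching -------------------------------------------------------------

def test_empty_events_are_all_misses(standard_profile):
    out = match_inputs([], make_schedule([0, 1, 2, 3]), standard_profile)
    assert [c.level for c in out] == [AcceptanceLevel.MISS] * 4


def test_matching_example_with_miss_and_spurious(standard_profile):
    out = match_inputs(
        [InputEvent(0.98), InputEvent(2.30)],
        make_schedule([1.0, 2.0]),
        standard_profile,
    )
    assert out[0].delta_tap == pytest.approx(-0.02)
    assert out[0].level is AcceptanceLevel.PERFECT
    assert out[1].level is AcceptanceLevel.MISS
    assert out[2].level is AcceptanceLevel.SPURIOUS
    assert out[2].event_time == pytest.approx(2.30)


def test_equidistant_events_match_the_earlier_one(standard_profile):
    out = match_inputs(
        [InputEvent(0.9), InputEvent(1.1)],
        make_schedule([1.0]),
        standard_profile,
    )
    matched = out[0]
    assert matched.event_time == pytest.approx(0.9)
    assert out[1].level is AcceptanceLevel.SPURIOUS


def test_matched_inputs_always_within_the_acceptable_window(standard_profile):
    out = match_inputs(
        [InputEvent(t) for t in (0.5, 0.74, 1.26, 2.0)],
        make_schedule([1.0, 2.0]),
        standard_profile,
    )
    for c in out:
        if c.delta_tap is not None:
            assert abs(c.delta_tap) <= standard_profile.t_correct + 1e-12


@given(
    events=st.lists(st.floats(min_value=0, max_value=3), max_size=6),
    expected=st.lists(
        st.floats(min_value=0, max_value=3), min_size=1, max_size=6, unique=True
    ),
)
def test_assignment_equals_exhaustive_optimum(events, expected, standard_profile):
    expected = sorted(expected)
    if min(np.diff(expected), default=1.0) <= 1e-6:
        return
    caps = [standard_profile.t_correct] * len(expected)
    got = _assign(np.sort(np.asarray(events)), np.asarray(expected), np.asarray(caps))
    got_cost = sum(
        abs(sorted(events)[e] - expected[x]) for x, e in got.items()
    )
    opt_matches, opt_cost = brute_force_assignment(events, expected, caps)
    assert len(got) == opt_matches
    assert got_cost == pytest.approx(opt_cost, abs=1e-6)


# --- Sing Lab -------------------------------------------------------------

def singlab_schedule():
    return make_schedule([1.0, 3.0, 5.0], duration=7.0, note_durations=[1.0, 1.0, 1.0])


def test_singlab_credits_on_time_fully_sung_note(singlab_profile):
    out = score_singlab(
        [InputEvent(1.0)], singlab_schedule(), [1.0, 0.0, 0.0], singlab_profile
    )
    assert out[0].level is AcceptanceLevel.CORRECT
    assert out[0].input_score == 100.0


def test_singlab_rejects_half_sung_note(singlab_profile):
    out = score_singlab(
        [InputEvent(1.0)], singlab_schedule(), [0.5, 0.0, 0.0], singlab_profile
    )
    assert out[0].level is AcceptanceLevel.MISS
    assert out[0].input_score == 0.0


def test_singlab_onset_window_is_capped(singlab_profile):
    # 1.0 s note: window = min(0.15, 0.30 * 1.0) = 0.15 s
    out = score_singlab(
        [InputEvent(1.14)], singlab_schedule(), [0.7, 0.0, 0.0], singlab_profile
    )
    assert out[0].level is AcceptanceLevel.CORRECT
    # onset 0.16 s late falls outside the window
    out = score_singlab(
        [InputEvent(1.16)], singlab_schedule(), [0.7, 0.0, 0.0], singlab_profile
    )
    assert out[0].level is AcceptanceLevel.MISS


def test_singlab_sung_time_cannot_exceed_duration(singlab_profile):
    with pytest.raises(ValueError):
        score_singlab(
            [InputEvent(1.0)], singlab_schedule(), [1.5, 0.0, 0.0], singlab_profile
        )


# --- session aggregation --------------------------------------------------

def perfect_input(t):
    return ClassifiedInput(
        level=AcceptanceLevel.PERFECT, input_score=100.0,
        expected_time=t, event_time=t, delta_tap=0.0,
    )


def miss(t):
    return ClassifiedInput(
        level=AcceptanceLevel.MISS, input_score=0.0, expected_time=t
    )


def spurious(t):
    return ClassifiedInput(
        level=AcceptanceLevel.SPURIOUS, input_score=0.0, event_time=t
    )


def test_all_perfect_session():
    result = score_session([perfect_input(float(t)) for t in range(10)])
    assert result.acceptable_ratio == 1.0
    assert result.mean_score == 100.0
    assert result.stars == 3


def test_misses_drag_the_mean_score():
    matched = [
        ClassifiedInput(
            level=AcceptanceLevel.GOOD, input_score=80.0,
            expected_time=float(t), event_time=float(t), delta_tap=0.05,
        )
        for t in range(8)
    ]
    result = score_session(matched + [miss(8.0), miss(9.0)])
    assert result.mean_score == pytest.approx(64.0)
    assert result.n_expected == 10


def test_spurious_events_do_not_change_ratio_or_mean():
    base = [perfect_input(float(t)) for t in range(4)] + [miss(4.0)]
    with_spurious = base + [spurious(0.33), spurious(2.71)]
    r0 = score_session(base)
    r1 = score_session(with_spurious)
    assert r1.acceptable_ratio == r0.acceptable_ratio
    assert r1.mean_score == r0.mean_score
    assert r1.n_spurious == 2


def test_session_requires_expected_inputs():
    with pytest.raises(ValueError):
        score_session([spurious(1.0)])


@pytest.mark.parametrize(
    "ratio,stars", [(0.40, 0), (0.50, 1), (0.60, 1), (0.75, 2), (0.76, 2),
                    (0.90, 3), (0.92, 3), (1.0, 3)]
)
def test_star_thresholds(ratio, stars):
    assert stars_for_ratio(ratio) == stars


@given(r1=st.floats(0, 1), r2=st.floats(0, 1))
def test_stars_non_decreasing_and_one_star_iff_half(r1, r2):
    if r1 <= r2:
        assert stars_for_ratio(r1) <= stars_for_ratio(r2)
    assert (stars_for_ratio(r1) >= 1) == (r1 >= 0.5)
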