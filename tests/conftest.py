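import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhythmlearn import BeatSchedule, Density, ResponseType, ToleranceProfile

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def standard_profile() -> ToleranceProfile:
    """The 0.1/0.15/0.25 s window set shared by most tasks."""
    return ToleranceProfile(t_perfect=0.1, t_good=0.15, t_correct=0.25)


@pytest.fixture
def singlab_profile() -> ToleranceProfile:
    return ToleranceProfile(
        singlab_onset_tolerance=0.15,
        singlab_onset_cap_fraction=0.30,
        singlab_min_sung_fraction=0.60,
    )


def make_schedule(expected_times, duration=None, note_durations=None):
    """Hand-built schedule wrapper for scoring tests."""
    expected_times = tuple(float(t) for t in expected_times)
    return BeatSchedule(
        expected_times=expected_times,
        tempo_bpm=60.0,
        duration_s=duration if duration is not None else (expected_times[-1] + 1 if expected_times else 1.0),
        density=Density.EVERY_BEAT,
        response_type=ResponseType.CONTINUOUS_TAPPING,
        note_durations=tuple(note_durations) if note_durations is not None else None,
    )


def brute_force_assignment(event_times, expected_times, caps):
    """Exhaustive-optimum oracle for event->expected matching.

    Bitmask DP over (event index, used expected set) returning
    (max matches, min total |delta|) lexicographically.
    """
    events = list(event_times)
    expected = list(expected_times)
    caps = list(caps)
    n_x = len(expected)
    feasible = [
        [j for j in range(n_x) if abs(e - expected[j]) <= caps[j] + 1e-12]
        for e in events
    ]
    memo: dict[tuple[int, int], tuple[int, float]] = {}

    def rec(i: int, used: int) -> tuple[int, float]:
        if i == len(events):
            return (0, 0.0)
        key = (i, used)
        if key in memo:
            return memo[key]
        best_m, best_c = rec(i + 1, used)  # leave event i spurious
        for j in feasible[i]:
            if not used >> j & 1:
                m, c = rec(i + 1, used | 1 << j)
                m, c = m + 1, c + abs(events[i] - expected[j])
                if m > best_m or (m == best_m and c < best_c - 1e-15):
                    best_m, best_c = m, c
        memo[key] = (best_m, best_c)
        return memo[key]

    return rec(0, 0)
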