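"""Timing-tolerance scoring of player inputs against a beat schedule.

Each expected beat time T defines nested tolerance windows
(t_perfect < t_good < t_correct).  An input at time t has asynchrony
``delta_tap = t - T`` (after latency correction) and is acceptable when
``|delta_tap| <= t_correct``; finer windows grade it perfect or good.
Each expected input also receives a normalized 0-100 performance score

    score = (-100 / threshold) * |delta_tap| + 100   if |delta_tap| <= threshold
    score = 0                                        otherwise

with threshold = t_correct.  A session is summarised by the ratio of
acceptable inputs over expected inputs, the mean performance score, and a
star award (>=50% -> 1, >=75% -> 2, >=90% -> 3 stars).

Raw events are matched to expected times by an exact one-to-one
assignment that maximises the number of matched pairs within t_correct
and, among those, minimises the total |delta_tap| (ties broken toward the
earlier event).  Expected times left unmatched are misses; events left
unmatched are spurious and never enter the session denominators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .schedule import BeatSchedule
from .tasks import Interaction, ToleranceProfile, Version

__all__ = [
    "AcceptanceLevel",
    "InputEvent",
    "ClassifiedInput",
    "SessionResult",
    "DEFAULT_LATENCY_S",
    "correct_latency",
    "classify",
    "score_input",
    "match_inputs",
    "score_singlab",
    "score_session",
    "stars_for_ratio",
]

#: standard delay between the player's real action and the timestamp the
#: operating system reports; corrected before matching
DEFAULT_LATENCY_S = 0.020

_ACCEPTABLE_FRACTIONS = ((0.90, 3), (0.75, 2), (0.50, 1))


class AcceptanceLevel(str, enum.Enum):
    PERFECT = "perfect"
    GOOD = "good"
    CORRECT = "correct"
    UNACCEPTABLE = "unacceptable"
    MISS = "miss"
    SPURIOUS = "spurious"


ACCEPTABLE_LEVELS = frozenset(
    {AcceptanceLevel.PERFECT, AcceptanceLevel.GOOD, AcceptanceLevel.CORRECT}
)


@dataclass(frozen=True)
class InputEvent:
    """One timestamped player action, in seconds from level start."""

    timestamp: float
    modality: Optional[Interaction] = None

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("event timestamps must be >= 0")


@dataclass(frozen=True)
class ClassifiedInput:
    """One expected input (matched or missed) or one spurious event."""

    level: AcceptanceLevel
    input_score: float
    expected_time: Optional[float] = None
    event_time: Optional[float] = None
    delta_tap: Optional[float] = None


@dataclass(frozen=True)
class SessionResult:
    """Level-wise aggregate of one played session."""

    task: str
    time_index: int
    acceptable_ratio: float
    mean_score: float
    stars: int
    n_expected: int
    n_spurious: int = 0


def correct_latency(
    events: Sequence[InputEvent], latency_s: float = DEFAULT_LATENCY_S
) -> list[InputEvent]:
    """Shift every timestamp earlier by the device latency (clipped at 0).

    Devices report an input after the player's real action; subtracting a
    standard latency recovers the action time.
    """
    if latency_s < 0:
        raise ValueError(f"latency_s must be >= 0, got {latency_s}")
    return [
        InputEvent(max(0.0, e.timestamp - latency_s), e.modality) for e in events
    ]


def classify(delta_tap: float, profile: ToleranceProfile) -> AcceptanceLevel:
    """Grade one asynchrony against the nested windows (closed intervals)."""
    if profile.is_singlab:
        raise ValueError("Sing Lab uses the credited/uncredited rule")
    a = abs(delta_tap)
    if a <= profile.t_perfect:
        return AcceptanceLevel.PERFECT
    if a <= profile.t_good:
        return AcceptanceLevel.GOOD
    if a <= profile.t_correct:
        return AcceptanceLevel.CORRECT
    return AcceptanceLevel.UNACCEPTABLE


def score_input(delta_tap: float, threshold: float) -> float:
    """Normalized 0-100 performance score of one input."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    a = abs(delta_tap)
    if a <= threshold:
        return (-100.0 / threshold) * a + 100.0
    return 0.0


def _assign(
    event_times: np.ndarray, expected_times: np.ndarray, caps: np.ndarray
) -> dict[int, int]:
    """Exact assignment event->expected maximising matches within the
    per-expected cap, then minimising total |delta|; equal-|delta| ties go
    to the earlier event.  Returns {expected index: event index}."""
    n_e, n_x = len(event_times), len(expected_times)
    if n_e == 0 or n_x == 0:
        return {}
    delta = np.abs(event_times[:, None] - expected_times[None, :])
    feasible = delta <= caps[None, :] + 1e-12
    # a large penalty makes infeasible pairs strictly worse than leaving
    # both sides unmatched, so the solver maximises feasible matches first
    big = 1e6
    cost = np.where(feasible, delta, big)
    # infinitesimal preference for earlier events on exact ties
    cost = cost + np.arange(n_e)[:, None] * 1e-9
    rows, cols = linear_sum_assignment(cost)
    return {
        int(x): int(e)
        for e, x in zip(rows, cols)
        if feasible[e, x]
    }


def match_inputs(
    events: Sequence[InputEvent],
    schedule: BeatSchedule,
    profile: ToleranceProfile,
) -> list[ClassifiedInput]:
    """Match events to expected times and classify every expected input.

    Returns one entry per expected time (in schedule order) followed by
    one SPURIOUS entry per unmatched event (in time order).
    """
    if profile.is_singlab:
        raise ValueError("use score_singlab for Sing-Lab sessions")
    event_times = np.sort(np.asarray([e.timestamp for e in events], dtype=float))
    expected = np.asarray(schedule.expected_times, dtype=float)
    caps = np.full(len(expected), profile.t_correct)
    matched = _assign(event_times, expected, caps)
    out: list[ClassifiedInput] = []
    used = set(matched.values())
    for i, t_exp in enumerate(expected):
        if i in matched:
            t_ev = event_times[matched[i]]
            delta = float(t_ev - t_exp)
            out.append(
                ClassifiedInput(
                    level=classify(delta, profile),
                    input_score=score_input(delta, profile.t_correct),
                    expected_time=float(t_exp),
                    event_time=float(t_ev),
                    delta_tap=delta,
                )
            )
        else:
            out.append(
                ClassifiedInput(
                    level=AcceptanceLevel.MISS,
                    input_score=0.0,
                    expected_time=float(t_exp),
                )
            )
    for j in range(len(event_times)):
        if j not in used:
            out.append(
                ClassifiedInput(
                    level=AcceptanceLevel.SPURIOUS,
                    input_score=0.0,
                    event_time=float(event_times[j]),
                )
            )
    return out


def score_singlab(
    note_onsets: Sequence[InputEvent],
    schedule: BeatSchedule,
    sung_seconds: Sequence[float],
    profile: ToleranceProfile,
) -> list[ClassifiedInput]:
    """Binary credited/uncredited scoring of sung notes.

    A note is credited when its onset falls within the Sing-Lab onset
    window — min(onset tolerance, cap fraction x note duration) — and the
    note was sung for at least the minimum fraction of its duration.
    ``sung_seconds`` is the per-note sung time, parallel to the schedule.
    """
    if not profile.is_singlab:
        raise ValueError("score_singlab requires a Sing-Lab tolerance profile")
    if schedule.note_durations is None:
        raise ValueError("Sing-Lab scoring needs a schedule with note durations")
    durations = np.asarray(schedule.note_durations, dtype=float)
    sung = np.asarray(sung_seconds, dtype=float)
    if len(sung) != len(durations):
        raise ValueError("sung_seconds must parallel the schedule's notes")
    if np.any(sung > durations + 1e-12):
        raise ValueError("sung time per note cannot exceed the note duration")
    onset_times = np.sort(np.asarray([e.timestamp for e in note_onsets], dtype=float))
    expected = np.asarray(schedule.expected_times, dtype=float)
    caps = np.asarray([profile.onset_window(d) for d in durations])
    matched = _assign(onset_times, expected, caps)
    out = []
    for i, t_exp in enumerate(expected):
        credited = (
            i in matched
            and sung[i] >= profile.singlab_min_sung_fraction * durations[i] - 1e-12
        )
        if credited:
            delta = float(onset_times[matched[i]] - t_exp)
            out.append(
                ClassifiedInput(
                    level=AcceptanceLevel.CORRECT,
                    input_score=100.0,
                    expected_time=float(t_exp),
                    event_time=float(onset_times[matched[i]]),
                    delta_tap=delta,
                )
            )
        else:
            out.append(
                ClassifiedInput(
                    level=AcceptanceLevel.MISS,
                    input_score=0.0,
                    expected_time=float(t_exp),
                )
            )
    return out


def stars_for_ratio(acceptable_ratio: float) -> int:
    """Star award from the acceptable-input ratio (>=50/75/90%)."""
    for cut, stars in _ACCEPTABLE_FRACTIONS:
        if acceptable_ratio >= cut:
            return stars
    return 0


def score_session(
    classified: Iterable[ClassifiedInput],
    version: Version | str = Version.FINAL,
    time_index: int = 1,
    task: str = "",
) -> SessionResult:
    """Aggregate classified inputs into a session summary.

    The denominator of both the acceptable ratio and the mean score is
    the number of expected inputs; misses contribute zero and spurious
    events are counted but excluded.
    """
    version = Version(version)
    classified = list(classified)
    expected = [c for c in classified if c.level is not AcceptanceLevel.SPURIOUS]
    n_spurious = len(classified) - len(expected)
    if not expected:
        raise ValueError("a session needs at least one expected input")
    n_acceptable = sum(1 for c in expected if c.level in ACCEPTABLE_LEVELS)
    ratio = n_acceptable / len(expected)
    mean_score = float(np.mean([c.input_score for c in expected]))
    return SessionResult(
        task=task,
        time_index=time_index,
        acceptable_ratio=ratio,
        mean_score=mean_score,
        stars=stars_for_ratio(ratio),
        n_expected=len(expected),
        n_spurious=n_spurious,
    )
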