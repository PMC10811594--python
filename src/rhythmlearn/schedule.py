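"""Expected-input beat grids for one level of one task.

A level plays a song at a fixed tempo in 4/4; the schedule lists the
times T at which the player's input is expected.  Which beats carry an
expected input depends on the task's response type:

* ``continuous_tapping`` — every pattern slot carries an input;
* ``last_beat`` — two demonstration beats open each measure and the
  player answers on beat 3 (beats indexed 1-4 within a measure);
* ``call_and_response`` — measures alternate demonstration/response and
  only response measures carry expected inputs.

The rhythmic density of the pattern varies with difficulty: one input on
every beat, an "eighth" pattern of 3 evenly spaced inputs per 2 beats, or
a half-time pattern of one input every 2 beats.  At higher levels the
density can change mid-task, anchored to a measure boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .tasks import ResponseType, TaskSpec

__all__ = [
    "Density",
    "BeatSchedule",
    "build_schedule",
    "apply_rhythm_change",
    "schedule_to_frame",
]

BEATS_PER_MEASURE = 4


class Density(str, enum.Enum):
    EVERY_BEAT = "every_beat"
    EIGHTH_PATTERN = "eighth_pattern"
    HALF_TIME = "half_time"


#: inter-input spacing in beat periods
_SPACING = {
    Density.EVERY_BEAT: 1.0,
    Density.EIGHTH_PATTERN: 2.0 / 3.0,  # 3 inputs in 2 beats
    Density.HALF_TIME: 2.0,
}

#: difficulty rank used by the curriculum (every-beat is the entry level)
DENSITY_RANK = {
    Density.EVERY_BEAT: 0,
    Density.EIGHTH_PATTERN: 1,
    Density.HALF_TIME: 1,
}


@dataclass(frozen=True)
class BeatSchedule:
    expected_times: tuple[float, ...]
    tempo_bpm: float
    duration_s: float
    density: Density
    response_type: ResponseType
    start_offset: float = 0.0
    note_durations: Optional[tuple[float, ...]] = None
    change_points: tuple[tuple[float, Density], ...] = ()

    def __post_init__(self) -> None:
        times = self.expected_times
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("expected_times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration_s):
            raise ValueError("expected_times must lie in [0, duration_s]")
        if self.note_durations is not None and len(self.note_durations) != len(times):
            raise ValueError("note_durations must parallel expected_times")

    @property
    def beat_period(self) -> float:
        return 60.0 / self.tempo_bpm

    @property
    def n_expected(self) -> int:
        return len(self.expected_times)


def _pattern_times(origin: float, end: float, spacing: float) -> list[float]:
    """Grid origin, origin+spacing, ... strictly below end."""
    out = []
    k = 0
    while True:
        t = origin + k * spacing
        if t >= end - 1e-12:
            break
        out.append(t)
        k += 1
    return out


def _segment_times(
    response_type: ResponseType,
    density: Density,
    beat: float,
    seg_start: float,
    seg_end: float,
    offset: float,
) -> list[float]:
    """Expected times of one constant-density segment.

    ``seg_start`` must sit on a measure boundary of the grid anchored at
    ``offset`` (the song start); segment times are generated relative to
    that boundary so a mid-task change restarts the pattern cleanly.
    """
    measure = BEATS_PER_MEASURE * beat
    spacing = _SPACING[density] * beat
    if response_type is ResponseType.CONTINUOUS_TAPPING:
        return _pattern_times(seg_start, seg_end, spacing)
    if response_type is ResponseType.LAST_BEAT:
        if density is not Density.EVERY_BEAT:
            raise ValueError(
                "last-beat tasks answer once per measure and only support "
                "the every_beat density"
            )
        # player answers on beat 3 of each 4-beat measure
        times = []
        m = 0
        while True:
            t = seg_start + m * measure + 2 * beat
            if t >= seg_end - 1e-12:
                break
            times.append(t)
            m += 1
        return times
    # call and response: measures alternate demonstration/response, one
    # measure each; parity is anchored to the song start so measure 0
    # (counted from `offset`) is a demonstration
    times = []
    first_measure = round((seg_start - offset) / measure)
    m = first_measure
    while offset + m * measure < seg_end - 1e-12:
        m_start = offset + m * measure
        if m % 2 == 1:  # response measure
            m_end = min(m_start + measure, seg_end)
            times.extend(_pattern_times(m_start, m_end, spacing))
        m += 1
    return times


def build_schedule(
    spec: TaskSpec,
    tempo_bpm: float,
    duration_s: float,
    density: Density | str = Density.EVERY_BEAT,
    start_offset: float = 0.0,
    note_duration_s: Optional[float] = None,
) -> BeatSchedule:
    """Expected-input grid for one level.

    ``note_duration_s`` sets the sung-note length for Sing Lab; by
    default notes last 80% of the inter-input spacing.
    """
    if tempo_bpm <= 0:
        raise ValueError(f"tempo_bpm must be positive, got {tempo_bpm}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if start_offset < 0 or start_offset >= duration_s:
        raise ValueError("start_offset must lie in [0, duration_s)")
    density = Density(density)
    beat = 60.0 / tempo_bpm
    times = _segment_times(
        spec.response_type, density, beat, start_offset, duration_s, start_offset
    )
    durations = None
    if spec.tolerance.is_singlab:
        note = note_duration_s if note_duration_s is not None else 0.8 * _SPACING[density] * beat
        durations = tuple(note for _ in times)
    return BeatSchedule(
        expected_times=tuple(times),
        tempo_bpm=tempo_bpm,
        duration_s=duration_s,
        density=density,
        response_type=spec.response_type,
        start_offset=start_offset,
        note_durations=durations,
    )


def apply_rhythm_change(
    schedule: BeatSchedule,
    change_time: float,
    new_density: Density | str,
) -> BeatSchedule:
    """Regenerate the tail of a schedule under a new density.

    Times before ``change_time`` are kept; from the first measure
    boundary at or after ``change_time`` the grid restarts under
    ``new_density``.
    """
    if not (0 < change_time < schedule.duration_s):
        raise ValueError(
            f"change_time must lie in (0, {schedule.duration_s}), got {change_time}"
        )
    new_density = Density(new_density)
    beat = schedule.beat_period
    measure = BEATS_PER_MEASURE * beat
    anchor = schedule.start_offset + measure * math.ceil(
        (change_time - schedule.start_offset) / measure - 1e-12
    )
    head = [t for t in schedule.expected_times if t < change_time - 1e-12]
    tail = (
        _segment_times(
            schedule.response_type,
            new_density,
            beat,
            anchor,
            schedule.duration_s,
            schedule.start_offset,
        )
        if anchor < schedule.duration_s
        else []
    )
    durations = None
    if schedule.note_durations is not None:
        note = 0.8 * _SPACING[new_density] * beat
        durations = tuple(schedule.note_durations[: len(head)]) + tuple(
            note for _ in tail
        )
    return replace(
        schedule,
        expected_times=tuple(head) + tuple(tail),
        note_durations=durations,
        change_points=schedule.change_points + ((change_time, new_density),),
    )


def schedule_to_frame(schedule: BeatSchedule) -> pd.DataFrame:
    """Tabular view of a schedule (for CSV export and fixtures)."""
    n = schedule.n_expected
    return pd.DataFrame(
        {
            "index": range(n),
            "expected_time_s": schedule.expected_times,
            "note_duration_s": (
                schedule.note_durations
                if schedule.note_durations is not None
                else [float("nan")] * n
            ),
            "density": schedule.density.value,
        }
    )
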