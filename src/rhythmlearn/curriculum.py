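"""Level curriculum: 12 chapters of 6 levels with progressive difficulty.

Tasks are introduced one at a time, each practiced at least twice before
the next appears.  Across chapters the tempo rises and the rhythmic
pattern moves from one input per beat to the denser eighth pattern (or
the sparser half-time pattern), with mid-task rhythm changes at the
highest chapters.  Entry pathways are conditioned on declared diagnoses:
a child with dyspraxia starts with the motorically moderate Sing Lab
before River Splash and Karate Fruits, while a child with dyslexia is
offered River Splash before Sing Lab (Sing Lab loads the phonological
loop).  When both flags are present the motor-accessibility rule wins.

Daily missions revisit four previously played tasks, worst results first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .schedule import DENSITY_RANK, Density
from .scoring import SessionResult
from .tasks import ResponseType, TaskSpec, Version, list_tasks

__all__ = [
    "LevelPlan",
    "PathwayRule",
    "CurriculumConfig",
    "build_curriculum",
    "daily_missions",
]

N_CHAPTERS = 12
TASKS_PER_CHAPTER = 6
N_MISSIONS = 4


@dataclass(frozen=True)
class LevelPlan:
    chapter: int
    position: int
    task: str
    tempo_bpm: float
    density: Density
    duration_s: float
    change_points: tuple[tuple[float, Density], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.chapter <= N_CHAPTERS:
            raise ValueError(f"chapter must be in [1, {N_CHAPTERS}]")
        if not 1 <= self.position <= TASKS_PER_CHAPTER:
            raise ValueError(f"position must be in [1, {TASKS_PER_CHAPTER}]")


@dataclass(frozen=True)
class PathwayRule:
    """Diagnosis-conditioned reordering of the task-introduction sequence."""

    trigger: str
    advanced: tuple[str, ...]
    deferred: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.advanced) & set(self.deferred):
            raise ValueError(
                "a pathway rule cannot both advance and defer a task: "
                f"{set(self.advanced) & set(self.deferred)}"
            )


#: rule order encodes precedence (motor accessibility first)
DEFAULT_PATHWAYS: tuple[PathwayRule, ...] = (
    PathwayRule("dyspraxia", advanced=("Sing Lab",),
                deferred=("River Splash", "Karate Fruits")),
    PathwayRule("dyslexia", advanced=("River Splash",), deferred=("Sing Lab",)),
)


@dataclass(frozen=True)
class CurriculumConfig:
    tempo_start_bpm: float = 90.0
    tempo_end_bpm: float = 132.0
    practice_repeats: int = 2  # 2 or 3 plays before the next task appears
    dense_from_chapter: int = 7
    change_from_chapter: int = 10
    pathways: tuple[PathwayRule, ...] = DEFAULT_PATHWAYS

    def __post_init__(self) -> None:
        if self.practice_repeats not in (2, 3):
            raise ValueError("practice_repeats must be 2 or 3")
        if self.tempo_end_bpm < self.tempo_start_bpm:
            raise ValueError("tempo must not decrease across chapters")


def _intro_order(
    specs: Sequence[TaskSpec],
    diagnoses: frozenset[str],
    pathways: Sequence[PathwayRule],
) -> list[str]:
    """Task-introduction order after applying triggered pathway rules.

    Earlier rules take precedence: a later rule is applied only where it
    does not undo an earlier rule's ordering.
    """
    order = [s.name for s in specs]
    pinned: set[tuple[str, str]] = set()  # (before, after) pairs already enforced
    for rule in pathways:
        if rule.trigger not in diagnoses:
            continue
        wanted = [
            (a, d)
            for a in rule.advanced
            for d in rule.deferred
            if (d, a) not in pinned
        ]
        for a, d in wanted:
            if order.index(a) > order.index(d):
                order.remove(a)
                order.insert(order.index(d), a)
        pinned.update(wanted)
    return order


def _tempo(cfg: CurriculumConfig, chapter: int) -> float:
    span = cfg.tempo_end_bpm - cfg.tempo_start_bpm
    return round(cfg.tempo_start_bpm + span * (chapter - 1) / (N_CHAPTERS - 1))


def _density(cfg: CurriculumConfig, spec: TaskSpec, chapter: int) -> Density:
    if spec.response_type is ResponseType.LAST_BEAT:
        return Density.EVERY_BEAT  # one answer per measure, fixed pattern
    if chapter >= cfg.dense_from_chapter:
        return Density.EIGHTH_PATTERN
    return Density.EVERY_BEAT


def _duration(chapter: int, position: int) -> float:
    # songs run 1:20-1:30, with a rare 1:40 closer
    if chapter == N_CHAPTERS and position == TASKS_PER_CHAPTER:
        return 100.0
    return 80.0 if (chapter + position) % 2 == 0 else 90.0


def build_curriculum(
    diagnoses: Iterable[str] = (),
    version: Version | str = Version.FINAL,
    config: Optional[CurriculumConfig] = None,
) -> list[LevelPlan]:
    """The 72-level sequence (12 chapters x 6 levels) for one player.

    ``diagnoses`` is the set of declared diagnosis names (lower-case,
    e.g. ``{"dyspraxia"}``); only pathway triggers are consulted here.
    """
    cfg = config or CurriculumConfig()
    specs = list_tasks(version)
    by_name = {s.name: s for s in specs}
    diagnoses = frozenset(str(d).lower() for d in diagnoses)
    order = _intro_order(specs, diagnoses, cfg.pathways)

    # introduction phase: each task practiced practice_repeats times in a
    # row before the next appears, then one play of each task per chapter
    task_seq: list[str] = []
    for name in order:
        task_seq.extend([name] * cfg.practice_repeats)
    while len(task_seq) < N_CHAPTERS * TASKS_PER_CHAPTER:
        task_seq.extend(order)
    task_seq = task_seq[: N_CHAPTERS * TASKS_PER_CHAPTER]

    plans = []
    for idx, name in enumerate(task_seq):
        chapter = idx // TASKS_PER_CHAPTER + 1
        position = idx % TASKS_PER_CHAPTER + 1
        spec = by_name[name]
        duration = _duration(chapter, position)
        density = _density(cfg, spec, chapter)
        changes: tuple[tuple[float, Density], ...] = ()
        if (
            chapter >= cfg.change_from_chapter
            and spec.response_type is not ResponseType.LAST_BEAT
        ):
            changes = ((duration / 2, Density.HALF_TIME),)
        plans.append(
            LevelPlan(
                chapter=chapter,
                position=position,
                task=name,
                tempo_bpm=_tempo(cfg, chapter),
                density=density,
                duration_s=duration,
                change_points=changes,
            )
        )
    return plans


def daily_missions(
    history: Sequence[SessionResult],
    version: Version | str = Version.FINAL,
    seed: int = 0,
    config: Optional[CurriculumConfig] = None,
) -> list[LevelPlan]:
    """Four revision levels drawn from previously played tasks.

    Tasks are prioritised by ascending stars, then ascending mean score
    (most recent session per task), then registry order; with fewer than
    four distinct played tasks the list cycles.  Deterministic given the
    history (the seed is recorded for interface stability but the default
    tie-breaks are already deterministic).
    """
    if not history:
        raise ValueError("daily missions need a non-empty play history")
    cfg = config or CurriculumConfig()
    registry_order = [s.name for s in list_tasks(version)]
    latest: dict[str, SessionResult] = {}
    for s in history:
        latest[s.task] = s  # later entries win
    ranked = sorted(
        latest.values(),
        key=lambda s: (s.stars, s.mean_score, registry_order.index(s.task)
                       if s.task in registry_order else len(registry_order)),
    )
    plans = []
    for i in range(N_MISSIONS):
        s = ranked[i % len(ranked)]
        plans.append(
            LevelPlan(
                chapter=N_CHAPTERS,
                position=i + 1,
                task=s.task,
                tempo_bpm=_tempo(cfg, (N_CHAPTERS + 1) // 2),
                density=Density.EVERY_BEAT,
                duration_s=80.0,
            )
        )
    return plans
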