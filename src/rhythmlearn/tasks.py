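"""Task registry for the six rhythm tasks of each game version.

Every task asks the player to synchronise a motor response (tap, clap,
shake, punch, or sung note) with an expected beat time T.  The quality of
a response is judged against nested tolerance windows
``t_perfect < t_good < t_correct`` around T; an input inside
``[T - t_correct, T + t_correct]`` counts as acceptable.  Sing Lab is the
exception: a sung note is credited from an onset-tolerance rule plus a
minimum sung fraction of the note duration, with no perfect/good/correct
triple.

The registry holds the two published parameter sets: the second ("v2")
version and the final version, which renames Follow Me to Clap Hero and
changes several interaction modes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Version",
    "ResponseType",
    "Interaction",
    "Capture",
    "SongSource",
    "ToleranceProfile",
    "TaskSpec",
    "get_task_spec",
    "list_tasks",
    "registry_to_config",
    "registry_from_config",
]


class Version(str, enum.Enum):
    V2 = "v2"
    FINAL = "final"


class ResponseType(str, enum.Enum):
    CONTINUOUS_TAPPING = "continuous_tapping"
    LAST_BEAT = "last_beat"
    CALL_AND_RESPONSE = "call_and_response"


class Interaction(str, enum.Enum):
    TAPPING = "tapping"
    CLAPPING = "clapping"
    SHAKING = "shaking"
    SINGING = "singing"
    PUNCHING = "punching"
    BILATERAL_TAPPING = "bilateral_tapping"


class Capture(str, enum.Enum):
    CONTACT_PRESSURE = "contact_pressure"
    MICROPHONE = "microphone"
    ACCELEROMETER = "accelerometer"
    WEBCAM = "webcam"
    TOUCH = "touch"


class SongSource(str, enum.Enum):
    COMMERCIAL = "commercial"
    BUILT_IN_HOUSE = "built_in_house"
    # the v2 Sing Lab row lists both sources; recorded verbatim rather
    # than harmonised with the final version's "customized"
    COMMERCIAL_AND_BUILT_IN_HOUSE = "commercial_and_built_in_house"
    CUSTOMIZED = "customized"


@dataclass(frozen=True)
class ToleranceProfile:
    """Nested timing windows for one task, in seconds.

    For every task except Sing Lab the three thresholds satisfy
    ``0 < t_perfect < t_good < t_correct``.  Sing Lab instead stores the
    onset tolerance (0.15 s, capped at a fraction of the note duration)
    and the minimum fraction of the note that must be sung.
    """

    t_perfect: Optional[float] = None
    t_good: Optional[float] = None
    t_correct: Optional[float] = None
    singlab_onset_tolerance: Optional[float] = None
    singlab_onset_cap_fraction: Optional[float] = None
    singlab_min_sung_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        triple = (self.t_perfect, self.t_good, self.t_correct)
        sing = (
            self.singlab_onset_tolerance,
            self.singlab_onset_cap_fraction,
            self.singlab_min_sung_fraction,
        )
        if all(v is not None for v in triple):
            if not (0 < self.t_perfect < self.t_good < self.t_correct):
                raise ValueError(
                    "tolerance thresholds must satisfy "
                    "0 < t_perfect < t_good < t_correct, got "
                    f"{triple}"
                )
            if any(v is not None for v in sing):
                raise ValueError(
                    "Sing-Lab fields are exclusive with the "
                    "perfect/good/correct triple"
                )
        elif all(v is not None for v in sing):
            if self.singlab_onset_tolerance <= 0:
                raise ValueError("singlab_onset_tolerance must be > 0")
            for frac in sing[1:]:
                if not (0 < frac <= 1):
                    raise ValueError(
                        "Sing-Lab fractions must lie in (0, 1], got "
                        f"{frac}"
                    )
        else:
            raise ValueError(
                "a ToleranceProfile needs either the full "
                "t_perfect/t_good/t_correct triple or the full set of "
                "Sing-Lab fields"
            )

    @property
    def is_singlab(self) -> bool:
        return self.singlab_onset_tolerance is not None

    def onset_window(self, note_duration: float) -> float:
        """Sing-Lab onset window: the 0.15 s tolerance capped at 30% of
        the note duration."""
        if not self.is_singlab:
            raise ValueError("onset_window applies to Sing-Lab profiles only")
        return min(
            self.singlab_onset_tolerance,
            self.singlab_onset_cap_fraction * note_duration,
        )


@dataclass(frozen=True)
class TaskSpec:
    name: str
    version: Version
    response_type: ResponseType
    interaction: Interaction
    capture: Capture
    song_source: SongSource
    tolerance: ToleranceProfile

    @property
    def threshold(self) -> float:
        """The per-input scoring threshold: the acceptability bound
        t_correct."""
        if self.tolerance.is_singlab:
            raise ValueError(
                "Sing Lab is scored by the credited/uncredited rule and "
                "has no scoring threshold"
            )
        return self.tolerance.t_correct


def _triple(tp: float, tg: float, tc: float) -> ToleranceProfile:
    return ToleranceProfile(t_perfect=tp, t_good=tg, t_correct=tc)


_SINGLAB_PROFILE = ToleranceProfile(
    singlab_onset_tolerance=0.15,
    singlab_onset_cap_fraction=0.30,
    singlab_min_sung_fraction=0.60,
)

# Second version of the game, in table order.
_V2: tuple[TaskSpec, ...] = (
    TaskSpec("Follow Me", Version.V2, ResponseType.CONTINUOUS_TAPPING,
             Interaction.TAPPING, Capture.CONTACT_PRESSURE,
             SongSource.COMMERCIAL, _triple(0.1, 0.15, 0.25)),
    TaskSpec("Clap Trap", Version.V2, ResponseType.LAST_BEAT,
             Interaction.CLAPPING, Capture.MICROPHONE,
             SongSource.COMMERCIAL, _triple(0.1, 0.15, 0.25)),
    TaskSpec("River Splash", Version.V2, ResponseType.LAST_BEAT,
             Interaction.SHAKING, Capture.ACCELEROMETER,
             SongSource.COMMERCIAL, _triple(0.1, 0.15, 0.25)),
    TaskSpec("Sing Lab", Version.V2, ResponseType.CALL_AND_RESPONSE,
             Interaction.SINGING, Capture.MICROPHONE,
             SongSource.COMMERCIAL_AND_BUILT_IN_HOUSE, _SINGLAB_PROFILE),
    TaskSpec("Fruity Jump", Version.V2, ResponseType.CALL_AND_RESPONSE,
             Interaction.TAPPING, Capture.CONTACT_PRESSURE,
             SongSource.BUILT_IN_HOUSE, _triple(0.2, 0.25, 0.3)),
    TaskSpec("Karate Fruits", Version.V2, ResponseType.LAST_BEAT,
             Interaction.PUNCHING, Capture.WEBCAM,
             SongSource.BUILT_IN_HOUSE, _triple(0.08, 0.14, 0.3)),
)

# Final version: Follow Me became Clap Hero (call and response, clapping),
# Clap Trap moved to bilateral screen taps, Fruity Jump to shaking.
_FINAL: tuple[TaskSpec, ...] = (
    TaskSpec("Clap Hero", Version.FINAL, ResponseType.CALL_AND_RESPONSE,
             Interaction.CLAPPING, Capture.MICROPHONE,
             SongSource.CUSTOMIZED, _triple(0.1, 0.15, 0.25)),
    TaskSpec("Clap Trap", Version.FINAL, ResponseType.LAST_BEAT,
             Interaction.BILATERAL_TAPPING, Capture.TOUCH,
             SongSource.COMMERCIAL, _triple(0.1, 0.15, 0.25)),
    TaskSpec("River Splash", Version.FINAL, ResponseType.LAST_BEAT,
             Interaction.SHAKING, Capture.ACCELEROMETER,
             SongSource.COMMERCIAL, _triple(0.1, 0.15, 0.25)),
    TaskSpec("Sing Lab", Version.FINAL, ResponseType.CALL_AND_RESPONSE,
             Interaction.SINGING, Capture.MICROPHONE,
             SongSource.CUSTOMIZED, _SINGLAB_PROFILE),
    TaskSpec("Fruity Jump", Version.FINAL, ResponseType.CALL_AND_RESPONSE,
             Interaction.SHAKING, Capture.ACCELEROMETER,
             SongSource.CUSTOMIZED, _triple(0.2, 0.25, 0.3)),
    TaskSpec("Karate Fruits", Version.FINAL, ResponseType.LAST_BEAT,
             Interaction.PUNCHING, Capture.WEBCAM,
             SongSource.CUSTOMIZED, _triple(0.08, 0.14, 0.3)),
)

_REGISTRY: dict[Version, tuple[TaskSpec, ...]] = {
    Version.V2: _V2,
    Version.FINAL: _FINAL,
}


def _coerce_version(version: Version | str) -> Version:
    try:
        return Version(version)
    except ValueError:
        valid = ", ".join(v.value for v in Version)
        raise KeyError(
            f"unknown version {version!r}; valid versions: {valid}"
        ) from None


def list_tasks(version: Version | str) -> tuple[TaskSpec, ...]:
    """All six tasks of one game version, in table order."""
    return _REGISTRY[_coerce_version(version)]


def get_task_spec(name: str, version: Version | str) -> TaskSpec:
    """Look up one task of one version; raises KeyError naming the valid
    choices when the task does not exist in that version."""
    version = _coerce_version(version)
    for spec in _REGISTRY[version]:
        if spec.name == name:
            return spec
    valid = ", ".join(s.name for s in _REGISTRY[version])
    raise KeyError(
        f"no task named {name!r} in version {version.value!r}; "
        f"valid tasks: {valid}"
    )


def _profile_to_dict(profile: ToleranceProfile) -> dict:
    return {
        k: v
        for k, v in {
            "t_perfect": profile.t_perfect,
            "t_good": profile.t_good,
            "t_correct": profile.t_correct,
            "singlab_onset_tolerance": profile.singlab_onset_tolerance,
            "singlab_onset_cap_fraction": profile.singlab_onset_cap_fraction,
            "singlab_min_sung_fraction": profile.singlab_min_sung_fraction,
        }.items()
        if v is not None
    }


def registry_to_config(version: Version | str) -> dict:
    """Serialise one version's registry as a plain mapping suitable for a
    YAML/JSON config document."""
    version = _coerce_version(version)
    return {
        "version": version.value,
        "tasks": [
            {
                "name": s.name,
                "response_type": s.response_type.value,
                "interaction": s.interaction.value,
                "capture": s.capture.value,
                "song_source": s.song_source.value,
                "tolerance": _profile_to_dict(s.tolerance),
            }
            for s in _REGISTRY[version]
        ],
    }


def registry_from_config(doc: dict) -> tuple[TaskSpec, ...]:
    """Rebuild TaskSpecs from a config document (inverse of
    :func:`registry_to_config`)."""
    version = _coerce_version(doc["version"])
    return tuple(
        TaskSpec(
            name=t["name"],
            version=version,
            response_type=ResponseType(t["response_type"]),
            interaction=Interaction(t["interaction"]),
            capture=Capture(t["capture"]),
            song_source=SongSource(t["song_source"]),
            tolerance=ToleranceProfile(**t["tolerance"]),
        )
        for t in doc["tasks"]
    )
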