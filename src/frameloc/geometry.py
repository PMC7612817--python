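"""Angle conventions, frame transforms and the experimental condition grid.

A circular arena is surrounded by twelve speaker/port slots at 30 degree
intervals.  A rotatable central platform dissociates two descriptions of any
speaker position:

* ``speaker_world`` -- angle of the speaker in the fixed arena frame,
* ``speaker_head`` -- angle of the speaker relative to the subject's head.

All angles are in degrees, wrapped to the half-open interval (-180, +180].
The head frame puts the front of the head at +180 and directly behind at 0,
with -90 on the left of the midline and +90 on the right.  The world frame is
anchored so that the head of a subject sitting at the training platform
orientation points at +180 (i.e. "North" = +180, "South" = 0, the East
response port at +90 and the West port at -90).  The platform angle is the
rotation applied to the platform relative to that training orientation, so

    speaker_head = wrap(speaker_world - platform_angle)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "GRID_STEP_DEG",
    "N_SLOTS",
    "ALL_SLOTS",
    "TaskCondition",
    "PortLayout",
    "TaskVariant",
    "TASK_VARIANTS",
    "wrap_angle",
    "circular_difference",
    "head_from_world",
    "world_from_head",
    "condition_grid",
    "correct_response",
    "load_task_variant",
]

GRID_STEP_DEG = 30.0
N_SLOTS = 12

#: The twelve nominal peripheral slots, in (-180, 180].
ALL_SLOTS: tuple[float, ...] = tuple(float(a) for a in range(-150, 181, 30))

PROBE = "probe"


def wrap_angle(theta):
    """Wrap an angle (degrees) into the half-open interval (-180, +180].

    Accepts scalars or array-likes; returns a float for scalar input.
    Raises ``ValueError`` for non-finite input.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle must be finite")
    wrapped = np.mod(arr, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # np.mod maps exact multiples of 360 to 0.0; nothing else to fix.
    if np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


def circular_difference(a, b):
    """Signed circular difference a - b, wrapped to (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def head_from_world(speaker_world, platform_angle):
    """Speaker angle relative to the head given its world angle.

    ``head = wrap(world - platform)``; inverse of :func:`world_from_head`.
    """
    return wrap_angle(np.asarray(speaker_world, dtype=float) - np.asarray(platform_angle, dtype=float))


def world_from_head(speaker_head, platform_angle):
    """Speaker angle in the arena frame given its head-centered angle."""
    return wrap_angle(np.asarray(speaker_head, dtype=float) + np.asarray(platform_angle, dtype=float))


@dataclass(frozen=True)
class TaskCondition:
    """One cell of the 12 x 12 (platform angle x speaker) condition grid."""

    platform_angle: float
    speaker_world: float
    speaker_head: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "platform_angle", wrap_angle(self.platform_angle))
        object.__setattr__(self, "speaker_world", wrap_angle(self.speaker_world))
        derived = head_from_world(self.speaker_world, self.platform_angle)
        if self.speaker_head is not None:
            if abs(circular_difference(self.speaker_head, derived)) > 1e-9:
                raise ValueError(
                    f"speaker_head={self.speaker_head} inconsistent with "
                    f"wrap(world - platform)={derived}"
                )
        object.__setattr__(self, "speaker_head", derived)


@dataclass(frozen=True)
class PortLayout:
    """Active response ports for a task variant, in the world frame.

    ``primary``/``secondary`` give the world angles of the two active ports;
    the primary port is the one whose response probability all models report
    (West in the arena tasks).  The remaining ten slots are null ports.  The
    physical arena lacks the rear port at 0 degrees, but that slot is always
    null so the nominal twelve-slot layout has no behavioral consequence.
    """

    primary: float
    secondary: float
    primary_label: str = "West"
    secondary_label: str = "East"

    def __post_init__(self):
        object.__setattr__(self, "primary", wrap_angle(self.primary))
        object.__setattr__(self, "secondary", wrap_angle(self.secondary))
        if self.primary == self.secondary:
            raise ValueError("active ports must be distinct")

    @property
    def active_ports(self) -> frozenset[float]:
        return frozenset((self.primary, self.secondary))

    @property
    def null_ports(self) -> frozenset[float]:
        return frozenset(ALL_SLOTS) - self.active_ports


@dataclass(frozen=True)
class TaskVariant:
    """A task definition: which frame is rewarded and how responses map.

    ``trained`` maps trained speaker angles (in ``frame`` coordinates) to the
    rewarded response label.  Every other speaker position is a probe, on
    which either response is rewarded.
    """

    name: str
    frame: str  # "world" or "head"
    trained: dict[float, str]
    response_space: str  # "EastWest" or "LeftRight"
    primary_response: str  # "West" or "Left"
    secondary_response: str
    layout: PortLayout

    def __post_init__(self):
        if self.frame not in ("world", "head"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if len(self.trained) != 2:
            raise ValueError("a two-choice task needs exactly two trained angles")

    @property
    def trained_angles(self) -> tuple[float, ...]:
        return tuple(sorted(self.trained))

    @property
    def probe_angles(self) -> tuple[float, ...]:
        return tuple(a for a in ALL_SLOTS if a not in self.trained)

    @property
    def responses(self) -> tuple[str, str]:
        return (self.primary_response, self.secondary_response)


def _east_west_layout() -> PortLayout:
    return PortLayout(primary=-90.0, secondary=90.0, primary_label="West", secondary_label="East")


def _left_right_layout() -> PortLayout:
    # Platform response ports sit 60 degrees left/right of the central spout.
    # Angles here are head-frame and only used for bookkeeping; compensation
    # strategies apply to the arena (EastWest) tasks only.
    return PortLayout(primary=-60.0, secondary=60.0, primary_label="Left", secondary_label="Right")


#: The four task variants used in the study.
TASK_VARIANTS: dict[str, TaskVariant] = {
    # North (+180) -> East, South (0) -> West, fixed in the arena.
    "world_NS": TaskVariant(
        name="world_NS",
        frame="world",
        trained={180.0: "East", 0.0: "West"},
        response_space="EastWest",
        primary_response="West",
        secondary_response="East",
        layout=_east_west_layout(),
    ),
    # North-West (-150) -> West, South-East (+30) -> East.
    "world_NW_SE": TaskVariant(
        name="world_NW_SE",
        frame="world",
        trained={-150.0: "West", 30.0: "East"},
        response_space="EastWest",
        primary_response="West",
        secondary_response="East",
        layout=_east_west_layout(),
    ),
    # Front of head (+180) -> Right port, behind (0) -> Left port.
    "head_FB": TaskVariant(
        name="head_FB",
        frame="head",
        trained={180.0: "Right", 0.0: "Left"},
        response_space="LeftRight",
        primary_response="Left",
        secondary_response="Right",
        layout=_left_right_layout(),
    ),
    # Left of head (-90) -> Left port, right (+90) -> Right port.
    "head_LR": TaskVariant(
        name="head_LR",
        frame="head",
        trained={-90.0: "Left", 90.0: "Right"},
        response_space="LeftRight",
        primary_response="Left",
        secondary_response="Right",
        layout=_left_right_layout(),
    ),
}


def condition_grid(platform_angles: Iterable[float] | None = None,
                   speaker_angles: Iterable[float] | None = None) -> list[TaskCondition]:
    """All combinations of platform angle and world speaker angle.

    With defaults this is the full 12 x 12 = 144 condition grid; every
    (speaker_head, speaker_world) pair appears exactly once because the
    platform angle is determined by their difference.
    """
    platforms = ALL_SLOTS if platform_angles is None else tuple(wrap_angle(a) for a in platform_angles)
    speakers = ALL_SLOTS if speaker_angles is None else tuple(wrap_angle(a) for a in speaker_angles)
    return [TaskCondition(platform_angle=p, speaker_world=s) for p in platforms for s in speakers]


def correct_response(condition: TaskCondition, task: str | TaskVariant) -> str:
    """Rewarded response label for a condition, or ``"probe"``.

    World tasks reward a fixed label per trained ``speaker_world``; head tasks
    per trained ``speaker_head``.  Probe conditions reward either response.
    """
    variant = task if isinstance(task, TaskVariant) else _lookup_variant(task)
    angle = condition.speaker_world if variant.frame == "world" else condition.speaker_head
    for trained_angle, label in variant.trained.items():
        if abs(circular_difference(angle, trained_angle)) < 1e-9:
            return label
    return PROBE


def _lookup_variant(task: str) -> TaskVariant:
    try:
        return TASK_VARIANTS[task]
    except KeyError:
        raise ValueError(
            f"unknown task variant {task!r}; expected one of {sorted(TASK_VARIANTS)}"
        ) from None


def load_task_variant(source) -> TaskVariant:
    """Load a task variant from a name, a mapping, or a YAML/JSON file path.

    The mapping form mirrors :class:`TaskVariant`::

        name: my_task
        frame: world
        trained: {0: West, 180: East}
        response_space: EastWest
        primary_response: West
        secondary_response: East
    """
    if isinstance(source, TaskVariant):
        return source
    if isinstance(source, str) and source in TASK_VARIANTS:
        return TASK_VARIANTS[source]
    if isinstance(source, str):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise ValueError(f"cannot interpret task variant from {type(source)!r}")
    layout = (_east_west_layout() if source["response_space"] == "EastWest"
              else _left_right_layout())
    return TaskVariant(
        name=source["name"],
        frame=source["frame"],
        trained={wrap_angle(float(k)): v for k, v in source["trained"].items()},
        response_space=source["response_space"],
        primary_response=source["primary_response"],
        secondary_response=source["secondary_response"],
        layout=layout,
    )


def slot_index(angle) -> np.ndarray:
    """Index of a grid angle within :data:`ALL_SLOTS` (vectorized).

    Raises ``ValueError`` if any angle is not on the 30-degree grid.
    """
    arr = np.atleast_1d(wrap_angle(angle))
    idx = np.round((arr + 150.0) / GRID_STEP_DEG).astype(int)
    if np.any(np.abs(arr - (idx * GRID_STEP_DEG - 150.0)) > 1e-6) or np.any((idx < 0) | (idx >= N_SLOTS)):
        raise ValueError("angle is not on the 30-degree slot grid")
    return idx


def is_on_slot(angle, tol: float = 1e-6) -> bool:
    """Whether an angle lies on one of the twelve 30-degree slots."""
    a = wrap_angle(angle)
    return bool(math.isclose((a + 150.0) % GRID_STEP_DEG, 0.0, abs_tol=tol)
                or math.isclose((a + 150.0) % GRID_STEP_DEG, GRID_STEP_DEG, abs_tol=tol))
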