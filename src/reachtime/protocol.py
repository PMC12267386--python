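"""Randomized trial schedules for the computerized and 3D reaction-time tests.

Two testing modalities share one protocol family:

* phase 1 (``com_srt``/``com_crt`` on the computer, ``press_srt``/``press_crt``
  with the hand controller): 260-ms square/cube stimuli, 1000–2000 ms
  inter-stimulus intervals, four colors; the simple phase treats every color
  as go, the choice phase restricts go to green and yellow.
* phase 2 (reach-to-touch): 2000-ms cubes, 3000–4500 ms intervals, three
  simple tasks — Center (always the central location), Spatial (random
  locations, two per location), Dynamic (cubes in motion at staged speeds
  0.6/0.75/0.9 m/s, three origins per location).

Color proportions are enforced exactly by shuffling counterbalanced decks
with a seeded generator, so identical (config, seed) pairs reproduce
identical schedules.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .geometry import MotionSpec

COLORS: tuple[str, ...] = ("yellow", "green", "blue", "red")
CRT_GO_COLORS = frozenset({"green", "yellow"})
CRT_NOGO_COLORS = frozenset({"blue", "red"})

TaskName = Literal[
    "com_srt", "com_crt", "press_srt", "press_crt", "center", "spatial", "dynamic"
]
PRESS_TASKS = frozenset({"com_srt", "com_crt", "press_srt", "press_crt"})
REACH_TASKS = frozenset({"center", "spatial", "dynamic"})
CRT_TASKS = frozenset({"com_crt", "press_crt"})
VR_TASKS = frozenset({"press_srt", "press_crt", "center", "spatial", "dynamic"})
CENTER_LOCATION = 5


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class TrialSpec:
    """One planned stimulus presentation."""

    task: str
    index: int  # ordinal within the schedule, training included
    is_training: bool
    color: str
    is_go: bool
    display_ms: float
    isi_ms: float  # interval preceding this stimulus
    location_index: Optional[int] = None
    motion: Optional[MotionSpec] = None

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ProtocolError(f"unknown color {self.color!r}")
        if self.display_ms <= 0:
            raise ProtocolError("display_ms must be positive")
        if (self.motion is not None) != (self.task == "dynamic"):
            raise ProtocolError("motion present iff task is dynamic")


@dataclass(frozen=True)
class TaskSchedule:
    task: str
    trials: tuple[TrialSpec, ...]
    rng_seed: int

    @property
    def test_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for t in self.trials if not t.is_training)

    def __post_init__(self) -> None:
        flags = [t.is_training for t in self.trials]
        if any(a and not b for a, b in zip(flags[1:], flags[:-1])):
            raise ProtocolError("training trials must precede test trials")


@dataclass(frozen=True)
class ProtocolConfig:
    """Counts, durations, intervals, and speeds for every task.

    Defaults reproduce the published protocol.  ``phase1_count_mode``
    resolves the ambiguity of "20 trials per stimulus type": ``"category"``
    reads the type as go/no-go category (simple phase = 20 trials, 5 per
    color; choice phase = 40, 10 per color); ``"color"`` reads it per color
    (80 trials each phase).
    """

    phase1_trials_per_type: int = 20
    phase1_count_mode: Literal["category", "color"] = "category"
    phase1_training: int = 4
    phase1_display_ms: float = 260.0
    phase1_isi_ms: tuple[float, float] = (1000.0, 2000.0)
    reach_training: int = 2
    reach_display_ms: float = 2000.0
    reach_isi_ms: tuple[float, float] = (3000.0, 4500.0)
    center_test_trials: int = 20
    spatial_trials_per_location: int = 2
    dynamic_trials_per_location: int = 3
    dynamic_speeds: tuple[float, ...] = (0.6, 0.75, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.phase1_isi_ms, self.reach_isi_ms):
            if not lo < hi:
                raise ProtocolError("ISI range must have min < max")
        if any(s <= 0 for s in self.dynamic_speeds):
            raise ProtocolError("speeds must be positive")
        if self.phase1_trials_per_type <= 0 or self.center_test_trials <= 0:
            raise ProtocolError("trial counts must be positive")


def task_seed(base_seed: int, task: str) -> int:
    """Stable per-task stream seed derived from the protocol seed."""
    return (base_seed * 1000003 + zlib.crc32(task.encode())) % (2**31 - 1)


def _isi(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(bounds[0], bounds[1]))


def _color_deck(rng: np.random.Generator, total: int, colors: Sequence[str]) -> list[str]:
    """Near-counterbalanced color deck of length ``total``, shuffled."""
    reps = -(-total // len(colors))
    deck = list(colors) * reps
    rng.shuffle(deck)
    return deck[:total]


def _phase1_test_colors(
    cfg: ProtocolConfig, rng: np.random.Generator, phase: Literal["srt", "crt"]
) -> list[str]:
    n = cfg.phase1_trials_per_type
    if cfg.phase1_count_mode == "category":
        if phase == "srt":
            if n % 4:
                raise ProtocolError(
                    "category-mode simple-phase count must divide by 4 colors"
                )
            deck = list(COLORS) * (n // 4)
        else:
            if n % 2:
                raise ProtocolError(
                    "category-mode choice-phase count must divide by 2 colors per category"
                )
            deck = (["green", "yellow"] + ["blue", "red"]) * (n // 2)
    else:  # per-color counts
        deck = list(COLORS) * n
    rng.shuffle(deck)
    return deck


def _build_phase1(
    cfg: ProtocolConfig, mode: Literal["computer", "press"], phase: Literal["srt", "crt"]
) -> TaskSchedule:
    task = f"{'com' if mode == 'computer' else 'press'}_{phase}"
    seed = task_seed(cfg.seed, task)
    rng = np.random.default_rng(seed)

    test_colors = _phase1_test_colors(cfg, rng, phase)
    train_colors = _color_deck(rng, cfg.phase1_training, COLORS)
    trials = []
    for i, (color, training) in enumerate(
        [(c, True) for c in train_colors] + [(c, False) for c in test_colors]
    ):
        is_go = True if phase == "srt" else color in CRT_GO_COLORS
        trials.append(
            TrialSpec(
                task=task,
                index=i,
                is_training=training,
                color=color,
                is_go=is_go,
                display_ms=cfg.phase1_display_ms,
                isi_ms=_isi(rng, cfg.phase1_isi_ms),
                location_index=CENTER_LOCATION if mode == "press" else None,
            )
        )
    return TaskSchedule(task=task, trials=tuple(trials), rng_seed=seed)


def build_srt_phase(cfg: ProtocolConfig, mode: Literal["computer", "press"]) -> TaskSchedule:
    """Simple phase: every color is a go stimulus."""
    return _build_phase1(cfg, mode, "srt")


def build_crt_phase(cfg: ProtocolConfig, mode: Literal["computer", "press"]) -> TaskSchedule:
    """Choice phase: go on green/yellow, withhold on blue/red."""
    return _build_phase1(cfg, mode, "crt")


def build_center_task(cfg: ProtocolConfig) -> TaskSchedule:
    """Reach task with every cube over the fixation point (location 5)."""
    seed = task_seed(cfg.seed, "center")
    rng = np.random.default_rng(seed)
    test_colors = _color_deck(rng, cfg.center_test_trials, COLORS)
    train_colors = _color_deck(rng, cfg.reach_training, COLORS)
    trials = [
        TrialSpec(
            task="center",
            index=i,
            is_training=i < len(train_colors),
            color=c,
            is_go=True,
            display_ms=cfg.reach_display_ms,
            isi_ms=_isi(rng, cfg.reach_isi_ms),
            location_index=CENTER_LOCATION,
        )
        for i, c in enumerate(train_colors + test_colors)
    ]
    return TaskSchedule(task="center", trials=tuple(trials), rng_seed=seed)


def build_spatial_task(cfg: ProtocolConfig) -> TaskSchedule:
    """Reach task over all nine locations.

    Each location receives ``spatial_trials_per_location`` cubes, half in a
    formerly-go color (yellow/green) and half in a formerly-no-go color
    (blue/red); every cube is responded to (the task is simple).
    """
    seed = task_seed(cfg.seed, "spatial")
    rng = np.random.default_rng(seed)
    per_loc = cfg.spatial_trials_per_location
    if per_loc % 2:
        raise ProtocolError("spatial trials per location must be even (go/no-go color split)")
    deck: list[tuple[int, str]] = []
    for loc in range(1, 10):
        for _ in range(per_loc // 2):
            deck.append((loc, str(rng.choice(["yellow", "green"]))))
            deck.append((loc, str(rng.choice(["blue", "red"]))))
    rng.shuffle(deck)
    train = [
        (int(rng.integers(1, 10)), str(rng.choice(COLORS)))
        for _ in range(cfg.reach_training)
    ]
    trials = [
        TrialSpec(
            task="spatial",
            index=i,
            is_training=i < len(train),
            color=color,
            is_go=True,
            display_ms=cfg.reach_display_ms,
            isi_ms=_isi(rng, cfg.reach_isi_ms),
            location_index=loc,
        )
        for i, (loc, color) in enumerate(train + deck)
    ]
    return TaskSchedule(task="spatial", trials=tuple(trials), rng_seed=seed)


def build_dynamic_task(cfg: ProtocolConfig) -> TaskSchedule:
    """Reach task with moving cubes.

    Origins are randomized subject to ``dynamic_trials_per_location`` per
    location; speed staging is by test-trial position (first nine at
    ``speeds[0]``, next nine at ``speeds[1]``, ...) regardless of seed; the
    motion target is drawn uniformly from the other eight locations.
    """
    seed = task_seed(cfg.seed, "dynamic")
    rng = np.random.default_rng(seed)
    origins = [loc for loc in range(1, 10) for _ in range(cfg.dynamic_trials_per_location)]
    rng.shuffle(origins)
    n_test = len(origins)
    colors = _color_deck(rng, n_test, COLORS)
    per_stage = 9  # the staging the protocol prescribes: blocks of nine repetitions
    trials: list[TrialSpec] = []
    for i in range(cfg.reach_training):
        origin = int(rng.integers(1, 10))
        trials.append(
            _dynamic_trial(cfg, rng, i, True, str(rng.choice(COLORS)), origin,
                           cfg.dynamic_speeds[0])
        )
    for j, (origin, color) in enumerate(zip(origins, colors)):
        stage = min(j // per_stage, len(cfg.dynamic_speeds) - 1)
        trials.append(
            _dynamic_trial(cfg, rng, cfg.reach_training + j, False, color, origin,
                           cfg.dynamic_speeds[stage])
        )
    return TaskSchedule(task="dynamic", trials=tuple(trials), rng_seed=seed)


def _dynamic_trial(
    cfg: ProtocolConfig,
    rng: np.random.Generator,
    index: int,
    training: bool,
    color: str,
    origin: int,
    speed: float,
) -> TrialSpec:
    others = [loc for loc in range(1, 10) if loc != origin]
    target = int(rng.choice(others))
    return TrialSpec(
        task="dynamic",
        index=index,
        is_training=training,
        color=color,
        is_go=True,
        display_ms=cfg.reach_display_ms,
        isi_ms=_isi(rng, cfg.reach_isi_ms),
        location_index=origin,
        motion=MotionSpec(origin_index=origin, target_index=target, speed=speed),
    )


def build_com_schedules(cfg: ProtocolConfig) -> list[TaskSchedule]:
    """The computerized test: simple then choice phase."""
    return [build_srt_phase(cfg, "computer"), build_crt_phase(cfg, "computer")]


def build_vr_schedules(
    cfg: ProtocolConfig, tasks: Optional[Sequence[str]] = None
) -> list[TaskSchedule]:
    """The headset test: press phases then the three reach tasks, in test order."""
    builders = {
        "press_srt": lambda: build_srt_phase(cfg, "press"),
        "press_crt": lambda: build_crt_phase(cfg, "press"),
        "center": lambda: build_center_task(cfg),
        "spatial": lambda: build_spatial_task(cfg),
        "dynamic": lambda: build_dynamic_task(cfg),
    }
    order = ["press_srt", "press_crt", "center", "spatial", "dynamic"]
    wanted = order if tasks is None else [t for t in order if t in set(tasks)]
    return [builders[t]() for t in wanted]
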