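"""Synthetic participants: time-stamped event logs with known ground truth.

Decision latencies follow an ex-Gaussian (Gaussian + exponential) model —
the standard parametric family for response times — with additive offsets
for a shared per-participant speed, a systematic headset-vs-computer bias,
and a choice/inhibition cost in the go/no-go phase.  Reaches follow a
minimum-jerk profile sampled at the controller rate; moving cubes are
intercepted by linear prediction of the arrival position, corrupted by
arrival-time misjudgment and isotropic endpoint noise, so touch failures
emerge from the noise model rather than a fixed rate.

Everything here is a stand-in with recorded ground truth for validating the
scoring and agreement pipeline; it makes no claim about real cohorts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

import numpy as np

from .geometry import (
    BASE_RADIUS_M,
    CUBE_EDGE_M,
    Calibration,
    CubeStimulus,
    LocationGrid,
    Vec3,
    build_grid,
    calibrate,
    cube_contains,
    cube_frame,
    cube_position_at,
)
from .protocol import (
    CRT_TASKS,
    PRESS_TASKS,
    VR_TASKS,
    ProtocolConfig,
    TaskSchedule,
    TrialSpec,
    build_com_schedules,
    build_vr_schedules,
)

#: task → latency family (press-button vs the three reach contexts)
FAMILY_BY_TASK: Mapping[str, str] = {
    "com_srt": "press",
    "com_crt": "press",
    "press_srt": "press",
    "press_crt": "press",
    "center": "center",
    "spatial": "spatial",
    "dynamic": "dynamic",
}


class SimulationError(ValueError):
    """Inconsistent simulation inputs (schedule/calibration mismatch, ...)."""


@dataclass(frozen=True)
class ExGauss:
    """Ex-Gaussian latency component: Normal(mu, sigma) + Exp(tau), in ms."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.tau < 0:
            raise SimulationError("sigma and tau must be non-negative")


def _default_exgauss() -> dict[str, ExGauss]:
    # Central values chosen so that simulated group means sit near the
    # published cohort (computer simple ≈ 240 ms mean, headset center ≈ 352,
    # spatial ≈ 394, dynamic ≈ 351; mean of an ex-Gaussian is mu + tau).
    return {
        "press": ExGauss(mu=205.0, sigma=16.0, tau=35.0),
        "center": ExGauss(mu=280.0, sigma=30.0, tau=40.0),
        "spatial": ExGauss(mu=322.0, sigma=30.0, tau=40.0),
        "dynamic": ExGauss(mu=280.0, sigma=28.0, tau=40.0),
    }


def _default_mt_median() -> dict[str, float]:
    # Reach-duration medians (ms) near the published task medians.
    return {"center": 187.0, "spatial": 191.0, "dynamic": 147.0}


@dataclass(frozen=True)
class ParticipantParams:
    """Latent structure of one synthetic participant.

    ``latent_speed`` shifts every latency (shared across both tests, the
    source of cross-test correlation); ``vr_bias`` is added to all headset
    latencies; ``choice_cost`` to the go/no-go phase.  ``mt_*`` control
    lognormal reach durations; error processes are explicit probabilities
    except dynamic-task touch failures, which also arise from
    ``timing_jitter_ms`` (arrival-time misjudgment scaled by cube speed)
    and ``aim_noise_m``.
    """

    latent_speed: float = 0.0
    exgauss: Mapping[str, ExGauss] = field(default_factory=_default_exgauss)
    vr_bias: float = 32.0
    choice_cost: float = 120.0
    mt_median_ms: Mapping[str, float] = field(default_factory=_default_mt_median)
    mt_sigma_log: float = 0.25
    mt_scale: float = 1.0
    lapse_p: float = 0.005
    anticipation_p: float = 0.005
    false_alarm_p: float = 0.08
    miss_touch_p: float = 0.01
    aim_noise_m: float = 0.012
    aim_noise_scale: Mapping[str, float] = field(
        default_factory=lambda: {"center": 1.0, "spatial": 2.0, "dynamic": 1.0}
    )
    retry_mt_factor: float = 3.2
    timing_jitter_ms: float = 40.0
    base_jitter_m: float = 0.012
    sample_rate: float = 72.0

    def __post_init__(self) -> None:
        for p in (self.lapse_p, self.anticipation_p, self.false_alarm_p, self.miss_touch_p):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0, 1]")
        if self.sample_rate <= 0:
            raise SimulationError("sample_rate must be positive")
        if self.base_jitter_m > BASE_RADIUS_M:
            raise SimulationError("base jitter must stay within the base sphere")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "latent_speed": self.latent_speed,
            "exgauss": {k: [v.mu, v.sigma, v.tau] for k, v in sorted(self.exgauss.items())},
            "vr_bias": self.vr_bias,
            "choice_cost": self.choice_cost,
            "mt_median_ms": dict(sorted(self.mt_median_ms.items())),
            "mt_sigma_log": self.mt_sigma_log,
            "mt_scale": self.mt_scale,
            "lapse_p": self.lapse_p,
            "anticipation_p": self.anticipation_p,
            "false_alarm_p": self.false_alarm_p,
            "miss_touch_p": self.miss_touch_p,
            "aim_noise_m": self.aim_noise_m,
            "aim_noise_scale": dict(sorted(self.aim_noise_scale.items())),
            "retry_mt_factor": self.retry_mt_factor,
            "timing_jitter_ms": self.timing_jitter_ms,
            "base_jitter_m": self.base_jitter_m,
            "sample_rate": self.sample_rate,
        }
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


EVENT_KINDS = (
    "stimulus_onset",
    "stimulus_offset",
    "button_down",
    "controller_sample",
    "base_exit",
    "touch",
)


@dataclass(frozen=True)
class Event:
    """One time-stamped record in a session stream (t in ms from start)."""

    t: float
    kind: str
    trial_index: int
    payload: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SimulationError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class EventLog:
    """Header (who/how) plus the ordered event stream of one session."""

    participant: str
    calibration: Calibration
    grid: LocationGrid
    schedules: tuple[TaskSchedule, ...]
    seed: int
    params_hash: str
    events: tuple[Event, ...]

    def trial_specs(self) -> dict[int, TrialSpec]:
        """Global trial index → spec, ordering schedules as run."""
        out: dict[int, TrialSpec] = {}
        i = 0
        for sched in self.schedules:
            for spec in sched.trials:
                out[i] = spec
                i += 1
        return out


def sample_decision_time(
    params: ParticipantParams, task: str, is_go: bool, rng: np.random.Generator
) -> float:
    """One ex-Gaussian latency draw (ms) for the given task context.

    Non-positive draws are resampled; degenerate sigma=tau=0 returns the
    deterministic offset sum.
    """
    ex = params.exgauss[FAMILY_BY_TASK[task]]
    base = ex.mu + params.latent_speed
    if task in VR_TASKS:
        base += params.vr_bias
    if task in CRT_TASKS:
        base += params.choice_cost
    for _ in range(1000):
        draw = base
        if ex.sigma > 0:
            draw += rng.normal(0.0, ex.sigma)
        if ex.tau > 0:
            draw += rng.exponential(ex.tau)
        if draw > 0:
            return float(draw)
    raise SimulationError("latency resampling failed; offsets far below zero")


def _minimum_jerk(s: float) -> float:
    return s * s * s * (10.0 - 15.0 * s + 6.0 * s * s)


def simulate_reach(
    start: Vec3, target: Vec3, duration_ms: float, sample_rate: float
) -> list[tuple[float, Vec3]]:
    """Minimum-jerk path samples from start to target.

    Returns (t_ms, position) pairs at the controller rate, including the
    exact endpoint; boundary velocities are zero by construction.
    """
    if duration_ms <= 0:
        raise SimulationError("reach duration must be positive")
    step = 1000.0 / sample_rate
    times = [i * step for i in range(1, int(duration_ms / step) + 1) if i * step < duration_ms]
    times.append(duration_ms)
    out = []
    delta = target - start
    for t in times:
        s = _minimum_jerk(t / duration_ms)
        out.append((t, start + delta.scale(s)))
    return out


def _jitter_in_sphere(rng: np.random.Generator, radius: float) -> Vec3:
    if radius <= 0:
        return Vec3(0.0, 0.0, 0.0)
    while True:
        v = rng.uniform(-radius, radius, size=3)
        if float(np.dot(v, v)) <= radius * radius:
            return Vec3(float(v[0]), float(v[1]), float(v[2]))


def _onset_payload(spec: TrialSpec) -> dict[str, Any]:
    p: dict[str, Any] = {
        "task": spec.task,
        "is_training": spec.is_training,
        "color": spec.color,
        "is_go": spec.is_go,
        "display_ms": spec.display_ms,
    }
    if spec.location_index is not None:
        p["location_index"] = spec.location_index
    if spec.motion is not None:
        p["motion"] = {
            "origin_index": spec.motion.origin_index,
            "target_index": spec.motion.target_index,
            "speed": spec.motion.speed,
        }
    return p


def _cube_center_at(
    grid: LocationGrid, spec: TrialSpec, dt_ms: float
) -> Vec3:
    if spec.motion is not None:
        return cube_position_at(grid, spec.motion, max(dt_ms, 0.0) / 1000.0)
    return grid.location(spec.location_index)


def simulate_session(
    params: ParticipantParams,
    schedules: Sequence[TaskSchedule],
    cal: Calibration,
    grid: LocationGrid,
    seed: int,
    participant: str = "sim",
) -> EventLog:
    """Run one synthetic participant through the given schedules.

    Press tasks emit ``button_down`` responses; reach tasks emit a
    controller sample at onset (inside the base sphere), ``base_exit`` at
    the decision latency, minimum-jerk ``controller_sample`` positions, and
    ``touch`` when the aim point lands inside the cube before offset.
    """
    for sched in schedules:
        for spec in sched.trials:
            if spec.location_index is not None and not 1 <= spec.location_index <= 9:
                raise SimulationError("schedule references a location outside the grid")
    rng = np.random.default_rng(seed)
    events: list[tuple[float, int, Event]] = []
    seq = 0

    def emit(t: float, kind: str, trial: int, payload: Optional[dict[str, Any]] = None) -> None:
        nonlocal seq
        events.append((t, seq, Event(t=t, kind=kind, trial_index=trial, payload=payload or {})))
        seq += 1

    clock = 0.0
    gidx = 0
    for sched in schedules:
        for spec in sched.trials:
            clock += spec.isi_ms
            onset = clock
            offset = onset + spec.display_ms
            emit(onset, "stimulus_onset", gidx, _onset_payload(spec))
            emit(offset, "stimulus_offset", gidx)
            if spec.task in PRESS_TASKS:
                rt = _press_response(params, spec, rng)
                if rt is not None:
                    emit(onset + rt, "button_down", gidx)
                clock = offset
            else:
                end = _reach_response(
                    params, spec, cal, grid, rng, onset, offset, gidx, emit
                )
                clock = max(offset, end)
            gidx += 1
    ordered = tuple(e for _, _, e in sorted(events, key=lambda x: (x[0], x[1])))
    return EventLog(
        participant=participant,
        calibration=cal,
        grid=grid,
        schedules=tuple(schedules),
        seed=seed,
        params_hash=params.digest(),
        events=ordered,
    )


def _press_response(
    params: ParticipantParams, spec: TrialSpec, rng: np.random.Generator
) -> Optional[float]:
    if spec.is_go:
        if rng.random() < params.anticipation_p:
            return float(rng.uniform(30.0, 99.0))
        if rng.random() < params.lapse_p:
            return None
        return sample_decision_time(params, spec.task, spec.is_go, rng)
    if rng.random() < params.false_alarm_p:
        return sample_decision_time(params, spec.task, spec.is_go, rng)
    return None


def _reach_response(
    params: ParticipantParams,
    spec: TrialSpec,
    cal: Calibration,
    grid: LocationGrid,
    rng: np.random.Generator,
    onset: float,
    offset: float,
    gidx: int,
    emit,
) -> float:
    b = cal.location_b
    p_onset = b + _jitter_in_sphere(rng, params.base_jitter_m)
    emit(onset, "controller_sample", gidx, {"position": [p_onset.x, p_onset.y, p_onset.z]})

    if rng.random() < params.lapse_p:
        return offset
    if rng.random() < params.anticipation_p:
        rt = float(rng.uniform(30.0, 99.0))
    else:
        rt = sample_decision_time(params, spec.task, spec.is_go, rng)
    if onset + rt >= offset:  # too slow to start before the cube vanished
        return offset

    family = FAMILY_BY_TASK[spec.task]
    mt = params.mt_median_ms[family] * params.mt_scale * math.exp(
        rng.normal(0.0, params.mt_sigma_log)
    )
    exit_t = onset + rt
    touch_t = exit_t + mt

    # Aim by linear prediction of the cube's front-face center at arrival,
    # misjudging the arrival time (matters only when the cube moves) and
    # adding isotropic endpoint noise.
    judged_arrival = touch_t + (
        rng.normal(0.0, params.timing_jitter_ms) if spec.motion is not None else 0.0
    )
    aim = _cube_center_at(grid, spec, judged_arrival - onset)
    noise_sd = params.aim_noise_m * params.aim_noise_scale.get(family, 1.0)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=3)
        aim = aim + Vec3(float(noise[0]), float(noise[1]), float(noise[2]))

    # The hand stops at the cube's face plane: decompose the aim error in
    # the cube frame and clamp depth to the cube body, so misses happen
    # only when the contact point falls outside the face extent.
    true_center = _cube_center_at(grid, spec, touch_t - onset)
    cube = CubeStimulus(face_center=true_center, edge=CUBE_EDGE_M, color=spec.color)
    w, u, v = cube_frame(true_center - b)
    err = aim - true_center
    # keep the contact strictly behind the face plane so containment is
    # never decided by floating-point noise on the boundary
    depth = min(max(err.dot(w), 1e-9), CUBE_EDGE_M - 1e-9)
    contact = true_center + u.scale(err.dot(u)) + v.scale(err.dot(v)) + w.scale(depth)

    exit_pos = b + (contact - b).unit().scale(BASE_RADIUS_M)
    emit(exit_t, "base_exit", gidx, {"position": [exit_pos.x, exit_pos.y, exit_pos.z]})
    for dt, pos in simulate_reach(exit_pos, contact, mt, params.sample_rate):
        if dt < mt:
            emit(exit_t + dt, "controller_sample", gidx, {"position": [pos.x, pos.y, pos.z]})

    gave_up = rng.random() < params.miss_touch_p
    on_cube = cube_contains(contact, cube, inward=(true_center - b))
    if on_cube and not gave_up and touch_t <= offset:
        emit(touch_t, "touch", gidx, {"position": [contact.x, contact.y, contact.z]})
        return touch_t

    # Missed first contact.  A static cube allows a corrective second
    # movement (the source of very long movement times); a moving cube has
    # already left the predicted point, so the trial ends untouched.
    if not on_cube and not gave_up and spec.motion is None:
        touch2_t = exit_t + mt * params.retry_mt_factor
        if touch2_t <= offset:
            w2, u2, v2 = cube_frame(true_center - b)
            lat = float(rng.normal(0.0, params.aim_noise_m))
            vert = float(rng.normal(0.0, params.aim_noise_m))
            half = CUBE_EDGE_M / 2 - 1e-9
            contact2 = (
                true_center
                + u2.scale(min(max(lat, -half), half))
                + v2.scale(min(max(vert, -half), half))
                + w2.scale(1e-9)
            )
            for dt, pos in simulate_reach(contact, contact2, touch2_t - touch_t,
                                          params.sample_rate):
                if dt < touch2_t - touch_t:
                    emit(touch_t + dt, "controller_sample", gidx,
                         {"position": [pos.x, pos.y, pos.z]})
            emit(touch2_t, "touch", gidx, {"position": [contact2.x, contact2.y, contact2.z]})
            return touch2_t
    return touch_t


DEFAULT_CAL_B = Vec3(0.0, 1.35, 0.0)
DEFAULT_CAL_R = Vec3(0.0, 1.35, 0.55)


@dataclass(frozen=True)
class CohortParams:
    """Population hyperparameters for paired computer + headset simulation."""

    s_between_ms: float = 18.0  # SD of the shared latent speed across participants
    choice_cost_sd_ms: float = 30.0  # between-participant SD of the go/no-go cost
    vr_bias: float = 32.0
    mt_scale_sigma_log: float = 0.2
    base: ParticipantParams = field(default_factory=ParticipantParams)


@dataclass(frozen=True)
class CohortMember:
    participant: str
    params: ParticipantParams
    com_log: EventLog
    vr_log: EventLog


def simulate_cohort(
    n: int,
    pop: Optional[CohortParams] = None,
    seed: int = 0,
    tasks: Optional[Sequence[str]] = None,
    protocol: Optional[ProtocolConfig] = None,
) -> list[CohortMember]:
    """Paired computer + headset sessions for ``n`` synthetic participants.

    Participants share schedules' structure but draw their own latent speed
    (``Normal(0, s_between_ms)``) and reach-duration scale; ``tasks``
    restricts the headset session (e.g. press phases only).
    """
    if n < 2:
        raise SimulationError("a cohort needs at least two participants")
    pop = pop or CohortParams()
    root = np.random.default_rng(seed)
    members = []
    for i in range(n):
        latent = float(root.normal(0.0, pop.s_between_ms))
        cost = max(0.0, pop.base.choice_cost + float(root.normal(0.0, pop.choice_cost_sd_ms)))
        mt_scale = float(math.exp(root.normal(0.0, pop.mt_scale_sigma_log)))
        params = replace(
            pop.base, latent_speed=latent, vr_bias=pop.vr_bias,
            choice_cost=cost, mt_scale=mt_scale,
        )
        cfg = protocol or ProtocolConfig()
        cfg = replace(cfg, seed=int(root.integers(0, 2**31 - 1)))
        cal = calibrate(DEFAULT_CAL_B, DEFAULT_CAL_R)
        grid = build_grid(cal)
        pid = f"p{i:03d}"
        com = simulate_session(
            params, build_com_schedules(cfg), cal, grid,
            seed=int(root.integers(0, 2**31 - 1)), participant=pid,
        )
        vr = simulate_session(
            params, build_vr_schedules(cfg, tasks=tasks), cal, grid,
            seed=int(root.integers(0, 2**31 - 1)), participant=pid,
        )
        members.append(CohortMember(participant=pid, params=params, com_log=com, vr_log=vr))
    return members
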