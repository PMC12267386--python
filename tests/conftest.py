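"""Shared fixtures: a canonical calibration/grid and hand-built event logs."""

from __future__ import annotations

import pytest

from reachtime.geometry import Vec3, build_grid, calibrate
from reachtime.protocol import ProtocolConfig, TaskSchedule, TrialSpec
from reachtime.simulant import Event, EventLog, ParticipantParams


@pytest.fixture(scope="session")
def cal():
    return calibrate(Vec3(0.0, 1.2, 0.0), Vec3(0.0, 1.2, 0.5))


@pytest.fixture(scope="session")
def grid(cal):
    return build_grid(cal)


@pytest.fixture
def proto_cfg():
    return ProtocolConfig(seed=42)


@pytest.fixture
def quiet_params():
    """Error-free participant whose latencies stay inside the validity window."""
    from reachtime.simulant import ExGauss

    return ParticipantParams(
        exgauss={
            "press": ExGauss(mu=250.0, sigma=10.0, tau=10.0),
            "center": ExGauss(mu=300.0, sigma=10.0, tau=10.0),
            "spatial": ExGauss(mu=320.0, sigma=10.0, tau=10.0),
            "dynamic": ExGauss(mu=300.0, sigma=10.0, tau=10.0),
        },
        lapse_p=0.0,
        anticipation_p=0.0,
        false_alarm_p=0.0,
        miss_touch_p=0.0,
        aim_noise_m=0.0,
        timing_jitter_ms=0.0,
        base_jitter_m=0.0,
    )


def make_log(cal, grid, trials, events, seed=0):
    """Assemble an EventLog from explicit trial specs and events."""
    sched = TaskSchedule(task=trials[0].task, trials=tuple(trials), rng_seed=seed)
    return EventLog(
        participant="fixture",
        calibration=cal,
        grid=grid,
        schedules=(sched,),
        seed=seed,
        params_hash="fixture",
        events=tuple(sorted(events, key=lambda e: e.t)),
    )


def reach_trial(task="center", index=0, color="green", location_index=5, **kw):
    return TrialSpec(
        task=task,
        index=index,
        is_training=False,
        color=color,
        is_go=True,
        display_ms=kw.pop("display_ms", 2000.0),
        isi_ms=kw.pop("isi_ms", 3200.0),
        location_index=location_index,
        **kw,
    )


def press_trial(task="com_srt", index=0, color="green", is_go=True, **kw):
    return TrialSpec(
        task=task,
        index=index,
        is_training=False,
        color=color,
        is_go=is_go,
        display_ms=kw.pop("display_ms", 260.0),
        isi_ms=kw.pop("isi_ms", 1500.0),
        **kw,
    )


def ev(t, kind, trial=0, **payload):
    return Event(t=t, kind=kind, trial_index=trial, payload=payload)
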