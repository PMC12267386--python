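"""Score event logs into per-trial records and per-task summaries.

Reaction time (RT) is stimulus onset to response — the button press in the
press tasks, the controller leaving the 0.028-m base sphere in the reach
tasks.  Valid RTs lie in [100, 1000] ms: faster responses are anticipations
(guesses), slower or absent ones omissions.  Responses on no-go stimuli are
false alarms.  For reach trials, movement time (MT) runs from base exit to
cube touch; movement displacement is the onset-to-touch controller gap
minus the 0.028-m base radius (MT only starts once the controller has
already moved that far); movement velocity MV = displacement / MT.  MTs
above 600 ms are excluded from MT/MV central values (robust cutoff) but
counted in the over-600 rate; trials with a valid RT but no touch before
stimulus offset are movement omissions (M-omissions).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .geometry import BASE_RADIUS_M, Vec3
from .protocol import PRESS_TASKS
from .simulant import Event, EventLog

RT_MIN_MS = 100.0
RT_MAX_MS = 1000.0
MT_CUTOFF_MS = 600.0

CLASSIFICATIONS = ("valid", "anticipation", "omission", "false_alarm", "correct_rejection")


class MalformedLogError(ValueError):
    """Structurally invalid event stream; names the offending trial."""


class InsufficientDataError(ValueError):
    """Too few values to compute the requested statistic."""


@dataclass(frozen=True)
class TrialRecord:
    """Scored outcome of one trial."""

    task: str
    index: int  # global trial index within the session
    is_training: bool
    color: str
    is_go: bool
    location_index: Optional[int]
    classification: str
    rt_ms: Optional[float] = None
    mt_ms: Optional[float] = None
    displacement_m: Optional[float] = None
    mv_mps: Optional[float] = None
    touched: bool = False
    over_600: bool = False
    m_omission: bool = False
    paused: bool = False


def classify_rt(rt_ms: Optional[float], is_go: bool, task: str) -> str:
    """Apply the RT validity window (go) or the response rule (no-go).

    Boundaries are inclusive: rt = 100 and rt = 1000 are both valid.
    """
    if not is_go:
        return "false_alarm" if rt_ms is not None else "correct_rejection"
    if rt_ms is None or rt_ms > RT_MAX_MS:
        return "omission"
    if rt_ms < RT_MIN_MS:
        return "anticipation"
    return "valid"


def _payload_pos(ev: Event) -> Vec3:
    x, y, z = ev.payload["position"]
    return Vec3(float(x), float(y), float(z))


def score_log(log: EventLog) -> list[TrialRecord]:
    """Score every trial of a session.

    Events carry their trial index; a trial's window runs from its onset to
    the next onset, so late responses still belong to the trial that opened
    the window.  A ``base_exit`` before its trial's onset means the
    controller left base with no stimulus present (the run paused); that
    trial is flagged and excluded from every rate denominator.
    """
    specs = log.trial_specs()
    events = log.events
    for a, b in zip(events, events[1:]):
        if b.t < a.t:
            raise MalformedLogError(
                f"events out of order near trial {b.trial_index} (t {b.t} < {a.t})"
            )

    by_trial: dict[int, list[Event]] = {}
    # last controller sample seen before each trial's onset, as a fallback
    # onset position when the trial itself has no at-onset sample
    carry_pos: dict[int, Vec3] = {}
    prev_pos: Optional[Vec3] = None
    for ev in events:
        if ev.kind == "stimulus_onset" and prev_pos is not None:
            carry_pos[ev.trial_index] = prev_pos
        if ev.kind == "controller_sample":
            prev_pos = _payload_pos(ev)
        by_trial.setdefault(ev.trial_index, []).append(ev)

    return [
        _score_trial(idx, specs[idx], by_trial.get(idx, []), carry_pos.get(idx))
        for idx in sorted(specs)
    ]


def _score_trial(
    idx: int, spec, evs: list[Event], carry_pos: Optional[Vec3]
) -> TrialRecord:
    onset = next((e for e in evs if e.kind == "stimulus_onset"), None)
    if onset is None:
        raise MalformedLogError(f"trial {idx}: no stimulus_onset event")
    paused = any(e.kind == "base_exit" and e.t < onset.t for e in evs)
    base = dict(
        task=spec.task,
        index=idx,
        is_training=spec.is_training,
        color=spec.color,
        is_go=spec.is_go,
        location_index=spec.location_index,
        paused=paused,
    )

    if spec.task in PRESS_TASKS:
        press = next((e for e in evs if e.kind == "button_down"), None)
        rt = press.t - onset.t if press is not None else None
        return TrialRecord(**base, classification=classify_rt(rt, spec.is_go, spec.task), rt_ms=rt)

    exit_ev = next((e for e in evs if e.kind == "base_exit" and e.t >= onset.t), None)
    touch_ev = next((e for e in evs if e.kind == "touch"), None)
    if touch_ev is not None and exit_ev is None:
        raise MalformedLogError(f"trial {idx}: touch without base_exit")
    if touch_ev is not None and touch_ev.t < exit_ev.t:
        raise MalformedLogError(f"trial {idx}: touch precedes base_exit")

    rt = exit_ev.t - onset.t if exit_ev is not None else None
    cls = classify_rt(rt, spec.is_go, spec.task)
    mt = disp = mv = None
    touched = touch_ev is not None
    if touched:
        mt = touch_ev.t - exit_ev.t
        p_onset = _onset_position(evs, onset.t) or carry_pos
        if p_onset is not None:
            disp = (_payload_pos(touch_ev) - p_onset).norm() - BASE_RADIUS_M
            if mt > 0:
                mv = disp / (mt / 1000.0)
    return TrialRecord(
        **base,
        classification=cls,
        rt_ms=rt,
        mt_ms=mt,
        displacement_m=disp,
        mv_mps=mv,
        touched=touched,
        over_600=mt is not None and mt > MT_CUTOFF_MS,
        m_omission=cls == "valid" and not touched,
    )


def _onset_position(evs: list[Event], onset_t: float) -> Optional[Vec3]:
    """Most recent controller sample at/before stimulus onset."""
    best = None
    for e in evs:
        if e.kind == "controller_sample" and e.t <= onset_t:
            best = e
    return _payload_pos(best) if best is not None else None


def icv(values: Sequence[float]) -> float:
    """Intra-individual coefficient of variation: sample SD / mean."""
    if len(values) < 2:
        raise InsufficientDataError("ICV needs at least two values")
    mean = statistics.fmean(values)
    if mean == 0:
        raise InsufficientDataError("ICV undefined for zero mean")
    return statistics.stdev(values) / mean


@dataclass(frozen=True)
class MeasureSummary:
    """Central tendency and variability of one measure within a task."""

    median: Optional[float]
    mean: Optional[float]
    icv: Optional[float]
    n: int


@dataclass(frozen=True)
class TaskSummary:
    task: str
    rt: MeasureSummary
    mt: MeasureSummary
    mv: MeasureSummary
    anticipation_rate: Optional[float]
    omission_rate: Optional[float]
    false_alarm_rate: Optional[float]
    m_omission_rate: float
    over_600_rate: float
    n_trials: int
    n_go: int
    n_nogo: int
    n_paused: int
    no_valid_warning: bool = False


def _summ(values: list[float]) -> MeasureSummary:
    if not values:
        return MeasureSummary(None, None, None, 0)
    med = statistics.median(values)  # even counts: midpoint of the two central values
    mean = statistics.fmean(values)
    cv = icv(values) if len(values) >= 2 and mean != 0 else None
    return MeasureSummary(median=med, mean=mean, icv=cv, n=len(values))


def summarize_task(records: Iterable[TrialRecord], task: str) -> TaskSummary:
    """Per-task summary over non-training, non-paused trials."""
    recs = [r for r in records if r.task == task and not r.is_training]
    n_paused = sum(r.paused for r in recs)
    recs = [r for r in recs if not r.paused]
    go = [r for r in recs if r.is_go]
    nogo = [r for r in recs if not r.is_go]

    rts = [r.rt_ms for r in recs if r.classification == "valid"]
    kept = [r for r in recs if r.touched and r.mt_ms is not None and r.mt_ms <= MT_CUTOFF_MS]
    mts = [r.mt_ms for r in kept]
    mvs = [r.mv_mps for r in kept if r.mv_mps is not None]

    n = len(recs)
    return TaskSummary(
        task=task,
        rt=_summ(rts),
        mt=_summ(mts),
        mv=_summ(mvs),
        anticipation_rate=(
            sum(r.classification == "anticipation" for r in go) / len(go) if go else None
        ),
        omission_rate=(
            sum(r.classification == "omission" for r in go) / len(go) if go else None
        ),
        false_alarm_rate=(
            sum(r.classification == "false_alarm" for r in nogo) / len(nogo) if nogo else None
        ),
        m_omission_rate=(sum(r.m_omission for r in recs) / n if n else 0.0),
        over_600_rate=(sum(r.over_600 for r in recs) / n if n else 0.0),
        n_trials=n,
        n_go=len(go),
        n_nogo=len(nogo),
        n_paused=n_paused,
        no_valid_warning=not rts,
    )


@dataclass(frozen=True)
class RTDiff:
    """Choice-minus-simple RT cost, for medians and means."""

    diff_median: float
    diff_mean: float


def rt_diff(crt_summary: TaskSummary, srt_summary: TaskSummary) -> RTDiff:
    """Componentwise CRT − SRT of the central RT values."""
    if crt_summary.rt.median is None or srt_summary.rt.median is None:
        raise InsufficientDataError("both summaries need valid RTs")
    return RTDiff(
        diff_median=crt_summary.rt.median - srt_summary.rt.median,
        diff_mean=crt_summary.rt.mean - srt_summary.rt.mean,
    )
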