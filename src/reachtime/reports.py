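"""Summary tables and the validation report.

Per-task summaries are flattened to long CSV rows (one participant × task);
``wide_frame`` pivots them to one row per participant with the same
variable set as the published descriptive tables (median/mean/ICV per
measure, error rates, choice-minus-simple RT differences), and
``validation_report`` runs the full agreement suite on a paired cohort:
cross-method Pearson correlations, Bland–Altman panels, repeated-measures
ANOVA with sphericity correction, nonparametric comparisons, and
Bonferroni-adjusted decision thresholds.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable, Mapping

import pandas as pd

from . import agreement, metrics
from .metrics import TaskSummary, TrialRecord
from .simulant import EventLog

#: long-format summary columns (one row per participant × task)
SUMMARY_COLUMNS = (
    "participant",
    "test",
    "task",
    "rt_median",
    "rt_mean",
    "rt_icv",
    "omission_rate",
    "anticipation_rate",
    "false_alarm_rate",
    "mt_median",
    "mt_mean",
    "mt_icv",
    "m_omission_rate",
    "over_600_rate",
    "mv_median",
    "mv_mean",
    "mv_icv",
    "n_trials",
    "n_valid_rt",
    "n_valid_mt",
    "n_valid_mv",
    "n_paused",
)

TEST_BY_TASK = {
    "com_srt": "com",
    "com_crt": "com",
    "press_srt": "vr",
    "press_crt": "vr",
    "center": "vr",
    "spatial": "vr",
    "dynamic": "vr",
}


def session_summaries(log: EventLog) -> dict[str, TaskSummary]:
    """Score a session and summarize every task it contains."""
    records = metrics.score_log(log)
    return {
        sched.task: metrics.summarize_task(records, sched.task) for sched in log.schedules
    }


def summary_row(participant: str, summary: TaskSummary) -> dict:
    return {
        "participant": participant,
        "test": TEST_BY_TASK.get(summary.task, "external"),
        "task": summary.task,
        "rt_median": summary.rt.median,
        "rt_mean": summary.rt.mean,
        "rt_icv": summary.rt.icv,
        "omission_rate": summary.omission_rate,
        "anticipation_rate": summary.anticipation_rate,
        "false_alarm_rate": summary.false_alarm_rate,
        "mt_median": summary.mt.median,
        "mt_mean": summary.mt.mean,
        "mt_icv": summary.mt.icv,
        "m_omission_rate": summary.m_omission_rate,
        "over_600_rate": summary.over_600_rate,
        "mv_median": summary.mv.median,
        "mv_mean": summary.mv.mean,
        "mv_icv": summary.mv.icv,
        "n_trials": summary.n_trials,
        "n_valid_rt": summary.rt.n,
        "n_valid_mt": summary.mt.n,
        "n_valid_mv": summary.mv.n,
        "n_paused": summary.n_paused,
    }


def summary_frame(logs: Iterable[EventLog]) -> pd.DataFrame:
    """Long summary table for any number of sessions."""
    rows = []
    for log in logs:
        for task, summ in session_summaries(log).items():
            rows.append(summary_row(log.participant, summ))
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def records_frame(*logs: EventLog) -> pd.DataFrame:
    """Per-trial CSV shape: one scored TrialRecord per row."""
    rows = []
    for log in logs:
        for r in metrics.score_log(log):
            d = asdict(r)
            d["participant"] = log.participant
            rows.append(d)
    cols = ["participant"] + [f.name for f in TrialRecord.__dataclass_fields__.values()]
    return pd.DataFrame(rows, columns=cols)


def wide_frame(long: pd.DataFrame) -> pd.DataFrame:
    """One row per participant; columns ``{task}_{measure}`` plus the
    choice-minus-simple RT differences per modality."""
    out: dict[str, dict] = {}
    for _, row in long.iterrows():
        p = out.setdefault(row["participant"], {"participant": row["participant"]})
        task = row["task"]
        for col in SUMMARY_COLUMNS[3:]:
            p[f"{task}_{col}"] = row[col]
    df = pd.DataFrame(list(out.values())).set_index("participant", drop=False)
    for modality, srt, crt in (("com", "com_srt", "com_crt"), ("vr", "press_srt", "press_crt")):
        for stat in ("median", "mean"):
            a, b = f"{crt}_rt_{stat}", f"{srt}_rt_{stat}"
            if a in df.columns and b in df.columns:
                df[f"{modality}_rt_diff_{stat}"] = df[a] - df[b]
    return df


# Paired computer-vs-headset variables of the validation layer
_CORRELATION_PAIRS = (
    ("srt_median", "com_srt_rt_median", "press_srt_rt_median"),
    ("srt_mean", "com_srt_rt_mean", "press_srt_rt_mean"),
    ("crt_median", "com_crt_rt_median", "press_crt_rt_median"),
    ("crt_mean", "com_crt_rt_mean", "press_crt_rt_mean"),
    ("rt_diff_median", "com_rt_diff_median", "vr_rt_diff_median"),
    ("rt_diff_mean", "com_rt_diff_mean", "vr_rt_diff_mean"),
)

_WILCOXON_PAIRS = (
    ("srt_icv", "com_srt_rt_icv", "press_srt_rt_icv"),
    ("crt_icv", "com_crt_rt_icv", "press_crt_rt_icv"),
    ("srt_omissions", "com_srt_omission_rate", "press_srt_omission_rate"),
    ("crt_omissions", "com_crt_omission_rate", "press_crt_omission_rate"),
    ("srt_anticipations", "com_srt_anticipation_rate", "press_srt_anticipation_rate"),
    ("crt_anticipations", "com_crt_anticipation_rate", "press_crt_anticipation_rate"),
    ("false_alarms", "com_crt_false_alarm_rate", "press_crt_false_alarm_rate"),
)


def validation_report(wide: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Cross-method validation statistics on a paired wide table.

    Returns a JSON-ready dict: Pearson correlations and Bland–Altman panels
    for the central RT variables, Wilcoxon comparisons for the rate/ICV
    variables at the Bonferroni-adjusted alpha, and a repeated-measures
    ANOVA over the four press-task conditions when present.
    """
    report: dict = {"n_participants": int(len(wide)), "alpha": alpha}

    correlations = {}
    panels = {}
    for name, a_col, b_col in _CORRELATION_PAIRS:
        if a_col not in wide.columns or b_col not in wide.columns:
            continue
        sub = wide[[a_col, b_col]].dropna()
        if len(sub) < 4:
            continue
        com, vr = sub[a_col].to_numpy(), sub[b_col].to_numpy()
        r, p, n = agreement.pearson_validate(com, vr)
        correlations[name] = {"r": r, "p": p, "n": n}
        ba = agreement.bland_altman(vr, com)  # headset minus computer
        panels[name] = asdict(ba)
    report["pearson"] = correlations
    report["bland_altman"] = panels

    m = len(_WILCOXON_PAIRS)
    adj = agreement.bonferroni(alpha, m)
    wilcoxon = {}
    for name, a_col, b_col in _WILCOXON_PAIRS:
        if a_col not in wide.columns or b_col not in wide.columns:
            continue
        sub = wide[[a_col, b_col]].dropna()
        if len(sub) < 5:
            continue
        try:
            stat, p = agreement.wilcoxon_signed_rank(
                sub[a_col].to_numpy(), sub[b_col].to_numpy()
            )
        except agreement.AnalysisError:
            stat, p = float("nan"), 1.0  # identical distributions: no evidence of difference
        wilcoxon[name] = {"W": stat, "p": p, "significant": p < adj}
    report["wilcoxon"] = {"adjusted_alpha": adj, "tests": wilcoxon}

    anova_cols = [
        "com_srt_rt_median",
        "com_crt_rt_median",
        "press_srt_rt_median",
        "press_crt_rt_median",
    ]
    if all(c in wide.columns for c in anova_cols):
        X = wide[anova_cols].dropna().to_numpy()
        if len(X) >= 4:
            report["rm_anova_rt"] = {
                "conditions": anova_cols,
                **asdict(agreement.rm_anova_gg(X)),
            }
    return report


def render_report_markdown(report: Mapping) -> str:
    """Human-readable rendering of ``validation_report`` output."""
    lines = [
        "# Method-agreement validation report",
        "",
        f"Participants: {report['n_participants']}  (alpha = {report['alpha']})",
        "",
        "## Pearson correlations (computer vs headset)",
        "",
        "| variable | r | p | n |",
        "|---|---|---|---|",
    ]
    for name, d in report.get("pearson", {}).items():
        lines.append(f"| {name} | {d['r']:.3f} | {d['p']:.2e} | {d['n']} |")
    lines += [
        "",
        "## Bland–Altman (headset − computer)",
        "",
        "| variable | bias | LoA low | LoA high | prop. slope p |",
        "|---|---|---|---|---|",
    ]
    for name, d in report.get("bland_altman", {}).items():
        lines.append(
            f"| {name} | {d['bias']:.2f} | {d['loa_low']:.2f} | "
            f"{d['loa_high']:.2f} | {d['prop_slope_p']:.3f} |"
        )
    wil = report.get("wilcoxon", {})
    lines += [
        "",
        f"## Wilcoxon signed-rank (adjusted alpha = {wil.get('adjusted_alpha')})",
        "",
        "| variable | W | p | significant |",
        "|---|---|---|---|",
    ]
    for name, d in wil.get("tests", {}).items():
        lines.append(f"| {name} | {d['W']:.1f} | {d['p']:.4f} | {d['significant']} |")
    if "rm_anova_rt" in report:
        a = report["rm_anova_rt"]
        lines += [
            "",
            "## Repeated-measures ANOVA on median RT",
            "",
            f"F({a['df1']:.2f}, {a['df2']:.2f}) = {a['F']:.2f}, p = {a['p']:.3e}, "
            f"partial eta^2 = {a['partial_eta_sq']:.3f} "
            f"(Mauchly W = {a['mauchly_w']:.3f}, p = {a['mauchly_p']:.3f}, "
            f"GG epsilon = {a['gg_epsilon']:.3f})",
        ]
    return "\n".join(lines) + "\n"


def dump_report_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=float)
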