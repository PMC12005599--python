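"""Response rate, completeness, quality, and context-correlation statistics.

Definitions follow the per-prompt compliance convention: a prompt with no
response scores 0, a complete response 1, and a partial response the
answered fraction of asked questions.  *Response rate* is the percentage of
prompts with at least one answered question (re-delivery attempts of the
same prompt count once).  *Completeness* is the mean compliance among
responded prompts, as a percentage.

*Careless responding* captures habitual answering: the percentage of a
participant's normalized answers within 0.2 of that participant's modal
answer (mode ties broken to the lowest tied value).  Habituation over a
study is measured by splitting each participant's collection span at its
calendar midpoint and contrasting carelessness and response variance
between halves, with a paired two-sided t test across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ema_context.ema_core import ResponseSession, StudyManifest

__all__ = [
    "WELLBEING_CATEGORIES",
    "TrendFit",
    "HalfSplitResult",
    "QualityReport",
    "RateTable",
    "response_rate",
    "completeness",
    "incomplete_share",
    "careless_pct",
    "half_split_change",
    "trend_fit",
    "context_correlation",
    "rate_table",
    "quality_report",
    "responses_by_participant",
    "absolute_gap",
]

#: The three self-report dimensions analyzed for quality and dynamics.
WELLBEING_CATEGORIES = ("sharp", "fatigue", "stress")


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares line with its Pearson correlation."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class HalfSplitResult:
    """First-half vs second-half habituation contrast across participants."""

    d_careless_pct: float
    d_variance: float
    p_careless: float
    p_variance: float
    n_participants: int
    n_excluded: int


@dataclass
class QualityReport:
    category_mean: dict
    category_variance: dict
    careless_pct: float
    interparticipant_variance: float
    half_split: HalfSplitResult
    #: how careless_pct aggregates: per participant then averaged
    careless_aggregation: str = "per-participant mean"


@dataclass
class RateTable:
    """Response rate (%) with prompt counts, overall and per stratum.

    ``by_tod`` / ``by_dow`` index the strata and carry rate and count
    columns for the pooled cohort and each age group; strata with no prompts
    are absent rather than reported as 0.
    """

    overall: tuple[float, int]
    by_tod: pd.DataFrame
    by_dow: pd.DataFrame
    by_age: pd.DataFrame
    diffs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "overall": {"rate_pct": self.overall[0], "n_prompts": self.overall[1]},
            "by_tod": self.by_tod.to_dict(orient="index"),
            "by_dow": self.by_dow.to_dict(orient="index"),
            "by_age": self.by_age.to_dict(orient="index"),
            "diffs": self.diffs,
        }


def response_rate(sessions: Sequence[ResponseSession]) -> float:
    """Percentage of prompts with at least one answered question."""
    if not sessions:
        raise ValueError("response_rate undefined for an empty session list")
    return 100.0 * float(np.mean([s.responded for s in sessions]))


def completeness(sessions: Sequence[ResponseSession]) -> float:
    """Mean compliance among responded prompts, in percent."""
    vals = [s.compliance for s in sessions if s.responded]
    if not vals:
        raise ValueError("completeness undefined without responded sessions")
    return 100.0 * float(np.mean(vals))


def incomplete_share(n_incomplete: int, n_responded: int) -> float:
    """Percent of responded sessions that were started but not completed."""
    if n_responded < 1 or not 0 <= n_incomplete <= n_responded:
        raise ValueError("inconsistent session counts")
    return 100.0 * n_incomplete / n_responded


def absolute_gap(a: float, b: float) -> float:
    """Absolute difference between two rates (e.g. observed vs literature)."""
    return abs(a - b)


def _mode_lowest(values: np.ndarray) -> float:
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])  # np.unique sorts: ties -> lowest


def careless_pct(values: Iterable[float]) -> float:
    """Percent of one participant's answers within 0.2 of their mode.

    Values are on the normalized 1–5 scale; the mode tie-break is the lowest
    tied value and the 0.2 band is inclusive.
    """
    arr = np.asarray(list(values), float)
    if arr.size == 0:
        raise ValueError("careless_pct undefined for no responses")
    mode = _mode_lowest(arr)
    return 100.0 * float(np.mean(np.abs(arr - mode) <= 0.2 + 1e-9))


def responses_by_participant(
    sessions: Sequence[ResponseSession],
    categories: Sequence[str] = WELLBEING_CATEGORIES,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Collect (elapsed_day, norm_value) arrays per participant, time-ordered."""
    acc: dict[str, list[tuple[float, float]]] = {}
    for s in sessions:
        for a in s.answers:
            if a.category in categories:
                acc.setdefault(s.prompt.participant_id, []).append(
                    (float(s.prompt.elapsed_day), a.norm_value)
                )
    out = {}
    for pid, pairs in acc.items():
        arr = np.array(pairs, float)
        out[pid] = (arr[:, 0], arr[:, 1])
    return out


def half_split_change(
    responses: Mapping[str, tuple[np.ndarray, np.ndarray]],
    min_per_half: int = 2,
) -> HalfSplitResult:
    """Habituation contrast between each participant's study halves.

    Each participant's own collection span is split at its calendar
    midpoint; per half we compute the carelessness percentage and the
    response variance, take second-half minus first-half deltas, average the
    deltas over participants, and test them against zero with a two-sided
    paired t test.  Participants without at least ``min_per_half`` responses
    in both halves are excluded (their count is reported).
    """
    d_care, d_var = [], []
    excluded = 0
    for pid, (days, values) in responses.items():
        days = np.asarray(days, float)
        values = np.asarray(values, float)
        mid = (days.min() + days.max()) / 2.0
        first = values[days <= mid]
        second = values[days > mid]
        if len(first) < min_per_half or len(second) < min_per_half:
            excluded += 1
            continue
        d_care.append(careless_pct(second) - careless_pct(first))
        d_var.append(np.var(second) - np.var(first))
    if not d_care:
        raise ValueError("no participant has responses in both study halves")
    d_care = np.asarray(d_care)
    d_var = np.asarray(d_var)
    if len(d_care) >= 2:
        p_c = float(stats.ttest_1samp(d_care, 0.0).pvalue)
        p_v = float(stats.ttest_1samp(d_var, 0.0).pvalue)
    else:  # a single participant carries no test
        p_c = p_v = float("nan")
    return HalfSplitResult(
        d_careless_pct=float(d_care.mean()),
        d_variance=float(d_var.mean()),
        p_careless=p_c,
        p_variance=p_v,
        n_participants=len(d_care),
        n_excluded=excluded,
    )


def trend_fit(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS line plus Pearson r and its two-sided p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend undefined")
    res = stats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
    )


def context_correlation(
    compliance: Sequence[float], feature: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of per-prompt compliance with a context feature.

    NaN feature values (the "context unavailable" sentinel) are dropped
    pairwise before correlating.
    """
    c = np.asarray(compliance, float)
    f = np.asarray(feature, float)
    if len(c) != len(f):
        raise ValueError("compliance and feature must be paired")
    keep = ~(np.isnan(c) | np.isnan(f))
    c, f = c[keep], f[keep]
    if len(c) < 3:
        raise ValueError("fewer than 3 usable pairs")
    if np.ptp(f) == 0 or np.ptp(c) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(c, f)
    return float(r), float(p)


def _rates(df: pd.DataFrame, by: str) -> pd.DataFrame:
    rows = {}
    for stratum, g in df.groupby(by, sort=False):
        row = {
            "rate_pct": 100.0 * g["responded"].mean(),
            "n_prompts": int(len(g)),
        }
        for age, ga in g.groupby("age_group", sort=False):
            row[f"rate_pct_{age}"] = 100.0 * ga["responded"].mean()
            row[f"n_prompts_{age}"] = int(len(ga))
        rows[stratum] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def rate_table(
    sessions: Sequence[ResponseSession],
    manifests: Mapping[str, StudyManifest],
) -> RateTable:
    """Response-rate table by time of day, day of week, and age group.

    Reported like the cohort summary of a multi-study analysis: pooled rates
    with older/younger splits and the weekday-minus-weekend difference per
    group.  Empty strata are simply absent.
    """
    if not sessions:
        raise ValueError("rate_table undefined for an empty session list")
    df = pd.DataFrame(
        {
            "responded": [s.responded for s in sessions],
            "tod": [s.prompt.tod_stratum for s in sessions],
            "dow": [s.prompt.dow_stratum for s in sessions],
            "age_group": [manifests[s.prompt.study_id].age_group for s in sessions],
        }
    )
    by_tod = _rates(df, "tod")
    by_dow = _rates(df, "dow")
    by_age = _rates(df, "age_group")
    diffs: dict[str, float] = {}
    if {"weekday", "weekend"} <= set(by_dow.index):
        for col in by_dow.columns:
            if col.startswith("rate_pct"):
                wd, we = by_dow.loc["weekday", col], by_dow.loc["weekend", col]
                if pd.notna(wd) and pd.notna(we):
                    diffs[f"weekday_minus_weekend_{col[9:] or 'overall'}"] = float(wd - we)
    return RateTable(
        overall=(100.0 * df["responded"].mean(), len(df)),
        by_tod=by_tod,
        by_dow=by_dow,
        by_age=by_age,
        diffs=diffs,
    )


def quality_report(sessions: Sequence[ResponseSession]) -> QualityReport:
    """Response averages and quality summary for a session collection.

    Per-category means and variances pool all normalized answers; the
    carelessness percentage is computed per participant and averaged; the
    interparticipant variance is the variance across participants of their
    mean normalized response.  The habituation contrast comes from
    :func:`half_split_change`.
    """
    cat_vals: dict[str, list[float]] = {c: [] for c in WELLBEING_CATEGORIES}
    for s in sessions:
        for a in s.answers:
            if a.category in cat_vals:
                cat_vals[a.category].append(a.norm_value)
    per_pid = responses_by_participant(sessions)
    if not per_pid:
        raise ValueError("no well-being answers in sessions")
    careless = np.mean([careless_pct(v) for _, v in per_pid.values()])
    pid_means = np.array([v.mean() for _, v in per_pid.values()])
    return QualityReport(
        category_mean={
            c: float(np.mean(v)) for c, v in cat_vals.items() if v
        },
        category_variance={
            c: float(np.var(v)) for c, v in cat_vals.items() if v
        },
        careless_pct=float(careless),
        interparticipant_variance=float(np.var(pid_means)),
        half_split=half_split_change(per_pid),
    )
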