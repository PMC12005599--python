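"""Data model and ingestion for EMA prompts, responses, and study manifests.

An EMA (ecological momentary assessment) study delivers repeated prompts to a
participant's mobile device; each prompt asks a short battery of Likert
questions.  Scales differ between studies, so all answers are normalized onto
a common 1–5 scale with higher values more positive (negatively-phrased
questions are inverted).  A prompt with at least one answered question counts
as *responded*; its *compliance* is the answered fraction of asked questions
(0 for no response, 1 for a complete response).

Prompts are stratified by local time of day — morning before 12 PM, afternoon
from 12 PM through 5 PM, evening after 5 PM — and by weekday vs weekend.  All
timestamps are interpreted on the participant's local clock.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "AGE_GROUPS",
    "CATEGORIES",
    "StudyManifest",
    "PromptEvent",
    "LikertResponse",
    "ResponseSession",
    "normalize_likert",
    "session_compliance",
    "stratify_prompt",
    "read_manifests",
    "read_event_logs",
    "write_prompt_log",
    "EventLogData",
]

AGE_GROUPS = ("older", "younger")
PURPOSES = ("intervention", "observational")
CATEGORIES = ("sharp", "fatigue", "stress", "other")
TOD_STRATA = ("morning", "afternoon", "evening")
DOW_STRATA = ("weekday", "weekend")

Category = Literal["sharp", "fatigue", "stress", "other"]

#: Columns of the prompt/response event log (one row per prompt attempt and
#: question; ``raw_value`` empty means the question went unanswered).
PROMPT_LOG_COLUMNS = [
    "study_id",
    "participant_id",
    "prompt_id",
    "attempt",
    "scheduled_time",
    "question_id",
    "category",
    "raw_value",
    "raw_min",
    "raw_max",
    "inverted",
]


@dataclass(frozen=True)
class StudyManifest:
    """Per-study design parameters.

    Parameters
    ----------
    age_group
        ``"older"`` for studies whose participants are aged 50+ years,
        otherwise ``"younger"``.
    purpose
        ``"intervention"`` (e.g. cognitive-health training) or
        ``"observational"``.
    time_blocks
        Non-overlapping daily windows (start, end clock times); one prompt is
        issued per block per day, uniformly at random within the block.
    max_reissues
        Maximum number of delivery attempts per prompt; an unanswered prompt
        is re-issued at ``reissue_interval_min`` minute intervals.
    """

    study_id: str
    age_group: str
    purpose: str
    n_questions: int
    time_blocks: tuple[tuple[dt.time, dt.time], ...]
    max_reissues: int = 5
    reissue_interval_min: float = 5.0
    duration_days: int = 14

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if self.purpose not in PURPOSES:
            raise ValueError(f"purpose must be one of {PURPOSES}")
        if self.n_questions < 1:
            raise ValueError("n_questions must be >= 1")
        if self.max_reissues < 1:
            raise ValueError("max_reissues must be >= 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        blocks = sorted(self.time_blocks)
        for (s, e) in blocks:
            if not s < e:
                raise ValueError(f"empty time block {s}-{e}")
        for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError("time blocks overlap")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyManifest":
        blocks = tuple(
            (dt.time.fromisoformat(str(s)), dt.time.fromisoformat(str(e)))
            for s, e in d["time_blocks"]
        )
        return cls(
            study_id=str(d["study_id"]),
            age_group=str(d["age_group"]),
            purpose=str(d["purpose"]),
            n_questions=int(d["n_questions"]),
            time_blocks=blocks,
            max_reissues=int(d.get("max_reissues", 5)),
            reissue_interval_min=float(d.get("reissue_interval_min", 5.0)),
            duration_days=int(d.get("duration_days", 14)),
        )

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "age_group": self.age_group,
            "purpose": self.purpose,
            "n_questions": self.n_questions,
            "time_blocks": [
                [s.isoformat("minutes"), e.isoformat("minutes")]
                for s, e in self.time_blocks
            ],
            "max_reissues": self.max_reissues,
            "reissue_interval_min": self.reissue_interval_min,
            "duration_days": self.duration_days,
        }


@dataclass(frozen=True)
class PromptEvent:
    """One scheduled EMA prompt (re-delivery attempts collapse to one event)."""

    participant_id: str
    study_id: str
    scheduled_time: dt.datetime
    attempt_count: int = 1
    elapsed_day: int = 0
    tod_stratum: str = field(init=False)
    dow_stratum: str = field(init=False)

    def __post_init__(self) -> None:
        if self.attempt_count < 1:
            raise ValueError("attempt_count must be >= 1")
        if self.elapsed_day < 0:
            raise ValueError("elapsed_day must be >= 0")
        tod, dow = stratify_prompt(self.scheduled_time)
        object.__setattr__(self, "tod_stratum", tod)
        object.__setattr__(self, "dow_stratum", dow)


@dataclass(frozen=True)
class LikertResponse:
    """One answered question, normalized onto the common 1–5 scale."""

    question_id: str
    category: str
    raw_value: float
    raw_min: float
    raw_max: float
    inverted: bool
    norm_value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        norm = normalize_likert(self.raw_value, self.raw_min, self.raw_max, self.inverted)
        object.__setattr__(self, "norm_value", norm)


@dataclass(frozen=True)
class ResponseSession:
    """One prompt with its (possibly empty or partial) set of answers."""

    prompt: PromptEvent
    answers: tuple[LikertResponse, ...]
    n_questions_asked: int
    responded: bool = field(init=False)
    complete: bool = field(init=False)
    compliance: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_questions_asked < 1:
            raise ValueError("n_questions_asked must be >= 1")
        if len(self.answers) > self.n_questions_asked:
            raise ValueError(
                f"{len(self.answers)} answers exceed {self.n_questions_asked} "
                "questions asked"
            )
        object.__setattr__(self, "responded", len(self.answers) > 0)
        object.__setattr__(self, "complete", len(self.answers) == self.n_questions_asked)
        object.__setattr__(self, "compliance", len(self.answers) / self.n_questions_asked)


def normalize_likert(
    raw_value: float, raw_min: float, raw_max: float, inverted: bool = False
) -> float:
    """Map a raw Likert answer linearly onto the common [1, 5] scale.

    Negatively-phrased questions (``inverted=True``) are reflected after the
    mapping (``x -> 6 - x``) so that a higher normalized value is always more
    positive.  Endpoints map to endpoints exactly.

    Raises
    ------
    ValueError
        If ``raw_min >= raw_max`` or ``raw_value`` lies outside the declared
        bounds.
    """
    if not raw_min < raw_max:
        raise ValueError(f"invalid scale bounds [{raw_min}, {raw_max}]")
    if not raw_min <= raw_value <= raw_max:
        raise ValueError(
            f"raw value {raw_value} outside declared bounds [{raw_min}, {raw_max}]"
        )
    norm = 1.0 + 4.0 * (raw_value - raw_min) / (raw_max - raw_min)
    if inverted:
        norm = 6.0 - norm
    return norm


def session_compliance(n_answered: int, n_questions_asked: int) -> float:
    """Graded per-prompt compliance: answered fraction of asked questions.

    0.0 for no response, 1.0 for a complete response, the answered fraction
    for a partial response.  Non-question tasks are excluded from the
    denominator by the caller (``n_questions_asked`` counts questions only).
    """
    if n_questions_asked < 1:
        raise ValueError("n_questions_asked must be >= 1")
    if n_answered < 0 or n_answered > n_questions_asked:
        raise ValueError(
            f"{n_answered} answers inconsistent with {n_questions_asked} questions"
        )
    return n_answered / n_questions_asked


def stratify_prompt(scheduled_time: dt.datetime) -> tuple[str, str]:
    """Return the (time-of-day, day-of-week) strata for a prompt time.

    Morning is before 12 PM, afternoon is 12 PM through 5 PM inclusive of
    both boundary instants, evening is after 5 PM.  Weekend is Saturday or
    Sunday.  Times are taken on the participant's local clock.
    """
    t = scheduled_time.time()
    if t < dt.time(12, 0):
        tod = "morning"
    elif t <= dt.time(17, 0):
        tod = "afternoon"
    else:
        tod = "evening"
    dow = "weekend" if scheduled_time.weekday() >= 5 else "weekday"
    return tod, dow


def read_manifests(path: str | Path) -> dict[str, StudyManifest]:
    """Read a YAML manifest file into ``{study_id: StudyManifest}``.

    The file holds either a list of study mappings or a mapping with a
    ``studies`` list.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["studies"] if isinstance(doc, Mapping) else doc
    manifests = {}
    for entry in entries:
        m = StudyManifest.from_dict(entry)
        if m.study_id in manifests:
            raise ValueError(f"duplicate study_id {m.study_id!r} in manifest")
        manifests[m.study_id] = m
    return manifests


@dataclass
class EventLogData:
    """Validated ingestion result: time-sorted sessions plus a row-issue log."""

    sessions: list[ResponseSession]
    issues: list[str]

    def by_participant(self) -> dict[str, list[ResponseSession]]:
        out: dict[str, list[ResponseSession]] = {}
        for s in self.sessions:
            out.setdefault(s.prompt.participant_id, []).append(s)
        return out


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in {"1", "true", "yes", "y"}


def read_event_logs(
    paths: str | Path | Sequence[str | Path],
    manifests: Mapping[str, StudyManifest],
) -> EventLogData:
    """Read delimited prompt/response logs into validated sessions.

    Each row describes one question of one prompt attempt (columns
    :data:`PROMPT_LOG_COLUMNS`).  Rows are grouped by
    (participant, prompt_id); a question counts as answered if any attempt
    row carries a raw value.  Malformed rows — unknown study, raw value
    outside its declared bounds, unparsable fields, duplicate prompt ids with
    conflicting schedules — are rejected and reported with their line number,
    never silently dropped.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    issues: list[str] = []
    frames = []
    for p in paths:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        missing = [c for c in PROMPT_LOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{p}: missing columns {missing}")
        df["_line"] = df.index + 2  # header is line 1
        df["_path"] = str(p)
        frames.append(df)
        if df.empty:
            issues.append(f"{p}: empty event log")
    if not frames or all(f.empty for f in frames):
        return EventLogData(sessions=[], issues=issues)
    raw = pd.concat(frames, ignore_index=True)

    sessions: list[ResponseSession] = []
    grouped = raw.groupby(["participant_id", "prompt_id"], sort=False)
    records = []
    for (pid, prompt_id), g in grouped:
        study_id = g["study_id"].iloc[0]
        man = manifests.get(study_id)
        if man is None:
            issues.append(
                f"{g['_path'].iloc[0]}:{g['_line'].iloc[0]}: unknown study_id "
                f"{study_id!r} (prompt {prompt_id} rejected)"
            )
            continue
        times = pd.to_datetime(g["scheduled_time"], errors="coerce")
        if times.isna().any():
            bad = g.loc[times.isna(), "_line"].iloc[0]
            issues.append(f"{g['_path'].iloc[0]}:{bad}: unparsable scheduled_time")
            continue
        if times.nunique() > 1:
            issues.append(
                f"{g['_path'].iloc[0]}:{g['_line'].iloc[0]}: prompt {prompt_id} has "
                "conflicting scheduled times (rejected)"
            )
            continue
        answers = []
        seen_q: set[str] = set()
        ok = True
        for _, row in g.iterrows():
            qid = row["question_id"]
            if row["raw_value"] == "" or qid in seen_q:
                continue
            try:
                resp = LikertResponse(
                    question_id=qid,
                    category=row["category"],
                    raw_value=float(row["raw_value"]),
                    raw_min=float(row["raw_min"]),
                    raw_max=float(row["raw_max"]),
                    inverted=_parse_bool(row["inverted"]),
                )
            except (ValueError, TypeError) as exc:
                issues.append(f"{row['_path']}:{row['_line']}: {exc} (prompt rejected)")
                ok = False
                break
            seen_q.add(qid)
            answers.append(resp)
        if not ok:
            continue
        try:
            attempts = g["attempt"].astype(int).max()
        except ValueError:
            issues.append(
                f"{g['_path'].iloc[0]}:{g['_line'].iloc[0]}: bad attempt number"
            )
            continue
        records.append(
            (pid, study_id, times.iloc[0].to_pydatetime(), int(attempts),
             man.n_questions, tuple(answers))
        )

    # elapsed_day is relative to each participant's first prompt date
    first_date: dict[str, dt.date] = {}
    for pid, _, t, _, _, _ in records:
        d = t.date()
        if pid not in first_date or d < first_date[pid]:
            first_date[pid] = d
    for pid, study_id, t, attempts, n_q, answers in records:
        prompt = PromptEvent(
            participant_id=pid,
            study_id=study_id,
            scheduled_time=t,
            attempt_count=attempts,
            elapsed_day=(t.date() - first_date[pid]).days,
        )
        try:
            sessions.append(
                ResponseSession(prompt=prompt, answers=answers, n_questions_asked=n_q)
            )
        except ValueError as exc:
            issues.append(f"prompt {pid}/{t.isoformat()}: {exc} (rejected)")
    sessions.sort(key=lambda s: (s.prompt.participant_id, s.prompt.scheduled_time))
    return EventLogData(sessions=sessions, issues=issues)


def write_prompt_log(
    rows: Iterable[Mapping], path: str | Path
) -> None:
    """Write prompt/response rows (mappings with :data:`PROMPT_LOG_COLUMNS`
    keys) as CSV."""
    df = pd.DataFrame(list(rows), columns=PROMPT_LOG_COLUMNS)
    df.to_csv(path, index=False)
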