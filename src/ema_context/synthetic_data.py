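"""Synthetic multi-study EMA datasets with sensor streams and ground truth.

The generator emits everything the analysis consumes — study manifests,
prompt schedules with re-delivery attempts, Likert answers on each study's
raw scale, smartwatch streams (per-minute acceleration magnitude, location
fixes every 5 minutes) or ambient smart-home streams (motion and door
events), plus the ground truth behind them — so that every estimator in the
package can be checked against known parameters.

The statistical structure mirrors what multi-study EMA compliance analyses
measure:

* a logistic response model: the probability of answering a prompt depends
  on a per-participant intercept, time of day (with an evening boost for
  older cohorts), the number of questions asked (calibrated so the local
  response-rate slope is about −1.9 percentage points per question at the
  80% base rate), and the behavior context (at-home fraction, nearness to
  an activity transition, activity level — all with positive effects);
* habituation: the careless-response probability rises linearly per elapsed
  day while answer noise shrinks across the study;
* a two-state home/away mobility model: log-normal away bouts displace the
  participant ≥200 m from home, acceleration is elevated during bouts and
  around transitions, and every home/away boundary is a true activity
  change point;
* between-study response-level differences (per-study Likert centers, an
  upward drift of the "sharp" dimension that is stronger for intervention
  than observational studies) large enough that between-study DTW distance
  exceeds within-study distance.

Covariates enter the response model centered at configured reference values
so the marginal response rate stays at ``base_rr``.  Identical config and
seed reproduce the dataset exactly.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ema_context.ema_core import (
    PROMPT_LOG_COLUMNS,
    LikertResponse,
    PromptEvent,
    ResponseSession,
    StudyManifest,
    normalize_likert,
)
from ema_context.sensor_markers import AmbientEvents

__all__ = [
    "StudyDesign",
    "BehaviorConfig",
    "ResponseModelConfig",
    "GeneratorConfig",
    "ParticipantTruth",
    "ParticipantData",
    "SyntheticDataset",
    "default_config",
    "small_config",
    "schedule_prompts",
    "simulate_behavior",
    "simulate_responses",
    "generate_dataset",
    "write_dataset",
]

#: Default daily prompt blocks (start, end clock times), one prompt each.
DEFAULT_BLOCKS = (
    (dt.time(8, 30), dt.time(10, 30)),
    (dt.time(11, 30), dt.time(13, 30)),
    (dt.time(14, 30), dt.time(16, 30)),
    (dt.time(18, 0), dt.time(20, 0)),
)

_BASE_DATE = dt.date(2023, 3, 6)  # a Monday; participant starts stagger off it


@dataclass(frozen=True)
class StudyDesign:
    """Design of one synthetic study (population, battery, scale, levels)."""

    study_id: str
    n_participants: int
    age_group: str
    purpose: str
    n_questions: int
    duration_days: int = 14
    raw_min: float = 1.0
    raw_max: float = 5.0
    max_reissues: int = 5
    modality: str = "watch"  # "watch" | "ambient"
    #: study-level shift of all category centers on the normalized scale
    level_offset: float = 0.0
    time_blocks: tuple = DEFAULT_BLOCKS

    def manifest(self) -> StudyManifest:
        return StudyManifest(
            study_id=self.study_id,
            age_group=self.age_group,
            purpose=self.purpose,
            n_questions=self.n_questions,
            time_blocks=self.time_blocks,
            max_reissues=self.max_reissues,
            duration_days=self.duration_days,
        )


@dataclass(frozen=True)
class BehaviorConfig:
    """Mobility and sensor-stream parameters."""

    away_bouts_per_day: float = 2.0
    bout_median_min: float = 45.0
    bout_sigma: float = 0.5  # log-normal shape of bout duration
    bout_window: tuple[float, float] = (8 * 60, 20 * 60)  # minutes of day
    fix_interval_min: float = 5.0
    accel_interval_min: float = 1.0
    gps_jitter_m: float = 10.0
    away_displacement_m: tuple[float, float] = (300.0, 2000.0)
    active_bouts_per_day: float = 10.0
    active_bout_min: tuple[float, float] = (30.0, 60.0)
    # (mean, sd) of per-minute acceleration magnitude by state, in g
    accel_home_idle: tuple[float, float] = (0.3, 0.1)
    accel_home_active: tuple[float, float] = (0.9, 0.15)
    accel_away: tuple[float, float] = (0.9, 0.15)
    accel_transition: tuple[float, float] = (1.8, 0.2)
    transition_halfwidth_min: float = 2.0
    motion_rate_active: float = 2.0  # events/min while home and active
    motion_rate_idle: float = 0.5  # events/min while home and idle
    home_lat: float = 46.73
    home_lon: float = -117.17


@dataclass(frozen=True)
class ResponseModelConfig:
    """Logistic response model and Likert answer model parameters.

    ``beta_questions`` defaults to the value that makes the local
    response-rate slope equal ``target_rr_slope`` percentage points per
    question at ``base_rr`` (derivative of the logistic:
    ``slope = 100·β·p(1−p)``).
    """

    base_rr: float = 0.80
    target_rr_slope: float = -1.9  # % points per question, local at base_rr
    beta_questions: float | None = None
    # time-of-day log-odds offsets by age group (kept near mean zero)
    tod_offsets: dict = field(
        default_factory=lambda: {
            "older": {"morning": -0.08, "afternoon": -0.08, "evening": 0.16},
            "younger": {"morning": -0.02, "afternoon": 0.04, "evening": -0.02},
        }
    )
    beta_home: float = 0.8  # per unit at-home fraction
    beta_cp: float = 0.5  # per unit change-point nearness
    beta_activity: float = 0.2  # per SD of activity level
    # reference (centering) values for the context covariates, matching the
    # realized distributions of the default behavior model at prompt times
    home_frac_ref: float = 0.89
    home_frac_sd: float = 0.28
    cp_ref: float = 0.37
    cp_sd: float = 0.29
    activity_ref: float = 0.64
    activity_sd: float = 0.30
    intercept_sd: float = 0.2  # per-participant random intercept (log-odds)
    reissue_response_p: float = 0.7  # geometric attempt-of-response parameter
    # answer quality
    careless_start: float = 0.35
    careless_drift_per_day: float = 0.012
    variance_shrink: float = 0.7
    noise_sd: float = 1.1  # on the normalized 1-5 scale, start of study
    mode_sd: float = 0.4  # participant mode spread around the study center
    q_dropout: float = 0.02  # per-question skip after the first answer
    category_centers: dict = field(
        default_factory=lambda: {"sharp": 3.5, "fatigue": 4.2, "stress": 4.4}
    )
    intervention_drift: float = 0.023  # sharp drift per response index
    observational_drift: float = 0.005

    def logit_variance_extra(self) -> float:
        """Variance of the non-question random terms of the response logit."""
        return (
            self.intercept_sd**2
            + (self.beta_home * self.home_frac_sd) ** 2
            + (self.beta_cp * self.cp_sd) ** 2
            + self.beta_activity**2  # activity enters standardized
        )


@dataclass(frozen=True)
class GeneratorConfig:
    studies: tuple[StudyDesign, ...]
    behavior: BehaviorConfig = BehaviorConfig()
    response: ResponseModelConfig = ResponseModelConfig()

    def manifests(self) -> dict[str, StudyManifest]:
        return {s.study_id: s.manifest() for s in self.studies}

    def mean_questions(self) -> float:
        """Prompt-weighted mean question count (the centering point Q̄)."""
        w = np.array(
            [s.n_participants * s.duration_days * len(s.time_blocks) for s in self.studies],
            float,
        )
        q = np.array([s.n_questions for s in self.studies], float)
        return float((w * q).sum() / w.sum())

    def calibrated_beta_q(self) -> float:
        """Question-count log-odds effect calibrated to the target RR slope.

        Solves for the β that makes the prompt-weighted least-squares slope
        of the marginal response-rate curve (in % points per question),
        evaluated at this design's question counts, equal
        ``response.target_rr_slope``.  The marginal curve accounts for the
        other random logit terms with the standard logistic-normal
        attenuation ``σ(x/√(1+0.346·v))``.
        """
        r = self.response
        if r.beta_questions is not None:
            return r.beta_questions
        from scipy.optimize import brentq
        from scipy.special import expit

        w = np.array(
            [s.n_participants * s.duration_days * len(s.time_blocks) for s in self.studies],
            float,
        )
        q = np.array([s.n_questions for s in self.studies], float)
        qbar = (w * q).sum() / w.sum()
        qc = q - qbar
        b0 = math.log(r.base_rr / (1.0 - r.base_rr))
        c = math.sqrt(1.0 + 0.346 * r.logit_variance_extra())
        if float((w * qc * qc).sum()) == 0.0:
            # degenerate design (single question count): local derivative,
            # attenuation-corrected
            p = r.base_rr
            return c * r.target_rr_slope / (100.0 * p * (1.0 - p))

        def slope(beta: float) -> float:
            rr = 100.0 * expit((b0 + beta * qc) / c)
            return float((w * qc * rr).sum() / (w * qc * qc).sum())

        return float(brentq(lambda b: slope(b) - r.target_rr_slope, -1.0, -1e-6))


def default_config() -> GeneratorConfig:
    """The default nine-study cohort (200 participants).

    Studies mirror the spread seen in multi-study EMA work: question counts
    from 7 to 15, two intervention studies with lower starting "sharp"
    levels, one ambient-sensor (smart-home) study, two small younger-adult
    cohorts on a 0–10 scale, and participant counts in proportion to a
    454-participant cohort scaled down to 200.
    """
    studies = (
        StudyDesign("mc", 15, "older", "observational", 8, 14, 1, 5, level_offset=-0.6),
        StudyDesign("func", 11, "older", "observational", 11, 21, 1, 7, level_offset=-0.3),
        StudyDesign("mn", 20, "older", "intervention", 15, 14, 1, 5, level_offset=-0.8),
        StudyDesign("bb", 81, "older", "intervention", 12, 14, 1, 7, level_offset=-0.7),
        StudyDesign("cs", 39, "older", "observational", 11, 14, 1, 5, level_offset=0.4),
        StudyDesign("sh", 19, "older", "observational", 7, 14, 1, 5,
                    modality="ambient", level_offset=0.2),
        StudyDesign("dyad", 4, "older", "observational", 8, 14, 1, 7,
                    max_reissues=2, level_offset=0.8),
        StudyDesign("gsur1", 3, "younger", "observational", 12, 14, 0, 10,
                    level_offset=0.0),
        StudyDesign("gsur2", 8, "younger", "observational", 15, 14, 0, 10,
                    level_offset=-0.2),
    )
    return GeneratorConfig(studies=studies)


def small_config(
    n_participants: int = 4, duration_days: int = 7
) -> GeneratorConfig:
    """A miniature two-study cohort for demos and quick tests."""
    studies = (
        StudyDesign("alpha", n_participants, "older", "intervention", 8,
                    duration_days, 1, 5, level_offset=-0.5),
        StudyDesign("beta", n_participants, "younger", "observational", 12,
                    duration_days, 0, 10, level_offset=0.5),
    )
    return GeneratorConfig(studies=studies)


@dataclass
class ParticipantTruth:
    """Ground truth behind one participant's streams and responses."""

    home_lat: float
    home_lon: float
    away_intervals: list[tuple[float, float]]  # epoch seconds
    transitions: np.ndarray  # epoch seconds of true activity change points
    p_respond: np.ndarray  # per prompt
    careless_by_prompt: np.ndarray
    modes_norm: dict[str, float]  # per category, normalized scale
    intercept: float


@dataclass
class ParticipantData:
    participant_id: str
    study_id: str
    start: dt.datetime
    sessions: list[ResponseSession]
    accel_times: np.ndarray  # epoch seconds
    accel_mag: np.ndarray
    fix_times: np.ndarray
    fix_lat: np.ndarray
    fix_lon: np.ndarray
    ambient: AmbientEvents | None
    truth: ParticipantTruth


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    seed: int
    participants: list[ParticipantData]

    def manifests(self) -> dict[str, StudyManifest]:
        return self.config.manifests()

    def all_sessions(self) -> list[ResponseSession]:
        return [s for p in self.participants for s in p.sessions]


def _epoch(d: dt.datetime) -> float:
    return d.replace(tzinfo=dt.timezone.utc).timestamp()


def schedule_prompts(
    study: StudyDesign, start: dt.datetime, rng: np.random.Generator
) -> list[dt.datetime]:
    """One prompt per time block per day, uniformly within the block."""
    out = []
    for day in range(study.duration_days):
        date = (start + dt.timedelta(days=day)).date()
        for (s, e) in study.time_blocks:
            lo = dt.datetime.combine(date, s)
            hi = dt.datetime.combine(date, e)
            span = (hi - lo).total_seconds()
            out.append(lo + dt.timedelta(seconds=float(rng.uniform(0, span))))
    return out


def _draw_bouts(
    n_days: int,
    per_day: float,
    window: tuple[float, float],
    dur_sampler,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Non-overlapping (start_min, end_min) bouts on the absolute minute axis."""
    bouts: list[tuple[float, float]] = []
    for day in range(n_days):
        n = rng.poisson(per_day)
        starts = np.sort(rng.uniform(window[0], window[1], size=n)) + day * 1440.0
        for s in starts:
            d = dur_sampler()
            if bouts and s <= bouts[-1][1] + 5.0:
                continue
            bouts.append((float(s), float(min(s + d, (day + 1) * 1440.0 - 1))))
    return bouts


def simulate_behavior(
    study: StudyDesign,
    start: dt.datetime,
    rng: np.random.Generator,
    behavior: BehaviorConfig,
):
    """Simulate one participant's mobility and sensor streams.

    A two-state home/away semi-Markov trajectory on a per-minute grid;
    location fixes every 5 minutes (GPS jitter at home, away bouts displaced
    ≥200 m); per-minute acceleration magnitudes elevated while away, during
    independent at-home activity bouts, and around transitions; for the
    ambient modality, motion events while home (rate depending on the
    activity state) and door open/close events at every home/away boundary.
    Every boundary is recorded as a true change point.
    """
    b = behavior
    n_min = study.duration_days * 1440
    t0 = _epoch(start.replace(hour=0, minute=0, second=0, microsecond=0))

    home_lat = b.home_lat + float(rng.uniform(-0.05, 0.05))
    home_lon = b.home_lon + float(rng.uniform(-0.05, 0.05))

    away_bouts = _draw_bouts(
        study.duration_days,
        b.away_bouts_per_day,
        b.bout_window,
        lambda: float(np.clip(rng.lognormal(math.log(b.bout_median_min), b.bout_sigma), 10, 240)),
        rng,
    )
    active_bouts = _draw_bouts(
        study.duration_days,
        b.active_bouts_per_day,
        (7 * 60, 22 * 60),
        lambda: float(rng.uniform(*b.active_bout_min)),
        rng,
    )

    minutes = np.arange(n_min, dtype=float)
    away = np.zeros(n_min, dtype=bool)
    for s, e in away_bouts:
        away[int(s): int(e) + 1] = True
    active = np.zeros(n_min, dtype=bool)
    for s, e in active_bouts:
        active[int(s): int(e) + 1] = True

    mean = np.full(n_min, b.accel_home_idle[0])
    sd = np.full(n_min, b.accel_home_idle[1])
    m = active & ~away
    mean[m], sd[m] = b.accel_home_active
    mean[away], sd[away] = b.accel_away
    # true activity transitions: every change of the idle/active/away state,
    # i.e. away-bout boundaries plus at-home activity-bout boundaries
    state = 2 * away.astype(np.int8) + m.astype(np.int8)
    transitions_min = (np.flatnonzero(np.diff(state)) + 1).astype(float)
    hw = int(b.transition_halfwidth_min)
    for tmin in transitions_min:
        lo = max(int(tmin) - hw, 0)
        hi = min(int(tmin) + hw + 1, n_min)
        mean[lo:hi], sd[lo:hi] = b.accel_transition
    accel = np.clip(rng.normal(mean, sd), 0.0, None)
    accel_times = t0 + minutes * 60.0

    # location fixes every fix_interval_min
    fix_idx = np.arange(0, n_min, int(b.fix_interval_min))
    jitter_deg = b.gps_jitter_m / 111_195.0
    fix_lat = home_lat + rng.normal(0, jitter_deg, size=len(fix_idx))
    fix_lon = home_lon + rng.normal(
        0, jitter_deg / math.cos(math.radians(home_lat)), size=len(fix_idx)
    )
    for s, e in away_bouts:
        dist = float(rng.uniform(*b.away_displacement_m))
        theta = float(rng.uniform(0, 2 * math.pi))
        dlat = dist * math.cos(theta) / 111_195.0
        dlon = dist * math.sin(theta) / (111_195.0 * math.cos(math.radians(home_lat)))
        sel = (fix_idx >= s) & (fix_idx <= e)
        fix_lat[sel] += dlat
        fix_lon[sel] += dlon
    fix_times = t0 + fix_idx * 60.0

    ambient = None
    if study.modality == "ambient":
        counts = rng.poisson(
            np.where(away, 0.0, np.where(active, b.motion_rate_active, b.motion_rate_idle))
        )
        motion = np.repeat(accel_times, counts) + rng.uniform(0, 60, size=int(counts.sum()))
        ev_t: list[float] = list(motion)
        ev_kind: list[str] = ["motion"] * len(motion)
        ev_state: list[str] = ["on"] * len(motion)
        ev_id: list[str] = ["m1"] * len(motion)
        for s, e in away_bouts:
            for tm, burst in ((s, False), (e, True)):
                ev_t.extend([t0 + tm * 60.0, t0 + tm * 60.0 + 30.0])
                ev_kind.extend(["door", "door"])
                ev_state.extend(["open", "closed"])
                ev_id.extend(["d1", "d1"])
                if burst:  # entry movement right after returning home
                    for off in np.sort(rng.uniform(35, 90, size=int(rng.integers(1, 4)))):
                        ev_t.append(t0 + tm * 60.0 + float(off))
                        ev_kind.append("motion")
                        ev_state.append("on")
                        ev_id.append("m1")
        order = np.argsort(ev_t, kind="stable")
        ambient = AmbientEvents(
            times=np.asarray(ev_t, float)[order],
            kinds=np.asarray(ev_kind, object)[order],
            states=np.asarray(ev_state, object)[order],
            sensor_ids=np.asarray(ev_id, object)[order],
        )

    truth = ParticipantTruth(
        home_lat=home_lat,
        home_lon=home_lon,
        away_intervals=[(t0 + s * 60.0, t0 + e * 60.0) for s, e in away_bouts],
        transitions=t0 + transitions_min * 60.0,
        p_respond=np.empty(0),
        careless_by_prompt=np.empty(0),
        modes_norm={},
        intercept=0.0,
    )
    return accel_times, accel, fix_times, fix_lat, fix_lon, ambient, truth


def _norm_to_raw(v: float, study: StudyDesign, inverted: bool) -> float:
    """Map a normalized value back onto the study's integer raw grid."""
    vv = 6.0 - v if inverted else v
    raw = study.raw_min + (vv - 1.0) * (study.raw_max - study.raw_min) / 4.0
    return float(np.clip(round(raw), study.raw_min, study.raw_max))


def simulate_responses(
    study: StudyDesign,
    participant_id: str,
    prompt_times: Sequence[dt.datetime],
    truth: ParticipantTruth,
    accel_times: np.ndarray,
    accel_mag: np.ndarray,
    rng: np.random.Generator,
    response: ResponseModelConfig,
    mean_questions: float,
    beta_q: float | None = None,
) -> list[ResponseSession]:
    """Draw response sessions for scheduled prompts given true behavior.

    The response probability is a logistic function of centered covariates
    (time of day, question count, true at-home fraction, true change-point
    nearness, true standardized activity); answered values follow the
    participant's per-category mode with the careless probability for that
    elapsed day and otherwise add discretized noise whose spread shrinks
    over the study.  Questions after the first answered one drop out
    independently with a small probability, yielding partial sessions.
    """
    r = response
    # participant modes per category (normalized scale, snapped to the raw grid)
    modes_norm: dict[str, float] = {}
    modes_raw: dict[str, float] = {}
    inverted = {"sharp": False, "fatigue": True, "stress": True, "other": False}
    for cat, center in r.category_centers.items():
        target = float(
            np.clip(center + study.level_offset + rng.normal(0, r.mode_sd), 1.0, 5.0)
        )
        raw = _norm_to_raw(target, study, inverted[cat])
        modes_raw[cat] = raw
        modes_norm[cat] = normalize_likert(raw, study.raw_min, study.raw_max, inverted[cat])
    modes_raw["other"] = _norm_to_raw(3.5, study, False)
    modes_norm["other"] = normalize_likert(
        modes_raw["other"], study.raw_min, study.raw_max, False
    )

    intercept = float(rng.normal(0, r.intercept_sd))
    drift = (
        r.intervention_drift if study.purpose == "intervention" else r.observational_drift
    )
    if beta_q is None:
        beta_q = r.target_rr_slope / (100.0 * r.base_rr * (1.0 - r.base_rr))
    b0 = math.log(r.base_rr / (1.0 - r.base_rr))
    t0_day = prompt_times[0].date()

    away = truth.away_intervals
    trans = np.asarray(truth.transitions, float)
    acc_cum = np.concatenate([[0.0], np.cumsum(accel_mag)])

    categories = ["sharp", "fatigue", "stress"] + ["other"] * (study.n_questions - 3)
    sessions: list[ResponseSession] = []
    p_list, c_list = [], []
    n_responded = 0
    for pt in prompt_times:
        t_s = _epoch(pt)
        w0 = t_s - 30 * 60.0
        # true context over the 30-min window ending at the prompt
        away_s = 0.0
        for a, b in away:
            lo, hi = max(a, w0), min(b, t_s)
            if hi > lo:
                away_s += hi - lo
        home_frac = 1.0 - away_s / (30 * 60.0)
        lo_i = int(np.searchsorted(accel_times, w0, side="right"))
        hi_i = int(np.searchsorted(accel_times, t_s, side="right"))
        act = (acc_cum[hi_i] - acc_cum[lo_i]) / 30.0 if hi_i > lo_i else r.activity_ref
        if trans.size:
            delta_min = float(np.min(np.abs(trans - t_s))) / 60.0
            cp = math.exp(-delta_min / 15.0)
        else:
            cp = 0.0
        tod = PromptEvent(
            participant_id=participant_id, study_id=study.study_id, scheduled_time=pt
        ).tod_stratum
        logit = (
            b0
            + intercept
            + r.tod_offsets[study.age_group][tod]
            + beta_q * (study.n_questions - mean_questions)
            + r.beta_home * (home_frac - r.home_frac_ref)
            + r.beta_cp * (cp - r.cp_ref)
            + r.beta_activity * (act - r.activity_ref) / r.activity_sd
        )
        p = 1.0 / (1.0 + math.exp(-logit))
        p_list.append(p)
        elapsed = (pt.date() - t0_day).days
        careless_p = float(np.clip(r.careless_start + r.careless_drift_per_day * elapsed, 0, 1))
        c_list.append(careless_p)
        responded = bool(rng.random() < p)
        if responded:
            attempts = int(min(rng.geometric(r.reissue_response_p), study.max_reissues))
        else:
            attempts = study.max_reissues
        answers: list[LikertResponse] = []
        if responded:
            n_responded += 1
            frac = elapsed / max(study.duration_days - 1, 1)
            sd_t = r.noise_sd * (1.0 + (r.variance_shrink - 1.0) * frac)
            for qi, cat in enumerate(categories):
                if qi > 0 and rng.random() < r.q_dropout:
                    continue
                if rng.random() < careless_p:
                    raw = modes_raw[cat]
                else:
                    v = modes_norm[cat] + float(rng.normal(0, sd_t))
                    if cat == "sharp":
                        v += drift * n_responded
                    raw = _norm_to_raw(float(np.clip(v, 1.0, 5.0)), study, inverted[cat])
                answers.append(
                    LikertResponse(
                        question_id=f"q{qi + 1}",
                        category=cat,
                        raw_value=raw,
                        raw_min=study.raw_min,
                        raw_max=study.raw_max,
                        inverted=inverted[cat],
                    )
                )
        prompt = PromptEvent(
            participant_id=participant_id,
            study_id=study.study_id,
            scheduled_time=pt,
            attempt_count=attempts,
            elapsed_day=(pt.date() - t0_day).days,
        )
        sessions.append(
            ResponseSession(
                prompt=prompt, answers=tuple(answers), n_questions_asked=study.n_questions
            )
        )
    truth.p_respond = np.asarray(p_list)
    truth.careless_by_prompt = np.asarray(c_list)
    truth.modes_norm = modes_norm
    truth.intercept = intercept
    return sessions


def generate_dataset(config: GeneratorConfig, seed: int) -> SyntheticDataset:
    """Generate the full multi-study dataset deterministically from a seed."""
    root = np.random.SeedSequence(seed)
    mean_q = config.mean_questions()
    beta_q = config.calibrated_beta_q()
    participants: list[ParticipantData] = []
    for study, ss_study in zip(config.studies, root.spawn(len(config.studies))):
        for k, ss in enumerate(ss_study.spawn(study.n_participants)):
            rng = np.random.default_rng(ss)
            pid = f"{study.study_id}-p{k + 1:03d}"
            start = dt.datetime.combine(
                _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 7))), dt.time(0, 0)
            )
            accel_t, accel_m, fix_t, fix_lat, fix_lon, ambient, truth = simulate_behavior(
                study, start, rng, config.behavior
            )
            prompt_times = schedule_prompts(study, start, rng)
            sessions = simulate_responses(
                study, pid, prompt_times, truth, accel_t, accel_m, rng,
                config.response, mean_q, beta_q,
            )
            participants.append(
                ParticipantData(
                    participant_id=pid,
                    study_id=study.study_id,
                    start=start,
                    sessions=sessions,
                    accel_times=accel_t,
                    accel_mag=accel_m,
                    fix_times=fix_t,
                    fix_lat=fix_lat,
                    fix_lon=fix_lon,
                    ambient=ambient,
                    truth=truth,
                )
            )
    return SyntheticDataset(config=config, seed=seed, participants=participants)


def _iso(t_s: float) -> str:
    return dt.datetime.fromtimestamp(t_s, dt.timezone.utc).replace(tzinfo=None).isoformat()


def write_dataset(
    dataset: SyntheticDataset, outdir: str | Path, include_streams: bool = True
) -> dict[str, Path]:
    """Write the dataset in the log schemas the ingestion layer consumes.

    Emits ``manifest.yaml``, ``prompts.csv`` (one row per prompt attempt and
    question), optional per-modality stream CSVs, and ``ground_truth.json``.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    man_path = outdir / "manifest.yaml"
    with open(man_path, "w") as fh:
        yaml.safe_dump(
            {"studies": [m.to_dict() for m in dataset.manifests().values()]}, fh
        )
    paths["manifest"] = man_path

    rows = []
    for p in dataset.participants:
        for i, s in enumerate(p.sessions):
            answered = {a.question_id: a for a in s.answers}
            study = dataset.manifests()[p.study_id]
            prompt_id = f"{p.participant_id}-{i:04d}"
            for attempt in range(1, s.prompt.attempt_count + 1):
                final = attempt == s.prompt.attempt_count
                for qi in range(study.n_questions):
                    qid = f"q{qi + 1}"
                    a = answered.get(qid) if final else None
                    rows.append(
                        {
                            "study_id": p.study_id,
                            "participant_id": p.participant_id,
                            "prompt_id": prompt_id,
                            "attempt": attempt,
                            "scheduled_time": s.prompt.scheduled_time.isoformat(),
                            "question_id": qid,
                            "category": a.category if a else "",
                            "raw_value": a.raw_value if a else "",
                            "raw_min": a.raw_min if a else "",
                            "raw_max": a.raw_max if a else "",
                            "inverted": a.inverted if a else "",
                        }
                    )
    import pandas as pd

    prompts_path = outdir / "prompts.csv"
    pd.DataFrame(rows, columns=PROMPT_LOG_COLUMNS).to_csv(prompts_path, index=False)
    paths["prompts"] = prompts_path

    if include_streams:
        streams = outdir / "streams"
        streams.mkdir(exist_ok=True)
        for p in dataset.participants:
            pid = p.participant_id
            pd.DataFrame(
                {
                    "timestamp": [_iso(t) for t in p.accel_times],
                    "magnitude": np.round(p.accel_mag, 4),
                }
            ).to_csv(streams / f"{pid}_accel.csv", index=False)
            pd.DataFrame(
                {
                    "timestamp": [_iso(t) for t in p.fix_times],
                    "latitude": np.round(p.fix_lat, 6),
                    "longitude": np.round(p.fix_lon, 6),
                }
            ).to_csv(streams / f"{pid}_location.csv", index=False)
            if p.ambient is not None:
                pd.DataFrame(
                    {
                        "timestamp": [_iso(t) for t in p.ambient.times],
                        "sensor_id": p.ambient.sensor_ids,
                        "kind": p.ambient.kinds,
                        "state": p.ambient.states,
                    }
                ).to_csv(streams / f"{pid}_ambient.csv", index=False)
        paths["streams"] = streams

    truth_path = outdir / "ground_truth.json"
    truth = {
        p.participant_id: {
            "home": [p.truth.home_lat, p.truth.home_lon],
            "away_intervals": [[_iso(a), _iso(b)] for a, b in p.truth.away_intervals],
            "transitions": [_iso(t) for t in p.truth.transitions],
            "p_respond": list(np.round(p.truth.p_respond, 5)),
            "modes_norm": p.truth.modes_norm,
        }
        for p in dataset.participants
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    paths["ground_truth"] = truth_path
    return paths
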