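"""Orchestration: generate → extract markers → metrics → compare.

A single reproducible run takes a generator config (or pre-existing event
logs), extracts the behavior-context features for every prompt, computes the
response-rate/quality statistics and context correlations, runs the
cross-study DTW/ARIMA comparison, and writes a JSON report plus a
human-readable markdown rendering of the same numbers.  Given the same seed
and config the report is identical between runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ema_context import response_metrics as rm
from ema_context import sensor_markers as sm
from ema_context import study_comparison as sc
from ema_context import synthetic_data as sd
from ema_context.ema_core import ResponseSession

__all__ = [
    "RunConfig",
    "extract_features",
    "compute_metrics",
    "compare_studies",
    "run_pipeline",
    "series_by_study",
    "render_markdown",
]

log = logging.getLogger("ema_context")


@dataclass
class RunConfig:
    """Parameters of one end-to-end run (serialized for provenance)."""

    seed: int = 0
    outdir: str | None = None
    small: bool = False  # use the miniature demo cohort
    cp_bin_min: float = 5.0  # binning of the activity series for change points
    cp_tau_min: float = 15.0
    dtw_max_pairs: int | None = 1500
    dtw_min_len: int = 5
    horizon: int = 48
    write_streams: bool = False
    generator: sd.GeneratorConfig | None = None

    def resolve_generator(self) -> sd.GeneratorConfig:
        if self.generator is not None:
            return self.generator
        return sd.small_config() if self.small else sd.default_config()


def _participant_features(
    p: sd.ParticipantData, cfg: RunConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(activity, home_frac, cp_nearness) arrays, one entry per prompt."""
    prompt_t = np.array(
        [sd._epoch(s.prompt.scheduled_time) for s in p.sessions], float
    )
    bin_s = cfg.cp_bin_min * 60.0
    n_prompts = len(prompt_t)
    if p.ambient is None and len(p.accel_times) == 0:
        nan = np.full(n_prompts, sm.CONTEXT_UNAVAILABLE)
        return nan, nan.copy(), nan.copy()
    if p.ambient is not None:
        away = sm.out_of_home_intervals(p.ambient)
        activity = np.array(
            [sm.activity_level_ambient(p.ambient, t) for t in prompt_t]
        )
        home = np.array([sm.at_home_fraction_ambient(away, t) for t in prompt_t])
        motion = p.ambient.motion_on_times()
        if len(p.accel_times):
            t0, t1 = p.accel_times[0], p.accel_times[-1]
        else:
            t0, t1 = p.ambient.times[0], p.ambient.times[-1]
        edges = np.arange(t0, t1 + bin_s, bin_s)
        series, _ = np.histogram(motion, bins=edges)
        bin_times = edges[:-1]
    else:
        activity = np.array(
            [sm.activity_level_watch(p.accel_times, p.accel_mag, t) for t in prompt_t]
        )
        if len(p.fix_times):
            fix_dt = pd.to_datetime(p.fix_times, unit="s")
            try:
                home_loc = sm.infer_home(fix_dt, p.fix_lat, p.fix_lon)
                home = np.array(
                    [
                        sm.at_home_fraction(p.fix_times, p.fix_lat, p.fix_lon, home_loc, t)
                        for t in prompt_t
                    ]
                )
            except sm.HomeUndeterminableError:
                home = np.full(n_prompts, sm.CONTEXT_UNAVAILABLE)
        else:
            home = np.full(n_prompts, sm.CONTEXT_UNAVAILABLE)
        k = int(cfg.cp_bin_min)
        n = (len(p.accel_mag) // k) * k
        series = p.accel_mag[:n].reshape(-1, k).mean(axis=1)
        bin_times = p.accel_times[:n:k]
    cps = sm.detect_change_points(series, times=bin_times)
    cp_near = np.array(
        [sm.cp_nearness(t, cps, tau_min=cfg.cp_tau_min) for t in prompt_t]
    )
    return activity, home, cp_near


def extract_features(dataset: sd.SyntheticDataset, cfg: RunConfig) -> pd.DataFrame:
    """Per-prompt behavior-context feature table for a whole dataset.

    Activity level is additionally z-scored within each study
    (``activity_z``) so watch (g·min⁻¹) and ambient (motion counts) scales
    can be pooled in one correlation.
    """
    manifests = dataset.manifests()
    rows = []
    for p in dataset.participants:
        activity, home, cp_near = _participant_features(p, cfg)
        for s, a, h, c in zip(p.sessions, activity, home, cp_near):
            rows.append(
                {
                    "study_id": p.study_id,
                    "participant_id": p.participant_id,
                    "time": s.prompt.scheduled_time,
                    "age_group": manifests[p.study_id].age_group,
                    "n_questions": manifests[p.study_id].n_questions,
                    "elapsed_day": s.prompt.elapsed_day,
                    "tod": s.prompt.tod_stratum,
                    "dow": s.prompt.dow_stratum,
                    "responded": s.responded,
                    "compliance": s.compliance,
                    "activity": a,
                    "home_frac": h,
                    "cp_near": c,
                }
            )
    df = pd.DataFrame(rows)
    df["activity_z"] = df.groupby("study_id")["activity"].transform(
        lambda x: (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    )
    return df


class LoadedDataset:
    """Duck-typed dataset (like the synthetic one) built from event logs."""

    def __init__(self, manifests: dict, participants: list):
        self._manifests = manifests
        self.participants = participants

    def manifests(self) -> dict:
        return self._manifests

    def all_sessions(self) -> list[ResponseSession]:
        return [s for p in self.participants for s in p.sessions]


def load_dataset(manifests: dict, event_data, streams_dir: str | Path | None) -> LoadedDataset:
    """Assemble a dataset from ingested sessions plus per-participant stream CSVs.

    Stream files are looked up as ``{pid}_accel.csv``, ``{pid}_location.csv``
    and ``{pid}_ambient.csv`` under ``streams_dir``; participants without
    streams get NaN ("context unavailable") features downstream.
    """
    streams = Path(streams_dir) if streams_dir is not None else None
    participants = []
    empty = np.empty(0)
    for pid, sessions in event_data.by_participant().items():
        accel_t = accel_m = fix_t = fix_lat = fix_lon = empty
        ambient = None
        if streams is not None:
            f = streams / f"{pid}_accel.csv"
            if f.exists():
                accel_t, accel_m = sm.read_accel_stream(f)
            f = streams / f"{pid}_location.csv"
            if f.exists():
                fix_t, fix_lat, fix_lon, _ = sm.read_location_stream(f)
            f = streams / f"{pid}_ambient.csv"
            if f.exists():
                ambient = sm.read_ambient_stream(f)
        participants.append(
            sd.ParticipantData(
                participant_id=pid,
                study_id=sessions[0].prompt.study_id,
                start=None,
                sessions=sessions,
                accel_times=accel_t,
                accel_mag=accel_m,
                fix_times=fix_t,
                fix_lat=fix_lat,
                fix_lon=fix_lon,
                ambient=ambient,
                truth=None,
            )
        )
    return LoadedDataset(manifests, participants)


def compute_metrics(
    sessions: list[ResponseSession],
    features: pd.DataFrame,
    manifests,
) -> dict:
    """Response-rate, quality, trend, and context-correlation sections."""
    out: dict = {}
    out["n_prompts"] = len(sessions)
    out["n_participants"] = len({s.prompt.participant_id for s in sessions})
    out["response_rate_pct"] = rm.response_rate(sessions)
    out["completeness_pct"] = rm.completeness(sessions)
    responded = [s for s in sessions if s.responded]
    out["incomplete_session_pct"] = rm.incomplete_share(
        sum(1 for s in responded if not s.complete), len(responded)
    )
    out["rate_table"] = rm.rate_table(sessions, manifests).as_dict()
    q = rm.quality_report(sessions)
    out["quality"] = {
        "category_mean": q.category_mean,
        "category_variance": q.category_variance,
        "careless_pct": q.careless_pct,
        "interparticipant_variance": q.interparticipant_variance,
        "careless_aggregation": q.careless_aggregation,
        "carelessness_change_pct_points": q.half_split.d_careless_pct,
        "variance_change": q.half_split.d_variance,
        "p_careless": q.half_split.p_careless,
        "p_variance": q.half_split.p_variance,
        "n_half_split": q.half_split.n_participants,
        "n_half_split_excluded": q.half_split.n_excluded,
    }
    # RR vs question count across participants
    per_pid = features.groupby("participant_id").agg(
        rr=("responded", "mean"), n_q=("n_questions", "first")
    )
    fit_q = rm.trend_fit(per_pid["n_q"], 100.0 * per_pid["rr"])
    out["rr_vs_questions"] = dataclasses.asdict(fit_q)
    # RR vs elapsed study day (pooled across participants)
    per_day = features.groupby("elapsed_day")["responded"].mean()
    fit_d = rm.trend_fit(per_day.index.to_numpy(float), 100.0 * per_day.to_numpy())
    out["rr_vs_elapsed_day"] = dataclasses.asdict(fit_d)
    out["context_correlations"] = {}
    for name, col in [
        ("activity", "activity_z"),
        ("at_home", "home_frac"),
        ("cp_nearness", "cp_near"),
    ]:
        r, p = rm.context_correlation(features["compliance"], features[col])
        out["context_correlations"][name] = {
            "r": r,
            "p": p,
            "n": int((~features[col].isna()).sum()),
        }
    return out


def series_by_study(
    sessions: list[ResponseSession],
) -> dict[str, dict[str, dict[str, list[float]]]]:
    """Chronological normalized response series per study/participant/category."""
    out: dict[str, dict[str, dict[str, list[float]]]] = {}
    for s in sorted(sessions, key=lambda s: (s.prompt.participant_id, s.prompt.scheduled_time)):
        for a in s.answers:
            if a.category in rm.WELLBEING_CATEGORIES:
                out.setdefault(s.prompt.study_id, {}).setdefault(
                    s.prompt.participant_id, {}
                ).setdefault(a.category, []).append(a.norm_value)
    return out


def compare_studies(
    sessions: list[ResponseSession],
    manifests,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """DTW within/between summary, per-category ARIMA fits, group trends."""
    groups = series_by_study(sessions)
    summary = sc.within_between_summary(
        groups, min_len=cfg.dtw_min_len, max_pairs=cfg.dtw_max_pairs, rng=rng
    )
    out: dict = {
        "dtw": {
            "within_mean": summary.within_mean,
            "within_sd": summary.within_sd,
            "between_mean": summary.between_mean,
            "between_sd": summary.between_sd,
            "pct_increase": summary.pct_increase,
            "per_category": {
                c: dict(
                    zip(("within_mean", "within_sd", "between_mean", "between_sd"), v)
                )
                for c, v in summary.per_category.items()
            },
            "n_within_pairs": summary.n_within_pairs,
            "n_between_pairs": summary.n_between_pairs,
        }
    }
    out["arima"] = {}
    for cat in rm.WELLBEING_CATEGORIES:
        series = [
            cats[cat]
            for pids in groups.values()
            for cats in pids.values()
            if cat in cats
        ]
        agg = sc.aggregate_series(series, horizon=cfg.horizon)
        fit = sc.fit_arima(agg) if len(agg) >= 20 else None
        out["arima"][cat] = dataclasses.asdict(fit) if fit else {"skipped": "short series"}
    sharp_by_purpose: dict[str, list] = {}
    for study, pids in groups.items():
        purpose = manifests[study].purpose
        for cats in pids.values():
            if "sharp" in cats:
                sharp_by_purpose.setdefault(purpose, []).append(cats["sharp"])
    gt = sc.group_trend(sharp_by_purpose, horizon=cfg.horizon)
    out["group_trend_sharp"] = {
        "overall": dataclasses.asdict(gt.overall),
        "groups": {g: dataclasses.asdict(f) for g, f in gt.fits.items()},
        "slope_diffs": gt.slope_diffs,
        "intercept_diffs": gt.intercept_diffs,
    }
    return out


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _md_section(d: dict, indent: int = 0) -> list[str]:
    lines = []
    for k, v in d.items():
        if isinstance(v, dict):
            lines.append(f"{'  ' * indent}- **{k}**")
            lines.extend(_md_section(v, indent + 1))
        else:
            if isinstance(v, float):
                v = f"{v:.4g}"
            lines.append(f"{'  ' * indent}- {k}: {v}")
    return lines


def render_markdown(report: dict) -> str:
    """Render the JSON report as markdown; every number comes from the JSON."""
    lines = ["# EMA cross-study analysis report", ""]
    for section, content in report.items():
        lines.append(f"## {section}")
        if isinstance(content, dict):
            lines.extend(_md_section(content))
        else:
            lines.append(str(content))
        lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run generate → markers → metrics → compare; return (and write) the report."""
    t_start = time.time()
    gen = cfg.resolve_generator()
    log.info("stage synth: generating %d studies (seed %d)", len(gen.studies), cfg.seed)
    dataset = sd.generate_dataset(gen, cfg.seed)
    sessions = dataset.all_sessions()
    manifests = dataset.manifests()
    log.info("stage synth: %d participants, %d prompts", len(dataset.participants), len(sessions))
    log.info("stage markers: extracting context features")
    features = extract_features(dataset, cfg)
    log.info("stage markers: %d feature rows", len(features))
    log.info("stage metrics: computing response statistics")
    metrics = compute_metrics(sessions, features, manifests)
    log.info("stage compare: DTW / ARIMA / trends")
    rng = np.random.default_rng(cfg.seed + 1)
    comparison = compare_studies(sessions, manifests, cfg, rng=rng)
    report = {
        "run": {
            "seed": cfg.seed,
            "n_studies": len(gen.studies),
            "n_participants": len(dataset.participants),
            "n_prompts": len(sessions),
            "elapsed_s": round(time.time() - t_start, 2),
            "config": {
                k: v
                for k, v in dataclasses.asdict(cfg).items()
                if k not in ("generator",)
            },
        },
        "metrics": metrics,
        "comparison": comparison,
    }
    report = _jsonable(report)
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        (outdir / "report.md").write_text(render_markdown(report))
        if cfg.write_streams:
            sd.write_dataset(dataset, outdir / "data", include_streams=True)
        log.info("report written to %s", outdir)
    return report
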