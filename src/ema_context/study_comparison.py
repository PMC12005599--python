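"""Cross-study response-dynamics comparison: DTW, aggregation, ARIMA, trends.

Participants' chronological normalized response sequences (per question
category) are compared with dynamic time warping — an elastic alignment
distance suited to series that differ in length as well as values.  Average
DTW distance over same-study participant pairs (the within-study baseline)
is contrasted with the average over cross-study pairs, summarized as a
percent increase.

For the shape of responses over time, the mean response across participants
at each response index (first 48 responses) forms one aggregated series per
category, which is fit with an ARIMA(0,1,1) model — differencing absorbs the
slow trend, leaving a first-order moving-average term — and checked with the
Ljung-Box portmanteau test on residuals.  Group trend lines (e.g.
intervention vs observational studies) are least-squares fits of the
aggregated series against the response index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ema_context.response_metrics import TrendFit, trend_fit

__all__ = [
    "DtwSummary",
    "ArimaFit",
    "GroupTrends",
    "dtw_distance",
    "pct_increase",
    "within_between_summary",
    "aggregate_series",
    "fit_arima",
    "group_trend",
]

#: Participants with fewer responses than this contribute no DTW pairs.
MIN_SERIES_LEN = 5


@dataclass
class DtwSummary:
    """Within- vs between-study DTW distance summary.

    ``within_mean``/``between_mean`` average the per-category summaries;
    ``per_category`` holds ``(within_mean, within_sd, between_mean,
    between_sd)`` per question category, and ``per_study_within`` /
    ``per_pair_between`` give per-study and per-study-pair means per
    category.
    """

    within_mean: float
    within_sd: float
    between_mean: float
    between_sd: float
    pct_increase: float
    per_category: dict = field(default_factory=dict)
    per_study_within: dict = field(default_factory=dict)
    per_pair_between: dict = field(default_factory=dict)
    n_within_pairs: int = 0
    n_between_pairs: int = 0


@dataclass
class ArimaFit:
    """ARIMA fit summary with residual diagnostics."""

    order: tuple[int, int, int]
    ma1_coef: float
    ma1_p: float
    loglik: float
    aic: float
    bic: float
    ljung_box_p: float
    degenerate: bool = False


@dataclass
class GroupTrends:
    """Per-group aggregated-series trend lines and their offsets vs all."""

    fits: dict[str, TrendFit]
    overall: TrendFit
    slope_diffs: dict[str, float]
    intercept_diffs: dict[str, float]


def dtw_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Classic dynamic time warping distance between two series.

    Absolute-difference local cost, symmetric match/insert/delete steps, no
    warping-window constraint, unnormalized cumulative cost.  Zero iff an
    alignment of zero total cost exists (e.g. identical series, or one series
    obtained from the other by repeating values).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("dtw_distance undefined for empty series")
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n, m = len(a), len(b)
    inf = float("inf")
    prev = [inf] * (m + 1)
    prev[0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur = [inf] * (m + 1)
        for j in range(1, m + 1):
            c = abs(ai - b[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev = cur
    return prev[m]


def pct_increase(within_mean: float, between_mean: float) -> float:
    """Percent increase of the between-study over the within-study mean."""
    if within_mean <= 0:
        raise ValueError("within-study mean must be positive")
    return 100.0 * (between_mean - within_mean) / within_mean


def _pair_distances(
    series: list[tuple[str, Sequence[float]]],
    pairs: list[tuple[int, int]],
    max_pairs: int | None,
    rng: np.random.Generator | None,
) -> np.ndarray:
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    return np.array([dtw_distance(series[i][1], series[j][1]) for i, j in pairs])


def within_between_summary(
    series_by_study: Mapping[str, Mapping[str, Mapping[str, Sequence[float]]]],
    min_len: int = MIN_SERIES_LEN,
    max_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> DtwSummary:
    """Within- vs between-study DTW summary over participant pairs.

    Parameters
    ----------
    series_by_study
        ``{study_id: {participant_id: {category: values}}}`` with values the
        participant's chronological normalized responses for that category.
    min_len
        Participants with fewer responses are excluded (noise floor).
    max_pairs
        Optional cap per category and side; when exceeded, pairs are
        subsampled with ``rng`` (statistical summary unchanged in
        expectation, runtime bounded).

    Within-pair distances use all unordered same-study participant pairs,
    between-pair distances all cross-study pairs; the overall numbers
    average the per-category summaries.
    """
    if len(series_by_study) < 2:
        raise ValueError("need at least 2 studies")
    categories = sorted(
        {c for pids in series_by_study.values() for cats in pids.values() for c in cats}
    )
    per_category = {}
    per_study_within: dict[str, dict[str, float]] = {}
    per_pair_between: dict[str, dict[str, float]] = {}
    n_within = n_between = 0
    for cat in categories:
        series = []  # (study, values)
        for study, pids in sorted(series_by_study.items()):
            for pid in sorted(pids):
                vals = pids[pid].get(cat)
                if vals is not None and len(vals) >= min_len:
                    series.append((study, vals))
        studies = [s for s, _ in series]
        within_pairs, between_pairs = [], []
        for i in range(len(series)):
            for j in range(i + 1, len(series)):
                (within_pairs if studies[i] == studies[j] else between_pairs).append((i, j))
        for study in sorted(set(studies)):
            if sum(s == study for s in studies) < 2:
                warnings.warn(
                    f"study {study!r} has <2 usable participants for {cat}; "
                    "no within pairs", stacklevel=2,
                )
        if not within_pairs or not between_pairs:
            raise ValueError(f"category {cat!r}: missing within or between pairs")
        dw = _pair_distances(series, within_pairs, max_pairs, rng)
        db = _pair_distances(series, between_pairs, max_pairs, rng)
        per_category[cat] = (
            float(dw.mean()), float(dw.std()), float(db.mean()), float(db.std())
        )
        n_within += len(dw)
        n_between += len(db)
        # breakdowns on the full (unsubsampled) pair sets would be costly;
        # compute them on the same sampled sets
        w_by_study: dict[str, list[float]] = {}
        for (i, j), d in zip(within_pairs[: len(dw)], dw):
            w_by_study.setdefault(studies[i], []).append(float(d))
        per_study_within[cat] = {s: float(np.mean(v)) for s, v in w_by_study.items()}
        b_by_pair: dict[str, list[float]] = {}
        for (i, j), d in zip(between_pairs[: len(db)], db):
            key = "/".join(sorted((studies[i], studies[j])))
            b_by_pair.setdefault(key, []).append(float(d))
        per_pair_between[cat] = {k: float(np.mean(v)) for k, v in b_by_pair.items()}
    wm = float(np.mean([v[0] for v in per_category.values()]))
    ws = float(np.mean([v[1] for v in per_category.values()]))
    bm = float(np.mean([v[2] for v in per_category.values()]))
    bs = float(np.mean([v[3] for v in per_category.values()]))
    if wm > 0:
        pct = pct_increase(wm, bm)
    else:  # degenerate within-study baseline (e.g. identical participants)
        pct = float("nan") if bm == 0 else float("inf")
    return DtwSummary(
        within_mean=wm,
        within_sd=ws,
        between_mean=bm,
        between_sd=bs,
        pct_increase=pct,
        per_category=per_category,
        per_study_within=per_study_within,
        per_pair_between=per_pair_between,
        n_within_pairs=n_within,
        n_between_pairs=n_between,
    )


def aggregate_series(
    series: Sequence[Sequence[float]], horizon: int = 48
) -> np.ndarray:
    """Mean response across participants at each response index.

    Position ``k`` (1-based, up to ``horizon``) averages the k-th response
    of every participant who has one; trailing positions with no
    contributors are truncated.
    """
    if not series or all(len(s) == 0 for s in series):
        raise ValueError("no responses to aggregate")
    out = []
    for k in range(horizon):
        vals = [s[k] for s in series if len(s) > k]
        if not vals:
            break
        out.append(float(np.mean(vals)))
    return np.asarray(out)


def fit_arima(
    series: Sequence[float],
    order: tuple[int, int, int] = (0, 1, 1),
    lb_lags: int = 10,
) -> ArimaFit:
    """Maximum-likelihood ARIMA fit with Ljung-Box residual diagnostics.

    Defaults to ARIMA(0,1,1) with no constant: differencing absorbs the
    slow trend of an aggregated response series and the remaining structure
    is a first-order moving average.  A degenerate input (zero variance
    after differencing) or a failed fit is returned flagged rather than
    raised, with NaN statistics.
    """
    y = np.asarray(series, float)
    if len(y) < 20:
        raise ValueError("series too short for a stable ARIMA fit (need >= 20)")
    d = order[1]
    if np.ptp(np.diff(y, n=d) if d else y) == 0:
        return ArimaFit(order, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, True)
    from statsmodels.stats.diagnostic import acorr_ljungbox
    from statsmodels.tsa.arima.model import ARIMA

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ARIMA(y, order=order, trend="n").fit()
        ma1 = ma1_p = np.nan
        names = list(getattr(fit, "param_names", []))
        if "ma.L1" in names:
            i = names.index("ma.L1")
            ma1 = float(np.asarray(fit.params)[i])
            ma1_p = float(np.asarray(fit.pvalues)[i])
        resid = np.asarray(fit.resid)[d:]
        lb = acorr_ljungbox(resid, lags=[lb_lags])
        return ArimaFit(
            order=order,
            ma1_coef=ma1,
            ma1_p=ma1_p,
            loglik=float(fit.llf),
            aic=float(fit.aic),
            bic=float(fit.bic),
            ljung_box_p=float(lb["lb_pvalue"].iloc[0]),
        )
    except (ValueError, np.linalg.LinAlgError):
        return ArimaFit(order, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, True)


def group_trend(
    series_by_group: Mapping[str, Sequence[Sequence[float]]],
    horizon: int = 48,
) -> GroupTrends:
    """Trend lines of aggregated response series per study group.

    Each group's participant series are aggregated (mean at each response
    index) and fit with an OLS line of value against 1-based response index;
    the pooled aggregate over all groups gives the reference line, and per
    group the slope/intercept offsets from it are reported.
    """
    fits = {}
    for group, series in series_by_group.items():
        agg = aggregate_series(series, horizon=horizon)
        if len(agg) < 3:
            raise ValueError(f"group {group!r} aggregate has <3 points")
        fits[group] = trend_fit(np.arange(1, len(agg) + 1), agg)
    all_series = [s for series in series_by_group.values() for s in series]
    agg_all = aggregate_series(all_series, horizon=horizon)
    overall = trend_fit(np.arange(1, len(agg_all) + 1), agg_all)
    return GroupTrends(
        fits=fits,
        overall=overall,
        slope_diffs={g: f.slope - overall.slope for g, f in fits.items()},
        intercept_diffs={g: f.intercept - overall.intercept for g, f in fits.items()},
    )
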