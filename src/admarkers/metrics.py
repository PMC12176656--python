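"""Horizon outcome labeling and diagnostic performance metrics.

Converts censored time-to-event follow-up into a binary 10-year outcome
with an explicit rule for participants censored early, then computes
confusion-matrix metrics (accuracy, sensitivity, specificity, PPV, NPV)
with percentile-bootstrap CIs and rank-based AUCs with DeLong CIs, for
single biomarkers and for combination predictors built from elevated
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BIOMARKER_SPECS
from .cutpoints import apply_cutoff

__all__ = [
    "HorizonDataset",
    "horizon_labels",
    "confusion_metrics",
    "auc_rank",
    "combine_elevated",
    "evaluate_pipeline",
    "PredictionReport",
]


@dataclass
class HorizonDataset:
    """Classifiable subset of a cohort at a fixed prediction horizon."""

    index: np.ndarray  # row labels of classifiable participants
    labels: np.ndarray  # 1 = event within horizon, 0 = event-free past horizon
    n_excluded: int
    exclusion_reasons: pd.Series
    horizon: float
    outcome: str


def horizon_labels(
    table: pd.DataFrame,
    horizon: float = 10.0,
    outcome: str = "all_cause",
    censored_as_negative: bool = False,
) -> HorizonDataset:
    """Binary outcome at the prediction horizon.

    Positive: qualifying event (any dementia, or AD dementia for the AD
    outcome) at time <= horizon. Negative: event-free with follow-up >=
    horizon. Participants whose follow-up ends before the horizon without
    a qualifying event — dropouts, deaths, and (for the AD outcome) other
    dementias — are excluded from classification by default, since their
    horizon outcome is unobserved; ``censored_as_negative=True`` instead
    counts them as negatives.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if outcome == "all_cause":
        qualifying = table["event"].isin(["ad_dementia", "other_dementia"])
    elif outcome == "ad":
        qualifying = table["event"] == "ad_dementia"
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    t = table["followup_years"].to_numpy(dtype=float)
    pos = qualifying.to_numpy() & (t <= horizon)
    neg = ~pos & (t >= horizon)
    excluded = ~pos & ~neg
    if censored_as_negative:
        neg = neg | excluded
        excluded = np.zeros_like(excluded)
    reasons = pd.Series("", index=table.index, dtype=object)
    reasons[excluded] = "insufficient event-free follow-up before horizon"
    labels = np.where(pos, 1, 0)[pos | neg]
    return HorizonDataset(
        index=table.index.to_numpy()[pos | neg],
        labels=labels,
        n_excluded=int(excluded.sum()),
        exclusion_reasons=reasons[excluded],
        horizon=float(horizon),
        outcome=outcome,
    )


@dataclass
class PredictionReport:
    """Horizon classification performance for one predictor (percent scale)."""

    predictor: str
    outcome: str
    horizon: float
    n_classified: int
    n_excluded: int
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    metrics: dict[str, float] = field(default_factory=dict)
    metric_cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "horizon": self.horizon,
            "n_classified": self.n_classified,
            "n_excluded": self.n_excluded,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
        }
        for k, v in self.metrics.items():
            row[k] = v
            row[f"{k}_ci_low"], row[f"{k}_ci_high"] = self.metric_cis.get(k, (np.nan, np.nan))
        return row


def _confusion(labels: np.ndarray, predictions: np.ndarray) -> dict[str, float]:
    tp = float(np.sum((labels == 1) & (predictions == 1)))
    tn = float(np.sum((labels == 0) & (predictions == 0)))
    fp = float(np.sum((labels == 0) & (predictions == 1)))
    fn = float(np.sum((labels == 1) & (predictions == 0)))
    n = tp + tn + fp + fn

    def ratio(a, b):
        return a / b if b > 0 else float("nan")  # undefined reported as missing

    return {
        "accuracy": ratio(tp + tn, n),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def confusion_metrics(
    labels,
    predictions,
    ci_reps: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[dict[str, float], dict[str, tuple[float, float]]]:
    """Confusion-matrix performance (percent) with percentile-bootstrap CIs.

    Resamples participants with replacement ``ci_reps`` times (seeded);
    metrics with a zero denominator are reported as NaN, never as 0.
    Returns ``(metrics, cis)`` on the 0-100 scale.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present among labels")
    point = {k: 100.0 * v for k, v in _confusion(labels, predictions).items()}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(labels)
    samples: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(ci_reps):
        idx = rng.integers(0, n, size=n)
        m = _confusion(labels[idx], predictions[idx])
        for k, v in m.items():
            if np.isfinite(v):
                samples[k].append(100.0 * v)
    cis = {}
    for k, vals in samples.items():
        if vals:
            lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            cis[k] = (float(lo), float(hi))
        else:
            cis[k] = (float("nan"), float("nan"))
    return point, cis


def _delong_variance(scores_pos: np.ndarray, scores_neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via midrank placements."""
    m, n = len(scores_pos), len(scores_neg)
    all_scores = np.concatenate([scores_pos, scores_neg])
    rank_all = stats.rankdata(all_scores)
    rank_pos = stats.rankdata(scores_pos)
    rank_neg = stats.rankdata(scores_neg)
    # placement values: fraction of the other class below each observation
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_rank(
    scores,
    labels,
    direction: str = "high_is_risk",
    ci: str = "delong",
    ci_reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Rank (Mann-Whitney) AUC with 95% CI, on the percent scale.

    AUC = P(score_pos > score_neg) + 0.5 P(equal) over all positive x
    negative pairs. Scores for low-risk markers (the amyloid ratio) are
    negated first. CI by DeLong (default) or participant bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if direction == "low_is_risk":
        scores = -scores
    pos, neg = scores[labels == 1], scores[labels == 0]
    auc, var = _delong_variance(pos, neg)
    z = stats.norm.ppf(1 - alpha / 2)
    if ci == "delong":
        se = np.sqrt(max(var, 0.0))
        lo, hi = np.clip([auc - z * se, auc + z * se], 0.0, 1.0)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(scores)
        vals = []
        for _ in range(ci_reps):
            idx = rng.integers(0, n, size=n)
            yl = labels[idx]
            if yl.min() == yl.max():
                continue
            p, ng = scores[idx][yl == 1], scores[idx][yl == 0]
            vals.append(_delong_variance(p, ng)[0])
        lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError("ci must be 'delong' or 'bootstrap'")
    return 100.0 * auc, (100.0 * float(lo), 100.0 * float(hi))


COMBINATION_MARKERS = ["ptau217", "nfl", "gfap"]


def combine_elevated(flags: pd.DataFrame, rule: str) -> np.ndarray:
    """Combination predictor scores from per-marker elevated flags.

    Rules: ``count`` (ordinal 0..k), ``at_least_k`` / ``exactly_k`` for
    integer k (e.g. ``at_least_2``), and ``pair_and(a,b)`` (positive iff
    both named flags are positive).
    """
    arr = flags.to_numpy(dtype=int)
    if rule == "count":
        return arr.sum(axis=1)
    if rule.startswith("at_least_"):
        k = int(rule.rsplit("_", 1)[1])
        return (arr.sum(axis=1) >= k).astype(int)
    if rule.startswith("exactly_"):
        k = int(rule.rsplit("_", 1)[1])
        return (arr.sum(axis=1) == k).astype(int)
    if rule.startswith("pair_and(") and rule.endswith(")"):
        a, b = [s.strip() for s in rule[len("pair_and(") : -1].split(",")]
        for name in (a, b):
            if name not in flags.columns:
                raise ValueError(f"flag column {name!r} not available")
        return ((flags[a] == 1) & (flags[b] == 1)).astype(int).to_numpy()
    raise ValueError(f"unknown combination rule {rule!r}")


DEFAULT_COMBINATIONS = [
    "at_least_1",
    "at_least_2",
    "at_least_3",
    "pair_and(ptau217,nfl)",
    "pair_and(ptau217,gfap)",
    "pair_and(nfl,gfap)",
]


def evaluate_predictor(
    name: str,
    scores: np.ndarray,
    predictions: np.ndarray | None,
    ds: HorizonDataset,
    direction: str = "high_is_risk",
    ci_reps: int = 2000,
    seed: int = 0,
) -> PredictionReport:
    """Performance report for one predictor on a horizon dataset."""
    rep = PredictionReport(
        predictor=name,
        outcome=ds.outcome,
        horizon=ds.horizon,
        n_classified=len(ds.labels),
        n_excluded=ds.n_excluded,
    )
    rep.auc, rep.auc_ci = auc_rank(scores, ds.labels, direction=direction)
    if predictions is not None:
        rep.metrics, rep.metric_cis = confusion_metrics(
            ds.labels, predictions, ci_reps=ci_reps, seed=seed
        )
    return rep


def evaluate_pipeline(
    frame: pd.DataFrame,
    cutoffs: dict[str, float],
    horizon: float = 10.0,
    outcome: str = "all_cause",
    combinations: list[str] | None = None,
    ci_reps: int = 2000,
    seed: int = 0,
    censored_as_negative: bool = False,
) -> list[PredictionReport]:
    """Full performance table on one split of the cohort.

    For each biomarker with a frozen cut-off: continuous-marker AUC plus
    at-cut-off confusion metrics. For each combination rule over the
    elevated flags of p-tau217, NfL and GFAP: the combination score's AUC
    and (for binary rules) confusion metrics.
    """
    ds = horizon_labels(frame, horizon=horizon, outcome=outcome,
                        censored_as_negative=censored_as_negative)
    if len(ds.labels) == 0 or ds.labels.min() == ds.labels.max():
        raise ValueError("horizon dataset lacks both outcome classes")
    sub = frame.loc[ds.index]
    reports = []
    flags = {}
    for name, cut in cutoffs.items():
        spec = BIOMARKER_SPECS[name]
        values = sub[name].to_numpy(dtype=float)
        pred = apply_cutoff(values, cut, spec.direction)
        flags[name] = pred
        reports.append(
            evaluate_predictor(name, values, pred, ds, direction=spec.direction,
                               ci_reps=ci_reps, seed=seed)
        )
    combo_flags = pd.DataFrame(
        {m: flags[m] for m in COMBINATION_MARKERS if m in flags}
    )
    if combinations is None:
        combinations = DEFAULT_COMBINATIONS
    for rule in combinations:
        if combo_flags.shape[1] < 2:
            break
        score = combine_elevated(combo_flags, rule)
        pred = score if set(np.unique(score)) <= {0, 1} else None
        reports.append(
            evaluate_predictor(
                f"combo:{rule}", score.astype(float), pred, ds, ci_reps=ci_reps, seed=seed
            )
        )
    return reports
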