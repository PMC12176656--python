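"""Bootstrap Youden-index cut-point estimation with internal validation.

The defining computation of the prediction stage: for each biomarker,
evaluate every observed value as a candidate cut point, pick the one
maximizing Youden's index (sensitivity + specificity - 1) within each of
B non-parametric bootstrap resamples, and take the arithmetic mean of
the B per-resample optima as the operational cut-off. Cut-offs are
derived on the 80% training split and frozen before being applied to
the unseen 20% test split.

`BootstrapYoudenCutpoint` wraps the procedure as a scikit-learn
compatible classifier (fit/predict, `get_params`, fitted attributes with
trailing underscores) so it composes with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "split_train_test",
    "youden",
    "best_cutpoint",
    "bootstrap_cutpoint",
    "apply_cutoff",
    "CutpointResult",
    "BootstrapYoudenCutpoint",
]


def split_train_test(ids, ratio: float = 0.8, seed: int | np.random.Generator = 0):
    """Deterministic random train/test partition of participant ids.

    The training set has round(ratio * n) members (banker's rounding via
    ``np.round``); the test set is the remainder. Disjoint and exhaustive.
    """
    ids = np.asarray(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 participants to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_train = int(np.round(ratio * n))
    perm = rng.permutation(n)
    return np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])


def youden(sensitivity, specificity):
    """Youden's index J = sensitivity + specificity - 1."""
    sensitivity = np.asarray(sensitivity, dtype=float)
    specificity = np.asarray(specificity, dtype=float)
    if np.any((sensitivity < 0) | (sensitivity > 1) | (specificity < 0) | (specificity > 1)):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    j = sensitivity + specificity - 1.0
    return float(j) if j.ndim == 0 else j


def _candidate_j(marker, labels, direction, weights=None):
    """Youden's index at every unique observed value as the candidate cut.

    Positive means value >= c for high_is_risk markers, value <= c for
    low_is_risk. Returns (candidates, J per candidate).
    """
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels, dtype=int)
    w = np.ones(len(marker)) if weights is None else np.asarray(weights, dtype=float)
    keep = w > 0  # zero-weight rows are absent from the (re)sample
    marker, labels, w = marker[keep], labels[keep], w[keep]
    order = np.argsort(marker, kind="mergesort")
    m, y, w = marker[order], labels[order], w[order]
    n_pos = float(np.sum(w * y))
    n_neg = float(np.sum(w * (1 - y)))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # group by unique value
    uniq, start = np.unique(m, return_index=True)
    pos_cum = np.concatenate([[0.0], np.cumsum(w * y)])
    neg_cum = np.concatenate([[0.0], np.cumsum(w * (1 - y))])
    ends = np.append(start[1:], len(m))
    if direction == "high_is_risk":
        # positive if value >= c: TP = pos with value >= c
        tp = n_pos - pos_cum[start]
        tn = neg_cum[start]
    elif direction == "low_is_risk":
        # positive if value <= c: TP = pos with value <= c
        tp = pos_cum[ends]
        tn = n_neg - neg_cum[ends]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    j = tp / n_pos + tn / n_neg - 1.0
    return uniq, j


def best_cutpoint(marker, labels, direction: str = "high_is_risk", weights=None) -> float:
    """Cut point maximizing Youden's index over all observed values.

    Candidates are the unique observed marker values; the classifier is
    "positive if value >= c" for high-risk markers (<= c for the amyloid
    ratio). Ties in J are resolved as the mean of the tied candidates.
    """
    uniq, j = _candidate_j(marker, labels, direction, weights)
    jmax = j.max()
    tied = uniq[np.isclose(j, jmax, rtol=0.0, atol=1e-12)]
    return float(tied.mean())


@dataclass
class CutpointResult:
    """Bootstrap-aggregated optimal cut-off for one biomarker."""

    biomarker: str
    direction: str
    mean_cutpoint: float
    bootstrap_cutpoints: np.ndarray = field(repr=False)
    n_bootstrap: int = 0
    seed: int | None = None
    n_redrawn: int = 0

    def summary(self) -> dict:
        bs = self.bootstrap_cutpoints
        return {
            "biomarker": self.biomarker,
            "direction": self.direction,
            "cutoff": self.mean_cutpoint,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "bootstrap_sd": float(np.std(bs, ddof=1)) if len(bs) > 1 else float("nan"),
            "bootstrap_q025": float(np.percentile(bs, 2.5)),
            "bootstrap_q975": float(np.percentile(bs, 97.5)),
        }


def bootstrap_cutpoint(
    marker,
    labels,
    direction: str = "high_is_risk",
    B: int = 5000,
    seed: int | np.random.Generator = 0,
    biomarker: str = "",
    max_retries: int = 100,
) -> CutpointResult:
    """Mean optimal cut point over B non-parametric bootstrap resamples.

    Each resample draws n pairs with replacement (implemented as
    multinomial case weights); resamples containing a single class are
    redrawn (counted in ``n_redrawn``). The arithmetic mean of the
    per-resample Youden-optimal cut points is the operational cut-off.
    Deterministic given the seed.
    """
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(marker)) < 2:
        raise ValueError("degenerate data: marker has no variation")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(marker)
    cuts = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for attempt in range(max_retries + 1):
            w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)
            if np.sum(w * labels) > 0 and np.sum(w * (1 - labels)) > 0:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        cuts[b] = best_cutpoint(marker, labels, direction, weights=w)
    return CutpointResult(
        biomarker=biomarker,
        direction=direction,
        mean_cutpoint=float(cuts.mean()),
        bootstrap_cutpoints=cuts,
        n_bootstrap=B,
        seed=seed if isinstance(seed, int) else None,
        n_redrawn=n_redrawn,
    )


def apply_cutoff(marker, cutpoint: float, direction: str = "high_is_risk") -> np.ndarray:
    """Elevated/positive flags at a frozen cut-off.

    A value exactly at the cut-off is positive. For the amyloid ratio
    (low_is_risk), positive means value <= cut-off.
    """
    marker = np.asarray(marker, dtype=float)
    if direction == "high_is_risk":
        return (marker >= cutpoint).astype(int)
    if direction == "low_is_risk":
        return (marker <= cutpoint).astype(int)
    raise ValueError(f"unknown direction {direction!r}")


class BootstrapYoudenCutpoint(ClassifierMixin, BaseEstimator):
    """Single-biomarker threshold classifier fitted by bootstrap Youden search.

    Parameters
    ----------
    direction : "high_is_risk" or "low_is_risk" — whether high or low
        marker values are called positive.
    n_bootstrap : number of bootstrap resamples (B).
    random_state : seed for the resampling stream.

    Attributes
    ----------
    cutpoint_ : the bootstrap-mean optimal cut-off.
    bootstrap_cutpoints_ : per-resample optimal cut points (length B).
    classes_ : [0, 1].
    """

    def __init__(self, direction: str = "high_is_risk", n_bootstrap: int = 5000,
                 random_state: int | None = 0):
        self.direction = direction
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expects a single marker column")
            X = X[:, 0]
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        res = bootstrap_cutpoint(
            X, y, direction=self.direction, B=self.n_bootstrap,
            seed=self.random_state if self.random_state is not None else 0,
        )
        self.cutpoint_ = res.mean_cutpoint
        self.bootstrap_cutpoints_ = res.bootstrap_cutpoints
        self.result_ = res
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "cutpoint_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return apply_cutoff(X, self.cutpoint_, self.direction)

    def decision_function(self, X):
        check_is_fitted(self, "cutpoint_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        s = X - self.cutpoint_
        return s if self.direction == "high_is_risk" else -s
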