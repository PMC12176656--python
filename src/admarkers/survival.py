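"""Proportional-hazards association stage.

Implements the association analyses of the cohort study: restricted
cubic spline dose-response curves, adjusted quartile hazard ratios with
trend tests, Schoenfeld-residual proportional-hazards diagnostics,
cause-specific censoring for the AD outcome, and stabilized
inverse-probability-of-dropout weighting.

Partial-likelihood maximization and the Schoenfeld score test are
delegated to lifelines; everything study-specific (the spline basis,
model assembly, contrasts) is built here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .cohort import BIOMARKER_SPECS
from .config import BIOMARKERS, DISEASES
from .descriptives import IncidenceResult, incidence_rate

logger = logging.getLogger(__name__)

#: Adjustment set of the fully adjusted models: age; sex; education;
#: the eight disease diagnoses; and APOE e4 carrier status.
ADJUSTMENT_TERMS = ["age", "sex_female", "edu_high_school", "edu_university"] + DISEASES + ["apoe_e4"]


def build_design(table: pd.DataFrame) -> pd.DataFrame:
    """Expand covariates into the model design columns (indicator coding,
    elementary education as reference)."""
    out = table.copy()
    if "sex" in out:
        out["sex_female"] = (out["sex"] == "female").astype(float)
    if "education" in out:
        out["edu_high_school"] = (out["education"] == "high school").astype(float)
        out["edu_university"] = (out["education"] == "university").astype(float)
    return out


def event_indicator(table: pd.DataFrame, outcome: str) -> pd.Series:
    """0/1 event column for the chosen outcome.

    ``all_cause`` counts any dementia; ``ad`` counts AD dementia only,
    censoring other dementias and deaths at their observed times
    (cause-specific censoring — the at-risk person-time is identical to
    the all-cause analysis, only event labels differ).
    """
    if outcome == "all_cause":
        return table["event"].isin(["ad_dementia", "other_dementia"]).astype(int)
    if outcome == "ad":
        return (table["event"] == "ad_dementia").astype(int)
    raise ValueError(f"unknown outcome {outcome!r}")


# ---------------------------------------------------------------------------
# Restricted cubic splines


@dataclass
class SplineBasis:
    """3-knot restricted cubic spline of a biomarker.

    The expansion has two columns: the identity (linear) term and one
    restricted-cubic term that is linear beyond the boundary knots with
    continuous first and second derivatives at the knots.
    """

    knots: np.ndarray
    names: list[str] = field(default_factory=lambda: ["rcs1", "rcs2"])

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t1, t2, t3 = self.knots
        p = lambda v: np.maximum(v, 0.0) ** 3
        s = (
            p(x - t1)
            - p(x - t2) * (t3 - t1) / (t3 - t2)
            + p(x - t3) * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        return np.column_stack([x, s])


def rcs_basis(x, percentiles=(25, 50, 75)) -> tuple[SplineBasis, np.ndarray]:
    """Restricted-cubic-spline basis with knots at fixed sample percentiles.

    Returns the basis object and the per-observation basis matrix
    (columns: linear term, restricted cubic term).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(np.unique(x)) < 10:
        raise ValueError("need at least 10 distinct values for a spline basis")
    knots = np.percentile(x, list(percentiles))
    if len(np.unique(knots)) < 3:
        raise ValueError("coincident knots; data too discrete for 3-knot spline")
    basis = SplineBasis(knots=knots)
    return basis, basis.transform(x)


# ---------------------------------------------------------------------------
# Cox fitting


@dataclass
class HazardFit:
    """A fitted proportional-hazards model."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    n: int
    events: int
    tie_method: str
    weights_used: bool
    outcome: str
    schoenfeld_p: pd.Series | None = None
    _fitter: CoxPHFitter | None = None
    _data: pd.DataFrame | None = None

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = pd.Series(np.sqrt(np.diag(self.covariance)), index=self.coefficients.index)
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": se,
                "hr": np.exp(self.coefficients),
                "ci_low": np.exp(self.coefficients - z * se),
                "ci_high": np.exp(self.coefficients + z * se),
                "p": 2 * stats.norm.sf(np.abs(self.coefficients / se)),
            }
        )


def fit_cox(
    frame: pd.DataFrame,
    terms: list[str],
    outcome: str = "all_cause",
    adjust: bool = True,
    weights: pd.Series | np.ndarray | None = None,
    ties: str = "efron",
) -> HazardFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    frame : cohort table (or analysis frame) with follow-up columns.
    terms : exposure columns of interest (z-scores, quartile indicators,
        spline columns, ...).
    outcome : "all_cause" or "ad" (cause-specific censoring).
    adjust : include the standard adjustment set (age, sex, education,
        eight disease diagnoses, APOE e4). Rows with missing adjustment
        covariates are dropped.
    weights : optional per-row case weights (e.g. stabilized IPW); a
        robust sandwich variance is used when given.
    ties : tie-handling method; only "efron" is available.
    """
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is available")
    df = build_design(frame)
    cols = list(terms) + (ADJUSTMENT_TERMS if adjust else [])
    df = df.assign(_event=event_indicator(df, outcome), _time=df["followup_years"])
    keep = cols + ["_time", "_event"]
    data = df[keep].apply(pd.to_numeric, errors="coerce")
    if weights is not None:
        data = data.assign(_w=np.asarray(weights, dtype=float))
    data = data.dropna()
    n_events = int(data["_event"].sum())
    if n_events < 1:
        raise ValueError("no events in the analysis sample")
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(
            data,
            duration_col="_time",
            event_col="_event",
            weights_col="_w" if weights is not None else None,
            robust=weights is not None,
            fit_options={
                "step_size": 0.7,
                "precision": 1e-12,
                "r_precision": 0.0,
                "max_steps": 500,
            },
        )
    return HazardFit(
        coefficients=fitter.params_.copy(),
        covariance=fitter.variance_matrix_.copy(),
        n=len(data),
        events=n_events,
        tie_method=ties,
        weights_used=weights is not None,
        outcome=outcome,
        _fitter=fitter,
        _data=data,
    )


def schoenfeld_check(fit: HazardFit) -> pd.Series:
    """Proportional-hazards diagnostic per covariate.

    Score test of zero slope when scaled Schoenfeld residuals are
    regressed against survival time. Returns per-covariate p-values;
    all-NaN when the fit has fewer than two events (undefined).
    """
    if fit._fitter is None or fit._data is None:
        raise ValueError("fit does not carry its training data")
    if fit.events < 2:
        return pd.Series(np.nan, index=fit.coefficients.index)
    res = proportional_hazard_test(fit._fitter, fit._data, time_transform="identity")
    p = res.summary["p"]
    p.index = [i[0] if isinstance(i, tuple) else i for i in p.index]
    fit.schoenfeld_p = p.reindex(fit.coefficients.index)
    return fit.schoenfeld_p


# ---------------------------------------------------------------------------
# Quartile hazard-ratio table


@dataclass
class QuartileHRRow:
    quartile: str
    hr: float
    ci_low: float
    ci_high: float
    reference: bool
    incidence: IncidenceResult | None = None


def quartile_hr_table(
    frame: pd.DataFrame,
    biomarker: str,
    outcome: str = "all_cause",
    adjust: bool = True,
    weights=None,
) -> tuple[list[QuartileHRRow], float]:
    """Adjusted hazard ratios by biomarker quartile plus the trend p-value.

    The quartile column ``<biomarker>_q`` must already be present (see
    ``cohort.add_derived_columns``). The reference quartile follows the
    marker's risk direction (Q1, or Q4 for the amyloid ratio). The trend
    test refits the model with the risk-ordered quartile index (1-4) as a
    single continuous term and reports its Wald p-value.

    Returns ``(rows, p_trend)`` with rows ordered Q1..Q4 for high-risk
    markers and Q4..Q1 for the amyloid ratio (reference first).
    """
    qcol = f"{biomarker}_q"
    if qcol not in frame.columns:
        raise ValueError(f"{qcol!r} missing; run add_derived_columns first")
    spec = BIOMARKER_SPECS[biomarker]
    order = ["Q1", "Q2", "Q3", "Q4"] if spec.direction == "high_is_risk" else ["Q4", "Q3", "Q2", "Q1"]
    ref = order[0]
    df = frame.copy()
    counts = df[qcol].value_counts()
    if any(counts.get(q, 0) == 0 for q in order):
        raise ValueError("empty quartile category in the analysis sample")
    ind_cols = []
    for q in order[1:]:
        col = f"{biomarker}_{q.lower()}"
        df[col] = (df[qcol] == q).astype(float)
        ind_cols.append(col)
    fit = fit_cox(df, ind_cols, outcome=outcome, adjust=adjust, weights=weights)
    hrs = fit.hazard_ratios()
    rows = [QuartileHRRow(quartile=ref, hr=1.0, ci_low=np.nan, ci_high=np.nan,
                          reference=True, incidence=_quartile_ir(df, qcol, ref, outcome))]
    for q, col in zip(order[1:], ind_cols):
        rows.append(
            QuartileHRRow(
                quartile=q,
                hr=float(hrs.loc[col, "hr"]),
                ci_low=float(hrs.loc[col, "ci_low"]),
                ci_high=float(hrs.loc[col, "ci_high"]),
                reference=False,
                incidence=_quartile_ir(df, qcol, q, outcome),
            )
        )
    # ordinal-score Wald trend test
    score = df[qcol].map({q: i + 1 for i, q in enumerate(order)}).astype(float)
    df["_trend"] = score
    tfit = fit_cox(df, ["_trend"], outcome=outcome, adjust=adjust, weights=weights)
    p_trend = float(tfit.hazard_ratios().loc["_trend", "p"])
    return rows, p_trend


def _quartile_ir(df: pd.DataFrame, qcol: str, q: str, outcome: str) -> IncidenceResult:
    sub = df[df[qcol] == q]
    ev = int(event_indicator(sub, outcome).sum())
    return incidence_rate(ev, float(sub["followup_years"].sum()))


# ---------------------------------------------------------------------------
# Spline dose-response curve


def spline_hr_curve(
    fit: HazardFit,
    basis: SplineBasis,
    term_names: tuple[str, str],
    x_grid,
    reference_value: float,
    data_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Hazard-ratio curve HR(x) = exp(eta(x) - eta(ref)) with pointwise CI.

    The CI comes from the delta method on the linear contrast between x
    and the reference value, using the fit's covariance restricted to the
    two spline coefficients. HR(reference_value) is exactly 1 with a
    zero-width interval. Grid points outside ``data_range`` are flagged
    as extrapolation.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    bx = basis.transform(x_grid)
    bref = basis.transform([reference_value])
    contrast = bx - bref  # (m, 2)
    beta = fit.coefficients[list(term_names)].to_numpy()
    cov = fit.covariance.loc[list(term_names), list(term_names)].to_numpy()
    eta = contrast @ beta
    var = np.einsum("ij,jk,ik->i", contrast, cov, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    out = pd.DataFrame(
        {
            "x": x_grid,
            "hr": np.exp(eta),
            "ci_low": np.exp(eta - 1.96 * se),
            "ci_high": np.exp(eta + 1.96 * se),
        }
    )
    if data_range is not None:
        out["extrapolated"] = (x_grid < data_range[0]) | (x_grid > data_range[1])
        if out["extrapolated"].any():
            logger.warning("spline curve evaluated outside the observed data range")
    return out


def fit_spline_model(
    frame: pd.DataFrame, biomarker: str, outcome: str = "all_cause", adjust: bool = True
) -> tuple[HazardFit, SplineBasis, tuple[str, str]]:
    """Fit the 3-knot restricted-cubic-spline Cox model for one biomarker."""
    x = frame[biomarker].to_numpy(dtype=float)
    basis, mat = rcs_basis(x)
    df = frame.copy()
    names = (f"{biomarker}_rcs1", f"{biomarker}_rcs2")
    df[names[0]] = basis.transform(x)[:, 0]
    df[names[1]] = basis.transform(x)[:, 1]
    fit = fit_cox(df, list(names), outcome=outcome, adjust=adjust)
    return fit, basis, names


# ---------------------------------------------------------------------------
# Inverse-probability-of-dropout weights


def ipw_dropout_weights(
    frame: pd.DataFrame,
    truncate_percentiles: tuple[float, float] = (1.0, 99.0),
) -> pd.Series:
    """Stabilized inverse-probability-of-dropout weights.

    Fits a logistic retention model on age, sex, education, number of
    chronic diseases and the six baseline biomarker levels, then returns
    weight = P(retained) / P(retained | covariates) for retained
    participants (NaN for dropouts). Weights are truncated at the given
    percentiles of the retained-sample weight distribution; truncation is
    logged.
    """
    if "dropout" not in frame.columns:
        raise ValueError("dropout flag column required")
    df = build_design(frame)
    retained = 1.0 - df["dropout"].astype(float)
    if retained.min() == 1.0:
        return pd.Series(1.0, index=frame.index, name="ipw")
    cols = ["age", "sex_female", "edu_high_school", "edu_university", "n_chronic_diseases"] + BIOMARKERS
    X = df[cols].apply(pd.to_numeric, errors="coerce")
    X = (X - X.mean()) / X.std(ddof=0).replace(0, 1.0)
    X = sm.add_constant(X.fillna(0.0))
    model = sm.GLM(retained, X, family=sm.families.Binomial())
    res = model.fit()
    p_ret = np.clip(res.predict(X), 1e-6, 1 - 1e-6)
    w = retained.mean() / p_ret
    w = w.where(retained == 1.0, np.nan)
    ok = w.dropna()
    lo, hi = np.percentile(ok, truncate_percentiles)
    n_trunc = int(((ok < lo) | (ok > hi)).sum())
    if n_trunc:
        logger.info("truncated %d IPW weight(s) to [%.3f, %.3f]", n_trunc, lo, hi)
    return w.clip(lower=lo, upper=hi).rename("ipw")
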