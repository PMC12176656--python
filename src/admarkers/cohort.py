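"""Cohort table schema, I/O, and preprocessing conventions.

The cohort table is the single exchange format between pipeline stages:
one row per participant with baseline covariates, the six blood
biomarkers, follow-up time and event type. Preprocessing follows the
study conventions: sub-LOD measurements imputed to 0, z-scores computed
against the whole baseline sample, quartile categories cut at sample
quartiles with a direction-dependent reference, and named analysis
filters for the subgroup and sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import BIOMARKERS, DISEASES

logger = logging.getLogger(__name__)

EVENT_LEVELS = ["none", "ad_dementia", "other_dementia", "death"]

REQUIRED_COLUMNS = (
    ["id", "age", "sex", "education"]
    + DISEASES
    + ["n_chronic_diseases", "mmse", "memory_complaints", "apoe_e4"]
    + BIOMARKERS
    + ["followup_years", "event", "dropout"]
)


@dataclass(frozen=True)
class BiomarkerSpec:
    """A biomarker's risk direction and assay detection limit."""

    name: str
    direction: str  # "high_is_risk" or "low_is_risk"
    lod: float = 0.0

    def __post_init__(self):
        if self.direction not in ("high_is_risk", "low_is_risk"):
            raise ValueError(f"unknown direction {self.direction!r}")


#: The amyloid 42/40 ratio is the only marker where *low* values signal
#: pathology; its highest quartile is the reference in quartile models.
BIOMARKER_SPECS = {
    "abeta_ratio": BiomarkerSpec("abeta_ratio", "low_is_risk", lod=0.005),
    "ptau181": BiomarkerSpec("ptau181", "high_is_risk", lod=0.08),
    "ptau217": BiomarkerSpec("ptau217", "high_is_risk", lod=0.006),
    "ttau": BiomarkerSpec("ttau", "high_is_risk", lod=0.06),
    "nfl": BiomarkerSpec("nfl", "high_is_risk", lod=0.5),
    "gfap": BiomarkerSpec("gfap", "high_is_risk", lod=2.0),
}


# ---------------------------------------------------------------------------
# I/O


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV into a typed table.

    Raises ``ValueError`` if required columns are missing, a biomarker
    column is non-numeric, or follow-up is negative. Extra columns are
    preserved.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file missing required column(s): {', '.join(missing)}")
    for col in BIOMARKERS + ["age", "followup_years"]:
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} is not numeric") from exc
    if (table["followup_years"] < 0).any():
        raise ValueError("negative follow-up time")
    bad = ~table["event"].isin(EVENT_LEVELS)
    if bad.any():
        raise ValueError(f"unknown event label(s): {sorted(table.loc[bad, 'event'].unique())}")
    if table["id"].duplicated().any():
        raise ValueError("duplicate participant ids")
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV, '.' decimal, empty cell = missing.

    Floats are written with 17 significant digits so write -> read is an
    exact round trip.
    """
    table.to_csv(path, index=False, encoding="utf-8", na_rep="", float_format="%.17g")


# ---------------------------------------------------------------------------
# Preprocessing conventions


def impute_below_lod(values, lod: float):
    """Replace values below the detection limit with exactly 0.

    Returns ``(imputed_values, n_imputed)``; values at or above the LOD are
    unchanged.
    """
    if lod < 0:
        raise ValueError("lod must be non-negative")
    arr = np.asarray(values, dtype=float).copy()
    below = arr < lod
    n = int(np.nansum(below))
    arr[below] = 0.0
    if n:
        logger.info("imputed %d value(s) below LOD %g to 0", n, lod)
    return arr, n


def standardize(values, reference_values=None):
    """z-scores of ``values`` against the mean/sd of ``reference_values``.

    The reference defaults to ``values`` itself (the whole-sample
    convention: z computed on the full baseline sample, then reused for
    subgroup analyses). Uses the sample (ddof=1) standard deviation.
    """
    arr = np.asarray(values, dtype=float)
    ref = arr if reference_values is None else np.asarray(reference_values, dtype=float)
    ref = ref[~np.isnan(ref)]
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero-variance reference; cannot standardize")
    return (arr - ref.mean()) / sd


def quartile_cuts(values) -> np.ndarray:
    """25th/50th/75th sample percentiles (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return np.percentile(arr, [25, 50, 75])


def quartile_assign(values, direction: str = "high_is_risk"):
    """Assign quartile categories Q1-Q4 and the reference label.

    Cuts at the 25th/50th/75th sample percentiles; a value exactly at a
    boundary goes to the lower quartile. ``high_is_risk`` markers use Q1 as
    the reference; ``low_is_risk`` (the amyloid ratio) uses Q4.

    Returns ``(categories, reference_label)`` where categories is an object
    array of 'Q1'..'Q4' (NaN preserved as None).
    """
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    if ok.sum() < 8:
        raise ValueError("need at least 8 non-missing values to form quartiles")
    cuts = quartile_cuts(arr[ok])
    if cuts[0] == cuts[2]:
        raise ValueError("degenerate quartiles: 25th and 75th percentiles coincide")
    # side="left": a value exactly at a cut stays in the lower quartile
    idx = np.searchsorted(cuts, arr[ok], side="left")
    labels = np.array(["Q1", "Q2", "Q3", "Q4"], dtype=object)
    cats = np.full(arr.shape, None, dtype=object)
    cats[ok] = labels[idx]
    ref = "Q1" if direction == "high_is_risk" else "Q4"
    return cats, ref


def add_derived_columns(table: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Return the analysis frame: cohort + z-scores + quartile categories.

    ``reference`` (default: the table itself) supplies the standardization
    sample and quartile cuts, implementing the whole-baseline-sample
    convention when a filtered table is analyzed. LOD imputation is applied
    to the raw biomarker columns first. All derived columns are pure
    functions of the raw columns, so the operation is idempotent.
    """
    ref = table if reference is None else reference
    out = table.copy()
    for name in BIOMARKERS:
        spec = BIOMARKER_SPECS[name]
        raw, _ = impute_below_lod(out[name].to_numpy(), spec.lod)
        ref_raw, _ = impute_below_lod(ref[name].to_numpy(), spec.lod)
        out[name] = raw
        out[f"{name}_z"] = standardize(raw, ref_raw)
        cuts = quartile_cuts(ref_raw)
        idx = np.searchsorted(cuts, raw, side="left")
        out[f"{name}_q"] = np.array(["Q1", "Q2", "Q3", "Q4"], dtype=object)[idx]
    return out


# ---------------------------------------------------------------------------
# Analysis filters (subgroup and sensitivity analyses)


def _truncate_followup(table: pd.DataFrame, years: float) -> pd.DataFrame:
    out = table.copy()
    late = out["followup_years"] > years
    out.loc[late, "followup_years"] = years
    out.loc[late, "event"] = "none"
    return out


FILTERS = {
    "mmse_ge_27": lambda t: t[t["mmse"] >= 27],
    "age_lt_78": lambda t: t[t["age"] < 78],
    "age_ge_78": lambda t: t[t["age"] >= 78],
    "female": lambda t: t[t["sex"] == "female"],
    "male": lambda t: t[t["sex"] == "male"],
    "apoe_carrier": lambda t: t[t["apoe_e4"] == 1],
    "apoe_noncarrier": lambda t: t[t["apoe_e4"] == 0],
    "memory_complaints": lambda t: t[t["memory_complaints"] == 1],
}


def analysis_filters(
    table: pd.DataFrame,
    filters: str | Iterable[str] = (),
    truncate_years: float | None = None,
) -> pd.DataFrame:
    """Apply named subgroup/sensitivity filters and optional follow-up truncation.

    Filters: mmse_ge_27, age_lt_78 / age_ge_78, female / male,
    apoe_carrier / apoe_noncarrier, memory_complaints. Truncation caps
    follow-up at ``truncate_years`` and relabels later events as censored.
    """
    if isinstance(filters, str):
        filters = [filters]
    out = table
    for name in filters:
        if name not in FILTERS:
            raise ValueError(f"unknown filter {name!r}; known: {sorted(FILTERS)}")
        out = FILTERS[name](out)
    if truncate_years is not None:
        if truncate_years <= 0:
            raise ValueError("truncate_years must be positive")
        out = _truncate_followup(out, truncate_years)
    return out.copy()
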