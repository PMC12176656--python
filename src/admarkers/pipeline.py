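"""End-to-end pipeline: simulate -> preprocess -> describe -> survival ->
cut-points -> prediction, as a configured, logged, seeded run.

Stages communicate only through file artifacts in the output directory:
cohort.csv, table1.csv, table2.csv, spline_hr.csv, cutoffs.json,
table3.csv, combinations.csv, run.log and manifest.json (config hash +
artifact checksums). Per-purpose seeds (simulation, split, bootstrap,
CI) let a stage be re-run without perturbing upstream randomness; a
fixed config yields byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    BIOMARKER_SPECS,
    add_derived_columns,
    analysis_filters,
    read_cohort,
    write_cohort,
)
from .config import BIOMARKERS, SimConfig
from .cutpoints import bootstrap_cutpoint, split_train_test
from .descriptives import cohort_incidence, summarize_by_group
from .metrics import evaluate_pipeline, horizon_labels
from .simulate import generate_cohort
from .survival import fit_spline_model, ipw_dropout_weights, quartile_hr_table, spline_hr_curve

logger = logging.getLogger(__name__)

OUTCOMES = ["all_cause", "ad"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None  # read a cohort CSV; None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    n_participants: int | None = None
    sim_seed: int = 1
    split_seed: int = 2
    bootstrap_seed: int = 3
    ci_seed: int = 4
    horizon_years: float = 10.0
    bootstrap_reps: int = 5000
    ci_reps: int = 2000
    split_ratio: float = 0.8
    filters: list[str] = field(default_factory=list)
    truncate_years: float | None = None
    use_ipw: bool = False
    fit_splines: bool = True
    output_dir: str = "out"

    def __post_init__(self):
        if self.bootstrap_reps < 1 or self.ci_reps < 1:
            raise ValueError("reps must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(data or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def load_or_simulate(config: RunConfig) -> pd.DataFrame:
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"cohort file not found: {path}")
        return read_cohort(path)
    n = config.n_participants or config.sim.n_participants
    return generate_cohort(config.sim, n=n, seed=config.sim_seed)


def make_table2(frame: pd.DataFrame, weights=None) -> pd.DataFrame:
    """Quartile IR/HR table for every biomarker and both outcomes."""
    rows = []
    for outcome in OUTCOMES:
        for name in BIOMARKERS:
            qrows, p_trend = quartile_hr_table(frame, name, outcome=outcome, weights=weights)
            for r in qrows:
                rows.append(
                    {
                        "outcome": outcome,
                        "biomarker": name,
                        "quartile": r.quartile,
                        "reference": int(r.reference),
                        "events": r.incidence.events,
                        "person_years": r.incidence.person_years,
                        "ir_per_100py": r.incidence.rate,
                        "ir_ci_low": r.incidence.ci_low,
                        "ir_ci_high": r.incidence.ci_high,
                        "hr": r.hr,
                        "hr_ci_low": r.ci_low,
                        "hr_ci_high": r.ci_high,
                        "p_trend": p_trend,
                    }
                )
    return pd.DataFrame(rows)


def make_spline_curves(frame: pd.DataFrame, n_grid: int = 50) -> pd.DataFrame:
    """Dose-response HR curves (reference = 25th percentile) per biomarker."""
    rows = []
    for outcome in OUTCOMES:
        for name in BIOMARKERS:
            fit, basis, terms = fit_spline_model(frame, name, outcome=outcome)
            x = frame[name].to_numpy(dtype=float)
            grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), n_grid)
            ref = np.percentile(x, 25)
            curve = spline_hr_curve(fit, basis, terms, grid, ref, data_range=(x.min(), x.max()))
            curve.insert(0, "biomarker", name)
            curve.insert(0, "outcome", outcome)
            rows.append(curve)
    return pd.concat(rows, ignore_index=True)


def derive_cutoffs(
    train: pd.DataFrame,
    horizon: float,
    B: int,
    seed: int,
) -> dict[str, dict[str, dict]]:
    """Bootstrap Youden cut-offs per outcome and biomarker, on the training split."""
    out: dict[str, dict[str, dict]] = {}
    for k, outcome in enumerate(OUTCOMES):
        ds = horizon_labels(train, horizon=horizon, outcome=outcome)
        sub = train.loc[ds.index]
        out[outcome] = {}
        for j, name in enumerate(BIOMARKERS):
            spec = BIOMARKER_SPECS[name]
            res = bootstrap_cutpoint(
                sub[name].to_numpy(dtype=float),
                ds.labels,
                direction=spec.direction,
                B=B,
                seed=seed + 1000 * k + j,
                biomarker=name,
            )
            out[outcome][name] = res.summary()
    return out


def run_all(config: RunConfig) -> dict:
    """Execute every pipeline stage and return the output manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("admarkers")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_all_stages(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all_stages(config: RunConfig, outdir: Path) -> dict:
    stage = "simulate/load"
    try:
        cohort = load_or_simulate(config)
        write_cohort(cohort, outdir / "cohort.csv")

        stage = "preprocess"
        frame = add_derived_columns(cohort)
        frame = analysis_filters(frame, config.filters, config.truncate_years)
        analysis = frame[frame["dropout"] == 0].copy() if "dropout" in frame else frame

        stage = "describe"
        analysis["incident_dementia"] = (
            analysis["event"].isin(["ad_dementia", "other_dementia"]).astype(int)
        )
        table1 = summarize_by_group(analysis, "incident_dementia")
        _write_csv(table1, outdir / "table1.csv")
        ir_all = cohort_incidence(analysis, "all_cause")
        ir_ad = cohort_incidence(analysis, "ad")
        logger.info("all-cause IR %.3f (%.3f-%.3f); AD IR %.3f", ir_all.rate,
                    ir_all.ci_low, ir_all.ci_high, ir_ad.rate)

        stage = "survival"
        weights = None
        if config.use_ipw:
            w = ipw_dropout_weights(frame)
            weights = w.loc[analysis.index]
        table2 = make_table2(analysis, weights=weights)
        _write_csv(table2, outdir / "table2.csv")
        if config.fit_splines:
            spl = make_spline_curves(analysis)
            _write_csv(spl, outdir / "spline_hr.csv")

        stage = "cutpoints"
        train_ids, test_ids = split_train_test(
            analysis["id"].to_numpy(), config.split_ratio, config.split_seed
        )
        train = analysis[analysis["id"].isin(train_ids)]
        test = analysis[analysis["id"].isin(test_ids)]
        cutoffs = derive_cutoffs(
            train, config.horizon_years, config.bootstrap_reps, config.bootstrap_seed
        )
        (outdir / "cutoffs.json").write_text(
            json.dumps(cutoffs, indent=2, sort_keys=True), encoding="utf-8"
        )

        stage = "predict"
        rows, combo_rows = [], []
        for outcome in OUTCOMES:
            cuts = {m: cutoffs[outcome][m]["cutoff"] for m in BIOMARKERS}
            for split_name, split_frame in [("train", train), ("test", test)]:
                reports = evaluate_pipeline(
                    split_frame,
                    cuts,
                    horizon=config.horizon_years,
                    outcome=outcome,
                    ci_reps=config.ci_reps,
                    seed=config.ci_seed,
                )
                for rep in reports:
                    row = {"split": split_name, **rep.to_row()}
                    (combo_rows if rep.predictor.startswith("combo:") else rows).append(row)
        _write_csv(pd.DataFrame(rows), outdir / "table3.csv")
        _write_csv(pd.DataFrame(combo_rows), outdir / "combinations.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    cfg_dict = config.to_dict()
    cfg_dict.pop("output_dir", None)  # where artifacts land is not part of the analysis
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    artifacts = sorted(
        p.name for p in outdir.iterdir() if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": {
            "simulation": config.sim_seed,
            "split": config.split_seed,
            "bootstrap": config.bootstrap_seed,
            "ci": config.ci_seed,
        },
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
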