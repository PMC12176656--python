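"""Spline basis, Cox fitting against a partial-likelihood oracle,
quartile HR machinery, PH diagnostics and IPW weights."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from admarkers import (
    fit_cox,
    fit_spline_model,
    ipw_dropout_weights,
    quartile_assign,
    quartile_hr_table,
    rcs_basis,
    schoenfeld_check,
    spline_hr_curve,
)
from admarkers.survival import SplineBasis


def _minimal_frame(time, event, x, name="x"):
    """Smallest frame fit_cox accepts for an unadjusted fit."""
    ev = np.asarray(event, dtype=int)
    return pd.DataFrame(
        {
            "followup_years": np.asarray(time, dtype=float),
            "event": np.where(ev == 1, "ad_dementia", "none"),
            name: np.asarray(x, dtype=float),
        }
    )


class TestRcsBasis:
    def test_left_tail_all_zero(self):
        x = np.linspace(0, 1, 50)
        basis = SplineBasis(knots=np.array([2.0, 3.0, 4.0]))
        mat = basis.transform(x)
        assert np.all(mat[:, 1] == 0.0)
        np.testing.assert_array_equal(mat[:, 0], x)

    def test_linear_beyond_boundary_knots(self):
        """Numeric second difference of the restricted cubic term vanishes
        above the last knot (finite-difference oracle)."""
        x = np.random.default_rng(0).normal(size=200)
        basis, _ = rcs_basis(x)
        t3 = basis.knots[2]
        grid = np.linspace(t3 + 0.1, t3 + 2.0, 30)
        h = grid[1] - grid[0]
        s = basis.transform(grid)[:, 1]
        second = (s[2:] - 2 * s[1:-1] + s[:-2]) / h**2
        assert np.all(np.abs(second) < 1e-8)

    def test_continuous_at_knots(self):
        basis = SplineBasis(knots=np.array([-1.0, 0.0, 1.0]))
        for t in basis.knots:
            eps = 1e-6
            left = basis.transform([t - eps])[0, 1]
            right = basis.transform([t + eps])[0, 1]
            assert left == pytest.approx(right, abs=1e-5)

    def test_knots_at_quartiles(self):
        x = np.arange(100.0)
        basis, mat = rcs_basis(x)
        np.testing.assert_allclose(basis.knots, np.percentile(x, [25, 50, 75]))
        assert mat.shape == (100, 2)

    def test_too_discrete_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.repeat([1.0, 2.0], 20))

    def test_linear_effect_gives_null_nonlinear_term(self, rng):
        """Data generated with a purely linear log-hazard: the restricted
        cubic coefficient is zero within 3 SE."""
        n = 4000
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
        frame = _minimal_frame(np.minimum(t, 20.0), (t <= 20.0).astype(int), x)
        fit, basis, names = fit_spline_model(frame, "x", outcome="ad", adjust=False)
        coef = fit.coefficients[names[1]]
        se = np.sqrt(fit.covariance.loc[names[1], names[1]])
        assert abs(coef) < 3 * se


def _partial_likelihood_oracle(time, event, x):
    """Independent maximizer of the exact Cox partial likelihood (instances
    are chosen without ties). A bounded search localizes the optimum, then
    a root of the hand-written score polishes it well past 1e-8."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)

    def neg_logpl(beta):
        ll = 0.0
        for i in np.where(event == 1)[0]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    def score(beta):
        s = 0.0
        for i in np.where(event == 1)[0]:
            risk = time >= time[i]
            w = np.exp(beta * x[risk])
            s += x[i] - np.sum(w * x[risk]) / np.sum(w)
        return s

    rough = optimize.minimize_scalar(neg_logpl, bounds=(-8, 8), method="bounded",
                                     options={"xatol": 1e-10}).x
    lo, hi = rough - 1e-3, rough + 1e-3
    if score(lo) * score(hi) > 0:
        return rough
    return optimize.brentq(score, lo, hi, xtol=1e-12)


class TestFitCox:
    def test_three_subject_toy_matches_grid_oracle(self):
        """Toy data (event t=1 x=1; event t=2 x=0; censored t=3 x=1): the
        fitted coefficient maximizes e^b/(2e^b+1) * 1/(e^b+1), located by an
        independent bounded search to 1e-6."""
        time, event, x = [1.0, 2.0, 3.0], [1, 1, 0], [1.0, 0.0, 1.0]
        fit = fit_cox(_minimal_frame(time, event, x), ["x"], outcome="ad", adjust=False)
        oracle = _partial_likelihood_oracle(time, event, x)
        assert fit.coefficients["x"] == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 4, 5, 6])  # instances with interior optima
    def test_small_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        time = rng.permutation(np.arange(1.0, n + 1))  # distinct times, no ties
        event = rng.integers(0, 2, n)
        event[rng.integers(0, n)] = 1  # at least one event
        x = rng.normal(0, 1, n)
        oracle = _partial_likelihood_oracle(time, event, x)
        assert abs(oracle) < 5  # not separated: beta-hat finite
        fit = fit_cox(_minimal_frame(time, event, x), ["x"], outcome="ad", adjust=False)
        assert fit.coefficients["x"] == pytest.approx(oracle, abs=1e-6)

    def test_label_swap_symmetry(self, rng):
        n = 300
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.8 * z)))
        frame = _minimal_frame(np.minimum(t, 15), (t <= 15).astype(int), z)
        fit1 = fit_cox(frame, ["x"], outcome="ad", adjust=False)
        frame2 = frame.assign(x=1.0 - frame["x"])
        fit2 = fit_cox(frame2, ["x"], outcome="ad", adjust=False)
        assert fit1.coefficients["x"] == pytest.approx(-fit2.coefficients["x"], abs=1e-8)

    def test_parameter_recovery_known_loghr(self, rng):
        """PH simulation with log-HR 0.5 at n=5,000: estimate within 3 SE."""
        n = 5000
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
        c = rng.uniform(0, 25, n)
        frame = _minimal_frame(np.minimum(t, c), (t <= c).astype(int), x)
        fit = fit_cox(frame, ["x"], outcome="ad", adjust=False)
        se = np.sqrt(fit.covariance.loc["x", "x"])
        assert abs(fit.coefficients["x"] - 0.5) < 3 * se

    def test_no_events_rejected(self):
        frame = _minimal_frame([1, 2, 3], [0, 0, 0], [1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="no events"):
            fit_cox(frame, ["x"], outcome="ad", adjust=False)

    def test_cause_specific_censoring_same_persontime(self, analysis_frame):
        """The AD analysis keeps the all-cause at-risk person-time; only the
        event labels differ."""
        fit_all = fit_cox(analysis_frame, ["nfl_z"], outcome="all_cause")
        fit_ad = fit_cox(analysis_frame, ["nfl_z"], outcome="ad")
        assert fit_all.n == fit_ad.n
        assert fit_ad.events < fit_all.events

    def test_breslow_unavailable(self, analysis_frame):
        with pytest.raises(NotImplementedError):
            fit_cox(analysis_frame, ["nfl_z"], ties="breslow")


class TestQuartileHRTable:
    def test_reference_row_unity(self, analysis_frame):
        rows, p_trend = quartile_hr_table(analysis_frame, "nfl", outcome="all_cause")
        assert rows[0].reference and rows[0].hr == 1.0
        assert rows[0].quartile == "Q1"
        assert np.isfinite(p_trend)

    def test_abeta_reference_is_q4(self, analysis_frame):
        rows, _ = quartile_hr_table(analysis_frame, "abeta_ratio", outcome="all_cause")
        assert rows[0].quartile == "Q4" and rows[0].reference

    def test_monotone_effect_strong_trend(self, analysis_frame):
        """At study-scale effect sizes the trend test is decisive."""
        _, p_trend = quartile_hr_table(analysis_frame, "nfl", outcome="all_cause")
        assert p_trend < 0.001

    def test_null_marker_ci_coverage(self, rng):
        """Quartile HRs of a marker unrelated to the hazard: the 95% CIs
        cover 1 in at least 93% of replicates."""
        cover, total = 0, 0
        for _ in range(150):
            n = 500
            x = rng.lognormal(3, 0.5, n)
            t = rng.exponential(8.0, n)
            frame = _minimal_frame(np.minimum(t, 16), (t <= 16).astype(int), x, name="nfl")
            cats, _ = quartile_assign(frame["nfl"].to_numpy())
            frame["nfl_q"] = cats
            rows, _ = quartile_hr_table(frame, "nfl", outcome="ad", adjust=False)
            for r in rows[1:]:
                total += 1
                cover += r.ci_low <= 1.0 <= r.ci_high
        assert cover / total >= 0.93

    def test_monotone_transform_invariance(self, analysis_frame):
        """Quartiles are rank-based, so a monotone transform of the marker
        leaves the HR table unchanged."""
        frame = analysis_frame.copy()
        cats_raw, _ = quartile_assign(frame["nfl"].to_numpy())
        frame["nfl_q"] = cats_raw
        transformed = frame.assign(nfl=np.log(frame["nfl"]))
        cats, _ = quartile_assign(transformed["nfl"].to_numpy())
        transformed["nfl_q"] = cats
        r1, p1 = quartile_hr_table(frame, "nfl")
        r2, p2 = quartile_hr_table(transformed, "nfl")
        for a, b in zip(r1, r2):
            assert a.hr == pytest.approx(b.hr, rel=1e-8)
        assert p1 == pytest.approx(p2, rel=1e-8)


class TestSplineCurve:
    def test_reference_hr_exactly_one(self, analysis_frame):
        fit, basis, names = fit_spline_model(analysis_frame, "nfl")
        curve = spline_hr_curve(fit, basis, names, [15.0], reference_value=15.0)
        assert curve["hr"].iloc[0] == pytest.approx(1.0)
        assert curve["ci_low"].iloc[0] == pytest.approx(1.0)
        assert curve["ci_high"].iloc[0] == pytest.approx(1.0)

    def test_zero_coefficients_flat_curve(self, analysis_frame):
        fit, basis, names = fit_spline_model(analysis_frame, "nfl")
        fit.coefficients[names[0]] = 0.0
        fit.coefficients[names[1]] = 0.0
        grid = np.linspace(5, 60, 20)
        curve = spline_hr_curve(fit, basis, names, grid, reference_value=15.0)
        np.testing.assert_allclose(curve["hr"], 1.0)

    def test_extrapolation_flagged(self, analysis_frame):
        fit, basis, names = fit_spline_model(analysis_frame, "nfl")
        x = analysis_frame["nfl"]
        curve = spline_hr_curve(
            fit, basis, names, [x.max() + 10], reference_value=15.0,
            data_range=(x.min(), x.max()),
        )
        assert curve["extrapolated"].iloc[0]

    def test_threshold_shape_recovered(self, rng):
        """A fit on data whose log hazard has the threshold shape (flat
        left tail, rising right tail, expressed in the spline span so the
        model is correctly specified) reproduces the generating curve
        within the pointwise CI at 90% of grid points."""
        n = 4000
        x = rng.lognormal(0, 0.5, n)
        gen_basis = SplineBasis(knots=np.percentile(x, [25, 50, 75]))
        b = np.array([0.15, 2.5])  # nearly flat below t1, rising above
        eff = gen_basis.transform(x) @ b
        t = rng.exponential(1.0 / (0.05 * np.exp(eff)))
        frame = _minimal_frame(np.minimum(t, 20), (t <= 20).astype(int), x)
        fit, basis, names = fit_spline_model(frame, "x", outcome="ad", adjust=False)
        np.testing.assert_allclose(basis.knots, gen_basis.knots)
        ref = np.percentile(x, 25)
        grid = np.linspace(np.percentile(x, 5), np.percentile(x, 95), 40)
        curve = spline_hr_curve(fit, basis, names, grid, reference_value=ref)
        truth = np.exp((gen_basis.transform(grid) - gen_basis.transform([ref])) @ b)
        inside = (curve["ci_low"] <= truth) & (truth <= curve["ci_high"])
        assert inside.mean() >= 0.9


class TestSchoenfeld:
    def test_null_calibration_uniform_p(self, rng):
        """Under proportional hazards with bounded (administratively
        censored) follow-up, the diagnostic p-values are uniform (KS test
        over replicates)."""
        ps = []
        for _ in range(150):
            n = 250
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1.0 / (0.2 * np.exp(0.5 * x)))
            frame = _minimal_frame(np.minimum(t, 6.0), (t <= 6.0).astype(int), x)
            fit = fit_cox(frame, ["x"], outcome="ad", adjust=False)
            ps.append(schoenfeld_check(fit)["x"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_time_varying_effect(self, rng):
        """A strongly time-varying effect is flagged with high power."""
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 400
            x = rng.integers(0, 2, n).astype(float)
            # exposed subjects: high hazard early, low hazard late
            t0 = rng.exponential(1.0, n)
            t1 = np.where(t0 < 0.7, rng.exponential(0.2, n), 0.7 + rng.exponential(3.0, n))
            t = np.where(x == 1, t1, t0)
            frame = _minimal_frame(t, np.ones(n, int), x)
            fit = fit_cox(frame, ["x"], outcome="ad", adjust=False)
            hits += schoenfeld_check(fit)["x"] < 0.05
        assert hits / reps > 0.8

    def test_single_event_undefined(self):
        frame = _minimal_frame([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0], [1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(frame, ["x"], outcome="ad", adjust=False)
        assert schoenfeld_check(fit).isna().all()


class TestIPW:
    def test_no_dropout_unit_weights(self, cohort):
        t = cohort.copy()
        t["dropout"] = 0
        w = ipw_dropout_weights(t)
        assert (w == 1.0).all()

    def test_random_dropout_stabilized_near_one(self, calibrated_config, rng):
        """Dropout independent of covariates: stabilized weights have sd
        below 0.05 at n=10,000."""
        from admarkers import generate_cohort

        coh = generate_cohort(calibrated_config, n=10_000, seed=31)
        t = coh.copy()
        t["dropout"] = rng.integers(0, 2, len(t)) * (rng.uniform(size=len(t)) < 0.12)
        w = ipw_dropout_weights(t).dropna()
        assert abs(w.mean() - 1.0) < 0.02
        assert w.std() < 0.05

    def test_weights_nan_for_dropouts(self, cohort):
        w = ipw_dropout_weights(cohort)
        assert w[cohort["dropout"] == 1].isna().all()
        assert w[cohort["dropout"] == 0].notna().all()
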