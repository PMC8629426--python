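"""Response classification, projection, truncation refits, and sensitivity."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import icikinetics as ik
from icikinetics.response import classify_projection


def _series(times, burdens, pid="p"):
    return ik.PatientSeries(pid, np.asarray(times, float), np.asarray(burdens, float))


class TestClassifyResponse:
    def test_no_change_is_unfavorable_under_both_conventions(self):
        s = _series([0.0, 60.0], [1.0, 1.0])
        for conv in ("volume-0.7", "diameter-0.343"):
            assert not ik.classify_response(s, conv).favorable

    def test_deep_response_favorable_under_both(self):
        s = _series([0.0, 60.0], [1.0, 0.30])
        for conv in ("volume-0.7", "diameter-0.343"):
            assert ik.classify_response(s, conv).favorable

    def test_intermediate_value_splits_conventions(self):
        # 50% volume reduction is >30% in volume but <30% in diameter
        s = _series([0.0, 60.0], [1.0, 0.50])
        assert ik.classify_response(s, "volume-0.7").favorable
        assert not ik.classify_response(s, "diameter-0.343").favorable

    def test_projected_value_accepted(self):
        lab = ik.classify_response(0.2, patient_id="x")
        assert lab.favorable and lab.patient_id == "x"

    def test_empty_series_rejected(self):
        s = _series([0.0], [1.0])
        with pytest.raises(ValueError):
            ik.classify_response(s)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            ik.classify_response(0.5, convention="volume-0.5", patient_id="x")


def _fit_result(alpha, lam, mu, pid="p"):
    traj = ik.TrajectoryModel.from_values(alpha, lam, mu)
    return ik.FitResult(pid, alpha, lam, mu, traj.rho_inf, 0.0, 8, True)


class TestProjectBurden:
    def test_steady_state(self):
        f = _fit_result(0.02, 1.5, 0.02)  # mu = alpha: rho_inf = 1
        assert ik.project_burden(f, 700.0) == pytest.approx(1.0)

    def test_growth_regime_closed_form(self):
        f = _fit_result(0.02, 1.0, 0.01)
        expected = 2.0 / (1.0 + math.exp(-14.0))
        assert ik.project_burden(f, 700.0) == pytest.approx(expected, rel=1e-12)

    def test_regression_regime_decreasing_and_matches_ode(self):
        f = _fit_result(0.01, 2.0, 0.03)  # rho_inf = 2/3, k < 0? check sign
        m = f.trajectory
        assert m.k < 0 or 0 < m.rho_inf < 1
        values = [ik.project_burden(f, h) for h in (200.0, 400.0, 700.0)]
        assert all(0.0 <= v < 1.0 for v in values)
        assert values == sorted(values, reverse=True)
        sol = solve_ivp(
            lambda t, y: m.k * y * (1 - y / m.rho_inf),
            (0, 700), [1.0], t_eval=[200, 400, 700], rtol=1e-10, atol=1e-12,
        )
        assert np.allclose(values, sol.y[0], rtol=1e-6)


class TestTruncateSeries:
    def test_strict_inequality(self):
        s = _series([0.0, 29.0, 30.0, 59.0], [1.0, 1.1, 1.2, 1.3])
        t = ik.truncate_series(s, 30.0)
        assert t.times.tolist() == [0.0, 29.0]

    def test_identity_beyond_last_point(self):
        s = _series([0.0, 29.0, 60.0], [1.0, 1.1, 1.2])
        t = ik.truncate_series(s, 1000.0)
        assert np.array_equal(t.times, s.times)
        assert np.array_equal(t.burdens, s.burdens)

    def test_counts_match_brute_force(self, noisy_cohort):
        for p in noisy_cohort.cohort:
            for w in (30.0, 60.0, 120.0, 200.0):
                t = ik.truncate_series(p, w)
                brute = 1 + sum(1 for x in p.times[1:] if x < w)
                assert t.n_points == brute

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            ik.truncate_series(_series([0.0, 10.0], [1.0, 1.1]), 0.0)


class TestTruncationAnalysis:
    def test_full_window_is_self_comparison(self, noiseless_cohort, noiseless_fits):
        amap = dict(zip(noiseless_cohort.truth.patient_id, noiseless_cohort.truth.alpha))
        rep = ik.truncation_analysis(
            noiseless_cohort.cohort, amap, windows=("all",), full_fits=noiseless_fits
        )
        row = rep.table.iloc[0]
        assert row.spearman_lambda == 1.0
        assert row.spearman_mu == 1.0
        assert row.misclassification == 0.0

    def test_noiseless_misclassification_nonincreasing(self, noiseless_cohort, noiseless_fits):
        """With noiseless data the projected label stabilizes as the fitting
        window grows: misclassification cannot increase with window length."""
        amap = dict(zip(noiseless_cohort.truth.patient_id, noiseless_cohort.truth.alpha))
        rep = ik.truncation_analysis(
            noiseless_cohort.cohort, amap,
            windows=(60.0, 120.0, 200.0, "all"),
            full_fits=noiseless_fits,
        )
        mis = rep.table.misclassification.to_numpy()
        assert np.all(np.diff(mis) <= 1e-12)
        assert mis[-1] == 0.0

    def test_exclusion_accounting(self, noisy_cohort, noisy_fits):
        amap = dict(zip(noisy_cohort.truth.patient_id, noisy_cohort.truth.alpha))
        rep = ik.truncation_analysis(
            noisy_cohort.cohort, amap, windows=(30.0, "all"), full_fits=noisy_fits
        )
        for _, row in rep.table.iterrows():
            assert row.n_fit + row.n_excluded == len(noisy_cohort.cohort)


class TestPerturbParameters:
    def test_lambda_inert_when_mu_zero(self):
        f = _fit_result(0.01, 2.0, 0.0)
        assert ik.perturb_parameters(f) == 0.0

    def test_matches_brute_force(self):
        f = _fit_result(0.02, 1.0, 0.01)
        base = ik.predict_burden(f.trajectory, 200.0)
        brute = max(
            abs(ik.predict_burden(ik.TrajectoryModel.from_values(0.02, lam, mu), 200.0) - base)
            for lam, mu in [(1.1, 0.01), (0.9, 0.01), (1.0, 0.011), (1.0, 0.009)]
        )
        assert ik.perturb_parameters(f, 0.10, 200.0) == pytest.approx(brute, rel=1e-12)

    def test_vanishes_as_fraction_shrinks(self):
        f = _fit_result(0.02, 1.0, 0.01)
        changes = [ik.perturb_parameters(f, frac) for frac in (0.1, 0.01, 0.001)]
        assert changes == sorted(changes, reverse=True)
        # roughly linear in the perturbation fraction near zero
        assert changes[-1] < 0.05 * changes[0]


class TestPerturbDataRefit:
    def test_zero_amplitude_gives_perfect_correlation(self, noisy_cohort, noisy_fits):
        amap = dict(zip(noisy_cohort.truth.patient_id, noisy_cohort.truth.alpha))
        sp_lam, sp_mu = ik.perturb_data_refit(
            noisy_cohort.cohort, amap, amplitude=0.0, seed=4,
            original_fits=noisy_fits,
        )
        assert sp_lam == pytest.approx(1.0)
        assert sp_mu == pytest.approx(1.0)

    def test_reproducible_for_fixed_seed(self, noiseless_cohort, noiseless_fits):
        amap = dict(zip(noiseless_cohort.truth.patient_id, noiseless_cohort.truth.alpha))
        sub = ik.Cohort(noiseless_cohort.cohort.patients[:8])
        fits = noiseless_fits[:8]
        a = ik.perturb_data_refit(sub, amap, 0.1, seed=9, original_fits=fits)
        b = ik.perturb_data_refit(sub, amap, 0.1, seed=9, original_fits=fits)
        assert a == b


class TestParameterSweep:
    def test_mu_zero_row_is_exponential(self):
        df = ik.parameter_sweep([0.01], [0.0, 0.5, 1.0], [0.0], eval_t=200.0)
        assert np.allclose(df.rho, math.exp(0.01 * 200.0))

    def test_consistent_with_pointwise_prediction(self):
        df = ik.parameter_sweep([0.02], [0.5, 1.0], [0.01, 0.05], eval_t=200.0)
        for _, r in df.iterrows():
            expected = ik.predict_burden_clamped(
                ik.TrajectoryModel.from_values(r.alpha, r.lam, r.mu), 200.0
            )
            assert r.rho == pytest.approx(expected)

    def test_burden_decreases_with_mu_at_fixed_alpha(self):
        mu_grid = np.linspace(0.0, 0.1, 11)
        df = ik.parameter_sweep([0.02], [1.0], mu_grid, eval_t=200.0)
        rho = df.sort_values("mu").rho.to_numpy()
        assert np.all(np.diff(rho) <= 1e-12)


def test_long_horizon_agreement_between_observed_and_projected(noiseless_cohort, noiseless_fits):
    """On noiseless data observed beyond 500 d, the label from the last
    observation matches the label projected from the fitted parameters."""
    checked = 0
    for p, f in zip(noiseless_cohort.cohort, noiseless_fits):
        if p.span_days < 500:
            continue
        observed = ik.classify_response(p)
        projected = classify_projection(f, horizon=p.span_days)
        assert observed.favorable == projected.favorable
        checked += 1
    assert checked >= 10
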