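"""Competing-risks estimators: Aalen–Johansen CIF and Fine–Gray regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macerisk.competing import (
    SeparationError,
    cif_aalen_johansen,
    fine_gray_pseudo_loglik,
    fit_fine_gray,
    single_factor_screen,
)

from conftest import competing_fixture_20, competing_fixture_40, make_profile

# Coefficients and pseudo-log-likelihood for competing_fixture_40, frozen
# from an independent Fine–Gray implementation (R cmprsk::crr, gtol=1e-12).
CRR_COEF = (0.1659663511, -0.1717349474)
CRR_LOGLIK = -54.5442119769
TIED_CRR_COEF = -0.2439950076


class TestAalenJohansen:
    def test_single_subject_jumps_to_one(self):
        est = cif_aalen_johansen([100.0], [1], cause=1)
        assert est.times.tolist() == [100.0]
        assert est.cif.tolist() == [1.0]

    def test_hand_tabulated_four_subject_fixture(self):
        # (10, c1), (20, c2), (30, cens), (40, c1):
        # jump at 10: 1/4; S(40-) = (3/4)(2/3) = 1/2, at-risk at 40 is 1
        # -> jump 1/2 -> CIF(40) = 3/4. Tabulated by hand.
        est = cif_aalen_johansen([10, 20, 30, 40], [1, 2, 0, 1], cause=1, horizon=400)
        assert np.allclose(est.times, [10, 20, 40])
        assert np.allclose(est.cif, [0.25, 0.25, 0.75], atol=1e-15)
        assert est.cif_at_horizon == pytest.approx(0.75, abs=1e-15)

    def test_reduces_to_empirical_cdf_without_competition_or_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(50, 100) + 0.1
        est = cif_aalen_johansen(t, np.ones(100, int), cause=1)
        ecdf = np.searchsorted(np.sort(t), est.times, side="right") / 100
        assert np.allclose(est.cif, ecdf, atol=1e-12)

    def test_equals_one_minus_km_when_competing_absent(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(50, 150) + 0.1
        ev = rng.choice([0, 1], 150, p=[0.35, 0.65])
        est = cif_aalen_johansen(t, ev, cause=1)
        km = KaplanMeierFitter().fit(t, ev)
        sf = km.survival_function_at_times(est.times).to_numpy()
        assert np.allclose(est.cif, 1 - sf, atol=1e-12)

    def test_matches_lifelines_aalen_johansen_with_competition(self):
        import warnings

        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(5)
        t = (rng.exponential(100, 200) + 0.01).round(2)
        ev = rng.choice([0, 1, 2], 200, p=[0.3, 0.4, 0.3])
        mine = cif_aalen_johansen(t, ev, cause=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aj = AalenJohansenFitter(calculate_variance=False, seed=1).fit(
                t, ev, event_of_interest=1
            )
        theirs = aj.cumulative_density_.iloc[:, 0]
        vals = (
            theirs.reindex(theirs.index.union(mine.times))
            .ffill()
            .fillna(0)
            .loc[mine.times]
            .to_numpy()
        )
        assert np.abs(vals - mine.cif).max() < 1e-12

    def test_no_events_of_requested_cause_is_zero_not_error(self):
        est = cif_aalen_johansen([5, 10], [0, 2], cause=1)
        assert est.at(100) == 0.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            cif_aalen_johansen([0.0, 5.0], [1, 1], cause=1)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_bounds_monotonicity_and_km_envelope(self, data):
        n = data.draw(st.integers(3, 40))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        t = rng.exponential(30, n) + 0.01
        ev = rng.integers(0, 3, n)
        c1 = cif_aalen_johansen(t, ev, cause=1)
        c2 = cif_aalen_johansen(t, ev, cause=2)
        for est in (c1, c2):
            assert np.all(est.cif >= -1e-12) and np.all(est.cif <= 1 + 1e-12)
            assert np.all(np.diff(est.cif) >= -1e-12)
            assert np.all(est.variance >= 0)
        if c1.times.size and c2.times.size:
            grid = np.union1d(c1.times, c2.times)
            total = np.array([c1.at(u) + c2.at(u) for u in grid])
            assert np.all(total <= 1 + 1e-9)
        # 1 - KM (competing cause relabeled as censoring) bounds the CIF above
        ev_up = np.where(ev == 2, 0, ev)
        up = cif_aalen_johansen(t, ev_up, cause=1)
        for u in c1.times:
            assert up.at(u) >= c1.at(u) - 1e-12


class TestFineGray:
    def test_matches_frozen_external_oracle(self):
        t, ev, X = competing_fixture_40()
        fit = fit_fine_gray(t, ev, X, covariate_names=["x1", "x2"])
        assert fit.coefficients == pytest.approx(CRR_COEF, abs=1e-5)
        assert fit.pseudo_loglik == pytest.approx(CRR_LOGLIK, abs=1e-6)

    def test_reduces_to_cox_without_competing_events(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(50, n) + 0.01
        ev = rng.choice([0, 1], n, p=[0.3, 0.7])
        fg = fit_fine_gray(t, ev, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": ev, "x": x}), "t", "e",
            fit_options={"precision": 1e-11},
        )
        assert abs(fg.coefficients[0] - cph.params_["x"]) < 1e-6

    def test_newton_estimate_maximizes_the_pseudo_likelihood_grid(self):
        """Two-stage 1-D grid search (final step 1e-4) over the coded
        pseudo-likelihood agrees with the Newton estimate."""
        t, ev, x = competing_fixture_20()
        fit = fit_fine_gray(t, ev, x)
        coarse = np.arange(-3.0, 3.0, 0.01)
        ll = [fine_gray_pseudo_loglik(t, ev, x, [b]) for b in coarse]
        b0 = coarse[int(np.argmax(ll))]
        fine = np.arange(b0 - 0.02, b0 + 0.02, 1e-4)
        ll = [fine_gray_pseudo_loglik(t, ev, x, [b]) for b in fine]
        b_grid = fine[int(np.argmax(ll))]
        assert abs(fit.coefficients[0] - b_grid) < 1e-3

    def test_sign_flips_with_covariate_coding(self):
        t, ev, x = competing_fixture_20()
        b_pos = fit_fine_gray(t, ev, x).coefficients[0]
        b_neg = fit_fine_gray(t, ev, 1.0 - x).coefficients[0]
        assert abs(b_pos + b_neg) < 1e-10

    def test_information_criteria_definitions_and_time_rescaling(self):
        t, ev, X = competing_fixture_40()
        fit_days = fit_fine_gray(t, ev, X)
        k = 2
        assert fit_days.aic == pytest.approx(-2 * fit_days.pseudo_loglik + 2 * k)
        assert fit_days.bic == pytest.approx(
            -2 * fit_days.pseudo_loglik + k * np.log(fit_days.n_events_cause1)
        )
        # risk sets are rank-based: affine time rescaling changes nothing
        fit_months = fit_fine_gray(t / 30.4375, ev, X)
        assert fit_months.aic == pytest.approx(fit_days.aic, abs=1e-8)
        assert fit_months.bic == pytest.approx(fit_days.bic, abs=1e-8)

    def test_shr_and_ci_consistent_with_coefficients(self):
        t, ev, X = competing_fixture_40()
        fit = fit_fine_gray(t, ev, X)
        assert np.allclose(fit.shr, np.exp(fit.coefficients))
        assert np.allclose(
            fit.ci95,
            np.column_stack([
                np.exp(fit.coefficients - 1.96 * fit.robust_se),
                np.exp(fit.coefficients + 1.96 * fit.robust_se),
            ]),
        )

    def test_breslow_ties_match_external_oracle(self):
        # tied event times handled by the Breslow approximation
        t = np.array([5, 5, 5, 8, 8, 12, 15, 20, 20, 30], float)
        ev = np.array([1, 1, 2, 1, 0, 1, 2, 1, 0, 0])
        x = np.array([1, 0, 1, 1, 0, 0, 1, 1, 0, 1], float)
        fit = fit_fine_gray(t, ev, x)
        # frozen from R cmprsk::crr on this table
        assert fit.coefficients[0] == pytest.approx(TIED_CRR_COEF, abs=1e-5)

    def test_complete_separation_names_the_covariate(self):
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], float)
        ev = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        with pytest.raises(SeparationError, match="group"):
            fit_fine_gray(t, ev, x, covariate_names=["group"])

    def test_requires_a_cause1_event_and_covariate_variation(self):
        with pytest.raises(ValueError):
            fit_fine_gray([1, 2], [0, 2], np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            fit_fine_gray([1, 2], [1, 0], np.array([1.0, 1.0]))

    def test_estimator_bias_small_under_repeated_sampling(self):
        """Mean log-sHR over 200 simulated two-group cohorts (n=1000,
        true log-sHR = log 2) is within 0.05 of the truth."""
        from macerisk.simulate import CohortConfig, simulate_outcomes

        betas = []
        for rep in range(200):
            cfg = CohortConfig(
                n=1000,
                seed=50_000 + rep,
                class_proportions={"a": 0.5, "b": 0.5},
                true_log_shr={"a": 0.0, "b": np.log(2)},
                baseline_cif=0.10,
            )
            coh = simulate_outcomes(cfg)
            xb = (coh.latent_class == "b").astype(float)
            betas.append(fit_fine_gray(coh.time, coh.event, xb).coefficients[0])
        assert abs(np.mean(betas) - np.log(2)) < 0.05


class TestSingleFactorScreen:
    def test_zero_positive_factor_flagged_inestimable(self):
        rng = np.random.default_rng(3)
        n = 60
        profiles = [
            make_profile(subject_id=f"s{i}", age=60,
                         ischemic_heart_disease=bool(rng.integers(0, 2)))
            for i in range(n)
        ]
        t = rng.exponential(100, n) + 0.1
        ev = rng.choice([0, 1, 2], n, p=[0.3, 0.4, 0.3])
        tab = single_factor_screen(t, ev, profiles,
                                   factors=["ischemic_heart_disease", "obesity"])
        ihd = tab.set_index("factor").loc["ischemic_heart_disease"]
        obe = tab.set_index("factor").loc["obesity"]
        assert bool(ihd["estimable"])
        assert not bool(obe["estimable"]) and np.isnan(obe["shr"])
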