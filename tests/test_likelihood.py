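"""Model functions (f2, v, S4, f4, f5), the likelihood, and MLE fitting."""

import math

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit

import condsurv as cs
from condsurv.encoding import design_matrices
from condsurv.likelihood import _loglik_grad
from conftest import random_design, random_monotone_params

LN2 = math.log(2.0)


class TestCauseProbability:
    def test_zero_linear_predictor_gives_half(self):
        assert cs.cause_probability(np.zeros(3), np.array([1.0, -2.0, 0.5])) \
            == pytest.approx(0.5)

    def test_example_patient_value(self, example_design, published):
        p = cs.cause_probability(example_design.x_alpha, published.alpha)
        assert p == pytest.approx(expit(-0.68))
        assert p == pytest.approx(0.3363, abs=5e-5)

    def test_complement_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=4)
            a = rng.normal(size=4)
            p = cs.cause_probability(x, a)
            assert p + (1.0 - p) == pytest.approx(1.0, abs=1e-15)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            cs.cause_probability(np.ones(3), np.ones(4))


class TestTimeIndexV:
    def test_example_values(self, example_design, published):
        v1 = cs.time_index_v(1.0, 1, example_design, published)
        assert v1 == pytest.approx(0.21)
        v2 = cs.time_index_v(2.0, 1, example_design, published)
        assert v2 == pytest.approx(0.21 - 1.18 * LN2)
        assert v2 == pytest.approx(-0.6079, abs=2e-4)

    def test_cause_difference_is_gamma_plus_rho_logt(self, example_design,
                                                     published):
        for t in (0.3, 1.0, 2.7):
            diff = cs.time_index_v(t, 2, example_design, published) \
                - cs.time_index_v(t, 1, example_design, published)
            expected = -(published.gamma[0] + published.rho[0] * math.log(t))
            assert diff == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_time_rejected(self, example_design, published):
        with pytest.raises(ValueError, match="positive"):
            cs.time_index_v(0.0, 1, example_design, published)


class TestSurvivalS4:
    def test_example_values(self, example_design, published):
        assert cs.survival_S4(1.0, 1, example_design, published) \
            == pytest.approx(0.5523, abs=5e-5)
        assert cs.survival_S4(2.0, 1, example_design, published) \
            == pytest.approx(0.3525, abs=5e-5)

    @pytest.mark.parametrize("family", cs.FAMILIES)
    def test_monotone_decreasing_with_limits(self, family):
        rng = np.random.default_rng(7)
        params = random_monotone_params(rng, family=family)
        design = random_design(rng)
        # the Gompertz time index is linear in t, so extreme times underflow
        # the cll link; probe a moderate range there
        grid = (np.linspace(0.01, 6.0, 40) if family == "gompertz"
                else np.geomspace(1e-3, 50.0, 40))
        for d in (1, 2):
            s = cs.survival_S4(grid, d, design, params)
            # strictly decreasing until the cll link underflows to 0
            assert np.all((np.diff(s) < 0) | (s[1:] == 0.0))
            assert np.all((s >= 0) & (s < 1))
            assert s[0] > 0
        if family != "gompertz":
            # log-time families are proper: S4 -> 1 at the origin, -> 0 at inf
            assert cs.survival_S4(1e-9, 2, design, params) > 0.999
            assert cs.survival_S4(1e9, 2, design, params) < 1e-3


class TestIntervalMassF4:
    def test_example_value(self, example_design, published):
        f4 = cs.interval_death_density_f4(1.0, 1, example_design, published,
                                          delta=1.0)
        assert f4 == pytest.approx(0.5523 - 0.3525, abs=1e-4)

    def test_vanishes_as_delta_shrinks(self, example_design, published):
        vals = [cs.interval_death_density_f4(1.0, 1, example_design,
                                             published, delta=d)
                for d in (1e-2, 1e-4, 1e-6)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-5

    def test_telescoping_over_partition(self, example_design, published):
        a, b = 0.5, 3.0
        edges = np.linspace(a, b, 11)
        total = sum(cs.interval_death_density_f4(
            float(lo), 1, example_design, published, delta=float(hi - lo))
            for lo, hi in zip(edges[:-1], edges[1:]))
        direct = cs.survival_S4(a, 1, example_design, published) \
            - cs.survival_S4(b, 1, example_design, published)
        assert total == pytest.approx(direct, abs=1e-12)


class TestMixtureSurvivalF5:
    def test_example_value(self, example_design, published):
        f5 = cs.censored_survival_f5(1.0, example_design, published)
        assert f5 == pytest.approx(0.7948, abs=2e-4)

    def test_equal_components_collapse_to_s4(self):
        rng = np.random.default_rng(3)
        design = random_design(rng)
        params = random_monotone_params(rng)
        params.gamma[:] = 0.0
        params.rho[:] = 0.0
        f5 = cs.censored_survival_f5(1.3, design, params)
        assert f5 == pytest.approx(
            cs.survival_S4(1.3, 2, design, params), abs=1e-15)

    def test_non_increasing(self, example_design, published):
        grid = np.linspace(0.05, 4.0, 50)
        f5 = cs.censored_survival_f5(grid, example_design, published)
        assert np.all(np.diff(f5) < 0)


def brute_force_loglik(cohort, params, encoding, delta):
    """Independent oracle: per-record product in extended precision."""
    mats = design_matrices(cohort.table, encoding)
    total = np.longdouble(0.0)
    for i in range(len(cohort)):
        design = mats.row(i)
        t = float(mats.t[i])
        d = int(mats.d[i])
        if d == 0:
            contrib = np.longdouble(cs.censored_survival_f5(t, design, params))
        else:
            p1 = np.longdouble(
                cs.cause_probability(design.x_alpha, params.alpha))
            pd_ = p1 if d == 1 else 1 - p1
            f4 = np.longdouble(cs.survival_S4(t, d, design, params)) \
                - np.longdouble(cs.survival_S4(t + delta, d, design, params))
            contrib = pd_ * f4
        total += np.log(contrib)
    return float(total)


class TestLogLikelihood:
    def test_single_censored_record_is_log_f5(self, published):
        rec = cs.PatientRecord("c1", 65.1, "male", "no", "0",
                               "adenocarcinoma", "no", "0-i", "r0", "no",
                               2.0, 0)
        cohort = cs.Cohort.from_records([rec])
        design = cs.encode_design(rec)
        ll = cs.log_likelihood(cohort, published)
        assert ll == pytest.approx(
            math.log(cs.censored_survival_f5(2.0, design, published)),
            abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_cohorts(self, published):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(1, 21))
            cohort = cs.simulate_cohort(
                cs.SimulationConfig(n=n, seed=int(rng.integers(2**31))))
            ll = cs.log_likelihood(cohort, published)
            oracle = brute_force_loglik(cohort, published, None, cs.DAY)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_halving_delta_shifts_loglik_by_events_log_half(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=500, seed=5))
        n_events = int((cohort.table["event"] > 0).sum())
        ll1 = cs.log_likelihood(cohort, published, delta=cs.DAY)
        ll2 = cs.log_likelihood(cohort, published, delta=cs.DAY / 2)
        # first-order in delta: the shift equals n_events*log(1/2) up to an
        # O(n_events * delta) remainder
        assert ll2 - ll1 == pytest.approx(n_events * math.log(0.5), rel=1e-3)

    def test_analytic_gradient_matches_numeric(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=200, seed=9))
        mats = design_matrices(cohort.table, None)
        rng = np.random.default_rng(1)
        for family in cs.FAMILIES:
            theta = published.flat() + rng.normal(0, 0.05, published.n_coef)
            ll, g = _loglik_grad(theta, mats, family, cs.DAY)
            gn = approx_fprime(
                theta, lambda th: _loglik_grad(th, mats, family, cs.DAY,
                                               want_grad=False)[0], 1e-7)
            assert np.max(np.abs(g - gn) / (1.0 + np.abs(gn))) < 1e-4

    def test_off_support_returns_minus_inf(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=50, seed=2))
        bad = published.with_flat(published.flat().copy())
        bad.phi[0] = 0.5    # S4 increasing: interval masses negative
        bad.rho[0] = 0.5
        assert cs.log_likelihood(cohort, bad) == -np.inf


class TestFitMLE:
    def test_duplicating_records_preserves_argmax_and_doubles_loglik(self):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=300, seed=21))
        doubled = cohort.subset(np.tile(np.arange(len(cohort)), 2))
        fit1 = cs.fit_mle(cohort, n_starts=1, compute_se=False)
        fit2 = cs.fit_mle(doubled, n_starts=1, compute_se=False,
                          init=fit1.params)
        np.testing.assert_allclose(fit1.params.flat(), fit2.params.flat(),
                                   atol=2e-3)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-4)

    def test_mle_invariant_to_interval_width(self):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=800, seed=22))
        f_day = cs.fit_mle(cohort, delta=1 / 365.25, n_starts=1,
                           compute_se=False)
        f_half = cs.fit_mle(cohort, delta=0.5 / 365.25, n_starts=1,
                            compute_se=False, init=f_day.params)
        np.testing.assert_allclose(f_day.params.flat(), f_half.params.flat(),
                                   atol=2e-2)

    def test_monotonicity_violation_flagged_not_fatal(self, published):
        params = published.with_flat(published.flat().copy())
        params.phi[0] = 0.2
        assert not params.monotone_ok()
        assert published.monotone_ok()

    def test_serialization_round_trip(self, tmp_path, published):
        path = published.save(tmp_path / "m.txt")
        back = cs.ModelParameters.load(path)
        np.testing.assert_array_equal(back.flat(), published.flat())
        assert back.flat_names() == published.flat_names()
        assert back.family == published.family

    def test_degenerate_cohort_warns(self):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=40, seed=3, cap=0.001))
        assert (cohort.table["event"] == 0).all()
        with pytest.warns(UserWarning, match="degenerate"):
            cs.fit_mle(cohort, n_starts=1, compute_se=False, max_iter=50)


class TestCompareFamilies:
    def test_aic_formula_and_equal_dimensions(self):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=400, seed=13))
        table = cs.compare_families(cohort, n_starts=1)
        assert set(table["family"]) == set(cs.FAMILIES)
        assert table["k"].nunique() == 1
        for _, row in table.iterrows():
            assert row["aic"] == pytest.approx(
                2 * row["k"] - 2 * row["loglik"])

    def test_loglogistic_wins_majority_on_its_own_data(self):
        wins = 0
        for rep in range(6):
            cohort = cs.simulate_cohort(
                cs.SimulationConfig(n=1500, seed=700 + rep))
            table = cs.compare_families(cohort, n_starts=1)
            table = table[table["converged"]]
            if table.iloc[0]["family"] == "loglogistic":
                wins += 1
        assert wins >= 4
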