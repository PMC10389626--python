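"""Time-dependent AUC, bootstrap CIs, calibration, and goodness of fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import condsurv as cs
from condsurv.validation import _auc_from_marker, _case_control_masks


def brute_force_auc(marker, cases, controls):
    """Independent oracle: enumerate all case-control pairs."""
    num = 0.0
    n_pairs = 0
    for mc in marker[cases]:
        for mk in marker[controls]:
            n_pairs += 1
            if mc > mk:
                num += 1.0
            elif mc == mk:
                num += 0.5
    return num / n_pairs


def toy_cohort(times, events):
    n = len(times)
    df = pd.DataFrame({
        "patient_id": [f"t{i}" for i in range(n)],
        "age": 65.0, "sex": "male", "education_gt12": "no", "cci": "0",
        "histology": "adenocarcinoma", "chemoradiotherapy": "no",
        "stage": "0-i", "margin": "r0", "reoperation_30d": "no",
        "time": times, "event": events,
    })
    return cs.Cohort.from_table(df)


class TestTimeDependentAUC:
    def test_perfectly_ordered_marker_gives_one(self):
        cohort = toy_cohort([0.5, 0.8, 3.0, 3.5], [1, 2, 0, 0])
        marker = np.array([0.9, 0.8, 0.2, 0.1])
        auc = cs.time_dependent_auc(cohort, cs.published_parameters(), 2.0,
                                    marker=marker)
        assert auc == 1.0

    def test_four_pair_enumeration(self):
        # 2 cases {0.9, 0.7}, 2 controls {0.8, 0.1}: 3 of 4 pairs concordant
        cohort = toy_cohort([0.5, 0.8, 3.0, 3.5], [1, 1, 0, 0])
        marker = np.array([0.9, 0.7, 0.8, 0.1])
        auc = cs.time_dependent_auc(cohort, cs.published_parameters(), 2.0,
                                    marker=marker)
        assert auc == pytest.approx(0.75)

    @given(st.integers(0, 500))
    def test_matches_bruteforce_on_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        t = rng.uniform(0.05, 4.0, n)
        d = rng.integers(0, 3, n)
        marker = np.round(rng.uniform(0, 1, n), 1)   # induce ties
        h = float(rng.uniform(0.5, 3.5))
        outcome = "allcause" if rng.random() < 0.5 else "cancer"
        cases, controls = _case_control_masks(t, d, h, outcome)
        if cases.sum() == 0 or controls.sum() == 0:
            return
        fast = _auc_from_marker(marker, cases, controls)
        slow = brute_force_auc(marker, cases, controls)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_random_marker_near_half(self):
        rng = np.random.default_rng(101)
        n = 2000
        t = rng.uniform(0.05, 4.0, n)
        d = rng.integers(0, 3, n)
        marker = rng.uniform(0, 1, n)
        cases, controls = _case_control_masks(t, d, 2.0, "allcause")
        auc = _auc_from_marker(marker, cases, controls)
        n1, n0 = cases.sum(), controls.sum()
        se = np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))
        assert auc == pytest.approx(0.5, abs=3 * se)

    def test_undefined_without_cases_or_controls(self):
        cohort = toy_cohort([3.0, 3.5], [0, 0])
        with pytest.raises(ValueError, match="case"):
            cs.time_dependent_auc(cohort, cs.published_parameters(), 2.0)

    def test_model_discriminates_on_synthetic_cohort(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=2000, seed=55))
        for outcome in ("allcause", "cancer"):
            for h in (2.0, 4.0):
                auc = cs.time_dependent_auc(cohort, published, h, outcome)
                assert 0.6 < auc < 0.9


class TestBootstrapAUC:
    def test_single_replicate_median_is_that_auc(self):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=300, seed=56))
        boot = cs.bootstrap_auc_cv(cohort, n_boot=1, mode="apparent", seed=4,
                                   horizons=(2.0,))
        assert len(boot.samples["replicate"].unique()) == 1
        med = boot.summary.loc[boot.summary.outcome == "allcause",
                               "median"].iloc[0]
        assert med == boot.samples.loc[boot.samples.outcome == "allcause",
                                       "auc"].iloc[0]

    def test_ci_bounds_ordered_and_bracket_median(self):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=400, seed=57))
        boot = cs.bootstrap_auc_cv(cohort, n_boot=20, seed=4, horizons=(2.0,))
        for _, row in boot.summary.iterrows():
            assert row.ci_low <= row["median"] <= row.ci_high

    def test_apparent_mode_exceeds_out_of_bag(self):
        """Refit-on-resample AUC is optimistic relative to out-of-bag."""
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=500, seed=58))
        app = cs.bootstrap_auc_cv(cohort, n_boot=30, mode="apparent", seed=9,
                                  horizons=(2.0,))
        oob = cs.bootstrap_auc_cv(cohort, n_boot=30, mode="out_of_bag",
                                  seed=9, horizons=(2.0,))
        for outcome in ("allcause", "cancer"):
            m_app = app.summary.loc[app.summary.outcome == outcome,
                                    "median"].iloc[0]
            m_oob = oob.summary.loc[oob.summary.outcome == outcome,
                                    "median"].iloc[0]
            assert m_app >= m_oob

    def test_bit_reproducible_given_seed(self):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=300, seed=59))
        b1 = cs.bootstrap_auc_cv(cohort, n_boot=5, seed=11, horizons=(2.0,))
        b2 = cs.bootstrap_auc_cv(cohort, n_boot=5, seed=11, horizons=(2.0,))
        assert b1.samples.equals(b2.samples)


class TestAUCDifference:
    def test_identical_cohorts_center_near_zero(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=1000, seed=60))
        diff = cs.auc_difference_ci(cohort, cohort, published,
                                    horizons=(2.0,), n_boot=200, seed=12)
        for _, row in diff.iterrows():
            assert row.ci_low <= 0.0 <= row.ci_high
            assert abs(row.median_diff) < 0.05

    def test_attenuated_external_model_shows_positive_difference(self,
                                                                 published):
        internal = cs.simulate_cohort(cs.SimulationConfig(n=3000, seed=61))
        weak = published.with_flat(published.flat().copy())
        # shrink every covariate effect, keep intercepts: the model's marker
        # separates the external cohort less well
        for block in (weak.alpha, weak.eta):
            block[1:] *= 0.25
        external = cs.simulate_cohort(cs.SimulationConfig(n=3000, seed=62),
                                      params=weak)
        diff = cs.auc_difference_ci(internal, external, published,
                                    horizons=(2.0,), n_boot=100, seed=13)
        assert (diff["median_diff"] > 0).all()

    def test_single_replicate_ci_collapses(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=500, seed=63))
        diff = cs.auc_difference_ci(cohort, cohort, published,
                                    horizons=(2.0,), n_boot=1, seed=14)
        for _, row in diff.iterrows():
            assert row.ci_low == row.ci_high == row.median_diff


class TestHosmerLemeshow:
    def test_exact_calibration_gives_zero_statistic(self):
        pred = np.repeat([0.2, 0.8], 10)
        obs = np.concatenate([np.repeat([1.0], 2), np.repeat([0.0], 8),
                              np.repeat([1.0], 8), np.repeat([0.0], 2)])
        res = cs.hosmer_lemeshow(pred, obs, n_groups=2)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_single_constant_group_split_evenly(self):
        pred = np.full(10, 0.5)
        obs = np.array([1, 0] * 5, dtype=float)
        res = cs.hosmer_lemeshow(pred, obs)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(0, 1, 500)
        obs = (rng.uniform(0, 1, 500) < pred).astype(float)
        r1 = cs.hosmer_lemeshow(pred, obs)
        perm = rng.permutation(500)
        r2 = cs.hosmer_lemeshow(pred[perm], obs[perm])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.df == r2.df

    def test_deciles_partition_the_sample(self):
        rng = np.random.default_rng(7)
        pred = rng.uniform(0, 1, 997)
        obs = (rng.uniform(0, 1, 997) < pred).astype(float)
        res = cs.hosmer_lemeshow(pred, obs)
        assert res.table["n"].sum() == 997
        assert res.df == len(res.table) - 2

    def test_miscalibrated_predictions_rejected(self):
        rng = np.random.default_rng(8)
        pred = rng.uniform(0, 1, 2000)
        obs = (rng.uniform(0, 1, 2000) < np.clip(pred + 0.15, 0, 1)).astype(float)
        res = cs.hosmer_lemeshow(pred, obs)
        assert res.pvalue < 0.01


class TestGoodnessOfFit:
    def test_immortal_cohort_discrepancy_is_one_minus_min_f5(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=300, seed=64,
                                                        cap=0.8))
        # keep only the censored records: KM stays at 1 everywhere
        keep = np.flatnonzero(cohort.table["event"].to_numpy() == 0)
        immortal = cohort.subset(keep)
        params0 = cs.ModelParameters([-0.5], [2.0], [-0.76], [-2.2], [-0.42])
        gof = cs.km_vs_model_gof(immortal, params0)
        assert np.allclose(gof.km, 1.0)
        assert gof.discrepancy == pytest.approx(1.0 - gof.model_f5.min())

    def test_invariant_to_patient_order(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=400, seed=65))
        params0 = cs.ModelParameters([-0.5], [2.0], [-0.76], [-2.2], [-0.42])
        g1 = cs.km_vs_model_gof(cohort, params0)
        rng = np.random.default_rng(0)
        g2 = cs.km_vs_model_gof(
            cohort.subset(rng.permutation(len(cohort))), params0)
        assert g1.discrepancy == pytest.approx(g2.discrepancy, abs=1e-12)

    def test_requires_intercept_only_model(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=100, seed=66))
        with pytest.raises(ValueError, match="intercept-only"):
            cs.km_vs_model_gof(cohort, published)


class TestValidateModel:
    def test_report_assembles_all_components(self, published):
        cohort = cs.simulate_cohort(cs.SimulationConfig(n=500, seed=67))
        report = cs.validate_model(cohort, published, horizons=(2.0,),
                                   n_boot=3)
        assert not report.auc_curve.empty
        assert report.auc_summary is not None
        assert (2.0, "allcause") in report.hl
        assert report.gof is not None
        assert report.gof.discrepancy < 0.2
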