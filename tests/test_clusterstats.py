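import numpy as np
import pandas as pd
import pytest

from eegate import (chain_montage, contrast_ols, fit_electrode_model, form_clusters,
                    interaction_model, median_split_analysis, permutation_test,
                    posthoc_condition_slopes, toy_grid_montage, vif)
from eegate.synth import CONDITIONS, EffectConfig, SubjectParams, synth_behavior
from eegate.behavior import accuracy_by_condition, filter_trials

from conftest import make_accuracy_table
from helpers import brute_force_clusters




class TestElectrodeModels:
    def _marker(self, acc, seed):
        subjects = sorted(acc["subject"].unique())
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=len(subjects)), index=subjects)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mixed_model_contrast_equals_difference_ols(self, seed):
        acc = make_accuracy_table(np.random.default_rng(seed), n_subjects=24)
        m = self._marker(acc, seed + 100)
        fast = contrast_ols(acc, m)
        reml = fit_electrode_model(acc, m)
        assert reml.contrast_beta == pytest.approx(fast.contrast_beta, abs=1e-8)
        assert reml.contrast_t == pytest.approx(fast.contrast_t, abs=1e-6)
        assert reml.contrast_p == pytest.approx(fast.contrast_p, abs=1e-6)

    def test_three_way_contrast_equivalence(self):
        acc = make_accuracy_table(np.random.default_rng(5), n_subjects=30)
        m = self._marker(acc, 6)
        aa = self._marker(acc, 7).abs() + 0.1
        fast = contrast_ols(acc, m, aa=aa)
        reml = fit_electrode_model(acc, m, formula_id="m2a", aa=aa)
        assert reml.contrast_t == pytest.approx(fast.contrast_t, abs=1e-6)

    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(8)
        n = 80
        subjects = [f"s{i:03d}" for i in range(n)]
        m = rng.normal(size=n)
        rows = []
        beta = -0.04
        for i, s in enumerate(subjects):
            u = rng.normal(0, 0.03)
            for c in CONDITIONS:
                mu = 0.9 + u + (beta * m[i] if c == "ignore" else 0.0)
                rows.append(dict(subject=s, condition=c,
                                 accuracy=mu + rng.normal(0, 0.03), n_trials=32))
        acc = pd.DataFrame(rows)
        fit = contrast_ols(acc, pd.Series(m, index=subjects))
        m_sd = m.std(ddof=0)
        assert fit.contrast_beta == pytest.approx(beta * m_sd, abs=2.5 * fit.coefficients["se"].iloc[0])
        assert fit.contrast_p < 0.01

    def test_null_contrast_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            acc = make_accuracy_table(rng, n_subjects=20)
            subjects = sorted(acc["subject"].unique())
            ps.append(contrast_ols(acc, pd.Series(rng.normal(size=20), index=subjects)).contrast_p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFormClusters:
    def _table(self, electrodes, ts, ps):
        return pd.DataFrame(dict(electrode=electrodes, contrast_t=ts, contrast_p=ps))

    def test_isolated_significant_electrode_is_no_cluster(self, chain8):
        t = self._table(chain8.channel_names, [3.0] + [0.1] * 7,
                        [0.01] + [0.9] * 7)
        assert form_clusters(t, chain8) == []

    def test_no_significant_electrodes(self, chain8):
        t = self._table(chain8.channel_names, [0.5] * 8, [0.5] * 8)
        assert form_clusters(t, chain8) == []

    def test_chain_pattern_resolves_two_clusters(self, chain8):
        # significant at indices 1,2 and 5,6,7
        ts = [0.1, 2.5, 2.7, 0.1, 0.2, 3.0, 2.8, 2.6]
        ps = [0.9, 0.01, 0.01, 0.9, 0.9, 0.01, 0.01, 0.02]
        clusters = form_clusters(self._table(chain8.channel_names, ts, ps), chain8)
        members = sorted(sorted(c.members) for c in clusters)
        assert members == [["E1", "E2"], ["E5", "E6", "E7"]]
        masses = {tuple(sorted(c.members)): c.mass for c in clusters}
        assert masses[("E1", "E2")] == pytest.approx(5.2)
        assert masses[("E5", "E6", "E7")] == pytest.approx(8.4)

    def test_opposite_signs_never_merge(self, chain8):
        ts = [2.5, -2.5, 2.5, 2.6, 0, 0, 0, 0]
        ps = [0.01] * 4 + [0.9] * 4
        clusters = form_clusters(self._table(chain8.channel_names, ts, ps), chain8)
        assert sorted(sorted(c.members) for c in clusters) == [["E2", "E3"]]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(10)
        for trial in range(50):
            n = int(rng.integers(4, 13))
            montage = (chain_montage(n) if rng.random() < 0.5
                       else toy_grid_montage(2, max(2, n // 2)))
            names = montage.channel_names
            ts = rng.normal(scale=2, size=len(names))
            ps = rng.uniform(size=len(names)) ** 2
            table = pd.DataFrame(dict(electrode=names, contrast_t=ts, contrast_p=ps))
            ours = sorted(sorted(c.members) for c in form_clusters(table, montage))
            assert ours == brute_force_clusters(table, montage)


class TestPermutationTest:
    def test_reproducible_from_seed(self, chain8, null_accuracy):
        subjects = sorted(null_accuracy["subject"].unique())
        M = pd.DataFrame(np.random.default_rng(11).normal(size=(len(subjects), 8)),
                         index=subjects, columns=chain8.channel_names)
        r1 = permutation_test(null_accuracy, M, chain8, B=150, seed=42)
        r2 = permutation_test(null_accuracy, M, chain8, B=150, seed=42)
        np.testing.assert_array_equal(r1.null_max_masses, r2.null_max_masses)
        np.testing.assert_array_equal(r1.cluster_p, r2.cluster_p)

    def test_strong_planted_effect_detected(self, chain8):
        rng = np.random.default_rng(12)
        n = 60
        subjects = [f"s{i:03d}" for i in range(n)]
        m = rng.normal(size=n)
        rows = []
        for i, s in enumerate(subjects):
            u = rng.normal(0, 0.02)
            for c in CONDITIONS:
                mu = 0.9 + u - (0.06 * m[i] if c == "ignore" else 0.0)
                rows.append(dict(subject=s, condition=c,
                                 accuracy=mu + rng.normal(0, 0.02), n_trials=32))
        acc = pd.DataFrame(rows)
        # same subject-level marker at all electrodes -> one big cluster
        M = pd.DataFrame(np.tile(m[:, None], (1, 8)) + rng.normal(scale=0.2, size=(n, 8)),
                         index=subjects, columns=chain8.channel_names)
        res = permutation_test(acc, M, chain8, B=200, seed=13)
        assert res.significant.any()
        assert res.cluster_p.min() == pytest.approx(1 / 201, abs=1e-9)

    def test_p_value_floor_and_bounds(self, chain8, null_accuracy):
        subjects = sorted(null_accuracy["subject"].unique())
        M = pd.DataFrame(np.random.default_rng(14).normal(size=(len(subjects), 8)),
                         index=subjects, columns=chain8.channel_names)
        res = permutation_test(null_accuracy, M, chain8, B=120, seed=3)
        assert np.all(res.cluster_p >= 1 / 121) and np.all(res.cluster_p <= 1)

    def test_few_permutations_warn(self, chain8, null_accuracy):
        subjects = sorted(null_accuracy["subject"].unique())
        M = pd.DataFrame(np.random.default_rng(15).normal(size=(len(subjects), 8)),
                         index=subjects, columns=chain8.channel_names)
        with pytest.warns(RuntimeWarning):
            permutation_test(null_accuracy, M, chain8, B=50, seed=4)


class TestPosthocAndInteraction:
    def test_condition_specific_slope_signs_recovered(self):
        rng = np.random.default_rng(16)
        cohort = [SubjectParams(f"s{i:03d}",
                                target_dfa=float(np.clip(rng.normal(0.77, 0.09), 0.55, 0.95)))
                  for i in range(200)]
        eff = EffectConfig(dfa_slope={"ignore": -0.03, "update": 0.0,
                                      "control_short": -0.02, "control_long": -0.03},
                          psd_aa_slope={c: 0.0 for c in CONDITIONS},
                          contaminant_rate=0.0, seed=17)
        acc = accuracy_by_condition(filter_trials(synth_behavior(cohort, eff)))
        marker = pd.Series({p.subject_id: p.dfa_scalar for p in cohort})
        slopes = posthoc_condition_slopes(acc, marker).set_index("condition")
        assert slopes.loc["ignore", "beta"] < 0
        assert slopes.loc["control_long", "beta"] < 0
        assert slopes.loc["control_short", "beta"] < 0
        assert slopes.loc["update", "p"] > 0.05

    def test_marker_shift_invariance(self, null_accuracy):
        subjects = sorted(null_accuracy["subject"].unique())
        m = pd.Series(np.random.default_rng(18).normal(size=len(subjects)), index=subjects)
        s1 = posthoc_condition_slopes(null_accuracy, m)
        s2 = posthoc_condition_slopes(null_accuracy, m + 100.0)
        pd.testing.assert_frame_equal(s1, s2)

    def test_interaction_model_recovers_planted_product_effect(self):
        rng = np.random.default_rng(19)
        n = 150
        subjects = [f"s{i:03d}" for i in range(n)]
        zd = rng.normal(size=n)
        zp = rng.normal(size=n)
        rows = []
        for i, s in enumerate(subjects):
            u = rng.normal(0, 0.02)
            for c in ("ignore", "update"):
                mu = 0.9 + u - 0.03 * zd[i] * zp[i]
                rows.append(dict(subject=s, condition=c,
                                 accuracy=mu + rng.normal(0, 0.02), n_trials=32))
        acc = pd.DataFrame(rows)
        out = interaction_model(acc, pd.Series(zd, index=subjects),
                                pd.Series(zp, index=subjects))
        assert out["dfa_psd"]["beta"] < 0
        assert out["dfa_psd"]["p"] < 0.01
        assert out["vif"]["dfa"] == pytest.approx(1.0, abs=0.1)

    def test_median_split_rules_and_group_comparison(self):
        rng = np.random.default_rng(20)
        n = 41                                  # odd: lower group gets the median subject
        subjects = [f"s{i:03d}" for i in range(n)]
        psd = pd.Series(np.arange(n, dtype=float), index=subjects)
        dfa_vals = pd.Series(0.7 + 0.002 * np.arange(n) + rng.normal(0, 0.01, n),
                             index=subjects)
        rows = [dict(subject=s, condition=c, accuracy=0.9 + rng.normal(0, 0.02),
                     n_trials=32)
                for s in subjects for c in ("ignore", "update")]
        out = median_split_analysis(pd.DataFrame(rows), dfa_vals, psd)
        assert out["flat"]["n"] == 21 and out["steep"]["n"] == 20
        # steep-PSD group has the higher DFA by construction
        assert out["steep"]["dfa_mean"] > out["flat"]["dfa_mean"]
        assert out["dfa_group_test"]["p"] < 0.001

    def test_identical_groups_give_null_welch_t(self):
        rng = np.random.default_rng(21)
        n = 40
        subjects = [f"s{i:03d}" for i in range(n)]
        rows = [dict(subject=s, condition=c, accuracy=0.9, n_trials=32)
                for s in subjects for c in ("ignore", "update")]
        out = median_split_analysis(pd.DataFrame(rows),
                                    pd.Series(rng.normal(size=n), index=subjects),
                                    pd.Series(rng.normal(size=n), index=subjects))
        assert abs(out["dfa_group_test"]["t"]) < 2.5


class TestVif:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(22)
        # orthogonal to each other and to the intercept column
        q, _ = np.linalg.qr(np.column_stack([np.ones(100), rng.normal(size=(100, 3))]))
        np.testing.assert_allclose(vif(q[:, 1:]), np.ones(3), atol=1e-10)

    def test_closed_form_for_two_correlated_predictors(self):
        n = 200_000
        rng = np.random.default_rng(23)
        r = 0.302
        x = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
        expected = 1 / (1 - r ** 2)             # = 1.10 for r = 0.302
        np.testing.assert_allclose(vif(x), [expected, expected], rtol=0.02)

    def test_perfect_collinearity_reported_infinite(self):
        x = np.random.default_rng(24).normal(size=100)
        assert np.isinf(vif(np.column_stack([x, 2 * x]))).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            vif(np.ones((10, 1)))
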