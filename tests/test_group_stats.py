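"""t-test / ANOVA / studentized range / Duncan MRT against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cytoilc import duncan_mrt, marker_contrasts, one_way_anova, \
    studentized_range_quantile, unpaired_ttest
from cytoilc.group_stats import duncan_alpha_p
from conftest import make_events


class TestTTest:
    def test_identical_samples(self):
        r = unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_pooled_example(self):
        # means 2 and 5, pooled s^2 = 1, se = sqrt(2/3):
        # t = -3 / 0.8165 = -3.674, df = 4
        r = unpaired_ttest([1, 2, 3], [4, 5, 6], variant="student")
        assert r.t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4
        assert r.p_value == pytest.approx(0.0214, abs=5e-4)

    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        r1 = unpaired_ttest(a, b)
        r2 = unpaired_ttest(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    @pytest.mark.parametrize("variant,equal_var", [("student", True),
                                                   ("welch", False)])
    def test_matches_scipy(self, variant, equal_var):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 9)
        ours = unpaired_ttest(a, b, variant=variant)
        ref = sps.ttest_ind(a, b, equal_var=equal_var)
        assert ours.t_statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_insufficient_data_errors(self):
        with pytest.raises(ValueError):
            unpaired_ttest([1.0], [2.0, 3.0])

    def test_constant_unequal_means_errors(self):
        with pytest.raises(ValueError, match="variance"):
            unpaired_ttest([1.0, 1.0], [2.0, 2.0])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(2)
        ps = np.array([
            unpaired_ttest(rng.normal(size=10), rng.normal(size=10)).p_value
            for _ in range(2000)
        ])
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestAnova:
    def test_all_equal_gives_zero_F(self):
        v = np.tile([5.0, 5.0], 3)
        g = np.repeat(["a", "b", "c"], 2)
        msb, msw, dfe, F, p = one_way_anova(v, g)
        assert F == 0.0 and msb == 0.0

    def test_two_groups_reduce_to_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 11)
        v = np.concatenate([a, b])
        g = np.array(["a"] * 8 + ["b"] * 11)
        _, _, dfe, F, p = one_way_anova(v, g)
        t = unpaired_ttest(a, b, variant="student")
        assert F == pytest.approx(t.t_statistic ** 2)
        assert p == pytest.approx(t.p_value)
        assert dfe == t.df

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        perm = rng.permutation(30)
        a = one_way_anova(v, g)
        b = one_way_anova(v[perm], g[perm])
        assert a == pytest.approx(b, rel=1e-12)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestStudentizedRange:
    def test_infinite_df_pair_limit(self):
        # range of two normals: q = sqrt(2) * z_{0.975}
        q = studentized_range_quantile(0.05, 2, 1e6)
        assert q == pytest.approx(np.sqrt(2) * sps.norm.ppf(0.975),
                                  abs=1e-2)

    def test_monotone_in_k(self):
        qs = [studentized_range_quantile(0.05, k, 20) for k in (2, 3, 5, 8)]
        assert np.all(np.diff(qs) > 0)

    def test_monte_carlo_oracle(self):
        q = studentized_range_quantile(0.05, 3, 10)
        rng = np.random.default_rng(5)
        n = 2_000_000
        z = rng.normal(size=(n, 3))
        s = np.sqrt(rng.chisquare(10, size=n) / 10)
        mc = np.quantile((z.max(axis=1) - z.min(axis=1)) / s, 0.95)
        assert q == pytest.approx(mc, abs=0.02)

    @pytest.mark.parametrize("args", [(0.0, 3, 10), (0.05, 1, 10),
                                      (0.05, 3, 0.5)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            studentized_range_quantile(*args)


class TestDuncan:
    def test_protection_level_closed_form(self):
        assert duncan_alpha_p(0.05, 3) == pytest.approx(1 - 0.95 ** 2)
        assert duncan_alpha_p(0.05, 3) == pytest.approx(0.0975)
        assert duncan_alpha_p(0.05, 2) == pytest.approx(0.05)

    def test_equal_means_one_homogeneous_subset(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        res = duncan_mrt(v, g)
        assert not res.significant.any()
        assert res.homogeneous_subsets == [["a", "b", "c"]]

    def test_well_separated_means_all_significant(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.normal(mu, 1, 10) for mu in (0, 10, 20)])
        g = np.repeat(["lo", "mid", "hi"], 10)
        res = duncan_mrt(v, g)
        assert res.significant[np.triu_indices(3, 1)].all()
        assert res.homogeneous_subsets == [["hi"], ["mid"], ["lo"]]
        assert list(res.groups) == ["hi", "mid", "lo"]

    def test_critical_ranges_nondecreasing_in_p(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=50)
        g = np.tile(["a", "b", "c", "d", "e"], 10)
        res = duncan_mrt(v, g)
        ranges = [res.critical_ranges[p] for p in sorted(res.critical_ranges)]
        assert np.all(np.diff(ranges) >= 0)

    def test_protection_consistency_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            k = rng.integers(3, 6)
            v = np.concatenate(
                [rng.normal(rng.uniform(0, 3), 1, 8) for _ in range(k)])
            g = np.repeat([f"g{i}" for i in range(k)], 8)
            res = duncan_mrt(v, g)
            for subset in res.homogeneous_subsets:
                idx = [res.groups.index(s) for s in subset]
                for a in idx:
                    for b in idx:
                        assert not res.significant[a, b]
            assert np.array_equal(res.significant, res.significant.T)
            assert not res.significant.diagonal().any()

    def test_null_calibration_at_nominal_levels(self):
        """Per-pair rejection under the complete null.

        The quantities with exact nominal levels: with two groups the single
        pair rejects at rate alpha; with three, the extreme pair rejects at
        alpha_3 = 0.0975.  Adjacent pairs are protected, so their rate must
        not exceed alpha.
        """
        rng = np.random.default_rng(9)
        reps = 2000
        g2 = np.repeat(["a", "b"], 20)
        rate2 = np.mean([
            duncan_mrt(rng.normal(size=40), g2).significant[0, 1]
            for _ in range(reps)])
        assert rate2 == pytest.approx(0.05, abs=0.015)

        g3 = np.repeat(["a", "b", "c"], 20)
        extreme = adjacent = 0
        for _ in range(reps):
            res = duncan_mrt(rng.normal(size=60), g3)
            extreme += res.significant[0, 2]
            adjacent += res.significant[0, 1] + res.significant[1, 2]
        assert extreme / reps == pytest.approx(duncan_alpha_p(0.05, 3),
                                               abs=0.02)
        assert adjacent / (2 * reps) <= 0.05 + 0.015

    def test_unequal_n_uses_pairwise_harmonic_mean(self):
        rng = np.random.default_rng(10)
        v = np.concatenate([rng.normal(0, 1, 5), rng.normal(0.5, 1, 40)])
        g = np.array(["a"] * 5 + ["b"] * 40)
        res = duncan_mrt(v, g)
        n_h = 2 / (1 / 5 + 1 / 40)
        q = studentized_range_quantile(0.05, 2, float(res.df_error))
        expected = q * np.sqrt(res.mse / n_h)
        diff = abs(res.means[0] - res.means[1])
        assert bool(res.significant[0, 1]) == (diff > expected)


class TestMarkerContrasts:
    def _pooled(self, mini_panel, labels, shift):
        rng = np.random.default_rng(11)
        n = len(labels)
        vals = rng.normal(1.0, 0.2, (n, mini_panel.n_markers))
        j = mini_panel.marker_names.index("CD127")
        vals[:, j] += shift * (np.asarray(labels) == "ILC2")
        em = make_events(np.abs(vals), mini_panel,
                         scale_state="transformed")
        em.annotations["phenotype"] = labels
        return em

    def test_identical_groups_nothing_significant(self, mini_panel):
        labels = ["ILC1"] * 30 + ["ILC2"] * 30
        em = self._pooled(mini_panel, labels, shift=0.0)
        results, means = marker_contrasts(em, ["CD56", "NKp44"])
        assert all(not r.significant.any() for r in results.values())

    def test_shifted_marker_detected(self, mini_panel):
        labels = ["ILC1"] * 30 + ["ILC2"] * 30
        em = self._pooled(mini_panel, labels, shift=2.0)
        results, means = marker_contrasts(em, ["CD127"])
        assert results["CD127"].significant[0, 1]
        m = means.set_index("group")["mean"]
        assert m["ILC2"] > m["ILC1"]

    def test_single_group_errors(self, mini_panel):
        em = self._pooled(mini_panel, ["ILC1"] * 20, shift=0.0)
        em.annotations["cluster"] = 1
        with pytest.raises(ValueError, match="2"):
            marker_contrasts(em, ["CD127"], grouping="cluster")
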