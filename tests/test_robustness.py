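"""Agreement statistics: exact permutation p-values, Lin's CCC,
Bland-Altman arithmetic, boundary sensitivity and clustering oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdxrad import robustness as rb


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        rho, _ = rb.spearman_rho_p(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = rb.spearman_rho_p(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_brute_force_enumeration_at_n5(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho_obs, p = rb.spearman_rho_p(x, y)
        # enumerate all 120 permutations independently
        count = 0
        for perm in permutations(y):
            r = stats.spearmanr(x, perm).statistic
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 120)

    def test_invariant_under_monotone_transform_of_either_argument(self, rng):
        x, y = rng.random(10), rng.random(10)
        rho, _ = rb.spearman_rho_p(x, y)
        rho2, _ = rb.spearman_rho_p(np.log(x + 1), y**3)
        assert rho2 == pytest.approx(rho)

    def test_constant_feature_reported_missing(self):
        rho, p = rb.spearman_rho_p(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_table_flags(self, rng):
        subj = [f"s{i}" for i in range(6)]
        a = pd.DataFrame({"f1": np.arange(6.0), "f2": rng.random(6)}, index=subj)
        b = pd.DataFrame({"f1": np.arange(6.0) * 2 + 1, "f2": rng.random(6)}, index=subj)
        tab = rb.spearman_table(a, b)
        assert tab.loc["f1", "rho"] == pytest.approx(1.0)
        assert bool(tab.loc["f1", "high_corr"])


class TestCCC:
    def test_identity_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert rb.ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_penalized_increasingly(self):
        x = np.arange(10.0)
        vals = [rb.ccc(x, x + c) for c in (0.0, 1.0, 3.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_hand_formula_to_machine_precision(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.1, 2.9, 4.2])
        # population moments by explicit arithmetic
        sxy = np.mean((x - x.mean()) * (y - y.mean()))
        expected = 2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
        assert rb.ccc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_lin_inequality_ccc_below_pearson(self, rng):
        for _ in range(50):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8) + 0.5 * x
            r = abs(stats.pearsonr(x, y).statistic)
            assert rb.ccc(x, y) <= r + 1e-12

    def test_sample_convention_option(self, rng):
        x, y = rng.random(8), rng.random(8)
        assert rb.ccc(x, y, "population") != rb.ccc(x, y, "sample")


class TestBlandAltman:
    def test_identical_volumes_zero_bias_zero_loa(self):
        v = np.array([10.0, 20.0, 30.0])
        ba = rb.bland_altman_volumes(v, v)
        assert ba["bias_percent"] == 0.0
        assert ba["loa_low"] == 0.0 and ba["loa_high"] == 0.0

    def test_constant_scaling_gives_exact_bias(self):
        v = np.array([10.0, 25.0, 40.0, 55.0])
        ba = rb.bland_altman_volumes(v, 0.95 * v)
        assert ba["bias_percent"] == pytest.approx(5.0, abs=1e-12)
        assert ba["sd_percent"] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_underestimation_positive(self):
        """A method that segments smaller volumes than the reference has
        positive bias, matching the convention of reporting underestimation
        as a positive mean volume change."""
        v = np.array([10.0, 20.0, 30.0])
        ba = rb.bland_altman_volumes(v, v * 0.9)
        assert ba["bias_percent"] > 0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rb.bland_altman_volumes(np.array([0.0, 1.0, 2.0]), np.ones(3))


class TestSensitivity:
    def _tables(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        subj = [f"s{i}" for i in range(n)]
        vol_a = pd.Series(rng.uniform(100, 300, n), index=subj)
        vol_b = vol_a - rng.uniform(5, 30, n)
        return subj, vol_a, vol_b, rng

    def test_feature_proportional_to_volume_change_not_robust(self):
        subj, vol_a, vol_b, _ = self._tables()
        dv = vol_a - vol_b
        a = pd.DataFrame({"f": 2 * dv}, index=subj)
        b = pd.DataFrame({"f": np.zeros(len(subj))}, index=subj)
        tab = rb.sensitivity_to_boundary(a, b, vol_a, vol_b)
        assert tab.loc["f", "rho"] == pytest.approx(1.0)
        assert not tab.loc["f", "robust"]

    def test_identical_tables_flagged_degenerate_not_robust(self):
        subj, vol_a, vol_b, rng = self._tables()
        a = pd.DataFrame({"f": rng.random(len(subj))}, index=subj)
        tab = rb.sensitivity_to_boundary(a, a.copy(), vol_a, vol_b)
        assert bool(tab.loc["f", "degenerate"])
        assert not tab.loc["f", "robust"]

    def test_band_coverage_matches_exact_null_under_independence(self):
        """With feature changes independent of volume changes, the fraction
        of replicates inside the +/-0.4 band must match the exact n=8
        permutation null (about 0.673)."""
        n = 8
        null = rb._exact_null_rhos(n)
        expected = float(np.mean(np.abs(null) <= rb.ROBUST_BAND))
        rng = np.random.default_rng(99)
        hits = 0
        reps = 300
        for _ in range(reps):
            df = rng.standard_normal(n)
            dv = rng.standard_normal(n)
            rho, _ = rb.spearman_rho_p(df, dv)
            hits += abs(rho) <= rb.ROBUST_BAND
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(hits / reps - expected) < 4 * se


def _brute_complete_linkage(d):
    """Naive O(n^3) agglomeration; returns sorted merge heights."""
    clusters = [{i} for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return sorted(heights)


class TestClustering:
    def test_two_perfectly_correlated_one_anticorrelated(self):
        subj = [f"s{i}" for i in range(6)]
        base = np.arange(6.0)
        tab = pd.DataFrame(
            {"a": base, "b": 2 * base + 1, "c": -base}, index=subj
        )
        report = rb.cluster_features(tab, cut_height=1.0)
        assert report.n_clusters == 2
        assert report.cluster_assignments["a"] == report.cluster_assignments["b"]
        assert report.cluster_assignments["a"] != report.cluster_assignments["c"]

    def test_merge_heights_match_naive_agglomeration(self, rng):
        for _ in range(5):
            n = 10
            tab = pd.DataFrame(
                rng.standard_normal((8, n)), columns=[f"f{i}" for i in range(n)]
            )
            d, _ = rb.correlation_distance_matrix(tab)
            report = rb.cluster_features(tab, cut_height=0.5)
            np.testing.assert_allclose(
                sorted(report.merge_heights), _brute_complete_linkage(d), atol=1e-12
            )

    def test_cluster_count_nonincreasing_in_cut_height(self, rng):
        tab = pd.DataFrame(rng.standard_normal((8, 12)))
        tab.columns = [f"f{i}" for i in range(12)]
        counts = [
            rb.cluster_features(tab, cut_height=h).n_clusters
            for h in (0.2, 0.6, 1.0, 1.6, 2.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ultrametric_distances_cophenetic_one(self):
        # two tight blocks far apart: distances are exactly ultrametric
        subj = [f"s{i}" for i in range(8)]
        base = np.arange(8.0)
        tab = pd.DataFrame({"a": base, "b": base * 3, "c": -base, "d": -2 * base},
                           index=subj)
        report = rb.cluster_features(tab, cut_height=1.0)
        assert report.cophenetic_coefficients["complete"] == pytest.approx(1.0)

    def test_cophenetic_in_valid_range(self, rng):
        tab = pd.DataFrame(rng.standard_normal((8, 6)))
        tab.columns = [f"f{i}" for i in range(6)]
        report = rb.cluster_features(tab, cut_height=1.0)
        for v in report.cophenetic_coefficients.values():
            assert -1.0 <= v <= 1.0


class TestConsensusReport:
    def _frames(self, flags):
        idx = [f"f{i}" for i in range(len(flags[0]))]
        scc = pd.DataFrame({"high_corr": flags[0]}, index=idx)
        ccc_t = pd.DataFrame({"reproducible": flags[1]}, index=idx)
        sens = pd.DataFrame({"robust": flags[2]}, index=idx)
        return scc, ccc_t, sens

    def test_all_flags_true_full_intersection(self):
        scc, ccc_t, sens = self._frames([[True] * 4] * 3)
        rep = rb.consensus_feature_report(scc, ccc_t, sens)
        assert rep["n_consensus"] == 4 and rep["pct_consensus"] == 100.0

    def test_disjoint_flags_empty_intersection(self):
        scc, ccc_t, sens = self._frames(
            [[True, False], [False, True], [True, True]]
        )
        rep = rb.consensus_feature_report(scc, ccc_t, sens)
        assert rep["n_consensus"] == 0

    def test_percentages_two_decimals_over_configurable_denominator(self):
        scc, ccc_t, sens = self._frames([[True, True, False]] * 3)
        rep = rb.consensus_feature_report(scc, ccc_t, sens, denominator=143)
        assert rep["pct_consensus"] == round(2 / 143 * 100, 2)
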