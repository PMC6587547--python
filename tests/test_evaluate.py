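"""Ranking, LD-linked true-positive matching, and the power/FDR/Type-I
arithmetic."""

import numpy as np
import pandas as pd
import pytest

import gwasbench as gb
from gwasbench.association import AssociationResult
from gwasbench.evaluate import RankedCalls

from conftest import toy_matrix


def freq_result(ps, positions=None):
    n = len(ps)
    table = pd.DataFrame({"id": [f"m{i}" for i in range(n)], "chrom": "1",
                          "pos": positions or range(100, 100 + 100 * n, 100),
                          "p": ps})
    return AssociationResult(table=table, engine="mlm")


def bayes_result(mf, mv):
    n = len(mf)
    table = pd.DataFrame({"id": [f"m{i}" for i in range(n)], "chrom": "1",
                          "pos": range(100, 100 + 100 * n, 100),
                          "model_frequency": mf, "marker_variance": mv})
    return AssociationResult(table=table, engine="bayescpi")


class TestRanking:
    def test_ascending_p(self):
        calls = gb.rank_markers(freq_result([0.5, 1e-4, 0.01]))
        np.testing.assert_array_equal(calls.order, [1, 2, 0])

    def test_model_frequency_tie_broken_by_variance(self):
        calls = gb.rank_markers(bayes_result([0.9, 0.9], [0.1, 0.4]))
        np.testing.assert_array_equal(calls.order, [1, 0])

    def test_all_equal_scores_stable_index_order(self):
        calls = gb.rank_markers(bayes_result([0.5] * 4, [0.2] * 4))
        np.testing.assert_array_equal(calls.order, [0, 1, 2, 3])

    def test_nonfinite_scores_last_and_flagged(self):
        calls = gb.rank_markers(freq_result([0.5, np.nan, 0.01]))
        assert calls.order[-1] == 1
        assert calls.n_flagged == 1


class TestMatching:
    def test_membership_only(self):
        # positives {m1, m7, m9}, causal {m1, m4}, no LD links
        rng = np.random.default_rng(0)
        G = toy_matrix(rng.binomial(2, 0.5, (10, 40)))
        arch = gb.TraitArchitecture([1, 4], [1.0, 1.0], h2=0.5)
        tp, eff, fp = gb.match_positives(np.array([1, 7, 9]), arch, G)
        assert (tp, eff, fp) == (1, 3, 2)

    def test_merging_linked_positives(self):
        # p1 and p2 both linked (r2 > 0.6) to causal c1; p3 unlinked
        rng = np.random.default_rng(1)
        c1 = rng.binomial(1, 0.5, 60).astype(float) * 2
        p1 = c1.copy()
        flip = rng.choice(60, 5, replace=False)
        p1[flip] = 2 - p1[flip]            # r2 ~ 0.7 with c1
        p2 = c1.copy()
        flip = rng.choice(60, 6, replace=False)
        p2[flip] = 2 - p2[flip]
        p3 = rng.binomial(1, 0.5, 60).astype(float) * 2
        G = toy_matrix([c1, p1, p2, p3])
        assert np.corrcoef(c1, p1)[0, 1] ** 2 > 0.6
        assert np.corrcoef(c1, p2)[0, 1] ** 2 > 0.6
        assert np.corrcoef(c1, p3)[0, 1] ** 2 < 0.6
        arch = gb.TraitArchitecture([0], [1.0], h2=0.5)
        tp, eff, fp = gb.match_positives(np.array([1, 2, 3]), arch, G)
        assert (tp, eff, fp) == (1, 2, 1)

    def test_r2_exactly_at_threshold_not_true_positive(self):
        # contingency built so r2 == 0.64 > 0.6 counts, == 0.6 does not:
        # use the strictness of the comparison at the exact threshold
        x = np.array([0, 0, 0, 0, 2, 2, 2, 2, 2, 2], float)
        ys = np.array([0, 0, 0, 2, 2, 2, 2, 2, 0, 0], float)
        r2 = np.corrcoef(x, ys)[0, 1] ** 2
        G = toy_matrix([x, ys])
        arch = gb.TraitArchitecture([0], [1.0], h2=0.5)
        tp, eff, fp = gb.match_positives(np.array([1]), arch, G,
                                         r2_threshold=r2)
        assert (tp, fp) == (0, 1)          # strict ">": equality is not TP
        tp2, _, _ = gb.match_positives(np.array([1]), arch, G,
                                       r2_threshold=r2 - 1e-9)
        assert tp2 == 1

    def test_ld_matching_respects_window(self):
        x = np.array([0, 2, 0, 2, 0, 2, 0, 2], float)
        G = toy_matrix([x, x], positions=[100, 15_000_100])
        arch = gb.TraitArchitecture([0], [1.0], h2=0.5)
        tp, _, fp = gb.match_positives(np.array([1]), arch, G)
        assert (tp, fp) == (0, 1)          # same chromosome but beyond 10 Mb


class TestMetricsArithmetic:
    def test_eqs_direct(self):
        row = gb.compute_metrics(1, 3, 2, n_causal=2, M=10)
        assert row["power"] == 0.5
        assert row["fdr"] == pytest.approx(2 / 3)
        assert row["type1"] == pytest.approx(0.25)

    def test_perfect_recovery(self):
        row = gb.compute_metrics(5, 5, 0, n_causal=5, M=100)
        assert (row["power"], row["fdr"], row["type1"]) == (1.0, 0.0, 0.0)

    def test_empty_call_set_flagged(self):
        row = gb.compute_metrics(0, 0, 0, n_causal=3, M=10)
        assert row["power"] == 0.0 and row["fdr"] == 0.0
        assert row["fdr_undefined"]

    def test_zero_causal_rejected(self):
        with pytest.raises(ValueError):
            gb.compute_metrics(0, 0, 0, n_causal=0, M=10)


class TestMetricsCurve:
    def _indep_geno(self, M=60, N=50, seed=3):
        rng = np.random.default_rng(seed)
        return toy_matrix(rng.binomial(2, 0.5, (M, N)))

    def test_single_k_equals_compute_metrics(self):
        G = self._indep_geno()
        arch = gb.TraitArchitecture([0, 5], [1.0, 1.0], h2=0.5)
        res = freq_result(list(np.linspace(0.01, 0.9, G.n_markers)),
                          positions=list(G.markers["pos"]))
        curve = gb.metrics_curve(res, arch, G, K_grid=[1])
        calls = gb.rank_markers(res)
        tp, eff, fp = gb.match_positives(calls, arch, G, K=1)
        row = gb.compute_metrics(tp, eff, fp, 2, G.n_markers)
        assert curve.iloc[0]["power"] == row["power"]
        assert curve.iloc[0]["fdr"] == row["fdr"]

    def test_oracle_ranking_reaches_power_one(self):
        G = self._indep_geno()
        causal = [2, 10, 20]
        p = np.full(G.n_markers, 0.5)
        p[causal] = [1e-9, 1e-8, 1e-7]
        res = freq_result(list(p), positions=list(G.markers["pos"]))
        arch = gb.TraitArchitecture(causal, [1.0] * 3, h2=0.5)
        curve = gb.metrics_curve(res, arch, G)
        at_k3 = curve[curve.K == 3].iloc[0]
        assert at_k3["power"] == 1.0 and at_k3["fdr"] == 0.0

    def test_monotone_in_k(self):
        G = self._indep_geno(seed=8)
        arch = gb.TraitArchitecture([1, 7, 30], [1.0] * 3, h2=0.5)
        res = freq_result(list(np.random.default_rng(9).uniform(
            size=G.n_markers)), positions=list(G.markers["pos"]))
        curve = gb.metrics_curve(res, arch, G)
        assert (np.diff(curve["true_positives"]) >= 0).all()
        assert (np.diff(curve["power"]) >= 0).all()
        assert (np.diff(curve["type1"]) >= 0).all()
        assert (curve["effective_positives"] <= curve["K"]).all()
        assert ((curve["true_positives"] + curve["false_positives"])
                == curve["effective_positives"]).all()

    def test_random_ranking_hypergeometric_power(self):
        # LD-free genotypes: power at K = n_causal matches the
        # hypergeometric expectation n_causal/M
        M, n_causal, reps = 600, 30, 40
        G = self._indep_geno(M=M, N=30, seed=12)
        powers = []
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            causal = np.sort(rng.choice(M, n_causal, replace=False))
            arch = gb.TraitArchitecture(causal, np.ones(n_causal), h2=0.5)
            order = rng.permutation(M)
            calls = RankedCalls(order=order, engine="mlm")
            tp, eff, fp = gb.match_positives(calls, arch, G, K=n_causal)
            powers.append(tp / n_causal)
        expect = n_causal / M
        se = np.sqrt(expect * (1 - expect) / (n_causal * reps))
        assert abs(np.mean(powers) - expect) < 3 * se

    def test_r2_threshold_insensitivity(self, small_pop):
        """Power changes little across matching thresholds 0.6-0.9."""
        G, _ = small_pop
        Q = gb.compute_pca(G)
        K = gb.compute_kinship(G)
        arch = gb.sample_architecture(G, 16, h2=0.7, seed=61, min_maf=0.1)
        ph = gb.simulate_trait(G, arch)
        res = gb.scan_mlm(G, ph, Q, K)
        powers = []
        for thr in (0.6, 0.7, 0.8, 0.9):
            curve = gb.metrics_curve(res, arch, G, K_grid=[16],
                                     r2_threshold=thr)
            powers.append(curve["power"].iloc[0])
        assert max(powers) - min(powers) < 0.1


class TestDetectionCategories:
    def test_set_algebra(self):
        rng = np.random.default_rng(4)
        G = toy_matrix(rng.binomial(2, 0.5, (8, 40)))
        causal = [0, 1, 2, 3]
        arch = gb.TraitArchitecture(causal, np.ones(4), h2=0.5)
        pa = np.full(8, 0.9)
        pa[[0, 1]] = 1e-6                      # A detects c0, c1
        pb = np.full(8, 0.9)
        pb[[1, 2]] = 1e-6                      # B detects c1, c2
        out = gb.detection_categories(
            freq_result(list(pa), positions=list(G.markers["pos"])),
            freq_result(list(pb), positions=list(G.markers["pos"])),
            arch, G, K=2)
        assert out["category"][0] == "a_only"
        assert out["category"][1] == "both"
        assert out["category"][2] == "b_only"
        assert out["category"][3] == "neither"

    def test_mann_whitney_separated_groups(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        assert mannwhitneyu(a, b, alternative="two-sided").pvalue < 1e-4
        same = mannwhitneyu(a, a, alternative="two-sided").pvalue
        assert same > 0.99

    def test_empty_category_skipped(self):
        rng = np.random.default_rng(4)
        G = toy_matrix(rng.binomial(2, 0.5, (6, 40)))
        arch = gb.TraitArchitecture([0, 1], np.ones(2), h2=0.5)
        pa = np.full(6, 0.9)
        pa[[0, 1]] = 1e-6
        res = freq_result(list(pa), positions=list(G.markers["pos"]))
        out = gb.detection_categories(res, res, arch, G, K=2)
        assert out["comparisons"][("a_only", "b_only")]["skipped"]
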