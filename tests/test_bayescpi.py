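"""BayesC-pi sampler: posterior summaries, two-step priors, architecture
estimation, and the exhaustive model-averaging oracle."""

import itertools

import numpy as np
import pytest
from scipy import stats

import gwasbench as gb

from conftest import make_population, toy_matrix


@pytest.fixture(scope="module")
def pop():
    G, _ = make_population(n_individuals=300, n_markers=1000, seed=81)
    return gb.filter_markers(G, min_maf=0.05)


def short_config(**kw):
    kw.setdefault("chain_length", 1500)
    kw.setdefault("burnin", 300)
    return gb.BayesChainConfig(**kw)


class TestSampler:
    def test_null_trait_recovers_empty_model(self, pop):
        ok = 0
        for seed in range(10):
            y = np.random.default_rng(900 + seed).standard_normal(
                pop.n_individuals)
            s = gb.run_bayescpi(pop, y, short_config(seed=seed))
            ok += (s.pi_hat > 0.99) and (s.h2_hat < 0.1)
        assert ok >= 9

    def test_dominant_signal_model_frequency(self):
        G, _ = make_population(n_individuals=400, n_markers=200, seed=82)
        G = gb.filter_markers(G, min_maf=0.2)
        arch = gb.sample_architecture(G, 1, h2=0.9, seed=83, min_maf=0.2)
        ph = gb.simulate_trait(G, arch)
        s = gb.two_step_run(G, ph, real_config=short_config(seed=84))
        c = int(arch.causal_indices[0])
        # the causal marker (or a proxy in near-perfect LD) dominates
        x = G.dosages[c]
        r2 = np.array([np.corrcoef(x, G.dosages[j])[0, 1] ** 2
                       for j in range(G.n_markers)])
        proxies = np.flatnonzero(r2 > 0.95)
        assert s.model_frequency[proxies].sum() > 0.9
        assert np.argmax(s.model_frequency) in proxies

    def test_seed_determinism(self, pop):
        y = np.random.default_rng(7).standard_normal(pop.n_individuals)
        a = gb.run_bayescpi(pop, y, short_config(seed=42))
        b = gb.run_bayescpi(pop, y, short_config(seed=42))
        np.testing.assert_array_equal(a.model_frequency, b.model_frequency)
        assert a.pi_hat == b.pi_hat

    def test_inclusion_count_consistency(self, pop):
        cfg = short_config(seed=11)
        arch = gb.sample_architecture(pop, 8, h2=0.7, seed=11, min_maf=0.1)
        ph = gb.simulate_trait(pop, arch)
        s = gb.run_bayescpi(pop, ph, cfg)
        n_post = cfg.chain_length - cfg.burnin
        total_events = s.model_frequency.sum() * n_post
        m_post = s.chain["m_included"].iloc[cfg.burnin:].sum()
        assert total_events == pytest.approx(m_post)

    def test_longer_chain_stable_pi(self, pop):
        arch = gb.sample_architecture(pop, 16, h2=0.7, seed=19, min_maf=0.1)
        ph = gb.simulate_trait(pop, arch)
        a = gb.run_bayescpi(pop, ph, short_config(chain_length=2000,
                                                  burnin=400, seed=1))
        b = gb.run_bayescpi(pop, ph, short_config(chain_length=4000,
                                                  burnin=400, seed=2))
        # Monte-Carlo SE of pi_hat from batch means of the shorter chain
        pi = a.chain["pi"].iloc[400:].to_numpy()
        batches = pi[: (len(pi) // 8) * 8].reshape(8, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(8)
        assert abs(a.pi_hat - b.pi_hat) < max(3 * se, 0.01)


class TestBmaOracle:
    def test_ranking_matches_exhaustive_averaging(self):
        """3-marker toy: Gibbs model frequencies at fixed variances and pi
        agree with exhaustive 2^3-model Bayesian averaging."""
        rng = np.random.default_rng(5)
        N = 30
        D = rng.binomial(2, 0.5, size=(3, N)).astype(float)
        G = toy_matrix(D)
        y = 1.2 * D[0] + 0.5 * D[1] + rng.standard_normal(N) * 0.7
        sb2, se2, pi = 0.5, 0.49, 0.5
        yc = y - y.mean()
        Xc = D - D.mean(axis=1, keepdims=True)
        # closed-form marginal likelihood of each of the 8 models
        post = {}
        for subset in itertools.chain.from_iterable(
                itertools.combinations(range(3), k) for k in range(4)):
            V = se2 * np.eye(N)
            for j in subset:
                V += sb2 * np.outer(Xc[j], Xc[j])
            ll = stats.multivariate_normal.logpdf(yc, mean=np.zeros(N), cov=V)
            prior = (1 - pi) ** len(subset) * pi ** (3 - len(subset))
            post[subset] = ll + np.log(prior)
        mx = max(post.values())
        probs = {k: np.exp(v - mx) for k, v in post.items()}
        z = sum(probs.values())
        incl = np.array([sum(p for s, p in probs.items() if j in s) / z
                         for j in range(3)])
        cfg = gb.BayesChainConfig(chain_length=6000, burnin=1000,
                                  pi_init=pi, effect_var_prior=sb2,
                                  residual_var_prior=se2, update_pi=False,
                                  update_variances=False, seed=9)
        s = gb.run_bayescpi(G, y, cfg)
        rho = stats.spearmanr(s.model_frequency, incl).statistic
        assert rho > 0.9
        np.testing.assert_allclose(s.model_frequency, incl, atol=0.05)


class TestTwoStep:
    def test_stable_ranking_when_priors_reasonable(self, pop):
        arch = gb.sample_architecture(pop, 8, h2=0.8, seed=31, min_maf=0.1)
        ph = gb.simulate_trait(pop, arch)
        # put the trait on unit scale so the default priors are well-specified
        y = ph.values / ph.values.std()
        single = gb.run_bayescpi(pop, y, short_config(seed=300))
        two = gb.two_step_run(pop, y, real_config=short_config(seed=300))
        top_s = set(np.argsort(-single.model_frequency)[:10])
        top_t = set(np.argsort(-two.model_frequency)[:10])
        assert len(top_s & top_t) >= 8

    def test_priors_follow_scale(self, pop):
        # high-heritability trait so both runs settle in the signal basin
        # (at moderate h2 the sparse and polygenic posterior modes compete
        # and rescaling can flip which one the short chain lands in)
        arch = gb.sample_architecture(pop, 8, h2=0.8, seed=37, min_maf=0.1)
        ph = gb.simulate_trait(pop, arch)
        base = gb.two_step_run(pop, ph.values,
                               real_config=short_config(seed=41))
        scaled = gb.two_step_run(pop, ph.values * 100.0,
                                 real_config=short_config(seed=41))
        ratio = scaled.residual_var_hat / base.residual_var_hat
        assert 100 ** 2 / 2 < ratio < 100 ** 2 * 2

    def test_fixed_seed_reproducible(self, pop):
        y = np.random.default_rng(3).standard_normal(pop.n_individuals)
        a = gb.two_step_run(pop, y, real_config=short_config(seed=8))
        b = gb.two_step_run(pop, y, real_config=short_config(seed=8))
        np.testing.assert_array_equal(a.model_frequency, b.model_frequency)
        assert a.test_summary.pi_hat == b.test_summary.pi_hat


class TestArchitectureEstimation:
    def test_pi_to_count_arithmetic(self, pop):
        arch = gb.sample_architecture(pop, 8, h2=0.9, seed=51, min_maf=0.1)
        ph = gb.simulate_trait(pop, arch)
        s = gb.run_bayescpi(pop, ph, short_config(seed=52))
        est = gb.estimate_architecture(s, pop.n_markers)
        assert est.n_causal_hat == pytest.approx((1 - s.pi_hat)
                                                 * pop.n_markers)
        lo, hi = est.n_causal_interval
        assert lo <= est.n_causal_hat <= hi or np.isclose(lo, hi)


class TestRecommendation:
    @pytest.mark.parametrize("n_hat, h2_hat, expected, flagged", [
        (8, 0.9, "farmcpu", False),
        (32, 0.9, "farmcpu", False),
        (256, 0.9, "bayescpi", False),
        (256, 0.4, "farmcpu", True),
    ])
    def test_decision_rule(self, n_hat, h2_hat, expected, flagged):
        rec = gb.recommend_method(n_hat, h2_hat)
        assert rec.method == expected
        assert rec.low_confidence == flagged
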