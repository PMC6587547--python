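"""Estimate trait architecture with BayesC-pi and pick an engine.

The posterior exclusion probability pi gives (1 - pi) * M as an estimate of
the number of causal variants, and the posterior genetic-variance share
estimates heritability; the recommendation rule maps these to the engine
expected to give the best power/FDR trade-off.
"""

import gwasbench as gb

G, _ = gb.generate_population(gb.PopulationSpec(n_individuals=400,
                                                n_markers=2000, seed=9))
G = gb.filter_markers(G, min_maf=0.05)

arch = gb.sample_architecture(G, n_qtn=8, h2=0.9, seed=17)
pheno = gb.simulate_trait(G, arch)

summary = gb.two_step_run(G, pheno, real_config=gb.BayesChainConfig(
    chain_length=2000, burnin=200, seed=17))
est = gb.estimate_architecture(summary, G.n_markers)

print(f"true architecture: {arch.n_qtn} QTNs at h2 = {arch.h2}")
print(f"estimated causal count: {est.n_causal_hat:.1f} "
      f"(95% interval {est.n_causal_interval[0]:.1f}-"
      f"{est.n_causal_interval[1]:.1f})")
print(f"estimated heritability: {est.h2_hat:.2f}")

rec = gb.recommend_method(est.n_causal_hat, est.h2_hat)
print(f"recommended engine: {rec.method}"
      + (" (low confidence)" if rec.low_confidence else ""))
print(f"  rationale: {rec.rationale}")
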