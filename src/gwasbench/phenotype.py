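"""Additive quantitative-trait simulation with exact heritability calibration.

A trait for individual j is Y_j = sum_i a_i S_ij + e_j, where S_ij is the
0/1/2 dosage at the i-th causal marker (QTN) and a_i its additive effect.
Residuals are drawn from N(0, sd^2) with

    sd = sqrt( Var(g) * (1/h^2 - 1) ),    g_j = sum_i a_i S_ij,

where Var(g) is the realized sample variance (denominator n-1) of the
genetic values across the simulated individuals, so the expected realized
heritability Var(g)/Var(Y) equals the target h^2.  At h^2 = 1 the residuals
are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["TraitArchitecture", "PhenotypeVector", "sample_architecture",
           "simulate_trait"]

# offset separating the architecture RNG stream from the residual stream
_RESIDUAL_SEED_OFFSET = 0x9E3779B1


@dataclass
class TraitArchitecture:
    """The simulated truth: causal marker indices, effects, and target h2."""

    causal_indices: np.ndarray
    effects: np.ndarray
    h2: float
    effect_dist: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.causal_indices.size < 1:
            raise ValueError("architecture needs at least one causal marker")
        if len(np.unique(self.causal_indices)) != self.causal_indices.size:
            raise ValueError("causal indices must be distinct")
        if self.effects.shape != self.causal_indices.shape:
            raise ValueError("effects and causal_indices length mismatch")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in (0, 1], got {self.h2}")

    @property
    def n_qtn(self) -> int:
        return self.causal_indices.size


@dataclass
class PhenotypeVector:
    """Simulated phenotype: values = genetic_values + residuals."""

    values: np.ndarray
    genetic_values: np.ndarray
    residuals: np.ndarray

    def realized_h2(self) -> float:
        """Var(g)/Var(Y) with sample variances."""
        return float(np.var(self.genetic_values, ddof=1)
                     / np.var(self.values, ddof=1))


def sample_architecture(G: GenotypeMatrix, n_qtn: int,
                        effect_dist: str = "normal", h2: float = 0.5,
                        seed: int = 0, geometric_ratio: float = 0.92,
                        min_maf: float = 0.0) -> TraitArchitecture:
    """Draw a random trait architecture on the markers of ``G``.

    Causal markers are sampled uniformly without replacement.  ``normal``
    effects are N(0, 1); ``geometric`` effects are r^1, r^2, ... with random
    sign (the declining-effect-size convention of multi-locus model
    benchmarks).  ``min_maf`` optionally restricts the causal candidates.
    """
    rng = np.random.default_rng(seed)
    candidates = np.arange(G.n_markers)
    if min_maf > 0.0:
        from .genotypes import summarize_markers
        maf = summarize_markers(G)["maf"].to_numpy()
        candidates = candidates[maf >= min_maf]
    if n_qtn > candidates.size:
        raise ValueError(f"n_qtn={n_qtn} exceeds the {candidates.size} "
                         "eligible markers")
    idx = np.sort(rng.choice(candidates, size=n_qtn, replace=False))
    if effect_dist == "normal":
        eff = rng.standard_normal(n_qtn)
    elif effect_dist == "geometric":
        eff = geometric_ratio ** np.arange(1, n_qtn + 1)
        eff *= rng.choice([-1.0, 1.0], size=n_qtn)
    else:
        raise ValueError(f"unknown effect distribution: {effect_dist!r}")
    return TraitArchitecture(idx, eff, h2=h2, effect_dist=effect_dist, seed=seed)


def simulate_trait(G: GenotypeMatrix, arch: TraitArchitecture) -> PhenotypeVector:
    """Simulate one phenotype replicate under the additive model.

    Pure function of (G, arch): the residual stream is derived from
    ``arch.seed`` by a fixed offset, so the same inputs always yield the
    same vector while architecture and noise stay independently re-drawable.
    """
    if not G.is_complete:
        raise ValueError("genotype matrix must be complete (impute first)")
    S = G.dosages[arch.causal_indices]          # m x N
    g = arch.effects @ S
    if arch.h2 == 1.0:
        e = np.zeros_like(g)
    else:
        var_g = np.var(g, ddof=1)
        if var_g <= 0.0:
            raise ValueError("degenerate genetic variance: causal set is "
                             "monomorphic, cannot calibrate h2 < 1")
        sd = np.sqrt(var_g * (1.0 / arch.h2 - 1.0))
        rng = np.random.default_rng(arch.seed + _RESIDUAL_SEED_OFFSET)
        e = rng.normal(0.0, sd, size=g.size)
    return PhenotypeVector(values=g + e, genetic_values=g, residuals=e)
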