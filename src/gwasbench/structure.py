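"""Population structure and linkage disequilibrium summaries.

PCA on marker-standardized dosages (covariates for the association engines),
two genomic-relationship estimators, pairwise dosage r-squared within a
distance window, and the log-binned LD-decay curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["PCMatrix", "KinshipMatrix", "compute_pca", "compute_kinship",
           "pairwise_ld", "ld_decay_curve"]


@dataclass
class PCMatrix:
    """Principal-component scores (individuals x components) and the
    fraction of genotypic variance each component explains."""

    scores: np.ndarray
    variance_explained: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.scores[:, :k]


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix between individuals.

    ``centered``: K = Xc Xc'/M with Xc the individuals x markers dosage
    matrix centered per marker (the convention of GEMMA's -gk 1).
    ``vanraden``: K = Xc Xc' / (2 sum_k p_k(1-p_k)) with p_k the
    counted-allele frequency.  The two differ only by a global scalar.
    """

    values: np.ndarray
    estimator: str

    def __post_init__(self) -> None:
        K = np.asarray(self.values, float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.values = (K + K.T) / 2.0


def _standardized(G: GenotypeMatrix, scale: bool) -> np.ndarray:
    X = G.dosages.T.astype(float)           # individuals x markers
    mu = X.mean(axis=0)
    Xc = X - mu
    if scale:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        Xc = Xc[:, keep] / sd[keep]
    return Xc


def compute_pca(G: GenotypeMatrix, n_components: int = 10,
                scale: bool = True) -> PCMatrix:
    """PCA of individuals on centered (and by default sd-scaled) dosages.

    variance_explained is each eigenvalue over the total genotypic variance;
    monomorphic markers are dropped before scaling.
    """
    if not G.is_complete:
        raise ValueError("genotype matrix must be complete (impute first)")
    n_max = min(G.n_individuals, G.n_markers)
    if n_components > n_max:
        raise ValueError(f"n_components={n_components} exceeds min(N, M)={n_max}")
    Xc = _standardized(G, scale)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    lam = s ** 2
    scores = U[:, :n_components] * s[:n_components]
    return PCMatrix(scores=scores, variance_explained=lam[:n_components] / lam.sum())


def compute_kinship(G: GenotypeMatrix, estimator: str = "centered") -> KinshipMatrix:
    if not G.is_complete:
        raise ValueError("genotype matrix must be complete (impute first)")
    X = G.dosages.T.astype(float)
    mu = X.mean(axis=0)
    Xc = X - mu
    if estimator == "centered":
        K = Xc @ Xc.T / G.n_markers
    elif estimator == "vanraden":
        p = mu / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0.0:
            raise ValueError("all markers monomorphic: VanRaden denominator is 0")
        K = Xc @ Xc.T / denom
    else:
        raise ValueError(f"unknown kinship estimator: {estimator!r}")
    return KinshipMatrix(values=K, estimator=estimator)


def pairwise_ld(G: GenotypeMatrix, max_dist_bp: int = 10_000_000) -> pd.DataFrame:
    """r² (squared Pearson correlation of dosage vectors) for every
    same-chromosome marker pair closer than ``max_dist_bp``.

    Zero-variance markers are skipped.  Columns: marker_i, marker_j,
    distance_bp, r2 — the layout of a PLINK ``.ld`` table.
    """
    if not G.is_complete:
        raise ValueError("genotype matrix must be complete (impute first)")
    ids = G.markers["id"].to_numpy()
    pos = G.markers["pos"].to_numpy(float)
    chrom = G.markers["chrom"].to_numpy()
    D = G.dosages
    sd = D.std(axis=1, ddof=0)
    out_i, out_j, out_d, out_r2 = [], [], [], []
    for c in pd.unique(chrom):
        idx = np.flatnonzero((chrom == c) & (sd > 0))
        if idx.size < 2:
            continue
        Z = D[idx] - D[idx].mean(axis=1, keepdims=True)
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        R2 = (Z @ Z.T) ** 2
        p = pos[idx]
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = p[jj] - p[ii]
        keep = dist < max_dist_bp
        out_i.append(ids[idx[ii[keep]]])
        out_j.append(ids[idx[jj[keep]]])
        out_d.append(dist[keep])
        out_r2.append(np.clip(R2[ii[keep], jj[keep]], 0.0, 1.0))
    if not out_i:
        return pd.DataFrame(columns=["marker_i", "marker_j", "distance_bp", "r2"])
    return pd.DataFrame({
        "marker_i": np.concatenate(out_i),
        "marker_j": np.concatenate(out_j),
        "distance_bp": np.concatenate(out_d).astype(int),
        "r2": np.concatenate(out_r2),
    })


def ld_decay_curve(ld: pd.DataFrame, threshold_frac: float = 0.5,
                   min_pairs: int = 10) -> tuple[pd.DataFrame, float]:
    """Mean r² in log10-distance bins of width 0.1 from 10^0.1 to 10^7.

    Returns the per-bin table (bin center in bp, mean r², pair count; empty
    bins carry NaN) and a decay scale: the first bin center at which the
    smoothed mean r² drops below ``threshold_frac`` of its maximum (the last
    bin center if it never does).  Bins with fewer than ``min_pairs`` pairs
    are reported in the table but excluded from the decay-scale estimate,
    whose per-bin means would otherwise be dominated by noise.
    """
    if len(ld) == 0:
        raise ValueError("empty LD table")
    edges = 10.0 ** np.arange(0.1, 7.05, 0.1)
    centers = 10.0 ** (np.arange(0.1, 7.0, 0.1) + 0.05)
    d = ld["distance_bp"].to_numpy(float)
    r2 = ld["r2"].to_numpy(float)
    which = np.digitize(d, edges) - 1
    ok = (which >= 0) & (which < len(centers))
    sums = np.bincount(which[ok], weights=r2[ok], minlength=len(centers))
    counts = np.bincount(which[ok], minlength=len(centers))
    mean_r2 = np.full(len(centers), np.nan)
    nz = counts > 0
    mean_r2[nz] = sums[nz] / counts[nz]
    table = pd.DataFrame({"bin_center_bp": centers, "mean_r2": mean_r2,
                          "n_pairs": counts})
    # 3-bin moving average over the well-filled bins, then threshold crossing
    solid = counts >= min_pairs
    if not solid.any():
        solid = nz
    filled = mean_r2[solid]
    nz = solid
    if filled.size >= 3:
        sm = np.convolve(filled, np.ones(3) / 3.0, mode="same")
        sm[0], sm[-1] = filled[0], filled[-1]
    else:
        sm = filled
    cut = threshold_frac * sm.max()
    below = np.flatnonzero(sm < cut)
    cnz = centers[nz]
    decay_scale = float(cnz[below[0]]) if below.size else float(cnz[-1])
    return table, decay_scale
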