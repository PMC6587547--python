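"""Multi-locus iterative scan alternating fixed- and random-effect models.

The scheme follows the fixed and random model circulating probability
unification (FarmCPU) idea: a fixed-effect genome scan is run with the
current set of pseudo-QTNs (markers promoted to covariates), then a
random-effect model selects the next pseudo-QTN set by maximizing the REML
likelihood of a kinship built from candidate markers only, over a grid of
genomic bin sizes and candidate counts (the "optimum bin" strategy).  The
two steps circulate until the pseudo-QTN set repeats.

The scan itself is ordinary least squares with intercept, leading principal
components, and pseudo-QTN dosages as covariates; a marker lying inside a
pseudo-QTN's genomic bin inherits the pseudo-QTN's own covariate t-test
p-value, so covariate markers never end up with an undefined score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import AssociationResult
from .genotypes import GenotypeMatrix
from .mlm import _LOG10_LAMBDA_BOUNDS, _as_vector, _covariates, _reml_neg_loglik
from .structure import compute_kinship

__all__ = ["PseudoQtnSet", "glm_scan", "select_pseudo_qtns", "run_farmcpu"]

DEFAULT_BIN_SIZES = (500_000, 5_000_000, 50_000_000)
DEFAULT_COUNTS = tuple(range(10, 101, 10))
_LD_PRUNE_R2 = 0.7


@dataclass
class PseudoQtnSet:
    """Markers currently promoted to fixed-effect covariates."""

    indices: tuple[int, ...] = ()
    bin_size: int = DEFAULT_BIN_SIZES[0]
    reml_loglik: float = np.nan

    def __len__(self) -> int:
        return len(self.indices)


def glm_scan(G: GenotypeMatrix, y, Q, pseudo: PseudoQtnSet | None = None
             ) -> AssociationResult:
    """Covariate-adjusted OLS scan with pseudo-QTN substitution.

    Collinear pseudo-QTN columns are dropped with a warning.  With an empty
    pseudo-QTN set this is a plain GLM scan.
    """
    if not G.is_complete:
        raise ValueError("genotype matrix must be complete (impute first)")
    yv = _as_vector(y)
    n = yv.size
    W = _covariates(Q, n)
    pseudo = pseudo or PseudoQtnSet()
    kept_pseudo: list[int] = []
    for idx in pseudo.indices:
        col = G.dosages[idx][:, None]
        Wtry = np.hstack([W, col])
        if np.linalg.matrix_rank(Wtry) > np.linalg.matrix_rank(W):
            W = Wtry
            kept_pseudo.append(idx)
        else:
            warnings.warn(f"pseudo-QTN {G.markers['id'].iloc[idx]} collinear "
                          "with existing covariates; dropped")
    c = W.shape[1]
    Qw, R = np.linalg.qr(W)
    yr = yv - Qw @ (Qw.T @ yv)
    X = G.dosages.T
    Xr = X - Qw @ (Qw.T @ X)
    xx = np.einsum("ij,ij->j", Xr, Xr)
    xy = Xr.T @ yr
    ok = xx > 1e-12
    beta = np.zeros(G.n_markers)
    beta[ok] = xy[ok] / xx[ok]
    df = n - c - 1
    rss = float(yr @ yr) - beta * xy
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.full(G.n_markers, np.nan)
    se[ok] = np.sqrt(sigma2[ok] / xx[ok])
    p = np.ones(G.n_markers)
    t = np.zeros(G.n_markers)
    t[ok] = beta[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)

    # covariate t-tests for the pseudo-QTNs themselves (joint model): each
    # covariate marker gets its own test's p-value rather than a dummy 1
    if kept_pseudo:
        coef = np.linalg.solve(R, Qw.T @ yv)
        resid = yv - W @ coef
        s2 = float(resid @ resid) / (n - c)
        Rinv = np.linalg.inv(R)
        cov = s2 * (Rinv @ Rinv.T)
        for k, idx in enumerate(kept_pseudo):
            j = c - len(kept_pseudo) + k
            tq = coef[j] / np.sqrt(cov[j, j])
            p[idx] = 2.0 * stats.t.sf(abs(tq), n - c)
            beta[idx] = coef[j]
            se[idx] = np.sqrt(cov[j, j])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = G.markers[["id", "chrom", "pos"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = p
    return AssociationResult(table=table, engine="farmcpu",
                             info={"pseudo_qtns": tuple(kept_pseudo)})


def _null_reml_loglik(yv: np.ndarray) -> float:
    """Intercept-only model likelihood on the same REML scale (lambda -> 0)."""
    n = yv.size
    Wt = np.ones((n, 1))
    return -_reml_neg_loglik(_LOG10_LAMBDA_BOUNDS[0], yv, Wt, np.zeros(n))


def _candidate_loglik(G: GenotypeMatrix, yv: np.ndarray,
                      indices: tuple[int, ...]) -> float:
    """REML log-likelihood of y ~ intercept + random effect with a
    VanRaden kinship built from the candidate markers only."""
    if not indices:
        return _null_reml_loglik(yv)
    sub = G.take_markers(np.array(indices))
    if np.all(np.ptp(sub.dosages, axis=1) == 0.0):
        return _null_reml_loglik(yv)
    K = compute_kinship(sub, estimator="vanraden")
    s, U = np.linalg.eigh(K.values)
    s = np.clip(s, 0.0, None)
    yt = U.T @ yv
    Wt = U.T @ np.ones((yv.size, 1))
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=_LOG10_LAMBDA_BOUNDS, method="bounded",
        args=(yt, Wt, s), options={"xatol": 1e-4})
    return -res.fun


def _prune_ld(G: GenotypeMatrix, indices: list[int], limit: int) -> list[int]:
    """Drop candidates in mutual LD r2 > threshold, keeping the better p
    (the input list is assumed p-sorted best-first); stop at ``limit``."""
    kept: list[int] = []
    kept_z: list[np.ndarray] = []
    for idx in indices:
        if len(kept) >= limit:
            break
        x = G.dosages[idx]
        sd = x.std()
        if sd == 0.0:
            continue
        z = (x - x.mean()) / (sd * np.sqrt(x.size))
        if kept_z and np.max((np.vstack(kept_z) @ z) ** 2) > _LD_PRUNE_R2:
            continue
        kept.append(idx)
        kept_z.append(z)
    return kept


def select_pseudo_qtns(result: AssociationResult, G: GenotypeMatrix, y,
                       bin_sizes=DEFAULT_BIN_SIZES, counts=DEFAULT_COUNTS,
                       p_entry: float | None = 0.01) -> PseudoQtnSet:
    """Optimum-bin pseudo-QTN selection.

    For every (bin size, count) pair, keep the best-p marker per genomic bin
    and take the top ``count``; score each candidate set by the REML
    likelihood of a random-effect model whose covariance is a kinship built
    from only those markers, and return the maximizing set.  The empty set,
    scored by the intercept-only model, is always in the running, so a null
    trait can legitimately select no pseudo-QTNs.

    ``p_entry`` caps the marginal p-value a marker may have and still be
    promoted to pseudo-QTN (the reference implementation's QTN threshold);
    ``None`` disables the gate.
    """
    yv = _as_vector(y)
    p = result.table["p"].to_numpy(float)
    chrom = G.markers["chrom"].to_numpy()
    pos = G.markers["pos"].to_numpy()
    best = PseudoQtnSet(indices=(), bin_size=bin_sizes[0],
                        reml_loglik=_null_reml_loglik(yv))
    cache: dict[tuple[int, ...], float] = {(): best.reml_loglik}
    for b in bin_sizes:
        bins = pd.Series(np.arange(G.n_markers)).groupby(
            [pd.Series(chrom), pd.Series(pos // b)], sort=False)
        per_bin = [grp.iloc[np.argmin(p[grp.to_numpy()])]
                   for _, grp in bins]
        per_bin = sorted(per_bin, key=lambda i: p[i])
        if p_entry is not None:
            per_bin = [i for i in per_bin if p[i] < p_entry]
        per_bin = _prune_ld(G, per_bin, limit=max(counts))
        for t in counts:
            cand = tuple(sorted(per_bin[:t]))
            if cand in cache:
                ll = cache[cand]
            else:
                ll = _candidate_loglik(G, yv, cand)
                cache[cand] = ll
            if ll > best.reml_loglik:
                best = PseudoQtnSet(indices=cand, bin_size=b, reml_loglik=ll)
    return best


def run_farmcpu(G: GenotypeMatrix, y, Q, max_iter: int = 10,
                bin_sizes=DEFAULT_BIN_SIZES, counts=DEFAULT_COUNTS,
                p_entry: float | None = 0.01,
                stop_threshold: float | str | None = "auto"
                ) -> AssociationResult:
    """Iterate fixed-effect scan and pseudo-QTN selection to convergence.

    ``stop_threshold`` (default ``"auto"`` = 0.01 / M, the reference
    implementation's p.threshold) ends the circulation after the first scan
    when no marker reaches it — the guard that keeps null traits at the
    plain covariate-adjusted scan instead of promoting noise markers.
    Convergence otherwise is exact repetition of a previously seen
    pseudo-QTN set (which covers cycles) or a candidate set that no longer
    improves the random-effect REML score of the standing set — without the
    latter, conditional scans keep refreshing weakly-supported candidates
    and the circulation can drift indefinitely.  On non-convergence at
    ``max_iter`` the last scan is returned with a flag.  Deterministic
    given its inputs.
    """
    if stop_threshold == "auto":
        stop_threshold = 0.01 / G.n_markers
    yv = _as_vector(y)
    current = PseudoQtnSet(reml_loglik=_null_reml_loglik(yv))
    seen: list[frozenset[int]] = []
    history: list[dict] = []
    converged = False
    for it in range(1, max_iter + 1):
        result = glm_scan(G, y, Q, pseudo=current)
        if (it == 1 and stop_threshold is not None
                and result.table["p"].min() > stop_threshold):
            result.info.update({"converged": True, "iterations": [],
                                "final_pseudo_qtns": (),
                                "stopped_at_threshold": True})
            return result
        seen.append(frozenset(current.indices))
        selected = select_pseudo_qtns(result, G, y, bin_sizes=bin_sizes,
                                      counts=counts, p_entry=p_entry)
        history.append({"iteration": it,
                        "pseudo_qtns": list(G.markers["id"].iloc[list(selected.indices)]),
                        "bin_size": selected.bin_size,
                        "reml_loglik": selected.reml_loglik})
        repeated = frozenset(selected.indices) in seen
        no_gain = selected.reml_loglik <= current.reml_loglik + 1e-2
        if repeated or no_gain:
            converged = True
            if not no_gain and selected.indices != current.indices:
                current = selected
                result = glm_scan(G, y, Q, pseudo=current)
            break
        current = selected
    if not converged:
        warnings.warn(f"FarmCPU did not converge in {max_iter} iterations")
        result = glm_scan(G, y, Q, pseudo=current)
    result.info.update({"converged": converged, "iterations": history,
                        "final_pseudo_qtns": current.indices})
    return result
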