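"""Single-marker mixed-linear-model scan (the Q+K model).

The trait is modelled as y = W alpha + x beta + u + e with fixed covariates
W (intercept plus leading principal components), a kinship-structured random
effect u ~ N(0, sigma_g^2 K), and i.i.d. residuals.  Variance components are
estimated once on the null model by restricted maximum likelihood, profiled
down to the single ratio lambda = sigma_g^2 / sigma_e^2 via an
eigendecomposition of K, and the per-marker Wald test is then a generalized
least squares regression in the rotated/whitened basis.  ``approx`` mode
reuses the null lambda for every marker (the EMMAX shortcut); ``exact`` mode
re-optimizes lambda per marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy import optimize, stats

from .association import AssociationResult
from .genotypes import GenotypeMatrix
from .phenotype import PhenotypeVector
from .structure import KinshipMatrix, PCMatrix

__all__ = ["VarianceComponents", "fit_null_mlm", "scan_mlm", "bonferroni_calls"]

_LOG10_LAMBDA_BOUNDS = (-5.0, 5.0)
_PSD_TOL = 1e-8


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    boundary: bool = False

    @property
    def lambda_(self) -> float:
        return self.sigma_g2 / self.sigma_e2


def _as_vector(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return np.asarray(y.values, float)
    return np.asarray(y, float).ravel()


def _covariates(Q, n: int, n_pcs: int = 3) -> np.ndarray:
    """Intercept plus the leading principal components."""
    W = [np.ones((n, 1))]
    if Q is not None:
        scores = Q.scores if isinstance(Q, PCMatrix) else np.asarray(Q, float)
        if scores.ndim == 1:
            scores = scores[:, None]
        W.append(scores[:, :n_pcs])
    return np.hstack(W)


def _eigen_kinship(K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    s, U = np.linalg.eigh(Kv)
    tol = _PSD_TOL * max(np.trace(Kv) / Kv.shape[0], 1.0)
    if s.min() < -1e-6 * max(abs(s).max(), 1.0) - tol:
        raise ValueError(f"kinship is not PSD (min eigenvalue {s.min():.3g})")
    return np.clip(s, 0.0, None), U


def _reml_neg_loglik(log10_lam: float, yt: np.ndarray, Wt: np.ndarray,
                     s: np.ndarray) -> float:
    lam = 10.0 ** log10_lam
    d = lam * s + 1.0
    w = 1.0 / d
    WtW = Wt.T @ (Wt * w[:, None])
    Wty = Wt.T @ (yt * w)
    beta = np.linalg.solve(WtW, Wty)
    resid = yt - Wt @ beta
    rss = float(resid @ (resid * w))
    n, c = yt.size, Wt.shape[1]
    sigma_e2 = rss / (n - c)
    ll = -0.5 * ((n - c) * np.log(2.0 * np.pi * sigma_e2) + (n - c)
                 + np.sum(np.log(d)) + np.linalg.slogdet(WtW)[1])
    return -ll


def fit_null_mlm(y, Q, K: KinshipMatrix) -> VarianceComponents:
    """REML variance components of the covariates-only mixed model.

    The likelihood is profiled to lambda and maximized by bounded scalar
    search on log10(lambda) in [-5, 5]; hitting a bound sets the
    ``boundary`` flag rather than erroring.
    """
    yv = _as_vector(y)
    W = _covariates(Q, yv.size)
    s, U = _eigen_kinship(K)
    yt, Wt = U.T @ yv, U.T @ W
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=_LOG10_LAMBDA_BOUNDS, method="bounded",
        args=(yt, Wt, s), options={"xatol": 1e-6})
    lam = 10.0 ** res.x
    d = lam * s + 1.0
    w = 1.0 / d
    WtW = Wt.T @ (Wt * w[:, None])
    beta = np.linalg.solve(WtW, Wt.T @ (yt * w))
    resid = yt - Wt @ beta
    sigma_e2 = float(resid @ (resid * w)) / (yv.size - W.shape[1])
    lo, hi = _LOG10_LAMBDA_BOUNDS
    boundary = bool(res.x < lo + 1e-3 or res.x > hi - 1e-3)
    return VarianceComponents(sigma_g2=lam * sigma_e2, sigma_e2=sigma_e2,
                              reml_loglik=-res.fun, boundary=boundary)


def scan_mlm(G: GenotypeMatrix, y, Q, K: KinshipMatrix,
             mode: str = "approx") -> AssociationResult:
    """Per-marker Wald test in the Q+K mixed model.

    ``approx`` whitens once with the null lambda and tests every marker by
    generalized least squares in a single vectorized pass; ``exact``
    re-optimizes lambda per marker (slower, used for validating the
    approximation).  Monomorphic markers get p = 1 and a flag.  Two-sided
    p-values from the t distribution with n - c - 1 degrees of freedom.
    """
    if not G.is_complete:
        raise ValueError("genotype matrix must be complete (impute first)")
    yv = _as_vector(y)
    W = _covariates(Q, yv.size)
    s, U = _eigen_kinship(K)
    yt, Wt = U.T @ yv, U.T @ W
    Xt = U.T @ G.dosages.T                      # N x M rotated dosages

    if mode == "approx":
        vc = fit_null_mlm(yv, Q, K)
        beta, se, pvals = _gls_all(yt, Wt, Xt, s, vc.lambda_)
    elif mode == "exact":
        beta = np.empty(G.n_markers)
        se = np.empty(G.n_markers)
        pvals = np.empty(G.n_markers)
        for m in range(G.n_markers):
            x = Xt[:, m]
            if np.ptp(G.dosages[m]) == 0.0:
                beta[m], se[m], pvals[m] = 0.0, np.nan, 1.0
                continue
            Wm = np.hstack([Wt, x[:, None]])
            res = optimize.minimize_scalar(
                _reml_neg_loglik, bounds=_LOG10_LAMBDA_BOUNDS, method="bounded",
                args=(yt, Wm, s), options={"xatol": 1e-6})
            b, e_, p = _gls_all(yt, Wt, x[:, None], s, 10.0 ** res.x)
            beta[m], se[m], pvals[m] = b[0], e_[0], p[0]
    else:
        raise ValueError(f"unknown scan mode: {mode!r}")

    mono = np.ptp(G.dosages, axis=1) == 0.0
    pvals[mono] = 1.0
    table = G.markers[["id", "chrom", "pos"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = pvals
    table["monomorphic"] = mono
    return AssociationResult(table=table, engine="mlm", info={"mode": mode})


def _gls_all(yt: np.ndarray, Wt: np.ndarray, Xt: np.ndarray, s: np.ndarray,
             lam: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized GLS marker tests at a fixed variance ratio."""
    w = 1.0 / np.sqrt(lam * s + 1.0)
    ys = yt * w
    Ws = Wt * w[:, None]
    Xs = Xt * w[:, None]
    Qw, _ = np.linalg.qr(Ws)
    yr = ys - Qw @ (Qw.T @ ys)
    Xr = Xs - Qw @ (Qw.T @ Xs)
    xx = np.einsum("ij,ij->j", Xr, Xr)
    xy = Xr.T @ yr
    ok = xx > 1e-12
    beta = np.zeros(Xt.shape[1])
    beta[ok] = xy[ok] / xx[ok]
    df = yt.size - Ws.shape[1] - 1
    rss = float(yr @ yr) - beta * xy
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.full(Xt.shape[1], np.nan)
    se[ok] = np.sqrt(sigma2[ok] / xx[ok])
    tstat = np.zeros(Xt.shape[1])
    tstat[ok] = beta[ok] / se[ok]
    p = np.ones(Xt.shape[1])
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p


def bonferroni_calls(result: AssociationResult, alpha: float = 0.05) -> set[str]:
    """Marker ids with p < alpha / M (Bonferroni-corrected cut-off)."""
    if "p" not in result.table.columns:
        raise ValueError("Bonferroni calls need a frequentist (p-value) result")
    thr = alpha / result.n_markers
    p = result.table["p"].to_numpy(float)
    return set(result.table["id"].to_numpy()[p < thr])
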