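"""Scoring association results against simulated truth.

Engines are compared on equal footing by the increasing-rank method: markers
are ranked by the engine's own evidence (ascending p-value for frequentist
engines; descending model frequency with genetic-variance tie-breaking for
the Bayesian engine) and metrics are evaluated at every accepted-positive
count K.  A positive marker is a true positive if it is itself causal or in
LD (r^2 strictly above a threshold, default 0.6, same chromosome, within a
10 Mb window) with a causal marker; several positives linked to the same
causal variant collapse into a single true positive and shrink the
effective positive count accordingly.  With TP/FP so defined:

    power  = TP / n_causal
    FDR    = FP / (TP + FP)          (0, flagged, when no positives)
    Type I = FP / (M - n_causal)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult
from .genotypes import GenotypeMatrix
from .phenotype import TraitArchitecture

__all__ = ["RankedCalls", "rank_markers", "match_positives", "compute_metrics",
           "metrics_curve", "detection_categories"]

DEFAULT_R2_THRESHOLD = 0.6
DEFAULT_WINDOW_BP = 10_000_000


@dataclass
class RankedCalls:
    """Engine-ranked marker indices, best first."""

    order: np.ndarray
    engine: str
    n_flagged: int = 0

    def top(self, K: int) -> np.ndarray:
        return self.order[:K]


def rank_markers(result: AssociationResult) -> RankedCalls:
    """Total marker ordering under the engine's ranking rule.

    Frequentist: ascending p.  Bayesian: descending model frequency, ties
    broken by descending marker variance, then by marker index.  Non-finite
    scores are placed last and counted in ``n_flagged``.
    """
    n = result.n_markers
    idx = np.arange(n)
    if result.engine == "bayescpi":
        mf = result.table["model_frequency"].to_numpy(float)
        mv = result.table["marker_variance"].to_numpy(float)
        bad = ~(np.isfinite(mf) & np.isfinite(mv))
        mf = np.where(bad, -np.inf, mf)
        mv = np.where(bad, -np.inf, mv)
        order = np.lexsort((idx, -mv, -mf))
    else:
        p = result.table["p"].to_numpy(float)
        bad = ~np.isfinite(p)
        p = np.where(bad, np.inf, p)
        order = np.lexsort((idx, p))
    return RankedCalls(order=order, engine=result.engine,
                       n_flagged=int(bad.sum()))


def _link_positives(calls: np.ndarray, arch: TraitArchitecture,
                    G: GenotypeMatrix, r2_threshold: float,
                    window_bp: int) -> np.ndarray:
    """For each called marker index, the causal index it is linked to
    (itself if causal; the highest-r2 causal within the window otherwise),
    or -1 if unlinked."""
    causal = np.asarray(arch.causal_indices)
    causal_set = set(causal.tolist())
    chrom = G.markers["chrom"].to_numpy()
    pos = G.markers["pos"].to_numpy()
    D = G.dosages
    Zc = D[causal] - D[causal].mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Zc, axis=1)
    link = np.full(calls.size, -1, dtype=int)
    for k, m in enumerate(calls):
        if m in causal_set:
            link[k] = m
            continue
        near = (chrom[causal] == chrom[m]) & (np.abs(pos[causal] - pos[m])
                                              < window_bp)
        near &= norm > 0
        if not near.any():
            continue
        x = D[m] - D[m].mean()
        nx = np.linalg.norm(x)
        if nx == 0:
            continue
        r2 = (Zc[near] @ x / (norm[near] * nx)) ** 2
        j = int(np.argmax(r2))
        if r2[j] > r2_threshold:
            link[k] = causal[near][j]
    return link


def match_positives(calls: RankedCalls | np.ndarray, arch: TraitArchitecture,
                    G: GenotypeMatrix, K: int | None = None,
                    r2_threshold: float = DEFAULT_R2_THRESHOLD,
                    window_bp: int = DEFAULT_WINDOW_BP
                    ) -> tuple[int, int, int]:
    """Count (TP, effective_positives, FP) among the top-K calls.

    Positives linked to the same causal variant count once; a positive
    linked to two causal variants credits only the highest-r2 one.  The r2
    comparison is strict (> threshold).
    """
    top = calls.top(K) if isinstance(calls, RankedCalls) else np.asarray(calls)
    if K is not None and not isinstance(calls, RankedCalls):
        top = top[:K]
    link = _link_positives(top, arch, G, r2_threshold, window_bp)
    hit = link[link >= 0]
    tp = len(np.unique(hit))
    fp = int((link < 0).sum())
    effective = tp + fp
    return tp, effective, fp


def compute_metrics(tp: int, effective_positives: int, fp: int,
                    n_causal: int, M: int) -> dict:
    """One metrics row: power, FDR, Type-I error from the counts."""
    if n_causal <= 0:
        raise ValueError("n_causal must be positive")
    if tp + fp != effective_positives:
        raise ValueError("inconsistent counts: TP + FP != effective positives")
    fdr_undefined = effective_positives == 0
    return {
        "true_positives": tp,
        "effective_positives": effective_positives,
        "false_positives": fp,
        "power": tp / n_causal,
        "fdr": 0.0 if fdr_undefined else fp / effective_positives,
        "fdr_undefined": fdr_undefined,
        "type1": fp / (M - n_causal),
    }


def metrics_curve(result: AssociationResult, arch: TraitArchitecture,
                  G: GenotypeMatrix, K_grid=None,
                  r2_threshold: float = DEFAULT_R2_THRESHOLD,
                  window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Metrics at every accepted-positive count K (default 1..2*n_causal)."""
    calls = rank_markers(result)
    if K_grid is None:
        K_grid = range(1, min(2 * arch.n_qtn, result.n_markers) + 1)
    K_grid = sorted(set(int(k) for k in K_grid))
    kmax = max(K_grid)
    link = _link_positives(calls.top(kmax), arch, G, r2_threshold, window_bp)
    rows = []
    seen: set[int] = set()
    tp = fp = 0
    grid_iter = iter(K_grid)
    next_k = next(grid_iter)
    for k in range(1, kmax + 1):
        li = link[k - 1]
        if li < 0:
            fp += 1
        elif li not in seen:
            seen.add(int(li))
            tp += 1
        if k == next_k:
            row = compute_metrics(tp, tp + fp, fp, arch.n_qtn, G.n_markers)
            row["K"] = k
            rows.append(row)
            next_k = next(grid_iter, None)
            if next_k is None:
                break
    df = pd.DataFrame(rows)
    return df[["K", "true_positives", "effective_positives", "false_positives",
               "power", "fdr", "fdr_undefined", "type1"]]


def detection_categories(result_a: AssociationResult,
                         result_b: AssociationResult,
                         arch: TraitArchitecture, G: GenotypeMatrix, K: int,
                         r2_threshold: float = DEFAULT_R2_THRESHOLD,
                         window_bp: int = DEFAULT_WINDOW_BP,
                         effects: np.ndarray | None = None) -> dict:
    """Classify causal variants by which engine detects them at matched K,
    and compare MAF and |effect| distributions between categories.

    Categories are mutually exclusive: both / a_only / b_only / neither.
    Named category pairs are compared by two-sided Mann-Whitney U tests on
    MAF and absolute effect size; empty categories are skipped with a flag.
    """
    from .genotypes import summarize_markers

    def detected(result):
        calls = rank_markers(result)
        link = _link_positives(calls.top(K), arch, G, r2_threshold, window_bp)
        return set(int(x) for x in link[link >= 0])

    det_a, det_b = detected(result_a), detected(result_b)
    causal = [int(c) for c in arch.causal_indices]
    category = {}
    for c in causal:
        in_a, in_b = c in det_a, c in det_b
        category[c] = ("both" if in_a and in_b else
                       "a_only" if in_a else
                       "b_only" if in_b else "neither")
    maf = summarize_markers(G).set_index(G.markers.index)["maf"]
    eff = np.abs(arch.effects if effects is None else effects)
    eff_by = dict(zip(causal, eff))
    groups = {name: [c for c in causal if category[c] == name]
              for name in ("both", "a_only", "b_only", "neither")}
    comparisons = {}
    for g1, g2 in (("a_only", "b_only"), ("both", "neither")):
        if not groups[g1] or not groups[g2]:
            comparisons[(g1, g2)] = {"skipped": True}
            continue
        row = {"skipped": False}
        for label, vals in (("maf", lambda c: maf.loc[c]),
                            ("abs_effect", lambda c: eff_by[c])):
            u = stats.mannwhitneyu([vals(c) for c in groups[g1]],
                                   [vals(c) for c in groups[g2]],
                                   alternative="two-sided")
            row[f"{label}_p"] = float(u.pvalue)
        comparisons[(g1, g2)] = row
    return {"category": category, "groups": groups, "comparisons": comparisons}
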