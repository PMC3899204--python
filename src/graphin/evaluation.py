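"""Leave-one-out cross-validation and baseline comparisons.

Each known disease gene of each family is held out in turn: the reduced
known set scores a pool consisting of the family's non-disease candidates
plus the held-out gene, and the held-out gene is the single positive of
that leave-out. Scores and labels are pooled over all leave-outs and
families (micro-averaging) and swept from the highest observed score to the
lowest; tied scores share one threshold point. The sweep yields confusion
counts, precision-recall and ROC points, the maximum F-score and the area
under the ROC curve.

Two reference rankings are provided: the neighborhood baseline (a candidate
is positive when it has at least ``k`` direct links to the known genes) and
random walk with restart from the known genes on the column-normalized
adjacency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .catalog import IsomerCatalog, build_catalogs
from .network import InteractionNetwork
from .scoring import (
    DiseaseFamily,
    NormalizationMode,
    ScoreTable,
    score_genes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationCurve",
    "LoocvResult",
    "sweep_curve",
    "confusion_at_threshold",
    "loocv",
    "graphlet_scorer",
    "neighborhood_scorer",
    "rwr_scorer",
    "baseline_neighborhood",
    "baseline_rwr",
    "pr_dominates",
]

# scorer(network, known_genes, pool, family) -> {gene: score}
Scorer = Callable[[InteractionNetwork, frozenset, Iterable[str], DiseaseFamily],
                  dict[str, float]]


@dataclass(frozen=True)
class EvaluationCurve:
    """Threshold-swept confusion counts with derived rates."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def precision(self) -> np.ndarray:
        denom = self.tp + self.fp
        return np.divide(self.tp, denom, out=np.zeros_like(denom, dtype=float),
                         where=denom > 0)

    @property
    def recall(self) -> np.ndarray:
        return self.tp / (self.tp + self.fn)

    tpr = recall

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / (self.fp + self.tn)

    @property
    def f_scores(self) -> np.ndarray:
        p, r = self.precision, self.recall
        denom = p + r
        return np.divide(2 * p * r, denom, out=np.zeros_like(denom),
                         where=denom > 0)

    @property
    def max_f(self) -> float:
        return float(self.f_scores.max()) if len(self.f_scores) else 0.0

    @property
    def auroc(self) -> float:
        """Area under the ROC curve by trapezoidal integration.

        Equivalent to the Mann-Whitney statistic with ties credited 1/2.
        """
        fpr = np.concatenate([[0.0], self.fpr, [1.0]])
        tpr = np.concatenate([[0.0], self.tpr, [1.0]])
        return float(np.trapezoid(tpr, fpr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "precision": self.precision, "recall": self.recall,
            "FPR": self.fpr, "TPR": self.tpr,
        })


def sweep_curve(scores: np.ndarray, labels: np.ndarray) -> EvaluationCurve:
    """Confusion counts at every distinct score, highest to lowest."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0:
        raise ValueError("no positives to evaluate")
    if n_neg == 0:
        raise ValueError("no negatives to evaluate")
    thresholds = np.unique(scores)[::-1]
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    cum_pos = np.cumsum(l_sorted)
    cum_all = np.arange(1, len(labels) + 1)
    # last index (inclusive) with score >= each threshold
    last = np.searchsorted(-s_sorted, -thresholds, side="right") - 1
    tp = cum_pos[last]
    called = cum_all[last]
    fp = called - tp
    fn = n_pos - tp
    tn = n_neg - fp
    return EvaluationCurve(thresholds, tp, fp, tn, fn)


def confusion_at_threshold(scored: ScoreTable, positives: set[str],
                           pool: set[str], s0: float
                           ) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) of a score table at a single threshold ``s0``."""
    pool = set(pool)
    if not pool:
        raise ValueError("empty evaluation pool")
    positives = set(positives)
    if not positives <= pool:
        raise ValueError("positives must be a subset of the pool")
    scores = scored.as_dict()
    called = {g for g in pool if scores.get(g, float("-inf")) >= s0}
    tp = len(called & positives)
    fp = len(called - positives)
    fn = len(positives - called)
    tn = len(pool) - tp - fp - fn
    return tp, fp, tn, fn


# ---------------------------------------------------------------------------
# scorers


def graphlet_scorer(weights=None, catalog: IsomerCatalog | None = None, *,
                    isomers: Sequence[int] | None = None,
                    norm_mode: NormalizationMode = "candidates") -> Scorer:
    """Scorer using graphlet-interaction scores against the known genes."""
    def run(net, known, pool, family):
        fam = family.replace_known(known)
        table = score_genes(net, fam, weights, catalog, isomers=isomers,
                            norm_mode=norm_mode, genes=pool)
        return table.as_dict()
    return run


def neighborhood_scorer() -> Scorer:
    """Scorer ranking genes by their number of direct links to known genes."""
    def run(net, known, pool, family):
        known_in = {g for g in known if g in net}
        return {
            j: float(len(net.neighbors(j) & known_in)) if j in net else 0.0
            for j in pool
        }
    return run


def rwr_scorer(restart_prob: float = 0.7) -> Scorer:
    """Scorer ranking genes by random-walk-with-restart probability."""
    def run(net, known, pool, family):
        probs = random_walk_with_restart(net, known, restart_prob)
        return {j: probs.get(j, 0.0) for j in pool}
    return run


# ---------------------------------------------------------------------------
# LOOCV


@dataclass(frozen=True)
class LoocvResult:
    """Pooled leave-one-out scores, labels and the swept curve."""

    scores: np.ndarray
    labels: np.ndarray
    rows: tuple[tuple[str, str, str], ...]  # (family, held_out, gene)
    curve: EvaluationCurve


def loocv(net: InteractionNetwork, families: Sequence[DiseaseFamily],
          scorer: Scorer | None = None,
          catalog: IsomerCatalog | None = None) -> LoocvResult:
    """Leave-one-out cross-validation of a ranking method.

    For each family and each held-out known gene: the remaining known genes
    score the pool ``(C \\ D) ∪ {held-out}``; the held-out gene is the
    positive. Genes absent from the network are excluded from the pool.
    Families with fewer than two in-network known genes are skipped with a
    warning.
    """
    catalog = catalog if catalog is not None else build_catalogs()[1]
    if scorer is None:
        scorer = graphlet_scorer(catalog=catalog)
    all_scores: list[float] = []
    all_labels: list[int] = []
    rows: list[tuple[str, str, str]] = []
    for fam in families:
        known = sorted(g for g in fam.known_genes if g in net)
        if len(known) < 2:
            logger.warning("family %r has %d in-network disease gene(s); "
                           "needs >= 2 for LOOCV, skipped",
                           fam.family_id, len(known))
            continue
        negatives = sorted(g for g in fam.candidates - fam.known_genes
                           if g in net)
        for held_out in known:
            reduced = frozenset(g for g in known if g != held_out)
            pool = negatives + [held_out]
            scored = scorer(net, reduced, pool, fam)
            for g in pool:
                all_scores.append(scored.get(g, 0.0))
                all_labels.append(1 if g == held_out else 0)
                rows.append((fam.family_id, held_out, g))
    if not all_scores:
        raise ValueError("no family was usable for LOOCV")
    scores = np.asarray(all_scores)
    labels = np.asarray(all_labels)
    return LoocvResult(scores, labels, tuple(rows), sweep_curve(scores, labels))


# ---------------------------------------------------------------------------
# baselines


def baseline_neighborhood(net: InteractionNetwork, family: DiseaseFamily,
                          k: int = 1) -> frozenset[str]:
    """Candidates with at least ``k`` direct edges to the known genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    known_in = {g for g in family.known_genes if g in net}
    out = set()
    for j in family.candidates - family.known_genes:
        if j in net and len(net.neighbors(j) & known_in) >= k:
            out.add(j)
    return frozenset(out)


def random_walk_with_restart(net: InteractionNetwork, seeds: Iterable[str],
                             restart_prob: float = 0.7, *,
                             tol: float = 1e-10,
                             max_iter: int = 10_000) -> dict[str, float]:
    """Stationary visiting probabilities of a restarting random walk.

    Iterates ``p <- (1 - r) W p + r p0`` with ``W`` the column-normalized
    adjacency matrix and ``p0`` uniform over the seed genes, until the L1
    change drops below ``tol``.
    """
    if not 0 < restart_prob < 1:
        raise ValueError("restart probability must be in (0, 1)")
    nodes = sorted(net.nodes)
    index = {g: n for n, g in enumerate(nodes)}
    seeds = [s for s in seeds if s in index]
    if not seeds:
        raise ValueError("no seed gene is in the network")
    a = _adjacency(net, index)
    deg = np.asarray(a.sum(axis=0)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    w = a @ sp.diags(inv)
    p0 = np.zeros(len(nodes))
    p0[[index[s] for s in seeds]] = 1.0 / len(seeds)
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1 - restart_prob) * (w @ p) + restart_prob * p0
        if np.abs(p_next - p).sum() < tol:
            return dict(zip(nodes, p_next))
        p = p_next
    residual = float(np.abs(p_next - p).sum())
    raise RuntimeError(
        f"random walk did not converge in {max_iter} iterations "
        f"(L1 residual {residual:.3e})")


def _adjacency(net: InteractionNetwork, index: dict[str, int]) -> sp.csr_matrix:
    rows, cols = [], []
    for u, v in net.graph.edges:
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(len(index), len(index)))


def baseline_rwr(net: InteractionNetwork, family: DiseaseFamily,
                 restart_prob: float = 0.7) -> ScoreTable:
    """Rank the family's candidates by random-walk-with-restart probability."""
    probs = random_walk_with_restart(net, family.known_genes, restart_prob)
    cand = family.candidates - family.known_genes
    return ScoreTable.from_scores({j: probs.get(j, 0.0) for j in sorted(cand)})


# ---------------------------------------------------------------------------
# curve comparison


def pr_dominates(curve: EvaluationCurve, other: EvaluationCurve, *,
                 strict: bool = True, tol: float = 1e-12) -> bool:
    """Does ``curve`` dominate ``other`` in precision at matched recalls?

    Both curves are reduced to their upper envelopes (the best precision
    achievable at equal-or-higher recall), so redundant dominated points do
    not influence the comparison. For every recall level ``other`` attains,
    ``curve``'s envelope must be at least as high; with ``strict=True`` it
    must additionally be strictly higher at some matched recall (curves can
    tie at precision 1.0, so pointwise strictness everywhere is not a
    meaningful requirement).
    """
    def envelope(c: EvaluationCurve, r: float) -> float:
        mask = c.recall >= r - tol
        return float(c.precision[mask].max()) if mask.any() else float("-inf")

    any_strict = False
    for r in other.recall:
        mine = envelope(curve, r)
        theirs = envelope(other, r)
        if mine < theirs - tol:
            return False
        if mine > theirs + tol:
            any_strict = True
    return any_strict or not strict
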