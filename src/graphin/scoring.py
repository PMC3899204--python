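"""Scoring and ranking candidate genes against a known disease-gene set.

For a disease family with known gene set ``D`` and candidate set ``C``, a
candidate ``j`` is scored

    S_j = sum_k v_k * sum_{i in D} norm(N_ij(I_k)),

where ``N_ij(I_k)`` is the count of interaction isomer ``I_k`` from disease
gene ``i`` to ``j``, normalized by gene ``i``'s total outflow of that isomer
over a *normalization set*:

    norm(N_ij(I_k)) = N_ij(I_k) / N_i(I_k),
    N_i(I_k) = sum_{j' in norm_set} N_ij'(I_k).

The normalization makes each disease gene distribute one unit of "evidence"
per isomer across the normalization set, so hub disease genes do not
dominate the score. Two normalization-set conventions are supported:

``"candidates"`` (default)
    The family's candidate pool plus the other known disease genes,
    ``(C ∪ D) \\ {i}`` — evidence is spread only over genes actually in play.
``"all"``
    Every other node of the network. This is the convention of the worked
    protocol example, where totals are summed over all other genes.

Isomer weights ``v_k`` may be supplied, set to 1, or learned by ordinary
least squares on binary disease labels (see :func:`fit_weights`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .catalog import IsomerCatalog, N_ISOMERS, build_catalogs
from .counting import pair_counts
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseFamily",
    "NormalizationMode",
    "ScoreTable",
    "FeatureMatrix",
    "normalization_set",
    "outflow_totals",
    "normalize",
    "summed_normalized",
    "score_genes",
    "build_feature_matrix",
    "fit_weights",
    "unit_weights",
]

NormalizationMode = Literal["candidates", "all"]


@dataclass(frozen=True)
class DiseaseFamily:
    """Known disease genes ``D`` and candidate genes ``C`` of one family."""

    family_id: str
    known_genes: frozenset[str]
    candidates: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "known_genes", frozenset(self.known_genes))
        object.__setattr__(self, "candidates", frozenset(self.candidates))

    def replace_known(self, known: Iterable[str]) -> "DiseaseFamily":
        return DiseaseFamily(self.family_id, frozenset(known), self.candidates)


@dataclass(frozen=True)
class ScoreTable:
    """Ranked gene scores; rank 1 is the best.

    Ties are broken by lexicographic gene identifier so rankings are
    deterministic and seed-free.
    """

    frame: pd.DataFrame  # columns: gene, score, rank

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "ScoreTable":
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        frame = pd.DataFrame(
            {"gene": [g for g, _ in items],
             "score": [s for _, s in items],
             "rank": np.arange(1, len(items) + 1)}
        )
        return cls(frame)

    def score_of(self, gene: str) -> float:
        row = self.frame.loc[self.frame["gene"] == gene, "score"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])

    def rank_of(self, gene: str) -> int:
        row = self.frame.loc[self.frame["gene"] == gene, "rank"]
        if row.empty:
            raise KeyError(gene)
        return int(row.iloc[0])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.frame["gene"], self.frame["score"]))

    def __len__(self) -> int:
        return len(self.frame)


def unit_weights(n: int = N_ISOMERS) -> np.ndarray:
    """All-ones weight vector (the weights of the protocol example)."""
    return np.ones(n, dtype=float)


def normalization_set(net: InteractionNetwork, family: DiseaseFamily,
                      i: str, mode: NormalizationMode = "candidates"
                      ) -> frozenset[str]:
    """The gene set over which disease gene ``i``'s outflow totals are summed."""
    if mode == "all":
        return frozenset(net.nodes - {i})
    members = (family.candidates | family.known_genes) - {i}
    return frozenset(g for g in members if g in net)


def outflow_totals(net: InteractionNetwork, i: str,
                   norm_set: Iterable[str],
                   catalog: IsomerCatalog | None = None) -> np.ndarray:
    """Per-isomer totals N_i(I_k) = sum over the normalization set of N_ij(I_k)."""
    catalog = catalog if catalog is not None else build_catalogs()[1]
    norm_set = set(norm_set)
    if not norm_set:
        raise ValueError("normalization set must be nonempty")
    if i in norm_set:
        raise ValueError(f"gene {i!r} cannot belong to its own normalization set")
    totals = np.zeros(N_ISOMERS, dtype=np.int64)
    for j in norm_set:
        totals += pair_counts(net, i, j, catalog).counts
    return totals


def normalize(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Elementwise counts / totals, defined as 0 where the total is 0.

    A zero total means the disease gene never exhibits that isomer toward
    the normalization set, so no evidence can flow through it.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    out = np.zeros_like(counts)
    nz = totals > 0
    out[nz] = counts[nz] / totals[nz]
    return out


def summed_normalized(net: InteractionNetwork, known: Iterable[str], j: str,
                      totals_by_gene: dict[str, np.ndarray],
                      catalog: IsomerCatalog | None = None) -> np.ndarray:
    """sum over disease genes i of norm(N_ij(I_k)), as a 28-vector."""
    catalog = catalog if catalog is not None else build_catalogs()[1]
    acc = np.zeros(N_ISOMERS, dtype=float)
    for i in known:
        if i == j:
            continue
        vec = pair_counts(net, i, j, catalog)
        acc += normalize(vec.counts, totals_by_gene[i])
    return acc


def _totals_for_family(net: InteractionNetwork, family: DiseaseFamily,
                       known: Iterable[str], mode: NormalizationMode,
                       catalog: IsomerCatalog) -> dict[str, np.ndarray]:
    totals = {}
    for i in known:
        ns = normalization_set(net, family, i, mode)
        totals[i] = outflow_totals(net, i, ns, catalog)
    return totals


def _restricted_weights(weights: Sequence[float] | np.ndarray | None,
                        isomers: Sequence[int] | None) -> tuple[np.ndarray, list[int]]:
    """Expand a weight vector to 28 entries, zeroing excluded isomers.

    ``isomers`` is a list of 1-based isomer indices to use (e.g. the five
    small-graphlet isomers); ``None`` means all 28.
    """
    idx = list(isomers) if isomers is not None else list(range(1, N_ISOMERS + 1))
    full = np.zeros(N_ISOMERS, dtype=float)
    if weights is None:
        full[[k - 1 for k in idx]] = 1.0
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape == (N_ISOMERS,):
            full[[k - 1 for k in idx]] = w[[k - 1 for k in idx]]
        elif w.shape == (len(idx),):
            full[[k - 1 for k in idx]] = w
        else:
            raise ValueError(
                f"weight vector has length {w.size}; expected {N_ISOMERS} "
                f"or {len(idx)} (one per selected isomer)")
    if not np.all(np.isfinite(full)):
        raise ValueError("weights must be finite")
    return full, idx


def score_genes(net: InteractionNetwork, family: DiseaseFamily,
                weights: Sequence[float] | np.ndarray | None = None,
                catalog: IsomerCatalog | None = None, *,
                isomers: Sequence[int] | None = None,
                norm_mode: NormalizationMode = "candidates",
                genes: Iterable[str] | None = None) -> ScoreTable:
    """Score and rank genes by their graphlet interaction with ``D``.

    Parameters
    ----------
    weights:
        Isomer weights; ``None`` means unit weights.
    isomers:
        Optional 1-based isomer subset (e.g. ``[1..5]`` for 3-node
        graphlets only); excluded isomers contribute nothing.
    norm_mode:
        Normalization-set convention (see module docstring).
    genes:
        Genes to score. Defaults to ``C \\ D`` — known disease genes are
        not re-ranked against themselves outside cross-validation.
    """
    catalog = catalog if catalog is not None else build_catalogs()[1]
    known = sorted(g for g in family.known_genes if g in net)
    if not family.known_genes:
        raise ValueError(f"family {family.family_id!r} has no known disease genes")
    if not known:
        raise ValueError(
            f"family {family.family_id!r}: no known disease gene is in the network")
    full_w, _ = _restricted_weights(weights, isomers)

    if genes is None:
        genes = family.candidates - family.known_genes
    genes = sorted(set(genes))

    totals = _totals_for_family(net, family, known, norm_mode, catalog)
    scores: dict[str, float] = {}
    for j in genes:
        if j not in net:
            logger.warning("gene %r absent from network; scored 0", j)
            scores[j] = 0.0
            continue
        x = summed_normalized(net, known, j, totals, catalog)
        scores[j] = float(x @ full_w)
    return ScoreTable.from_scores(scores)


@dataclass(frozen=True)
class FeatureMatrix:
    """Training design for isomer-weight regression.

    One row per (family, gene in C ∪ D): ``X[j, k]`` is the summed
    normalized interaction of gene j with the family's disease genes, and
    ``labels[j]`` is 1 iff j is a known disease gene. Rows for disease
    genes are computed with that gene removed from D, so a gene never
    contributes evidence for its own label.
    """

    X: np.ndarray            # (n_rows, n_columns)
    labels: np.ndarray       # (n_rows,) of {0.0, 1.0}
    rows: tuple[tuple[str, str], ...]   # (family_id, gene)
    isomers: tuple[int, ...]            # 1-based column -> isomer index


def build_feature_matrix(net: InteractionNetwork,
                         families: Sequence[DiseaseFamily],
                         catalog: IsomerCatalog | None = None, *,
                         isomers: Sequence[int] | None = None,
                         norm_mode: NormalizationMode = "candidates"
                         ) -> FeatureMatrix:
    """Assemble the regression design over a set of training families."""
    catalog = catalog if catalog is not None else build_catalogs()[1]
    if not families:
        raise ValueError("no training families")
    idx = list(isomers) if isomers is not None else list(range(1, N_ISOMERS + 1))
    cols = [k - 1 for k in idx]

    rows: list[tuple[str, str]] = []
    feats: list[np.ndarray] = []
    labels: list[float] = []
    for fam in families:
        known_all = sorted(g for g in fam.known_genes if g in net)
        if len(known_all) < 2:
            logger.warning("family %r has fewer than 2 in-network disease "
                           "genes; skipped in training", fam.family_id)
            continue
        pool = sorted((fam.candidates | fam.known_genes))
        totals = _totals_for_family(net, fam, known_all, norm_mode, catalog)
        for j in pool:
            is_disease = j in fam.known_genes
            known = [i for i in known_all if i != j]
            if j not in net:
                feats.append(np.zeros(len(cols)))
            else:
                x = summed_normalized(net, known, j, totals, catalog)
                feats.append(x[cols])
            labels.append(1.0 if is_disease else 0.0)
            rows.append((fam.family_id, j))
    if not rows:
        raise ValueError("no usable training families (need |D| >= 2)")
    return FeatureMatrix(np.asarray(feats), np.asarray(labels),
                         tuple(rows), tuple(idx))


def fit_weights(fm: FeatureMatrix) -> np.ndarray:
    """Ordinary least squares without intercept: v = argmin ||X v - s||.

    Uses the minimum-norm least-squares solution, which coincides with
    (X'X)^{-1} X' s at full column rank and remains defined when X'X is
    singular. Returns a weight vector aligned with ``fm.isomers``.
    """
    if fm.X.size == 0:
        raise ValueError("empty feature matrix")
    if not np.any(fm.X):
        raise ValueError("all-zero feature matrix: no isomer evidence to fit")
    v, *_ = np.linalg.lstsq(fm.X, fm.labels, rcond=None)
    return v
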