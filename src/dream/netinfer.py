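"""Consensus co-expression network inference.

Each method ranks all gene pairs by interaction strength; rankings are
combined by Borda (mean-rank) aggregation and the consensus is cut to a
network.  The ensemble mixes a correlation family (Pearson, Spearman,
ranked by |r|) with a mutual-information family (CLR, ARACNE, MRNET)
estimated from an equal-width-binned MI matrix (ceil(sqrt(n)) bins), so that
both linear/monotone and more general dependencies vote on every edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from dream.dataio import ExpressionDataset, GeneNetwork

METHODS = ("pearson", "spearman", "clr", "aracne", "mrnet")


@dataclass
class EdgeRanking:
    """A method's ranking of every unordered gene pair.

    ``edges`` is the fixed lexicographic pair universe; ``ranks`` are 1..E
    with average-rank ties (rank 1 = strongest); ``scores`` are the raw
    method scores (higher = stronger).
    """

    method_name: str
    edges: list[tuple[str, str]]
    ranks: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.ranks) or len(self.edges) != len(self.scores):
            raise ValueError("edges, ranks and scores must align")


def edge_universe(genes: list[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs, lexicographic within and across pairs."""
    g = sorted(genes)
    return [(g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g))]


def _scores_to_ranking(method: str, genes: list[str], score_matrix: np.ndarray) -> EdgeRanking:
    order = np.argsort(np.array(genes, dtype=object))
    genes_sorted = [genes[i] for i in order]
    m = score_matrix[np.ix_(order, order)]
    edges = edge_universe(genes_sorted)
    iu = np.triu_indices(len(genes_sorted), k=1)
    scores = m[iu]
    ranks = stats.rankdata(-scores, method="average")
    return EdgeRanking(method, edges, ranks, scores)


def mutual_information_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise MI (nats) by equal-width binning with ceil(sqrt(n)) bins.

    ``values`` is genes x samples.  Each gene is discretized over its own
    range; MI is computed from the joint histogram.  Diagonal is zero.
    """
    n_genes, n_samples = values.shape
    n_bins = max(2, math.ceil(math.sqrt(n_samples)))
    # digitize each gene into equal-width bins over its own range
    binned = np.empty_like(values, dtype=np.intp)
    for i in range(n_genes):
        lo, hi = values[i].min(), values[i].max()
        if hi <= lo:
            binned[i] = 0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        binned[i] = np.clip(np.searchsorted(edges, values[i], side="right") - 1, 0, n_bins - 1)
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            joint = np.zeros((n_bins, n_bins))
            np.add.at(joint, (binned[i], binned[j]), 1.0)
            joint /= n_samples
            px = joint.sum(axis=1, keepdims=True)
            py = joint.sum(axis=0, keepdims=True)
            nz = joint > 0
            mi_ij = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
            mi[i, j] = mi[j, i] = max(0.0, mi_ij)
    return mi


def _clr_scores(mi: np.ndarray) -> np.ndarray:
    """CLR background correction: z-score each MI against its row context."""
    n = mi.shape[0]
    off = ~np.eye(n, dtype=bool)
    mu = np.array([mi[i, off[i]].mean() for i in range(n)])
    sd = np.array([mi[i, off[i]].std() for i in range(n)])
    sd = np.where(sd > 0, sd, 1.0)
    z = (mi - mu[:, None]) / sd[:, None]
    zp = np.maximum(z, 0.0)
    return np.sqrt(zp**2 + zp.T**2)


def _aracne_scores(mi: np.ndarray, tolerance: float = 0.0) -> np.ndarray:
    """ARACNE: MI scores with data-processing-inequality demotion.

    For every triangle, the weakest edge is pruned when its MI is below the
    minimum of the other two minus ``tolerance`` (comparisons on the original
    MI matrix; demotions applied afterwards).  A pruned edge is demoted
    strictly below every kept edge (its score turns negative) but pruned
    edges stay ordered by their MI among themselves: collapsing them into a
    single tie would make the ranking nearly uninformative for mean-rank
    consensus.  Negative score therefore means "pruned as indirect".
    """
    n = mi.shape[0]
    remove = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                trio = [(mi[i, j], i, j), (mi[i, k], i, k), (mi[j, k], j, k)]
                trio.sort(key=lambda t: t[0])
                weakest, others = trio[0], (trio[1][0], trio[2][0])
                if weakest[0] < min(others) - tolerance:
                    remove[weakest[1], weakest[2]] = remove[weakest[2], weakest[1]] = True
    scores = mi.copy()
    scores[remove] = mi[remove] - (mi.max() + 1.0)
    return scores


def _mrnet_scores(mi: np.ndarray) -> np.ndarray:
    """MRNET: max-relevance-min-redundancy forward-selection scores.

    For each target gene, predictors are forward-selected by the MRMR score
    (relevance MI minus mean redundancy to already-selected predictors); the
    score of pair (i, j) is the max of i's score for target j and vice versa.
    """
    n = mi.shape[0]
    s = np.full((n, n), -np.inf)
    for target in range(n):
        candidates = [g for g in range(n) if g != target]
        selected: list[int] = []
        remaining = set(candidates)
        while remaining:
            best, best_score = None, -np.inf
            for c in remaining:
                redundancy = np.mean([mi[c, s_] for s_ in selected]) if selected else 0.0
                score = mi[c, target] - redundancy
                if score > best_score:
                    best, best_score = c, score
            selected.append(best)
            remaining.discard(best)
            s[best, target] = best_score
    return np.maximum(s, s.T)


def infer_single(ds: ExpressionDataset, method: str) -> EdgeRanking:
    """Rank all gene pairs with one inference method (all samples pooled)."""
    return infer_single_matrix(list(ds.gene_ids), ds.values, method)


def infer_single_matrix(genes: list[str], values: np.ndarray, method: str) -> EdgeRanking:
    """Rank all gene pairs from a raw genes x samples matrix.

    Correlation methods rank by |r|; MI-family methods transform the binned
    MI matrix (CLR background z-scores, ARACNE DPI pruning, MRNET forward
    scores).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    x = np.asarray(values, dtype=float)
    if x.shape[1] < 3 or len(genes) < 3:
        raise ValueError("need at least 3 samples and 3 genes")
    if method == "pearson":
        with np.errstate(invalid="ignore"):
            m = np.abs(np.corrcoef(x))
        m = np.nan_to_num(m, nan=0.0)
    elif method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, x)
        with np.errstate(invalid="ignore"):
            m = np.abs(np.corrcoef(ranks))
        m = np.nan_to_num(m, nan=0.0)
    else:
        mi = mutual_information_matrix(x)
        m = {"clr": _clr_scores, "aracne": _aracne_scores, "mrnet": _mrnet_scores}[method](mi)
    np.fill_diagonal(m, 0.0)
    return _scores_to_ranking(method, list(genes), m)


def infer_ensemble(ds: ExpressionDataset, methods: tuple[str, ...] = METHODS) -> list[EdgeRanking]:
    return [infer_single(ds, m) for m in methods]


def aggregate_rankings(rankings: list[EdgeRanking]) -> EdgeRanking:
    """Borda consensus: mean per-method rank, ties broken by edge label."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings to aggregate")
    universe = rankings[0].edges
    for r in rankings[1:]:
        if r.edges != universe:
            missing = sorted(set(universe) ^ set(r.edges))
            raise ValueError(f"edge universes differ; mismatched pairs: {missing[:10]}")
    mean_ranks = np.mean([r.ranks for r in rankings], axis=0)
    order = sorted(range(len(universe)), key=lambda i: (mean_ranks[i], universe[i]))
    consensus_ranks = np.empty(len(universe))
    for pos, i in enumerate(order, start=1):
        consensus_ranks[i] = pos
    return EdgeRanking(
        method_name="consensus",
        edges=universe,
        ranks=consensus_ranks,
        scores=-mean_ranks,  # higher = stronger, monotone with consensus rank
    )


def threshold_network(
    consensus: EdgeRanking,
    top_k: int | None = None,
    top_frac: float | None = None,
) -> GeneNetwork:
    """Cut the consensus ranking to a network of its strongest edges.

    Exactly one of ``top_k`` / ``top_frac`` must be given.  Edge weight is
    ``1 - (rank - 1) / E`` so the strongest edge has weight 1; isolated genes
    are dropped (a network has only the genes its kept edges touch).
    """
    if (top_k is None) == (top_frac is None):
        raise ValueError("give exactly one of top_k or top_frac")
    e = len(consensus.edges)
    if top_frac is not None:
        if not 0.0 < top_frac <= 1.0:
            raise ValueError("top_frac must be in (0, 1]")
        top_k = max(1, round(top_frac * e))
    if top_k > e:
        import logging

        logging.getLogger("dream.netinfer").warning(
            "top_k=%d exceeds %d ranked edges; keeping all", top_k, e
        )
        top_k = e
    order = np.argsort(consensus.ranks, kind="stable")
    edges = []
    for i in order[:top_k]:
        a, b = consensus.edges[i]
        edges.append((a, b, 1.0 - (consensus.ranks[i] - 1.0) / e))
    return GeneNetwork.from_edges(edges)
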