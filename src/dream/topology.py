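"""Topological drug properties on the disease network.

* area of action: fraction of disease-network nodes covered by a drug's
  in-network targets plus their direct interactors;
* target-pair distance: mean shortest-path length between the in-network
  target sets of two drugs (all cross pairs);
* combination coverage: area of action of the pooled target set of a drug
  subset.

Shortest paths are unweighted hop counts by default; a flag switches to
1 - weight edge lengths for weighted networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from dream.dataio import DistanceMatrix, DrugRecord, GeneNetwork

UnreachablePolicy = Literal["exclude", "penalize"]


def _in_network(net: GeneNetwork, targets: Iterable[str]) -> set[str]:
    return set(targets) & set(net.graph.nodes)


def area_of_action(net: GeneNetwork, targets: Iterable[str]) -> float:
    """|(targets in V) union their neighbors| / |V|.

    Targets absent from the network are ignored (drug libraries routinely
    exceed the disease network's gene universe); no in-network target
    gives 0.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    hits = _in_network(net, targets)
    covered = set(hits)
    for t in hits:
        covered.update(net.graph.neighbors(t))
    return len(covered) / net.n_nodes


def _path_lengths(net: GeneNetwork, source: str, weighted: bool) -> dict[str, float]:
    if not weighted:
        return nx.single_source_shortest_path_length(net.graph, source)
    # edge length 1 - weight: strong edges are short
    return nx.single_source_dijkstra_path_length(
        net.graph, source, weight=lambda u, v, d: 1.0 - d.get("weight", 1.0)
    )


def target_pair_distance(
    net: GeneNetwork,
    targets_a: Iterable[str],
    targets_b: Iterable[str],
    unreachable_policy: UnreachablePolicy = "exclude",
    weighted: bool = False,
) -> tuple[float, int]:
    """Mean shortest-path length over all cross target pairs of two drugs.

    Pairs (t_a, t_b) run over the in-network targets of each drug; a shared
    target contributes distance 0.  Pairs in different components are either
    excluded from the mean (default, counted) or penalized with |V|.
    Returns (mean distance, unreachable pair count).
    """
    ta = _in_network(net, targets_a)
    tb = _in_network(net, targets_b)
    if not ta or not tb:
        empty = "first" if not ta else "second"
        raise ValueError(f"{empty} drug has no target in the network")
    dists = []
    unreachable = 0
    for t in sorted(ta):
        lengths = _path_lengths(net, t, weighted)
        for u in sorted(tb):
            if u in lengths:
                dists.append(float(lengths[u]))
            else:
                unreachable += 1
                if unreachable_policy == "penalize":
                    dists.append(float(net.n_nodes))
    mean = float(np.mean(dists)) if dists else float("nan")
    return mean, unreachable


def combination_coverage(net: GeneNetwork, drugs: Sequence[DrugRecord]) -> float:
    """Area of action of the union of the subset's targets (no double count)."""
    if not drugs:
        raise ValueError("drug subset is empty")
    pooled: set[str] = set()
    for d in drugs:
        pooled |= d.targets
    return area_of_action(net, pooled)


@dataclass
class TopologyReport:
    """Batch per-drug and per-pair topology metrics on a disease network."""

    drug_ids: list[str]
    targets_in_network: dict[str, int]
    area: dict[str, float]
    pair_distance: DistanceMatrix
    unreachable_pairs: dict[tuple[str, str], int]
    errors: dict[str, str] = field(default_factory=dict)


def topology_report(
    net: GeneNetwork,
    drugs: Sequence[DrugRecord],
    unreachable_policy: UnreachablePolicy = "exclude",
    weighted: bool = False,
) -> TopologyReport:
    """Per-drug area of action and the symmetric pair-distance matrix.

    Drugs with no in-network target are reported in ``errors`` (their pair
    distances are NaN); the batch continues.
    """
    ids = [d.drug_id for d in drugs]
    in_net = {d.drug_id: _in_network(net, d.targets) for d in drugs}
    errors = {i: "no target in network" for i in ids if not in_net[i]}
    area = {d.drug_id: area_of_action(net, d.targets) for d in drugs}
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 0.0)
    unreachable: dict[tuple[str, str], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if not in_net[ids[i]] or not in_net[ids[j]]:
                continue
            mean, n_unreach = target_pair_distance(
                net, in_net[ids[i]], in_net[ids[j]], unreachable_policy, weighted
            )
            values[i, j] = values[j, i] = mean
            if n_unreach:
                unreachable[tuple(sorted((ids[i], ids[j])))] = n_unreach
    return TopologyReport(
        drug_ids=ids,
        targets_in_network={i: len(in_net[i]) for i in ids},
        area=area,
        pair_distance=_nan_symmetric_matrix(ids, values),
        unreachable_pairs=unreachable,
        errors=errors,
    )


def _nan_symmetric_matrix(ids: list[str], values: np.ndarray) -> DistanceMatrix:
    # DistanceMatrix checks symmetry; NaNs (drug with no in-network target)
    # are kept as NaN but compared as equal on both sides by construction.
    filled = values.copy()
    mask = np.isnan(filled)
    filled[mask] = -1.0
    dm = DistanceMatrix(ids, filled)
    dm.values[dm.values == -1.0] = np.nan
    return dm
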