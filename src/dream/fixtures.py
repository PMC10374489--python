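"""Synthetic inputs with known ground truth.

The expression generator plants three disjoint structures in a genes x
samples matrix: co-expressed blocks (multivariate normal with constant
within-block correlation rho, present in both conditions), location-shifted
genes (disease mean moved by delta within-gene standard deviations) and
variance genes (disease variance scaled by kappa).  Everything else is
i.i.d. standard normal, so unplanted genes are null for every test.

The drug generator draws real small-molecule SMILES from a fixed list and
derives each drug's perturbational network by seeded edge rewires of a base
network: more rewires give a larger expected HIM distance, providing a
monotone mechanism-of-action ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dream.dataio import DrugRecord, ExpressionDataset, GeneNetwork

# Real, verified small-molecule SMILES so cheminformatics steps behave like
# production inputs (names are colloquial identifiers, not label claims).
DRUG_SMILES: list[tuple[str, str]] = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("salicylic_acid", "O=C(O)c1ccccc1O"),
    ("phenol", "Oc1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("urea", "NC(N)=O"),
    ("glycine", "NCC(=O)O"),
    ("citric_acid", "OC(=O)CC(O)(C(=O)O)CC(=O)O"),
    ("nicotinamide", "NC(=O)c1cccnc1"),
    ("benzoic_acid", "O=C(O)c1ccccc1"),
    ("acetone", "CC(C)=O"),
    ("pyridine", "c1ccncc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("cyclohexane", "C1CCCCC1"),
    ("anthranilic_acid", "Nc1ccccc1C(=O)O"),
    ("resorcinol", "Oc1cccc(O)c1"),
    ("catechol", "Oc1ccccc1O"),
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure expression generator.

    Defaults give a mid-sized two-condition study: 150 genes, 20 samples per
    condition, three tightly co-expressed 8-gene blocks (rho = 0.9), 25
    genes shifted by 2 within-gene standard deviations and 20 genes with a
    4-fold disease variance.
    """

    n_genes: int = 150
    n_samples_per_condition: int = 20
    n_planted_blocks: int = 3
    block_size: int = 8
    within_block_correlation: float = 0.9
    n_shifted_genes: int = 25
    effect_size: float = 2.0  # delta, in within-gene SD units
    n_variance_genes: int = 20
    variance_ratio: float = 4.0  # kappa
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.within_block_correlation < 1.0:
            raise ValueError("within_block_correlation must be in (0, 1)")
        if self.n_samples_per_condition < 2:
            raise ValueError("need at least 2 samples per condition")
        if self.variance_ratio <= 0 or self.block_size < 2 and self.n_planted_blocks > 0:
            raise ValueError("invalid variance_ratio or block_size")
        n_planted = (
            self.n_planted_blocks * self.block_size
            + self.n_shifted_genes
            + self.n_variance_genes
        )
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted structures need {n_planted} genes but n_genes={self.n_genes}"
            )


@dataclass
class ExpressionTruth:
    """Which genes carry which planted structure."""

    block_genes: list[list[str]]
    block_edges: set[tuple[str, str]]
    shifted_genes: set[str]
    variance_genes: set[str]

    @property
    def altered_genes(self) -> set[str]:
        return self.shifted_genes | self.variance_genes


def make_expression(spec: SyntheticSpec) -> tuple[ExpressionDataset, ExpressionTruth]:
    """Generate a two-condition dataset with the planted ground truth.

    Planted structures occupy disjoint leading gene indices: blocks first,
    then shifted genes, then variance genes.
    """
    rng = np.random.default_rng(spec.seed)
    g, m = spec.n_genes, spec.n_samples_per_condition
    genes = [f"G{i:04d}" for i in range(g)]
    samples = [f"C{i:02d}" for i in range(m)] + [f"D{i:02d}" for i in range(m)]
    condition = ["control"] * m + ["disease"] * m

    values = rng.standard_normal((g, 2 * m))

    block_genes: list[list[str]] = []
    block_edges: set[tuple[str, str]] = set()
    pos = 0
    rho, b = spec.within_block_correlation, spec.block_size
    cov = np.full((b, b), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov) if spec.n_planted_blocks else None
    for _ in range(spec.n_planted_blocks):
        idx = list(range(pos, pos + b))
        # correlated draw shared across both conditions' generative process
        values[idx, :] = chol @ rng.standard_normal((b, 2 * m))
        members = [genes[i] for i in idx]
        block_genes.append(members)
        for i in range(b):
            for j in range(i + 1, b):
                block_edges.add(tuple(sorted((members[i], members[j]))))
        pos += b

    shifted = set(genes[pos : pos + spec.n_shifted_genes])
    values[pos : pos + spec.n_shifted_genes, m:] += spec.effect_size
    pos += spec.n_shifted_genes

    variance = set(genes[pos : pos + spec.n_variance_genes])
    values[pos : pos + spec.n_variance_genes, m:] *= np.sqrt(spec.variance_ratio)

    ds = ExpressionDataset(genes, samples, values, condition)
    return ds, ExpressionTruth(block_genes, block_edges, shifted, variance)


def block_truth_network(truth: ExpressionTruth) -> GeneNetwork:
    """The planted co-expression network: a clique per block."""
    return GeneNetwork.from_edges([(a, b, 1.0) for a, b in sorted(truth.block_edges)])


def disease_network(truth: ExpressionTruth) -> GeneNetwork:
    """A connected disease-network fixture: block cliques plus bridges.

    Consecutive blocks are linked by a single edge (last member to first
    member), mimicking the connectedness of real co-expression networks so
    every topological distance is defined while within-block distances stay
    short and between-block distances long.
    """
    edges = [(a, b, 1.0) for a, b in sorted(truth.block_edges)]
    blocks = truth.block_genes
    for k in range(len(blocks) - 1):
        a, b = sorted((blocks[k][-1], blocks[k + 1][0]))
        edges.append((a, b, 1.0))
    return GeneNetwork.from_edges(edges)


def rewire_network(net: GeneNetwork, n_rewires: int, rng: np.random.Generator) -> GeneNetwork:
    """Remove ``n_rewires`` random edges and add as many random non-edges.

    Node set is preserved, so rewired copies stay aligned with the base
    network and the expected HIM distance grows with ``n_rewires``.
    """
    nodes = net.nodes
    edges = {(a, b) for a, b, _ in net.edges()}
    all_pairs = {
        (nodes[i], nodes[j]) for i in range(len(nodes)) for j in range(i + 1, len(nodes))
    }
    non_edges = sorted(all_pairs - edges)
    edge_list = sorted(edges)
    k = min(n_rewires, len(edge_list), len(non_edges))
    drop_idx = set(rng.choice(len(edge_list), size=k, replace=False).tolist()) if k else set()
    add_idx = rng.choice(len(non_edges), size=k, replace=False).tolist() if k else []
    new_edges = {e for i, e in enumerate(edge_list) if i not in drop_idx}
    new_edges |= {non_edges[i] for i in add_idx}
    return GeneNetwork.from_edges([(a, b, 1.0) for a, b in sorted(new_edges)], nodes=nodes)


def make_drug_library(
    n_drugs: int,
    network: GeneNetwork,
    seed: int = 0,
    targets_per_drug: int = 2,
    rewire_step: int = 3,
) -> list[DrugRecord]:
    """A toy drug library tied to a base (disease) network.

    Targets are assigned deterministically round-robin over the network's
    sorted nodes; drug i's perturbational network is the base network with
    ``i * rewire_step`` seeded edge rewires (drug 0 keeps it unchanged), so
    pairwise HIM distances have a known expected ordering.
    """
    if not 2 <= n_drugs <= len(DRUG_SMILES):
        raise ValueError(f"n_drugs must be in [2, {len(DRUG_SMILES)}]")
    nodes = network.nodes
    if not nodes:
        raise ValueError("base network is empty")
    rng = np.random.default_rng(seed)
    drugs = []
    for i in range(n_drugs):
        name, smiles = DRUG_SMILES[i]
        targets = {nodes[(i * targets_per_drug + j) % len(nodes)] for j in range(targets_per_drug)}
        pert = rewire_network(network, i * rewire_step, rng)
        drugs.append(DrugRecord(name, smiles, targets, pert))
    return drugs
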