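"""Multi-objective search for drug combinations (NSGA-II).

A combination is a subset S of the drug library with 2 <= |S| <= max_size.
Five objectives are evaluated per subset:

    f1  number of drugs               (minimized: parsimony)
    f2  mean pairwise MOA distance    (maximized: complementary mechanisms)
    f3  mean pairwise chemical dist.  (maximized: complementary chemotypes)
    f4  disease-network coverage      (maximized)
    f5  mean inter-drug target dist.  (maximized: complementary exposure)

Each direction can be flipped in the configuration.  The engine is a
standard elitist NSGA-II: fast non-dominated sorting, crowding distance,
binary tournament on (rank, crowding), uniform crossover, per-bit mutation,
and repair of infeasible subsets.  All randomness flows from one seeded
generator, so runs are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from dream.dataio import DistanceMatrix, DrugRecord, GeneNetwork
from dream.topology import combination_coverage, topology_report

N_OBJECTIVES = 5
DEFAULT_DIRECTIONS = {
    "f1_size": "min",
    "f2_moa": "max",
    "f3_structure": "max",
    "f4_coverage": "max",
    "f5_target_dist": "max",
}
OBJECTIVE_NAMES = tuple(DEFAULT_DIRECTIONS)


class ObjectiveVector(NamedTuple):
    f1_size: float
    f2_moa: float
    f3_structure: float
    f4_coverage: float
    f5_target_dist: float


@dataclass(frozen=True)
class ParetoSolution:
    subset: tuple[str, ...]
    objectives: ObjectiveVector
    rank: int
    crowding: float


@dataclass
class GAConfig:
    pop_size: int = 100
    generations: int = 200
    p_crossover: float = 0.9
    p_mut_bit: float | None = None  # default 1/L
    max_size: int = 4
    seed: int = 0
    directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))

    def signs(self) -> np.ndarray:
        """+1 for minimized, -1 for maximized objectives (canonical = minimize)."""
        unknown = set(self.directions) - set(OBJECTIVE_NAMES)
        if unknown:
            raise ValueError(f"unknown objective keys: {sorted(unknown)}")
        dirs = {**DEFAULT_DIRECTIONS, **self.directions}
        return np.array([1.0 if dirs[k] == "min" else -1.0 for k in OBJECTIVE_NAMES])


class Precomputed:
    """Per-library inputs shared by every objective evaluation.

    Holds the MOA and chemical distance matrices, the disease network and
    per-drug target sets; the target-pair distance matrix is computed once
    at construction.
    """

    def __init__(
        self,
        drugs: Sequence[DrugRecord],
        moa: DistanceMatrix,
        chem: DistanceMatrix,
        network: GeneNetwork,
    ):
        self.drug_ids = [d.drug_id for d in drugs]
        self.drugs = {d.drug_id: d for d in drugs}
        self.moa = moa
        self.chem = chem
        self.network = network
        for name, matrix in (("MOA", moa), ("chemical", chem)):
            missing = [i for i in self.drug_ids if i not in matrix.labels]
            if missing:
                raise ValueError(f"drugs missing from the {name} matrix: {missing}")
        report = topology_report(network, list(drugs))
        if report.errors:
            raise ValueError(f"drugs unusable on the disease network: {report.errors}")
        self.target_dist = report.pair_distance
        self._coverage_cache: dict[frozenset, float] = {}

    def coverage(self, subset: Sequence[str]) -> float:
        key = frozenset(subset)
        if key not in self._coverage_cache:
            self._coverage_cache[key] = combination_coverage(
                self.network, [self.drugs[i] for i in subset]
            )
        return self._coverage_cache[key]


def _pair_mean(matrix: DistanceMatrix, subset: Sequence[str]) -> float:
    sub = matrix.submatrix(subset)
    iu = np.triu_indices(len(subset), k=1)
    return float(sub[iu].mean())


def evaluate(subset: Sequence[str], pre: Precomputed) -> ObjectiveVector:
    """Five-objective vector of a drug subset (pairwise means over C(|S|,2))."""
    subset = sorted(subset)
    if len(subset) < 2:
        raise ValueError("a combination needs at least 2 drugs")
    missing = [i for i in subset if i not in pre.drugs]
    if missing:
        raise ValueError(f"unknown drugs: {missing}")
    return ObjectiveVector(
        f1_size=float(len(subset)),
        f2_moa=_pair_mean(pre.moa, subset),
        f3_structure=_pair_mean(pre.chem, subset),
        f4_coverage=pre.coverage(subset),
        f5_target_dist=_pair_mean(pre.target_dist, subset),
    )


# ---------------------------------------------------------------------------
# Dominance machinery (canonical orientation: every objective minimized)
# ---------------------------------------------------------------------------


def dominates(v1: Sequence[float], v2: Sequence[float]) -> bool:
    """Pareto dominance: <= everywhere and < somewhere (canonical minimize)."""
    a, b = np.asarray(v1, float), np.asarray(v2, float)
    return bool(np.all(a <= b) and np.any(a < b))


def _domination_matrix(f: np.ndarray) -> np.ndarray:
    le = np.all(f[:, None, :] <= f[None, :, :], axis=2)
    lt = np.any(f[:, None, :] < f[None, :, :], axis=2)
    return le & lt


def pareto_front_mask(f: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated rows of a canonical objective matrix."""
    return ~_domination_matrix(f).any(axis=0)


def pareto_front(solutions: Sequence[ParetoSolution], signs: np.ndarray | None = None) -> list[ParetoSolution]:
    """The non-dominated subset of a list of solutions."""
    if not solutions:
        raise ValueError("no solutions given")
    if signs is None:
        signs = GAConfig().signs()
    f = np.array([s.objectives for s in solutions], float) * signs
    mask = pareto_front_mask(f)
    return [s for s, keep in zip(solutions, mask) if keep]


def fast_nondominated_sort(f: np.ndarray) -> np.ndarray:
    """NSGA-II rank (0 = first front) for each row of a canonical matrix."""
    dom = _domination_matrix(f)
    n_dominators = dom.sum(axis=0)
    rank = np.full(f.shape[0], -1, dtype=int)
    current = np.where(n_dominators == 0)[0]
    r = 0
    remaining = n_dominators.copy()
    while current.size:
        rank[current] = r
        for i in current:
            remaining[dom[i]] -= 1
        remaining[current] = -1
        current = np.where(remaining == 0)[0]
        r += 1
    return rank


def crowding_distance(f: np.ndarray) -> np.ndarray:
    """Crowding distance within one front (canonical objective matrix)."""
    n, m = f.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(f[:, j], kind="stable")
        span = f[order[-1], j] - f[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        gaps = (f[order[2:], j] - f[order[:-2], j]) / span
        dist[order[1:-1]] += gaps
    return dist


# ---------------------------------------------------------------------------
# The GA loop
# ---------------------------------------------------------------------------


def _repair(chrom: np.ndarray, max_size: int, rng: np.random.Generator) -> None:
    while chrom.sum() < 2:
        zeros = np.flatnonzero(chrom == 0)
        chrom[rng.choice(zeros)] = 1
    while chrom.sum() > max_size:
        ones = np.flatnonzero(chrom == 1)
        chrom[rng.choice(ones)] = 0


def _rank_and_crowd(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rank = fast_nondominated_sort(f)
    crowd = np.zeros(f.shape[0])
    for r in range(rank.max() + 1):
        idx = np.where(rank == r)[0]
        crowd[idx] = crowding_distance(f[idx])
    return rank, crowd


def _tournament(rank, crowd, rng) -> int:
    i, j = rng.integers(0, rank.size, size=2)
    if rank[i] != rank[j]:
        return int(i if rank[i] < rank[j] else j)
    if crowd[i] != crowd[j]:
        return int(i if crowd[i] > crowd[j] else j)
    return int(i)


def run_ga(
    drugs: Sequence[DrugRecord],
    pre: Precomputed,
    config: GAConfig | None = None,
    history: list[np.ndarray] | None = None,
) -> list[ParetoSolution]:
    """NSGA-II over drug subsets; returns the final first front, deduplicated.

    Reproducible for a fixed ``config.seed``: initialization, tournament,
    crossover, mutation and repair all draw from one seeded generator.
    When ``history`` is a list, the canonical objective matrix of each
    generation's first front is appended to it (for convergence diagnostics).
    """
    config = config or GAConfig()
    if config.max_size < 2:
        raise ValueError("max_size must be >= 2")
    ids = sorted(d.drug_id for d in drugs)
    n = len(ids)
    if n < config.max_size + 1:
        raise ValueError(f"need more than max_size={config.max_size} candidate drugs")
    rng = np.random.default_rng(config.seed)
    p_mut = config.p_mut_bit if config.p_mut_bit is not None else 1.0 / n
    signs = config.signs()

    cache: dict[bytes, ObjectiveVector] = {}

    def eval_chrom(chrom: np.ndarray) -> ObjectiveVector:
        key = chrom.tobytes()
        if key not in cache:
            subset = [ids[i] for i in np.flatnonzero(chrom)]
            cache[key] = evaluate(subset, pre)
        return cache[key]

    # initial population: random subsets of feasible size
    pop = np.zeros((config.pop_size, n), dtype=np.int8)
    for c in pop:
        size = int(rng.integers(2, config.max_size + 1))
        c[rng.choice(n, size=size, replace=False)] = 1
    obj = np.array([eval_chrom(c) for c in pop], float)

    for _ in range(config.generations):
        f = obj * signs
        rank, crowd = _rank_and_crowd(f)
        if history is not None:
            history.append(f[rank == 0].copy())
        # variation
        children = np.empty_like(pop)
        for k in range(0, config.pop_size, 2):
            p1 = pop[_tournament(rank, crowd, rng)]
            p2 = pop[_tournament(rank, crowd, rng)]
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < config.p_crossover:
                mask = rng.random(n) < 0.5
                c1[mask], c2[mask] = p2[mask], p1[mask]
            for c in (c1, c2):
                flip = rng.random(n) < p_mut
                c[flip] ^= 1
                _repair(c, config.max_size, rng)
            children[k] = c1
            if k + 1 < config.pop_size:
                children[k + 1] = c2
        child_obj = np.array([eval_chrom(c) for c in children], float)
        # elitist survival from the combined pool
        all_pop = np.vstack([pop, children])
        all_obj = np.vstack([obj, child_obj])
        rank, crowd = _rank_and_crowd(all_obj * signs)
        order = np.lexsort((-crowd, rank))
        keep = order[: config.pop_size]
        pop, obj = all_pop[keep], all_obj[keep]

    f = obj * signs
    rank, crowd = _rank_and_crowd(f)
    if history is not None:
        history.append(f[rank == 0].copy())
    seen: set[tuple[str, ...]] = set()
    front: list[ParetoSolution] = []
    for i in np.where(rank == 0)[0]:
        subset = tuple(ids[j] for j in np.flatnonzero(pop[i]))
        if subset in seen:
            continue
        seen.add(subset)
        front.append(
            ParetoSolution(
                subset=subset,
                objectives=ObjectiveVector(*obj[i]),
                rank=0,
                crowding=float(crowd[i]),
            )
        )
    front.sort(key=lambda s: s.subset)
    return front


def exhaustive_front(
    drugs: Sequence[DrugRecord], pre: Precomputed, max_size: int = 4, signs: np.ndarray | None = None
) -> list[ParetoSolution]:
    """Enumerate every feasible subset and return the exact Pareto front.

    Tractable for small libraries; the reference answer the GA approximates.
    """
    from itertools import combinations

    if signs is None:
        signs = GAConfig().signs()
    ids = sorted(d.drug_id for d in drugs)
    subsets = [
        combo for size in range(2, max_size + 1) for combo in combinations(ids, size)
    ]
    sols = [
        ParetoSolution(tuple(s), evaluate(s, pre), rank=0, crowding=float("inf"))
        for s in subsets
    ]
    return sorted(pareto_front(sols, signs), key=lambda s: s.subset)


def report_front(solutions: Sequence[ParetoSolution]) -> dict:
    """Group a front by combination size: counts plus per-solution rows."""
    counts: dict[int, int] = {}
    for s in solutions:
        counts[len(s.subset)] = counts.get(len(s.subset), 0) + 1
    return {
        "n_solutions": len(solutions),
        "counts_by_size": dict(sorted(counts.items())),
        "solutions": [
            {"size": len(s.subset), "drugs": list(s.subset), **s.objectives._asdict()}
            for s in solutions
        ],
    }


def hypervolume_mc(
    front: np.ndarray,
    reference: np.ndarray,
    lower: np.ndarray | None = None,
    n_samples: int = 20000,
    seed: int = 0,
) -> float:
    """Monte Carlo hypervolume of a canonical (minimize) front.

    Samples uniformly in the box [lower, reference]; with a fixed seed and a
    fixed box the same sample cloud is reused, so estimates are directly
    comparable across fronts (a point's dominated status can only flip one
    way when the dominated region grows).
    """
    front = np.asarray(front, float)
    reference = np.asarray(reference, float)
    lo = front.min(axis=0) if lower is None else np.asarray(lower, float)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, reference, size=(n_samples, front.shape[1]))
    dominated = np.zeros(n_samples, dtype=bool)
    for row in front:
        dominated |= np.all(row <= pts, axis=1)
    box = float(np.prod(reference - lo))
    return box * dominated.mean()
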