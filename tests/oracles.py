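"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (enumeration, dense grids, textbook DP)
and shares no code path with the implementation it validates.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def rank_sum_p_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n1 = len(x)
    # midranks, computed from scratch
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[:n1].sum()
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)])
    p = 2.0 * min((sums <= w_obs + 1e-12).mean(), (sums >= w_obs - 1e-12).mean())
    return min(p, 1.0)


def f_two_sided_p_numeric(f_obs: float, d1: int, d2: int, n_grid: int = 1_000_000) -> float:
    """Two-sided variance-ratio p by trapezoid integration of the F density.

    Lower CDFs only, on the substitution x = s^2 (which removes the
    x^(d1/2-1) singularity at 0 for small d1); the upper tail comes from the
    reciprocal identity P(F_{d1,d2} > f) = P(F_{d2,d1} < 1/f).
    """
    from math import exp, lgamma, log

    def cdf(f, a, b):
        log_const = lgamma((a + b) / 2) - lgamma(a / 2) - lgamma(b / 2) + (a / 2) * log(a / b)
        s = np.linspace(0.0, np.sqrt(f), n_grid)
        x = s**2
        with np.errstate(divide="ignore"):
            integrand = 2.0 * s ** (a - 1.0) * np.exp(-((a + b) / 2) * np.log1p(a * x / b))
        return exp(log_const) * np.trapezoid(integrand, s)

    lower = cdf(f_obs, d1, d2)
    upper = cdf(1.0 / f_obs, d2, d1)
    return min(1.0, 2.0 * min(lower, upper))


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p[i] * m / (pos + 1))
        adj[i] = running_min
    return adj


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def floyd_warshall(n: int, edges) -> np.ndarray:
    """All-pairs unweighted shortest paths; inf where unreachable."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in edges:
        d[a, b] = d[b, a] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def brute_force_front(vectors: np.ndarray) -> np.ndarray:
    """Non-dominated mask by O(n^2) pairwise checks (canonical minimize)."""
    v = np.asarray(vectors, float)
    n = v.shape[0]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.all(v[j] <= v[i]) and np.any(v[j] < v[i]):
                keep[i] = False
                break
    return keep


def im_trapezoid(freq_a: np.ndarray, freq_b: np.ndarray, gamma: float, n_points: int = 1_000_000) -> float:
    """Ipsen-Mikhailov distance on a dense grid, everything numeric.

    Both the normalization constants and the L2 integral come from the same
    trapezoid grid, so no closed form is shared with the implementation.
    """
    upper = float(max(freq_a.max(initial=0.0), freq_b.max(initial=0.0)) + 20.0 * gamma)
    omega = np.linspace(0.0, upper, n_points)
    # wide auxiliary grid for the [0, inf) normalization: geometric spacing
    # resolves the slowly decaying 1/omega^2 Lorentzian tails
    tail = np.geomspace(upper, upper * 1e6, 200_000)

    def lorentz_sum(x, freqs):
        rho = np.zeros_like(x)
        for w in freqs:
            rho += gamma / ((x - w) ** 2 + gamma**2)
        return rho

    def density(freqs):
        rho = lorentz_sum(omega, freqs)
        mass = np.trapezoid(rho, omega) + np.trapezoid(lorentz_sum(tail, freqs), tail)
        return rho / mass

    diff = density(freq_a) - density(freq_b)
    return float(np.sqrt(np.trapezoid(diff**2, omega)))


def mcs_brute_force(mol_a, mol_b) -> int:
    """Largest common connected substructure atom count by enumeration.

    Enumerates connected atom subsets of the smaller molecule and tests each
    induced subgraph for an element+bond-order preserving embedding in the
    other molecule (via networkx subgraph isomorphism).  Exponential; only
    for molecules with a handful of heavy atoms.
    """
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher

    def to_graph(mol):
        g = nx.Graph()
        for atom in mol.GetAtoms():
            g.add_node(atom.GetIdx(), el=atom.GetSymbol())
        for bond in mol.GetBonds():
            g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=str(bond.GetBondType()))
        return g

    ga, gb = to_graph(mol_a), to_graph(mol_b)
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    atoms = list(ga.nodes)
    for size in range(len(atoms), 0, -1):
        for subset in combinations(atoms, size):
            sub = ga.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = GraphMatcher(
                gb,
                sub,
                node_match=lambda x, y: x["el"] == y["el"],
                edge_match=lambda x, y: x["order"] == y["order"],
            )
            if gm.subgraph_is_isomorphic():
                return size
    return 0
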