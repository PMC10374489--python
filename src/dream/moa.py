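"""Mechanism-of-action distance between drug perturbational networks.

The Hamming-Ipsen-Mikhailov (HIM) distance combines a local term H (mean
absolute adjacency difference over node pairs) with a global spectral term
IM (L2 distance between Lorentzian-broadened spectral densities of the two
graph Laplacians):

    H  = sum_{i<j} |a_ij - b_ij| / C(N, 2)
    rho_G(omega) = K * sum_{i=2}^{N} gamma / ((omega - omega_i)^2 + gamma^2),
                   omega_i = sqrt(lambda_i),  L = D - W
    IM = sqrt( integral_0^inf (rho_A - rho_B)^2 domega )
    HIM = sqrt(H^2 + xi * IM^2) / sqrt(1 + xi)

The Lorentzian width ``gamma`` is calibrated per node count N so that the
empty/complete graph pair sits at IM = 1, which bounds all three terms in
[0, 1].  Networks over different gene sets are aligned on the union of their
nodes, padding each with isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

from dream.dataio import DistanceMatrix, DrugRecord, GeneNetwork

QUAD_EPSABS = 1e-8
GAMMA_BRACKET = (1e-4, 10.0)
GAMMA_XTOL = 1e-10


@dataclass
class AlignedGraphPair:
    """Two adjacency matrices over one canonical node ordering."""

    nodes: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for m in (self.a, self.b):
            if m.shape != (n, n):
                raise ValueError("adjacency shape does not match node universe")
            if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
                raise ValueError("adjacencies must be symmetric with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.nodes)


def align_graphs(g1: GeneNetwork, g2: GeneNetwork, binarize: bool = False) -> AlignedGraphPair:
    """Embed both graphs over the union of their node sets.

    Nodes absent from one graph become isolated in it, so perturbational
    networks inferred over different gene universes stay comparable.
    """
    nodes = sorted(set(g1.graph.nodes) | set(g2.graph.nodes))
    if not nodes:
        raise ValueError("both graphs are empty")
    a = g1.adjacency(nodes)
    b = g2.adjacency(nodes)
    if binarize:
        a = (a > 0).astype(float)
        b = (b > 0).astype(float)
    return AlignedGraphPair(nodes, a, b)


def hamming(p: AlignedGraphPair) -> float:
    """Normalized edge-difference distance in [0, 1]."""
    n = p.n
    if n < 2:
        raise ValueError("need at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(np.abs(p.a - p.b)[iu].sum() / (n * (n - 1) / 2.0))


def laplacian_frequencies(adjacency: np.ndarray) -> np.ndarray:
    """Vibrational frequencies omega_i = sqrt(lambda_i), i = 2..N.

    Eigenvalues of L = D - W; the trivial lambda_1 = 0 mode is dropped and
    tiny negative eigenvalues from roundoff are clipped to zero.
    """
    lap = np.diag(adjacency.sum(axis=1)) - adjacency
    lam = np.linalg.eigvalsh(lap)
    if lam[0] < -1e-9:
        raise ValueError(f"Laplacian produced eigenvalue {lam[0]} < 0")
    return np.sqrt(np.clip(lam[1:], 0.0, None))


def _lorentzian_density(omegas: np.ndarray, gamma: float):
    """Normalized spectral density rho(omega) on [0, inf) and its constant K.

    Each frequency contributes a Lorentzian of half-width gamma; K uses the
    closed form integral of a Lorentzian on [0, inf),
    pi/2 + arctan(omega_i / gamma).
    """
    k = 1.0 / float(np.sum(np.pi / 2.0 + np.arctan(omegas / gamma)))

    def rho(omega):
        omega = np.asarray(omega, dtype=float)
        return k * np.sum(
            gamma / ((omega[..., None] - omegas) ** 2 + gamma**2), axis=-1
        )

    return rho, k


def ipsen_mikhailov(p: AlignedGraphPair, gamma: float | None = None) -> float:
    """Spectral IM distance; ``gamma`` defaults to the calibrated width for N."""
    if p.n < 2:
        raise ValueError("need at least 2 nodes")
    if gamma is None:
        gamma = find_gamma(p.n)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    wa = laplacian_frequencies(p.a)
    wb = laplacian_frequencies(p.b)
    return _im_from_frequencies(wa, wb, gamma)


def _im_from_frequencies(wa: np.ndarray, wb: np.ndarray, gamma: float) -> float:
    rho_a, _ = _lorentzian_density(wa, gamma)
    rho_b, _ = _lorentzian_density(wb, gamma)
    upper = float(max(wa.max(initial=0.0), wb.max(initial=0.0)) + 20.0 * gamma)
    val, _err = integrate.quad(
        lambda w: (rho_a(w) - rho_b(w)) ** 2, 0.0, upper, epsabs=QUAD_EPSABS, limit=200
    )
    return float(np.sqrt(max(val, 0.0)))


@lru_cache(maxsize=None)
def find_gamma(n: int) -> float:
    """Lorentzian width making IM(empty_n, complete_n) = 1, by bisection.

    The empty graph has all frequencies at 0 and the unweighted complete
    graph has N-1 frequencies at sqrt(N); IM between them decreases
    monotonically in gamma, so the unit-distance width is unique.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    w_empty = np.zeros(n - 1)
    w_complete = np.full(n - 1, np.sqrt(n))

    def objective(gamma: float) -> float:
        return _im_from_frequencies(w_empty, w_complete, gamma) - 1.0

    lo, hi = GAMMA_BRACKET
    return float(optimize.brentq(objective, lo, hi, xtol=GAMMA_XTOL))


def him(p: AlignedGraphPair, xi: float = 1.0, gamma: float | None = None) -> float:
    """Combined HIM distance, normalized to [0, 1] for any mixing xi >= 0."""
    if xi < 0:
        raise ValueError("xi must be >= 0")
    h = hamming(p)
    im = ipsen_mikhailov(p, gamma=gamma)
    return float(np.sqrt(h**2 + xi * im**2) / np.sqrt(1.0 + xi))


def moa_matrix(
    drugs: Sequence[DrugRecord], xi: float = 1.0, binarize: bool = False
) -> DistanceMatrix:
    """Pairwise HIM distance matrix over a drug library.

    Every drug must carry a perturbational network; pairs are computed
    independently (order-invariant) with gamma cached per aligned size N.
    """
    missing = [d.drug_id for d in drugs if d.perturbational_network is None]
    if missing:
        raise ValueError(f"drugs without perturbational networks: {missing}")
    ids = [d.drug_id for d in drugs]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = align_graphs(
                drugs[i].perturbational_network,
                drugs[j].perturbational_network,
                binarize=binarize,
            )
            values[i, j] = values[j, i] = him(pair, xi=xi)
    return DistanceMatrix(ids, values)
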