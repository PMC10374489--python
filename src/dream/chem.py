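"""Chemo-structural drug comparison.

Three views of structural similarity between small molecules:

* ECFP (Morgan circular) fingerprints compared by Tanimoto similarity;
* maximal common connected substructure (MCS) under atom element+aromaticity
  and bond-order matching, with similarity mcs / (a1 + a2 - mcs);
* Levenshtein edit distance between canonical SMILES strings.

All comparisons canonicalize SMILES first, so results are invariant to how
the input molecule happened to be written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFMCS, rdFingerprintGenerator

from dream.dataio import DistanceMatrix, DrugRecord

RDLogger.DisableLog("rdApp.error")
logger = logging.getLogger("dream.chem")


@dataclass(frozen=True)
class Fingerprint:
    """Folded circular fingerprint: the set of on-bit positions."""

    drug_id: str
    bits: frozenset[int]
    n_bits: int
    radius: int

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit positions out of range")


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES form; idempotent, errors on parse failure."""
    return Chem.MolToSmiles(_mol(smiles))


def ecfp(smiles: str, radius: int = 2, n_bits: int = 1024, drug_id: str = "") -> Fingerprint:
    """Morgan circular fingerprint folded to ``n_bits`` (radius 2 = ECFP4)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    mol = _mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(drug_id=drug_id, bits=frozenset(bv.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(fp1: Fingerprint, fp2: Fingerprint) -> float:
    """Jaccard similarity of the two bit sets; 1.0 when both are empty."""
    if fp1.n_bits != fp2.n_bits:
        raise ValueError(f"fingerprint lengths differ: {fp1.n_bits} vs {fp2.n_bits}")
    union = fp1.bits | fp2.bits
    if not union:
        logger.warning("both fingerprints empty; similarity 1.0 by convention")
        return 1.0
    return len(fp1.bits & fp2.bits) / len(union)


@dataclass(frozen=True)
class McsResult:
    atom_count: int
    bond_count: int
    similarity: float
    approximate: bool = False  # hit the timeout; best result so far


def mcs(smiles1: str, smiles2: str, timeout_s: int = 10) -> McsResult:
    """Maximal common connected substructure of two molecules.

    Atoms match by element (aromatic vs aliphatic distinguished via bond
    matching), bonds by order; similarity is the atom-count overlap
    coefficient mcs / (a1 + a2 - mcs).  A search that hits the timeout is
    flagged approximate.
    """
    m1, m2 = _mol(smiles1), _mol(smiles2)
    res = rdFMCS.FindMCS(
        [m1, m2],
        timeout=timeout_s,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        matchValences=False,
    )
    a1, a2 = m1.GetNumAtoms(), m2.GetNumAtoms()
    n = res.numAtoms
    sim = n / (a1 + a2 - n) if (a1 + a2 - n) > 0 else 1.0
    return McsResult(n, res.numBonds, float(sim), approximate=bool(res.canceled))


def levenshtein(s1: str, s2: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute) on raw strings."""
    if not s1 or not s2:
        return max(len(s1), len(s2)) if (s1 or s2) else 0
    return int(edlib.align(s1, s2, task="distance")["editDistance"])


def smiles_levenshtein(smiles1: str, smiles2: str, normalize: bool = True) -> float:
    """Edit distance between CANONICAL SMILES of the two molecules.

    Canonicalization first makes the string distance a property of the
    molecules rather than of their arbitrary input encodings.  When
    ``normalize``, the distance is divided by the longer canonical string.
    """
    c1, c2 = canonical_smiles(smiles1), canonical_smiles(smiles2)
    d = levenshtein(c1, c2)
    if not normalize:
        return float(d)
    longest = max(len(c1), len(c2))
    return d / longest if longest else 0.0


def chem_matrices(
    drugs: Sequence[DrugRecord], radius: int = 2, n_bits: int = 1024, timeout_s: int = 10
) -> dict[str, DistanceMatrix]:
    """All three pairwise chemical distance matrices for a drug library.

    Drugs without a usable SMILES are excluded (logged).  Similarities are
    reported as distances 1 - s; Levenshtein is length-normalized.
    """
    usable = [d for d in drugs if d.smiles is not None]
    skipped = [d.drug_id for d in drugs if d.smiles is None]
    if skipped:
        logger.warning("excluded %d drug(s) without SMILES: %s", len(skipped), skipped)
    if len(usable) < 2:
        raise ValueError("need at least 2 drugs with valid SMILES")
    ids = [d.drug_id for d in usable]
    canon = [canonical_smiles(d.smiles) for d in usable]
    fps = [ecfp(c, radius=radius, n_bits=n_bits, drug_id=i) for c, i in zip(canon, ids)]
    n = len(ids)
    tani = np.zeros((n, n))
    mcs_d = np.zeros((n, n))
    lev = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tani[i, j] = tani[j, i] = 1.0 - tanimoto(fps[i], fps[j])
            mcs_d[i, j] = mcs_d[j, i] = 1.0 - mcs(canon[i], canon[j], timeout_s).similarity
            lev[i, j] = lev[j, i] = smiles_levenshtein(canon[i], canon[j])
    return {
        "tanimoto": DistanceMatrix(ids, tani),
        "mcs": DistanceMatrix(ids, mcs_d),
        "levenshtein": DistanceMatrix(ids, lev),
    }
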