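import numpy as np
import pytest

from dream import chem, fixtures as fx, ga, moa
from dream.dataio import GeneNetwork


@pytest.fixture(scope="session")
def star_net() -> GeneNetwork:
    """5-node star: center X with leaves L1..L4."""
    return GeneNetwork.from_edges([("X", f"L{i}") for i in range(1, 5)])


@pytest.fixture(scope="session")
def path_net() -> GeneNetwork:
    """4-node path A-B-C-D."""
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture(scope="session")
def ga_library():
    """10-drug synthetic library with all precomputed GA inputs.

    Built once per session: expression fixture -> connected disease network
    -> drug library with rewired perturbational networks -> MOA and chemical
    distance matrices.
    """
    spec = fx.SyntheticSpec(seed=1)
    _, truth = fx.make_expression(spec)
    net = fx.disease_network(truth)
    drugs = fx.make_drug_library(10, net, seed=1)
    moa_m = moa.moa_matrix(drugs)
    chem_m = chem.chem_matrices(drugs)["tanimoto"]
    pre = ga.Precomputed(drugs, moa_m, chem_m, net)
    return {"drugs": drugs, "net": net, "moa": moa_m, "chem": chem_m, "pre": pre}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
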