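import numpy as np
import pytest

from dtlrec.ccp import build_ccp
from dtlrec.dtlmodel import DTLRates
from dtlrec.simulate import SimulationConfig, simulate_dataset
from dtlrec.treeio import index_species_tree, parse_newick

NWK8 = "(((S1:1,S2:1):1,(S3:1,S4:1):1):1,((S5:1,S6:1):1,(S7:1,S8:1):1):1);"
NWK16 = (
    "((((S1:1,S2:1):1,(S3:1,S4:1):1):1,((S5:1,S6:1):1,(S7:1,S8:1):1):1):1,"
    "(((S9:1,S10:1):1,(S11:1,S12:1):1):1,((S13:1,S14:1):1,(S15:1,S16:1):1):1):1);"
)


@pytest.fixture(scope="session")
def st2():
    return index_species_tree(parse_newick("(A,B);"))


@pytest.fixture(scope="session")
def st3():
    return index_species_tree(parse_newick("((A,B),C);"))


@pytest.fixture(scope="session")
def st8():
    return index_species_tree(parse_newick(NWK8))


@pytest.fixture(scope="session")
def st16():
    return index_species_tree(parse_newick(NWK16))


@pytest.fixture(scope="session")
def sim8(st8):
    """Small simulated dataset on the 8-leaf tree, shared across tests."""
    cfg = SimulationConfig(
        rates=DTLRates(0.05, 0.3, 0.1), seed=123, min_copies=2, max_copies=40
    )
    ds = simulate_dataset(st8, 20, cfg)
    ccps = [build_ccp([f.gene_tree], leaf_map=f.leaf_map) for f in ds.families]
    return ds, ccps


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
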