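import warnings

import numpy as np
import pytest

import barcodelim as bl
from barcodelim.alignment import alignment_from_dict


@pytest.fixture(autouse=True)
def _quiet_rescale_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="coalescent of species", category=UserWarning)
        yield


@pytest.fixture
def quartet_alignment():
    return alignment_from_dict({
        "a": "ACGTACGTAA",
        "b": "ACCTACGTAA",
        "c": "AGGTATGTCA",
        "d": "ATGTATGACA",
    })


@pytest.fixture
def gtr_ig_model():
    return bl.SubstitutionModel.gtr(
        [0.3, 0.2, 0.25, 0.25], [1.5, 4.0, 0.7, 1.2, 6.0, 1.0],
        p_inv=0.3, alpha=0.5)


@pytest.fixture
def eight_taxon_tree():
    tree = bl.simulate_yule_tree(8, 1.0, 42)
    for nd in tree.preorder_node_iter():
        if nd.edge.length:
            nd.edge.length *= 0.4
    return tree


def random_sequences(n, length, seed):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return bl.Alignment([f"t{i}" for i in range(n)],
                        bases[rng.integers(0, 4, size=(n, length))])
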