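"""Shared fixtures: small alignments and trees built in memory."""

import numpy as np
import pytest

from lbalens.alignment import Alignment
from lbalens.io import parse_tree


@pytest.fixture
def aln4():
    """Four taxa, six columns: constant, variable and informative sites."""
    return Alignment.from_dict({
        "a": "ACGTAC",
        "b": "ACGTAA",
        "c": "ACGAAC",
        "d": "ACGAAA",
    })


@pytest.fixture
def gapped():
    return Alignment.from_dict({
        "a": "AC-TAC",
        "b": "ACGTAN",
        "c": "ACGAAC",
        "d": "AC-AAA",
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, n_taxa, n_cols, alphabet="ACGT"):
    lookup = np.array(list(alphabet))
    mat = lookup[rng.integers(0, len(alphabet), (n_taxa, n_cols))]
    return Alignment([f"t{i}" for i in range(n_taxa)], mat)


def quartet_tree_newick(p, q):
    return parse_tree(f"((A:{p},B:{q}):{q},C:{p},D:{q});")
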