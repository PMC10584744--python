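import numpy as np
import pytest

from chlorophylo import models, synthetic as sy
from chlorophylo.alignment_ops import Alignment
from chlorophylo.seq_data import MarkerDataset, MarkerSequence


@pytest.fixture
def toy_dataset():
    """Six sequences, three species, two genera, two markers."""
    seqs = [
        MarkerSequence("A1", "Chlorella vulgaris", "Chlorella", "18S", "ACGTACGT"),
        MarkerSequence("A2", "Chlorella sorokiniana", "Chlorella", "18S", "ACGTACGA"),
        MarkerSequence("A3", "Parachlorella kessleri", "Parachlorella", "18S", "ACGTTCGA"),
        MarkerSequence("B1", "Chlorella vulgaris", "Chlorella", "ITS", "GGCCGGCC"),
        MarkerSequence("B2", "Chlorella sorokiniana", "Chlorella", "ITS", "GGCCGGCA"),
        MarkerSequence("B3", "Parachlorella kessleri", "Parachlorella", "ITS", "GGCAGGCA"),
    ]
    return MarkerDataset(sequences=seqs, markers=["18S", "ITS"])


@pytest.fixture(scope="session")
def jc_model():
    return models.SubstitutionModel(family="JC")


@pytest.fixture(scope="session")
def six_taxon_sim(jc_model):
    """Tree + strong-signal JC alignment used by several inference tests."""
    tree = sy.simulate_species_tree(6, seed=1, height=0.3)
    aln = sy.simulate_alignment(tree, jc_model, 5000, seed=2)
    return tree, aln


def random_unrooted_tree(labels, rng):
    """Uniform-ish random binary unrooted topology by sequential attachment."""
    from chlorophylo.trees import Node, Tree
    labels = list(labels)
    root = Node()
    for lab in labels[:3]:
        root.add(Node(label=lab, length=rng.uniform(0.05, 0.3)))
    edges = list(root.children)
    for lab in labels[3:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node(length=rng.uniform(0.05, 0.3))
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        leaf = Node(label=lab, length=rng.uniform(0.05, 0.3))
        mid.add(leaf)
        edges.extend([mid, leaf])
    return Tree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
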