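import numpy as np
import pytest

from kinevo.io_formats import AlignedKinaseSet, SequenceLabels, parse_tree


@pytest.fixture
def three_leaf_tree():
    return parse_tree("((A:0.2,B:0.4)X:0.3,C:0.5)R;")


@pytest.fixture
def six_leaf_tree():
    return parse_tree(
        "(((A:1,B:1)X:1,(C:1,D:1)Y:1)Z:1,(E:1,F:1)W:1)R;")


def make_alignment(rows, families=None, column_map=None):
    """Build a labelled AlignedKinaseSet from {identifier: sequence}."""
    sequences = list(rows.items())
    labels = {}
    for ident, _ in sequences:
        fam = (families or {}).get(ident, "FAM")
        labels[ident] = SequenceLabels(species="sp", group="GRP", family=fam)
    if column_map is None:
        L = len(sequences[0][1])
        column_map = {c: c + 1 for c in range(L)}
    return AlignedKinaseSet(sequences, labels, column_map)


@pytest.fixture
def make_aln():
    return make_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
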