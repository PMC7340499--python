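import numpy as np
import pytest

from ca1quant.morphology import COMPARTMENT_CODES, NeuronMorphology


def build_neuron(nodes, metadata=None):
    """Hand-build a reconstruction from (x, y, z, compartment, parent) tuples.

    Parent indices are 0-based (-1 = root); compartments are names.
    """
    xyz = np.array([[n[0], n[1], n[2]] for n in nodes], dtype=float)
    comp = np.array([COMPARTMENT_CODES[n[3]] for n in nodes])
    parent = np.array([n[4] for n in nodes])
    return NeuronMorphology(
        xyz=xyz,
        radius=np.ones(len(nodes)),
        compartment=comp,
        parent=parent,
        metadata=metadata or {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def y_tree():
    """Soma + trunk splitting at y=150 into two 200-um daughters."""
    nodes = [(0, 0, 0, "soma", -1)]
    parent = 0
    for y in (50, 100, 150):
        nodes.append((0, y, 0, "apical", parent))
        parent = len(nodes) - 1
    split = parent
    for dx in (1.0, -1.0):
        parent = split
        for k in range(1, 5):
            nodes.append((dx * 30 * k, 150 + 40 * k, 0, "apical", parent))
            parent = len(nodes) - 1
    return build_neuron(nodes)


@pytest.fixture
def index_tree():
    """Trunk of 100 um, balanced split, each daughter 100 um with 2 internal
    bifurcations: Lp=100, Ld1=Ld2=100, Nd1=Nd2=2, Np=0."""
    nodes = [
        (0, 0, 0, "soma", -1),
        (0, 50, 0, "apical", 0),
        (0, 100, 0, "apical", 1),       # selected bifurcation, Lp = 100
    ]

    def add_daughter(sign):
        b = 2
        i1 = len(nodes)
        nodes.append((sign * 20, 100, 0, "apical", b))          # 20, bif
        nodes.append((sign * 20, 120, 0, "apical", i1))         # 20, bif
        nodes.append((sign * 40, 100, 0, "apical", i1))         # 20 tip
        nodes.append((sign * 20, 140, 0, "apical", i1 + 1))     # 20 tip
        nodes.append((sign * 40, 120, 0, "apical", i1 + 1))     # 20 tip

    add_daughter(+1)
    add_daughter(-1)
    return build_neuron(nodes)
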