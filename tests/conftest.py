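import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ptmnet.pin import InteractionNetwork
from ptmnet.ptm_data import PTMRecord


def make_net(edges, species=9606, label="test"):
    g = nx.Graph()
    for e in edges:
        if len(e) == 2:
            u, v = e
            conf = 1.0
        else:
            u, v, conf = e
        g.add_edge(u, v, confidence=conf)
    return InteractionNetwork(g, species, label)


@pytest.fixture
def triangle_net():
    return make_net([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3_net():
    return make_net([("A", "B"), ("B", "C")])


def rec(protein, position, ptm_type, species=9606, source="db1", **kw):
    return PTMRecord(
        species=species,
        protein_id=protein,
        position=position,
        ptm_type=ptm_type,
        sources=(source,),
        **kw,
    )
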