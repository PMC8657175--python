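import pandas as pd
import pytest

from rcrnet.bel import BackboneGraph, SignedEdge
from rcrnet.contextualize import KnockdownDataset, TranscriptLayer, TwoLayerNetwork
from rcrnet.resources import load_backbone


@pytest.fixture(scope="session")
def curated_backbone() -> BackboneGraph:
    """The packaged curated functional layer (keep_direct conflict policy)."""
    return load_backbone()


def make_backbone(edges, roles=None) -> BackboneGraph:
    """Backbone from (source, target, sign[, direct]) tuples."""
    bg = BackboneGraph()
    for e in edges:
        src, dst, sign = e[0], e[1], e[2]
        direct = e[3] if len(e) > 3 else False
        bg.add_edge(SignedEdge(source=src, target=dst, sign=sign, direct=direct,
                               evidence=("test",)))
    if roles:
        for n, r in roles.items():
            bg.g.nodes[n]["role"] = r
    return bg


def make_net(edges, terminal) -> TwoLayerNetwork:
    """Two-layer network from edge tuples and {node: {gene: sign}}."""
    bg = make_backbone(edges)
    for n in terminal:
        if n not in bg:
            bg.add_node(n)
    sets = {n: dict(terminal.get(n, {})) for n in bg.nodes}
    return TwoLayerNetwork(backbone=bg, terminal=TranscriptLayer(sets=sets))


def make_kd(target, rows) -> KnockdownDataset:
    """Knockdown table from (gene, log2fc, pvalue) tuples."""
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"])
    return KnockdownDataset(target=target, records=df)


@pytest.fixture
def chain_net() -> TwoLayerNetwork:
    """a -> b (+1) -> c (-1), one 3-gene terminal set per node."""
    terminal = {
        "A": {"gA1": +1, "gA2": +1, "gA3": -1},
        "B": {"gB1": +1, "gB2": -1, "gB3": +1},
        "C": {"gC1": -1, "gC2": +1, "gC3": +1},
    }
    return make_net([("A", "B", +1), ("B", "C", -1)], terminal)
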