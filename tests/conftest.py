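import pytest

from toposig.network_model import Edge, Effect, InteractionNetwork, InteractionType

T = InteractionType
E = Effect


def build_net(*edges: tuple, extra_nodes: set[str] = frozenset()) -> InteractionNetwork:
    """Build a network from (source, target[, type[, effect[, trust]]]) tuples."""
    out = []
    for e in edges:
        src, dst = e[0], e[1]
        etype = e[2] if len(e) > 2 else T.other
        eff = e[3] if len(e) > 3 else E.unspecified
        trust = e[4] if len(e) > 4 else 1
        out.append(Edge(src, dst, etype, eff, trust))
    nodes = {x.source for x in out} | {x.target for x in out} | set(extra_nodes)
    return InteractionNetwork(nodes=nodes, edges=out)


@pytest.fixture
def chain_net():
    """a -> b -> c over generic edges."""
    return build_net(("A", "B"), ("B", "C"))
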