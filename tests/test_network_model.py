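"""Network, DE-set and gene-set ingest: dialects, normalization, invariants."""

import pytest
from hypothesis import given, settings, strategies as st

from toposig.network_model import (
    DifferentialSetError,
    Edge,
    Effect,
    GeneSetError,
    InteractionNetwork,
    InteractionType,
    NetworkParseError,
    differential_set_from_ratios,
    filter_by_interaction_type,
    normalize_id,
    read_differential_set,
    read_gmt,
    read_network,
    write_network,
)

from conftest import build_net

T = InteractionType


# ---------------------------------------------------------------------------
# edge_tsv / SIF parsing
# ---------------------------------------------------------------------------

def test_edge_tsv_three_distinct_edges(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text(
        "# comment\n"
        "a\tbinding\tb\tactivation\t1\n"
        "b\tphosphorylation\tc\tinhibition\t2\n"
        "a\ttranscriptional_regulation\tc\tunspecified\t1\n"
    )
    net = read_network(p)
    assert len(net.edges) == 3
    assert net.nodes == {"A", "B", "C"}


def test_duplicate_edge_keeps_max_trust(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text(
        "a\tbinding\tb\tactivation\t1\n"
        "a\tbinding\tb\tactivation\t2\n"
    )
    net = read_network(p)
    assert len(net.edges) == 1
    assert net.edges[0].trust == 2


def test_wrong_field_count_names_line(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("a\tb\n")
    with pytest.raises(NetworkParseError, match="line 1: expected 5 fields"):
        read_network(p)


def test_unknown_interaction_type_lists_tokens(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("a\tmagic\tb\n")
    with pytest.raises(NetworkParseError) as exc:
        read_network(p)
    assert "binding" in str(exc.value) and "line 1" in str(exc.value)


def test_self_loops_dropped(tmp_path, caplog):
    p = tmp_path / "net.tsv"
    p.write_text("a\tbinding\ta\na\tbinding\tb\n")
    with caplog.at_level("WARNING"):
        net = read_network(p)
    assert len(net.edges) == 1
    assert "self-loop" in caplog.text


def test_sif_one_to_many(tmp_path):
    p = tmp_path / "net.sif"
    p.write_text("a\tbinding\tb\tc\td\n")
    net = read_network(p, format="sif")
    assert len(net.edges) == 3
    assert all(e.source == "A" for e in net.edges)
    assert all(e.trust == 1 and e.effect is Effect.unspecified for e in net.edges)


@st.composite
def small_networks(draw):
    names = [f"N{i}" for i in range(8)]
    n_edges = draw(st.integers(1, 12))
    edges = {}
    for _ in range(n_edges):
        s, t = draw(st.sampled_from(names)), draw(st.sampled_from(names))
        if s == t:
            continue
        etype = draw(st.sampled_from(list(InteractionType)))
        eff = draw(st.sampled_from(list(Effect)))
        trust = draw(st.integers(0, 5))
        edges[(s, t, etype)] = Edge(s, t, etype, eff, trust)
    if not edges:
        edges[("N0", "N1", T.binding)] = Edge("N0", "N1", T.binding)
    es = list(edges.values())
    nodes = {e.source for e in es} | {e.target for e in es}
    return InteractionNetwork(nodes=nodes, edges=es)


@settings(max_examples=50, derandomize=True)
@given(small_networks())
def test_edge_tsv_round_trip(tmp_path_factory, net):
    """write -> read preserves the edge multiset with all attributes."""
    p = tmp_path_factory.mktemp("rt") / "net.tsv"
    write_network(net, p)
    again = read_network(p)
    assert set(again.edges) == set(net.edges)
    assert again.nodes == net.nodes


@settings(max_examples=30, derandomize=True)
@given(small_networks())
def test_sif_round_trip_preserves_topology(tmp_path_factory, net):
    """SIF carries no effect/trust; topology and types survive a round trip."""
    p = tmp_path_factory.mktemp("rt") / "net.sif"
    write_network(net, p, format="sif")
    again = read_network(p, format="sif")
    assert {(e.source, e.target, e.interaction_type) for e in again.edges} == \
        {(e.source, e.target, e.interaction_type) for e in net.edges}


# ---------------------------------------------------------------------------
# interaction-type filtering
# ---------------------------------------------------------------------------

def test_filter_by_type_counts():
    net = build_net(
        ("A", "B", T.transcriptional_regulation),
        ("A", "C", T.transcriptional_regulation),
        ("C", "D", T.binding), ("D", "E", T.binding), ("E", "F", T.binding),
    )
    assert len(filter_by_interaction_type(net, {T.transcriptional_regulation}).edges) == 2
    assert len(filter_by_interaction_type(net, set(T)).edges) == 5
    empty = filter_by_interaction_type(net, {T.phosphorylation})
    assert not empty.edges and not empty.nodes


@settings(max_examples=40, derandomize=True)
@given(small_networks(),
       st.sets(st.sampled_from(list(InteractionType)), min_size=1),
       st.sets(st.sampled_from(list(InteractionType)), min_size=1))
def test_filter_idempotent_and_commutes(net, types_a, types_b):
    once = filter_by_interaction_type(net, types_a)
    twice = filter_by_interaction_type(once, types_a)
    assert set(once.edges) == set(twice.edges)
    ab = filter_by_interaction_type(filter_by_interaction_type(net, types_a), types_b)
    both = filter_by_interaction_type(net, types_a & types_b) \
        if types_a & types_b else None
    if both is not None:
        assert set(ab.edges) == set(both.edges)
    else:
        assert not ab.edges


# ---------------------------------------------------------------------------
# differential sets
# ---------------------------------------------------------------------------

def test_ratio_thresholds_are_inclusive(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text("id\tratio\na\t1.2\nb\t0.83\nc\t1.0\n")
    ds = read_differential_set(p)
    assert ds.de_up == {"A"}
    assert ds.de_down == {"B"}
    assert ds.universe == {"A", "B", "C"}


def test_direction_table(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text("id\tdirection\na\tup\nb\tnone\n")
    ds = read_differential_set(p)
    assert ds.de_up == {"A"} and not ds.de_down


def test_contradictory_directions_rejected(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text("id\tdirection\na\tup\na\tdown\n")
    with pytest.raises(DifferentialSetError, match="contradictory"):
        read_differential_set(p)


def test_non_numeric_ratio_rejected(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text("id\tratio\na\thigh\n")
    with pytest.raises(DifferentialSetError, match="ratio"):
        read_differential_set(p)


@settings(max_examples=50, derandomize=True)
@given(st.dictionaries(
    st.sampled_from([f"G{i}" for i in range(20)]),
    st.one_of(st.floats(0.3, 0.82), st.floats(0.84, 1.19), st.floats(1.2, 3.0)),
    min_size=1, max_size=15,
))
def test_ratio_and_direction_tables_equivalent(tmp_path_factory, ratios):
    """A ratio table and its pre-flagged direction table yield the same set."""
    ds_ratio = differential_set_from_ratios(ratios)
    d = tmp_path_factory.mktemp("de")
    lines = ["id\tdirection"]
    for ident, r in ratios.items():
        direction = "up" if r >= 1.2 else ("down" if r <= 0.83 else "none")
        lines.append(f"{ident}\t{direction}")
    p = d / "de.tsv"
    p.write_text("\n".join(lines) + "\n")
    ds_dir = read_differential_set(p)
    assert ds_dir.universe == ds_ratio.universe
    assert ds_dir.de_up == ds_ratio.de_up
    assert ds_dir.de_down == ds_ratio.de_down


def test_de_invariants_enforced():
    from toposig.network_model import DifferentialSet
    with pytest.raises(DifferentialSetError):
        DifferentialSet(universe={"A"}, de_up={"B"}, de_down=set())
    with pytest.raises(DifferentialSetError):
        DifferentialSet(universe={"A"}, de_up={"A"}, de_down={"A"})


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def test_gmt_read_counts(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("S1\tfirst\ta\tb\tc\nS2\tsecond\td\te\tf\tg\th\n")
    gsc = read_gmt(p)
    assert len(gsc) == 2
    assert len(gsc.members("S1")) == 3 and len(gsc.members("S2")) == 5


def test_gmt_rejects_empty_and_duplicate(tmp_path):
    p = tmp_path / "bad.gmt"
    p.write_text("S1\tdesc\n")
    with pytest.raises(GeneSetError):
        read_gmt(p)
    p.write_text("S1\tdesc\ta\nS1\tdesc\tb\n")
    with pytest.raises(GeneSetError, match="duplicate"):
        read_gmt(p)


def test_gmt_members_normalized(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("S1\tdesc\tTP53\ttp53\n")
    assert read_gmt(p).members("S1") == {"TP53"}


def test_normalize_id():
    assert normalize_id("  tp53 ") == "TP53"
    with pytest.raises(ValueError):
        normalize_id("   ")
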