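"""BEL label parsing, annotation, consistency filtering, subgraph extraction."""

from collections import deque

import numpy as np
import pytest

from xenotx import (
    AnnotatedGraph,
    CausalGraph,
    annotate,
    consistency_filter,
    extract_subgraph,
    parse_bel_label,
    simulate_causal_graph,
)
from xenotx.network import BelParseError, CONSISTENT, INCONSISTENT, UNDETERMINED


def test_parse_bel_labels():
    t = parse_bel_label("act(p(MGI:Tlr2))")
    assert (t.function, t.namespace, t.entity) == ("act", "MGI", "Tlr2")
    t = parse_bel_label("bp(PMIBP:wound healing)")
    assert (t.function, t.namespace, t.entity) == ("bp", "PMIBP", "wound healing")
    t = parse_bel_label("p(MGI:Vdr)")
    assert (t.function, t.namespace, t.entity) == ("p", "MGI", "Vdr")
    # unknown outer function is preserved with a pass-through flag
    t = parse_bel_label("frobnicate(MGI:X)")
    assert t.passthrough and t.function == "frobnicate"


def test_parse_bel_errors():
    with pytest.raises(BelParseError) as exc:
        parse_bel_label("p(MGI:Vdr")
    assert exc.value.offset == 10
    with pytest.raises(BelParseError):
        parse_bel_label("p(MGI:Vdr))")
    with pytest.raises(ValueError):
        parse_bel_label("   ")


def test_graph_construction_rules():
    g = CausalGraph(edges=[("a", 1, "b"), ("a", 1, "b")])  # exact duplicate collapses
    assert g.n_edges() == 1
    g.add_edge("a", -1, "b")  # opposite sign allowed but flagged
    assert g.n_edges() == 2 and g.conflicting_pairs == [("a", "b")]
    with pytest.raises(ValueError, match="self-loop"):
        g.add_edge("a", 1, "a")
    with pytest.raises(ValueError, match="sign"):
        g.add_edge("a", 2, "c")


def test_annotate_empty_and_unmapped():
    g = CausalGraph(edges=[("a", 1, "b")])
    ann = annotate(g, {})
    assert ann.directions == {}
    assert all(s == UNDETERMINED for s in ann.edge_status.values())
    ann = annotate(g, {"a": 1, "ghost": -1})
    assert ann.directions == {"a": 1} and ann.unmapped_calls == ["ghost"]


def test_annotate_ambiguous_mapping_rejected():
    g = CausalGraph(edges=[("a", 1, "b")])

    class MultiMap(dict):
        def items(self):
            return [("c1", "a"), ("c1", "b")]

    with pytest.raises(ValueError, match="ambiguous"):
        annotate(g, {"c1": 1}, mapping=MultiMap())


@pytest.mark.parametrize("du", [1, -1])
@pytest.mark.parametrize("sign", [1, -1])
@pytest.mark.parametrize("dv", [1, -1])
def test_consistency_truth_table(du, sign, dv):
    """All 8 (dir(u), sign, dir(v)) cases match the alignment rule."""
    g = CausalGraph(edges=[("u", sign, "v")])
    ann = annotate(g, {"u": du, "v": dv})
    expected = CONSISTENT if du * sign == dv else INCONSISTENT
    assert ann.edge_status[("u", sign, "v")] == expected
    filtered = consistency_filter(ann)
    if expected == INCONSISTENT:
        assert filtered.graph.n_edges() == 0 and filtered.removed == [("u", sign, "v")]
    else:
        assert filtered.graph.edges() == [("u", sign, "v")]


def test_filter_idempotent_and_monotone():
    rng = np.random.default_rng(4)
    g = simulate_causal_graph(15, 0.4, seed=2)
    dirs = {n: int(rng.choice([1, -1, 0])) for n in g.nodes}
    dirs = {n: d for n, d in dirs.items() if d != 0}
    ann = annotate(g, dirs)
    once = consistency_filter(ann)
    twice = consistency_filter(once)
    assert once.graph.edges() == twice.graph.edges()
    assert once.removed == twice.removed
    assert once.graph.n_edges() <= g.n_edges()
    assert set(once.graph.nodes) == set(g.nodes)  # node set preserved
    # undetermined edges (an unmeasured endpoint) are retained
    for (u, s, v), st in once.edge_status.items():
        if u not in dirs or v not in dirs:
            assert st == UNDETERMINED


def test_relabel_commutes_with_filter():
    g = simulate_causal_graph(10, 0.5, seed=8)
    rng = np.random.default_rng(1)
    dirs = {n: int(rng.choice([1, -1])) for n in g.nodes[:6]}
    bij = {n: f"renamed::{n}" for n in g.nodes}
    a = consistency_filter(annotate(g, dirs)).graph.relabel(bij)
    b = consistency_filter(annotate(g.relabel(bij), {bij[n]: d for n, d in dirs.items()})).graph
    assert a.edges() == b.edges()


def bfs_oracle(graph: CausalGraph, anchors, radius):
    """Independent breadth-first search over the undirected edge list."""
    adj = {}
    for u, _, v in graph.edges():
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen = {a: 0 for a in anchors}
    q = deque(anchors)
    while q:
        u = q.popleft()
        if seen[u] == radius:
            continue
        for w in adj.get(u, ()):
            if w not in seen:
                seen[w] = seen[u] + 1
                q.append(w)
    return set(seen)


def test_extract_subgraph():
    g = simulate_causal_graph(12, 0.3, seed=5)
    ann = annotate(g, {})
    anchors = g.nodes[:2]
    # radius 0: exactly the anchors, no edges
    sub0 = extract_subgraph(ann, anchors, 0)
    assert sub0.nodes == sorted(anchors) and sub0.n_edges() == 0
    # radius 1 matches an independent BFS oracle
    sub1 = extract_subgraph(ann, anchors, 1)
    assert set(sub1.nodes) == bfs_oracle(g, anchors, 1)
    # huge radius reaches every node connected to an anchor
    sub = extract_subgraph(ann, anchors, 10_000)
    assert set(sub.nodes) == bfs_oracle(g, anchors, 10_000)
    with pytest.raises(ValueError, match="anchor"):
        extract_subgraph(ann, ["nope"], 1)


def test_subgraph_excludes_inconsistent_edges():
    g = CausalGraph(edges=[("a", 1, "b"), ("b", 1, "c")])
    ann = annotate(g, {"a": 1, "b": -1})  # a->b inconsistent; b->c undetermined
    sub = extract_subgraph(ann, ["a"], 5)
    assert ("a", 1, "b") not in sub.edges()
    assert ("b", 1, "c") in sub.edges()


def test_annotation_round_trip_through_generator():
    """Planted directions annotate a truth-consistent graph losslessly."""
    from xenotx import SimConfig, simulate_node_signatures_and_de
    from xenotx.simulate import consistent_graph_from_truth

    cfg = SimConfig(n_nodes=30, genes_per_node=5, n_genes_orth=200,
                    n_genes_private_hs=0, n_genes_private_mm=0,
                    n_samples_per_group=2, seed=13)
    _, _, _, truth = simulate_node_signatures_and_de(cfg)
    g = consistent_graph_from_truth(truth, edge_density=0.3, seed=13)
    planted = {n: a for n, a in truth.node_activity.items() if a != 0}
    ann = annotate(g, planted)
    assert ann.directions == planted
    # every edge between two planted nodes is consistent by construction
    filtered = consistency_filter(ann)
    assert filtered.removed == []
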