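"""Signed causal networks and causal-consistency filtering.

Nodes carry BEL-like functional labels — ``act(p(MGI:Tlr2))`` is the
activity of the mouse Tlr2 protein, ``bp(PMIBP:wound healing)`` a
biological process — and directed edges carry a sign: ``increases`` (+1)
or ``decreases`` (-1).  Significant inferred node directions are stamped
onto the graph; an edge u ->(s) v between two measured nodes is causally
consistent iff ``dir(u) * s == dir(v)``, and inconsistent edges are
removed (logged).  Edges touching unmeasured nodes stay, with status
``undetermined``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

__all__ = [
    "BelTerm",
    "parse_bel_label",
    "CausalGraph",
    "AnnotatedGraph",
    "annotate",
    "consistency_filter",
    "extract_subgraph",
]

KNOWN_FUNCTIONS = {"act", "p", "bp", "tloc", "complex", "path", "g", "r", "m", "deg", "kin"}


@dataclass(frozen=True)
class BelTerm:
    """Parsed BEL-like label: outermost function, namespace, entity name."""

    function: str
    namespace: str
    entity: str
    passthrough: bool = False  # unknown outer function preserved verbatim


class BelParseError(ValueError):
    def __init__(self, label: str, offset: int, message: str) -> None:
        self.offset = offset
        super().__init__(f"{message} in {label!r} at offset {offset}")


def parse_bel_label(label: str) -> BelTerm:
    """Parse a nested functional label like ``act(p(MGI:Tlr2))``.

    Returns the outermost function, the (innermost) namespace and the
    entity name.  Unknown outer functions are preserved verbatim with the
    ``passthrough`` flag.  Unbalanced parentheses raise ``BelParseError``
    naming the 1-based offset of the failure.
    """
    if not label or not label.strip():
        raise ValueError("empty BEL label")
    label = label.strip()
    depth = 0
    for i, ch in enumerate(label):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise BelParseError(label, i + 1, "unbalanced ')'")
    if depth != 0:
        raise BelParseError(label, len(label) + 1, "unclosed '('")

    # peel nested f(...) wrappers down to the namespace:entity core
    outer = None
    core = label
    while "(" in core and core.endswith(")"):
        fn, rest = core.split("(", 1)
        fn = fn.strip()
        if outer is None:
            outer = fn
        core = rest[:-1].strip()
    if outer is None:
        outer = ""
    if ":" in core:
        namespace, entity = core.split(":", 1)
    else:
        namespace, entity = "", core
    return BelTerm(
        function=outer,
        namespace=namespace.strip(),
        entity=entity.strip(),
        passthrough=bool(outer) and outer not in KNOWN_FUNCTIONS,
    )


class CausalGraph:
    """Directed signed graph over BEL-like node labels.

    Backed by a ``networkx.MultiDiGraph`` with an integer ``sign``
    attribute per edge.  Self-loops are rejected; parallel edges of
    opposite sign between one node pair are allowed but recorded in
    ``conflicting_pairs``.
    """

    def __init__(self, edges: Iterable[Tuple[str, int, str]] = (), nodes: Iterable[str] = ()):
        self.g = nx.MultiDiGraph()
        self.conflicting_pairs: List[Tuple[str, str]] = []
        for n in nodes:
            self.g.add_node(n)
        for src, sign, dst in edges:
            self.add_edge(src, sign, dst)

    def add_edge(self, src: str, sign: int, dst: str) -> None:
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +1/-1, got {sign}")
        if src == dst:
            raise ValueError(f"self-loop on {src!r} not allowed")
        if self.g.has_edge(src, dst):
            signs = {d["sign"] for d in self.g[src][dst].values()}
            if sign in signs:
                return  # exact duplicate, ignore
            self.conflicting_pairs.append((src, dst))
        self.g.add_edge(src, dst, sign=sign)

    @property
    def nodes(self) -> List[str]:
        return sorted(self.g.nodes)

    def edges(self) -> List[Tuple[str, int, str]]:
        return sorted((u, d["sign"], v) for u, v, d in self.g.edges(data=True))

    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def relabel(self, mapping: Mapping[str, str]) -> "CausalGraph":
        return CausalGraph(
            edges=[(mapping.get(u, u), s, mapping.get(v, v)) for u, s, v in self.edges()],
            nodes=[mapping.get(n, n) for n in self.nodes],
        )


CONSISTENT, INCONSISTENT, UNDETERMINED = "consistent", "inconsistent", "undetermined"


@dataclass
class AnnotatedGraph:
    """A causal graph with inferred node directions and edge statuses.

    ``directions`` maps node label -> +1/-1 for measured significant
    nodes; absent nodes are unmeasured.  ``edge_status`` maps each
    (u, sign, v) edge to consistent / inconsistent / undetermined.
    ``removed`` logs edges dropped by the consistency filter.
    """

    graph: CausalGraph
    directions: Dict[str, int] = field(default_factory=dict)
    unmapped_calls: List[str] = field(default_factory=list)
    edge_status: Dict[Tuple[str, int, str], str] = field(default_factory=dict)
    removed: List[Tuple[str, int, str]] = field(default_factory=list)

    def status_counts(self) -> Dict[str, int]:
        out = {CONSISTENT: 0, INCONSISTENT: 0, UNDETERMINED: 0}
        for s in self.edge_status.values():
            out[s] += 1
        return out


def _edge_consistency(dir_u: Optional[int], sign: int, dir_v: Optional[int]) -> str:
    if dir_u is None or dir_v is None:
        return UNDETERMINED
    return CONSISTENT if dir_u * sign == dir_v else INCONSISTENT


def annotate(
    graph: CausalGraph,
    calls,
    mapping: Optional[Mapping[str, str]] = None,
) -> AnnotatedGraph:
    """Stamp significant node-call directions onto the graph.

    ``calls`` is a node-call DataFrame (index node id, columns including
    ``direction`` and ``significant``) or a plain ``{id: direction}``
    mapping of significant calls.  ``mapping`` translates call ids to
    graph labels (default: identity).  One call resolving to two labels
    is ambiguous and raises; calls absent from the graph are listed in
    ``unmapped_calls``.
    """
    if hasattr(calls, "index") and hasattr(calls, "columns"):
        sig = calls[calls["significant"]]
        call_dirs = dict(zip(sig.index, sig["direction"].astype(int)))
    else:
        call_dirs = {k: int(v) for k, v in dict(calls).items()}

    label_map: Dict[str, List[str]] = {}
    if mapping is not None:
        for call_id, label in mapping.items():
            label_map.setdefault(call_id, []).append(label)
        ambiguous = {k: v for k, v in label_map.items() if len(v) > 1}
        if ambiguous:
            raise ValueError(f"ambiguous call-to-label mapping: {ambiguous}")

    node_set = set(graph.g.nodes)
    directions: Dict[str, int] = {}
    unmapped: List[str] = []
    for call_id, d in call_dirs.items():
        label = label_map.get(call_id, [call_id])[0]
        if label in node_set:
            directions[label.strip()] = d
        else:
            unmapped.append(call_id)

    ann = AnnotatedGraph(graph=graph, directions=directions, unmapped_calls=sorted(unmapped))
    for u, s, v in graph.edges():
        ann.edge_status[(u, s, v)] = _edge_consistency(directions.get(u), s, directions.get(v))
    return ann


def consistency_filter(g: AnnotatedGraph) -> AnnotatedGraph:
    """Remove causally inconsistent edges (both endpoints measured and
    dir(u) * sign != dir(v)); keep undetermined edges.  Idempotent."""
    kept = CausalGraph(nodes=g.graph.nodes)
    removed = list(g.removed)
    status: Dict[Tuple[str, int, str], str] = {}
    for u, s, v in g.graph.edges():
        st = _edge_consistency(g.directions.get(u), s, g.directions.get(v))
        if st == INCONSISTENT:
            removed.append((u, s, v))
        else:
            kept.add_edge(u, s, v)
            status[(u, s, v)] = st
    return AnnotatedGraph(
        graph=kept,
        directions=dict(g.directions),
        unmapped_calls=list(g.unmapped_calls),
        edge_status=status,
        removed=removed,
    )


def extract_subgraph(g: AnnotatedGraph, anchors: Sequence[str], radius: int) -> CausalGraph:
    """Nodes within undirected distance <= radius of any anchor, with the
    induced consistent/undetermined edges; deterministic node order."""
    node_set = set(g.graph.g.nodes)
    for a in anchors:
        if a not in node_set:
            raise ValueError(f"unknown anchor {a!r}")
    und = g.graph.g.to_undirected(as_view=True)
    dist = {a: 0 for a in anchors}
    queue = deque(anchors)
    while queue:
        u = queue.popleft()
        if dist[u] == radius:
            continue
        for w in und.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    keep = set(dist)
    edges = [
        (u, s, v)
        for (u, s, v) in g.graph.edges()
        if u in keep and v in keep and g.edge_status.get((u, s, v), UNDETERMINED) != INCONSISTENT
    ]
    return CausalGraph(edges=edges, nodes=sorted(keep))
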