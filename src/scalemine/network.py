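"""Scale-MeSH co-occurrence networks, frequencies, and betweenness centrality.

Each annotated article contributes one unit of weight to the edge between
every scale it mentions and every MeSH term (within the chosen semantic
categories) it is indexed with, yielding a bipartite weighted graph per
category.  Node importance is summarized by betweenness centrality — the
number of shortest paths between other node pairs passing through a node —
computed on the unweighted topology (edge weights record co-occurrence
counts, not distances).

The graph container, the Brandes betweenness algorithm and GEXF/GraphML
serialization are provided by :mod:`networkx`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import networkx as nx

from .ner import AnnotatedArticle

__all__ = [
    "CoNetwork",
    "FrequencyRow",
    "build_network",
    "betweenness",
    "rank_by_betweenness",
    "frequency_table",
    "truncate2",
    "export_network",
    "import_graphml",
    "scale_document_frequencies",
]

EXPORT_FORMATS = ("gexf", "graphml", "csv")


@dataclass
class CoNetwork:
    """Bipartite scale-MeSH co-occurrence graph.

    Wraps an undirected :class:`networkx.Graph`; node attributes are
    ``kind`` ("scale" | "mesh"), ``category`` (semantic-category label or
    "" for scales), ``frequency`` (articles containing the node); the edge
    attribute ``weight`` counts articles containing both endpoints.
    """

    graph: nx.Graph

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_weights(self) -> dict[tuple[str, str], int]:
        """Edge weights keyed on (scale, mesh) pairs."""
        out = {}
        for u, v, w in self.graph.edges(data="weight"):
            if self.graph.nodes[u]["kind"] == "scale":
                out[(u, v)] = int(w)
            else:
                out[(v, u)] = int(w)
        return out

    def check_invariants(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            ku, kv = self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]
            if ku == kv:
                raise AssertionError(f"non-bipartite edge {u!r}-{v!r}")
            fu = self.graph.nodes[u]["frequency"]
            fv = self.graph.nodes[v]["frequency"]
            if not (1 <= w <= min(fu, fv)):
                raise AssertionError(f"edge {u!r}-{v!r} weight {w} vs frequencies {fu},{fv}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoNetwork):
            return NotImplemented
        g, h = self.graph, other.graph
        if set(g.nodes) != set(h.nodes) or set(map(frozenset, g.edges)) != set(map(frozenset, h.edges)):
            return False
        for n in g.nodes:
            a, b = g.nodes[n], h.nodes[n]
            if (
                a["kind"] != b["kind"]
                or a.get("category", "") != b.get("category", "")
                or int(a["frequency"]) != int(b["frequency"])
            ):
                return False
        return all(int(g.edges[e]["weight"]) == int(h.edges[e]["weight"]) for e in g.edges)


def build_network(
    annotations: list[AnnotatedArticle],
    category_filter: set[str],
    term_filter: set[str] | None = None,
    keep_isolates: bool = False,
) -> CoNetwork:
    """Build the co-occurrence network over the given semantic categories.

    For each article, each (scale, filtered MeSH term) pair present together
    contributes exactly 1 to that edge's weight; node frequency counts the
    articles containing the node.  ``term_filter`` optionally restricts to a
    subset of term names (e.g. the age-group terms within research_objects).
    Zero-degree nodes are excluded unless ``keep_isolates``.  Article order
    does not affect the result.
    """
    g = nx.Graph()
    scale_freq: dict[str, int] = {}
    term_freq: dict[str, int] = {}
    term_category: dict[str, str] = {}
    weights: dict[tuple[str, str], int] = {}
    for ann in annotations:
        scales = sorted(ann.scale_names())
        terms = set()
        for label in category_filter:
            for t in ann.mesh_by_category.get(label, ()):
                if term_filter is None or t in term_filter:
                    terms.add(t)
                    term_category.setdefault(t, label)
        for s in scales:
            scale_freq[s] = scale_freq.get(s, 0) + 1
        for t in terms:
            term_freq[t] = term_freq.get(t, 0) + 1
        for s in scales:
            for t in sorted(terms):
                weights[(s, t)] = weights.get((s, t), 0) + 1

    for s, f in scale_freq.items():
        g.add_node(s, kind="scale", category="", frequency=f)
    for t, f in term_freq.items():
        g.add_node(t, kind="mesh", category=term_category[t], frequency=f)
    for (s, t), w in weights.items():
        g.add_edge(s, t, weight=w)
    if not keep_isolates:
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    net = CoNetwork(g)
    net.check_invariants()
    return net


def betweenness(network: CoNetwork, normalized: bool = False) -> dict[str, float]:
    """Exact betweenness centrality on the unweighted topology.

    Uses Brandes' accumulation; pair counts are unnormalized by default
    (a 3-path's middle node scores 1, the hub of a 3-leaf star scores 3),
    with even split over equal-length geodesics.  ``normalized=True``
    divides by (N-1)(N-2)/2.
    """
    return dict(nx.betweenness_centrality(network.graph, normalized=normalized, weight=None))


def rank_by_betweenness(network: CoNetwork, normalized: bool = False) -> list[tuple[str, float]]:
    """Nodes ordered by descending betweenness, ties alphabetical."""
    bc = betweenness(network, normalized=normalized)
    return sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))


def truncate2(numerator: int, denominator: int) -> float:
    """100*numerator/denominator truncated (not rounded) to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (10000 * numerator // denominator) / 100


@dataclass(frozen=True)
class FrequencyRow:
    rank: int
    canonical_name: str
    count: int
    percentage: float


def scale_document_frequencies(annotations: list[AnnotatedArticle]) -> dict[str, int]:
    """Document frequency per canonical scale (one count per article)."""
    freq: dict[str, int] = {}
    for ann in annotations:
        for name in ann.scale_names():
            freq[name] = freq.get(name, 0) + 1
    return freq


def frequency_table(
    annotations: list[AnnotatedArticle],
    top_k: int | None = None,
    counts: dict[str, int] | None = None,
    total: int | None = None,
) -> list[FrequencyRow]:
    """Ranked scale frequency table with truncated percentage column.

    Rows sort by count descending, ties alphabetical.  The percentage is
    100*count/total truncated to two decimals, where the total is the sum
    of occurrences over the whole corpus (all scales, not only listed
    rows); ``counts``/``total`` allow re-deriving a table from published
    count columns.
    """
    if counts is None:
        counts = scale_document_frequencies(annotations)
    if not counts:
        return []
    if total is None:
        total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ordered = ordered[:top_k]
    return [
        FrequencyRow(rank=i, canonical_name=name, count=c, percentage=truncate2(c, total))
        for i, (name, c) in enumerate(ordered, start=1)
    ]


def _attach_metrics(network: CoNetwork, metrics: dict[str, float] | None) -> nx.Graph:
    g = network.graph.copy()
    bc = metrics if metrics is not None else betweenness(network)
    for n in g.nodes:
        g.nodes[n]["betweenness"] = float(bc.get(n, 0.0))
    return g


def export_network(
    network: CoNetwork,
    metrics: dict[str, float] | None = None,
    format: str = "graphml",
) -> str | dict[str, str]:
    """Serialize a network with node metrics.

    ``gexf``/``graphml`` return one XML document with node attributes kind,
    category, frequency, betweenness and edge attribute weight; ``csv``
    returns ``{"nodes.csv": ..., "edges.csv": ...}``.  GraphML re-imports to
    an equal network via :func:`import_graphml`.
    """
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}")
    g = _attach_metrics(network, metrics)
    if format == "gexf":
        return "\n".join(nx.generate_gexf(g, version="1.2draft"))
    if format == "graphml":
        return "\n".join(nx.generate_graphml(g, named_key_ids=True))
    nodes_lines = ["id\tkind\tcategory\tfrequency\tbetweenness"]
    for n in sorted(g.nodes):
        a = g.nodes[n]
        nodes_lines.append(f"{n}\t{a['kind']}\t{a['category']}\t{a['frequency']}\t{a['betweenness']}")
    edge_lines = ["scale\tmesh\tweight"]
    for u, v, w in sorted(g.edges(data="weight")):
        if g.nodes[u]["kind"] != "scale":
            u, v = v, u
        edge_lines.append(f"{u}\t{v}\t{w}")
    return {"nodes.csv": "\n".join(nodes_lines) + "\n", "edges.csv": "\n".join(edge_lines) + "\n"}


def import_graphml(text: str) -> CoNetwork:
    """Reconstruct a :class:`CoNetwork` from GraphML produced by export."""
    g = nx.read_graphml(io.StringIO(text))
    h = nx.Graph()
    for n, a in g.nodes(data=True):
        h.add_node(n, kind=a["kind"], category=a.get("category", ""), frequency=int(a["frequency"]))
    for u, v, a in g.edges(data=True):
        h.add_edge(u, v, weight=int(a["weight"]))
    return CoNetwork(h)
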