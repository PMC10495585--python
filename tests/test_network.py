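"""Co-occurrence networks: construction, betweenness, frequencies, export."""

import itertools
import random

import networkx as nx
import pytest

from scalemine.lexicon import default_lexicon
from scalemine.medline import ArticleRecord, MeshHeading
from scalemine.mesh import CATEGORY_LABELS, mini_tree
from scalemine.ner import annotate_corpus
from scalemine.network import (
    betweenness,
    build_network,
    export_network,
    frequency_table,
    import_graphml,
    rank_by_betweenness,
    truncate2,
)
from scalemine.simulate import SimConfig, simulate


def _ann(pmid, scales, mesh):
    """Minimal AnnotatedArticle stand-in built through the real pipeline types."""
    from scalemine.ner import AnnotatedArticle

    rec = ArticleRecord(pmid=pmid, title="t")
    by_cat = {label: set() for label in CATEGORY_LABELS}
    by_cat.update(mesh)
    occs = []
    from scalemine.ner import Mention, ScaleOccurrence

    for s in scales:
        occs.append(ScaleOccurrence(pmid, s, (Mention(s[:1] or "x", 0, 1, "title"),)))
    return AnnotatedArticle(rec, occs, [], by_cat)


def test_single_article_single_pair():
    ann = _ann("1", ["S"], {"countries_regions": {"China"}})
    net = build_network([ann], {"countries_regions"})
    assert set(net.graph.nodes) == {"S", "China"}
    assert net.graph.nodes["S"]["frequency"] == net.graph.nodes["China"]["frequency"] == 1
    assert net.edge_weights() == {("S", "China"): 1}


def test_edge_weight_additivity():
    anns = [_ann(str(i), ["PHQ"], {"countries_regions": {"China"}}) for i in range(2)]
    net = build_network(anns, {"countries_regions"})
    assert net.edge_weights() == {("PHQ", "China"): 2}


def test_article_order_invariance():
    anns = [
        _ann("1", ["A"], {"research_topics": {"Anxiety"}}),
        _ann("2", ["B"], {"research_topics": {"Anxiety", "Depression"}}),
        _ann("3", ["A", "B"], {"research_topics": {"Depression"}}),
    ]
    net1 = build_network(anns, {"research_topics"})
    net2 = build_network(list(reversed(anns)), {"research_topics"})
    assert net1 == net2


def test_edge_weights_match_bruteforce_on_synthetic_corpora():
    """Pair counting equals direct enumeration of (article, scale, term) triples."""
    lex, tree = default_lexicon(), mini_tree()
    for seed in range(50):
        recs, _ = simulate(SimConfig(n_articles=25, alias_prob=0.3, mesh_per_article=(0, 2), seed=seed), lex, tree)
        anns = annotate_corpus(recs, tree, lex)
        for label in CATEGORY_LABELS:
            brute = {}
            for ann in anns:
                for s, t in itertools.product(sorted(ann.scale_names()), sorted(ann.mesh_by_category[label])):
                    brute[(s, t)] = brute.get((s, t), 0) + 1
            assert build_network(anns, {label}).edge_weights() == brute


# --- independent geodesic-enumeration oracle -------------------------------


def _bfs_geodesics(adj, s, t):
    """All shortest s-t paths by BFS layering + backward enumeration."""
    from collections import deque

    dist = {s: 0}
    preds = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if t not in dist:
        return []

    def back(v):
        if v == s:
            return [[s]]
        return [p + [v] for pred in preds[v] for p in back(pred)]

    return back(t)


def oracle_betweenness(g: nx.Graph):
    adj = {n: sorted(g.neighbors(n)) for n in g.nodes}
    bc = dict.fromkeys(g.nodes, 0.0)
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        paths = _bfs_geodesics(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def _wrap(g):
    from scalemine.network import CoNetwork

    for n in g.nodes:
        g.nodes[n].setdefault("kind", "scale")
        g.nodes[n].setdefault("category", "")
        g.nodes[n].setdefault("frequency", 1)
    return CoNetwork(g)


def test_betweenness_path_closed_form():
    g = nx.path_graph(["A", "B", "C"])
    bc = betweenness(_wrap(g))
    assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}


def test_betweenness_star_closed_form():
    g = nx.star_graph(3)
    bc = betweenness(_wrap(g))
    assert bc[0] == 3.0  # C(3,2) leaf pairs
    assert all(bc[i] == 0.0 for i in (1, 2, 3))


def test_betweenness_matches_bfs_oracle_on_random_graphs():
    rng = random.Random(0)
    for _ in range(100):
        n = rng.randint(2, 8)
        g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=rng.randint(0, 10**6))
        bc = betweenness(_wrap(g))
        oracle = oracle_betweenness(g)
        for node in g.nodes:
            assert abs(bc[node] - oracle[node]) < 1e-9


def test_betweenness_normalization_flag():
    g = nx.path_graph(["A", "B", "C"])
    bc = betweenness(_wrap(g), normalized=True)
    assert bc["B"] == pytest.approx(1.0)  # 1 / ((3-1)(3-2)/2)


def test_single_node_network_all_zero():
    g = nx.Graph()
    g.add_node("solo", kind="scale", category="", frequency=1)
    assert betweenness(_wrap(g)) == {"solo": 0.0}


def test_rank_by_betweenness_order_and_ties():
    g = nx.path_graph(["A", "B", "C"])
    assert rank_by_betweenness(_wrap(g))[0][0] == "B"
    iso = nx.Graph()
    iso.add_nodes_from("ZYX")
    assert [n for n, _ in rank_by_betweenness(_wrap(iso))] == ["X", "Y", "Z"]


# --- frequency table --------------------------------------------------------


def test_truncation_of_published_cells():
    assert truncate2(177, 1110) == 15.94
    assert truncate2(102, 1110) == 9.18  # 9.189... truncates, never rounds to 9.19
    assert truncate2(57, 1110) == 5.13


def test_frequency_table_single_scale_is_100():
    ann = _ann("1", ["Only Scale"], {})
    (row,) = frequency_table([ann])
    assert row.count == 1 and row.percentage == 100.00


def test_frequency_table_total_covers_whole_corpus():
    anns = [_ann(str(i), ["A"], {}) for i in range(3)] + [_ann("9", ["B"], {})]
    rows = frequency_table(anns, top_k=1)
    assert rows[0].canonical_name == "A" and rows[0].count == 3
    assert rows[0].percentage == 75.00  # denominator includes B


def test_frequency_table_sorting_and_truncation_bound():
    anns = (
        [_ann(str(i), ["B"], {}) for i in range(3)]
        + [_ann(str(10 + i), ["A"], {}) for i in range(3)]
        + [_ann("x", ["C"], {})]
    )
    rows = frequency_table(anns)
    assert [r.canonical_name for r in rows] == ["A", "B", "C"]  # ties alphabetical
    assert [r.count for r in rows] == sorted([r.count for r in rows], reverse=True)
    total_pct = sum(r.percentage for r in rows)
    assert 100.00 - 0.01 * len(rows) <= total_pct <= 100.00


def test_frequency_table_empty():
    assert frequency_table([]) == []


# --- export -----------------------------------------------------------------


def _random_conetwork(seed):
    rng = random.Random(seed)
    anns = []
    for i in range(rng.randint(1, 12)):
        scales = rng.sample(["S1", "S2", "S3"], rng.randint(1, 2))
        terms = set(rng.sample(["China", "Italy", "Turkey"], rng.randint(1, 2)))
        anns.append(_ann(str(i), scales, {"countries_regions": terms}))
    return build_network(anns, {"countries_regions"})


def test_graphml_roundtrip_random_networks():
    for seed in range(100):
        net = _random_conetwork(seed)
        assert import_graphml(export_network(net, format="graphml")) == net


def test_export_empty_network():
    import networkx

    from scalemine.network import CoNetwork

    empty = CoNetwork(networkx.Graph())
    xml = export_network(empty, metrics={}, format="graphml")
    assert "graphml" in xml and import_graphml(xml) == empty


def test_export_gexf_and_csv_shapes():
    net = build_network([_ann("1", ["S"], {"countries_regions": {"China"}})], {"countries_regions"})
    gexf = export_network(net, format="gexf")
    assert 'version="1.2' in gexf and "weight" in gexf
    csv = export_network(net, format="csv")
    assert csv["edges.csv"].splitlines()[1] == "S\tChina\t1"


def test_export_unknown_format_lists_supported():
    net = _random_conetwork(0)
    with pytest.raises(ValueError, match="gexf, graphml, csv"):
        export_network(net, format="dot")
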