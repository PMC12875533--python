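import numpy as np
import pandas as pd
import pytest

from hrnetx.cocre import CREModulePartition, assign_hcg, extract_hubs, \
    locus_enrichment, louvain_modules
from hrnetx.io_graph import NodeSet, TypedEdgeSet


def brute_force_max_modularity(edges, nodes):
    """Exhaustive max-modularity partition for <= 8 nodes."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (s, t), w in zip(edges.pairs, edges.weights):
        g.add_edge(s, t, weight=float(w))

    def partitions(items):
        if not items:
            yield []
            return
        head, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield part + [[head]]

    best, best_q = None, -np.inf
    for part in partitions(list(nodes)):
        q = nx.community.modularity(g, [set(p) for p in part],
                                    weight="weight")
        if q > best_q:
            best_q, best = q, [frozenset(p) for p in part]
    return set(best), best_q


class TestLouvain:
    def test_two_disjoint_triangles_recovered_exactly(self):
        pairs = [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                 ("b1", "b2"), ("b2", "b3"), ("b1", "b3")]
        edges = TypedEdgeSet("CRE-CRE", pairs)
        part = louvain_modules(edges, seed=0)
        got = {frozenset(part.members(m))
               for m in set(part.module_of.values())}
        expect, q_star = brute_force_max_modularity(
            edges, sorted({n for p in pairs for n in p}))
        assert got == expect
        assert part.modularity == pytest.approx(q_star, abs=1e-12)

    def test_single_edge_joins_endpoints(self):
        part = louvain_modules(TypedEdgeSet("CRE-CRE", [("x", "y")]),
                               seed=0)
        assert part.module_of["x"] == part.module_of["y"]

    def test_same_seed_identical_partition(self, trained):
        edges = trained["hrnet"].layers["CRE-CRE"]
        a = louvain_modules(edges, seed=3)
        b = louvain_modules(edges, seed=3)
        assert a.module_of == b.module_of

    def test_modularity_at_least_singleton_partition(self, trained):
        import networkx as nx
        edges = trained["hrnet"].layers["CRE-CRE"]
        part = louvain_modules(edges, seed=0)
        g = nx.Graph()
        for (s, t), w in zip(edges.pairs, edges.weights):
            g.add_edge(s, t, weight=float(w))
        singletons = [{n} for n in g.nodes]
        q0 = nx.community.modularity(g, singletons, weight="weight")
        assert part.modularity >= q0

    def test_empty_edge_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            louvain_modules(TypedEdgeSet("CRE-CRE", []))


def _whole_graph_partition(edges):
    nodes = {n for p in edges.pairs for n in p}
    return CREModulePartition({n: 0 for n in nodes}, 0.0)


class TestHubs:
    def test_top_pair_endpoints_are_network_hubs(self):
        edges = TypedEdgeSet("CRE-CRE",
                             [("a", "b"), ("c", "d"), ("e", "f")],
                             [0.9, 0.5, 0.1])
        hubs = extract_hubs(edges, _whole_graph_partition(edges),
                            n_network=1, n_module=1, n_degree=1)
        assert hubs.network_hubs == ["a", "b"]

    def test_single_module_equals_network_hubs(self):
        edges = TypedEdgeSet("CRE-CRE",
                             [("a", "b"), ("b", "c"), ("c", "d")],
                             [0.9, 0.5, 0.1])
        hubs = extract_hubs(edges, _whole_graph_partition(edges),
                            n_network=2, n_module=2, n_degree=1)
        assert hubs.module_hubs == hubs.network_hubs

    def test_star_center_is_degree_hub(self):
        edges = TypedEdgeSet("CRE-CRE",
                             [("hub", x) for x in "abcd"],
                             [1.0] * 4)
        hubs = extract_hubs(edges, _whole_graph_partition(edges),
                            n_network=1, n_module=1, n_degree=1)
        assert hubs.degree_hubs == ["hub"]

    def test_invariant_to_edge_order(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("a", "c")]
        w = [0.9, 0.7, 0.5, 0.3]
        e1 = TypedEdgeSet("CRE-CRE", pairs, w)
        order = [2, 0, 3, 1]
        e2 = TypedEdgeSet("CRE-CRE", [pairs[i] for i in order],
                          [w[i] for i in order])
        p1, p2 = _whole_graph_partition(e1), _whole_graph_partition(e2)
        h1 = extract_hubs(e1, p1, 2, 2, 3)
        h2 = extract_hubs(e2, p2, 2, 2, 3)
        assert h1 == h2

    def test_oversized_n_takes_all_with_warning(self):
        edges = TypedEdgeSet("CRE-CRE", [("a", "b")], [1.0])
        with pytest.warns(UserWarning, match="exceeds"):
            hubs = extract_hubs(edges, _whole_graph_partition(edges),
                                n_network=10, n_module=1, n_degree=1)
        assert hubs.network_hubs == ["a", "b"]


def _cre_set(n=100, overlap_first=10, chrom="chr1"):
    ids, intervals = [], {}
    for i in range(n):
        start = 1000 * i
        nid = f"{chrom}:{start}-{start + 100}"
        ids.append(nid)
        intervals[nid] = (chrom, start, start + 100)
    loci = pd.DataFrame({
        "chrom": [chrom] * overlap_first,
        "start": [1000 * i + 10 for i in range(overlap_first)],
        "end": [1000 * i + 20 for i in range(overlap_first)]})
    return NodeSet("CRE", ids, intervals), loci


class TestLocusEnrichment:
    def test_full_cre_set_scores_exactly_one(self):
        cres, loci = _cre_set()
        res = locus_enrichment(list(cres.ids), loci, cres, n_perm=50,
                               seed=0)
        assert res["score"] == 1.0

    def test_ratio_arithmetic(self):
        # hubs contain all 10 overlapping CREs of 100 -> score = 10
        cres, loci = _cre_set()
        hubs = cres.ids[:10]
        res = locus_enrichment(hubs, loci, cres, n_perm=200, seed=0)
        assert res["score"] == pytest.approx(10.0)
        assert res["p_value"] < 0.05

    def test_zero_background_overlap_reported_undefined(self):
        cres, _ = _cre_set()
        far = pd.DataFrame({"chrom": ["chrX"], "start": [0],
                            "end": [10]})
        res = locus_enrichment(cres.ids[:5], far, cres, n_perm=10,
                               seed=0)
        assert np.isnan(res["score"])

    def test_random_hub_sets_give_uniformish_p(self):
        cres, loci = _cre_set()
        rng = np.random.default_rng(0)
        high_p = 0
        for rep in range(10):
            hubs = [cres.ids[i]
                    for i in rng.choice(100, size=15, replace=False)]
            res = locus_enrichment(hubs, loci, cres, n_perm=200,
                                   seed=rep)
            high_p += res["p_value"] > 0.05
        assert high_p >= 9


class TestAssignHcg:
    def _tss(self):
        return pd.DataFrame({
            "gene": ["in_window", "boundary_out", "inside_cre"],
            "chrom": ["chr1"] * 3,
            "tss": [1_500_000, 3_100_100, 1_000_050],
        })

    def test_window_boundaries_half_open(self):
        cres = NodeSet("CRE", ["chr1:1000000-1000100"],
                       {"chr1:1000000-1000100":
                        ("chr1", 1_000_000, 1_000_100)})
        # window = [start-2Mb clipped at 0, end+2Mb) = [0, 3100100)
        got = assign_hcg(["chr1:1000000-1000100"], cres, self._tss())
        assert got == {"in_window", "inside_cre"}

    def test_brute_force_interval_oracle(self):
        rng = np.random.default_rng(4)
        ids, intervals = [], {}
        for i in range(3):
            s = int(rng.integers(0, 5_000_000))
            nid = f"chr1:{s}-{s + 500}"
            ids.append(nid)
            intervals[nid] = ("chr1", s, s + 500)
        cres = NodeSet("CRE", ids, intervals)
        tss = pd.DataFrame({
            "gene": [f"g{i}" for i in range(5)],
            "chrom": ["chr1"] * 5,
            "tss": rng.integers(0, 8_000_000, size=5)})
        got = assign_hcg(ids, cres, tss)
        expect = set()
        for _, row in tss.iterrows():
            for nid in ids:
                _, s, e = intervals[nid]
                if max(0, s - 2_000_000) <= row["tss"] < e + 2_000_000:
                    expect.add(row["gene"])
        assert got == expect

    def test_missing_chromosome_warns(self):
        cres = NodeSet("CRE", ["chr9:10-20"],
                       {"chr9:10-20": ("chr9", 10, 20)})
        with pytest.warns(UserWarning, match="chr9"):
            got = assign_hcg(["chr9:10-20"], cres, self._tss())
        assert got == set()
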