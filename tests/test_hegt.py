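import numpy as np
import pytest

from hrnetx.hegt import EncoderConfig, gcn_layer, hgt_layer, \
    init_encoder_params, metapath_forward, sage_layer
from hrnetx.io_graph import FeatureMatrix, HeteroRegGraph, NodeSet, \
    TypedEdgeSet


class TestGCN:
    def test_two_node_hand_computation(self):
        # features [2],[4], one edge, W = I, sigma = id:
        # A~ = all-ones, D~ = diag(2,2) -> both nodes average to 3
        h = gcn_layer(np.array([[2.0], [4.0]]), np.array([[0, 1],
                                                          [1, 0.0]]),
                      np.eye(1), activation="identity")
        np.testing.assert_allclose(h.data, [[3.0], [3.0]], atol=1e-12)

    def test_no_edges_keeps_features(self):
        h_prev = np.array([[1.0, 2.0], [3.0, 4.0]])
        h = gcn_layer(h_prev, np.zeros((2, 2)), np.eye(2),
                      activation="identity")
        np.testing.assert_allclose(h.data, h_prev, atol=1e-12)

    def test_linearity_in_features(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 4))
        a = ((a + a.T) > 1).astype(float)
        np.fill_diagonal(a, 0)
        h = rng.normal(size=(4, 3))
        w = rng.normal(size=(3, 3))
        out1 = gcn_layer(h, a, w, activation="identity").data
        out3 = gcn_layer(3 * h, a, w, activation="identity").data
        np.testing.assert_allclose(out3, 3 * out1, atol=1e-10)

    def test_dense_oracle_on_small_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(2, 6))
            a = (rng.random((n, n)) > 0.5).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            h = rng.normal(size=(n, 2))
            w = rng.normal(size=(2, 2))
            at = a + np.eye(n)
            dhalf = np.diag(1 / np.sqrt(at.sum(1)))
            expect = np.maximum(dhalf @ at @ dhalf @ h @ w, 0)
            got = gcn_layer(h, a, w, activation="relu").data
            np.testing.assert_allclose(got, expect, atol=1e-6)


class TestSage:
    def test_mean_of_neighbor_features(self):
        h_src = np.array([[1.0, 0.0], [3.0, 0.0], [9.0, 9.0]])
        h_tgt = np.zeros((1, 2))
        # W picks out the aggregate block
        w = np.vstack([np.zeros((2, 2)), np.eye(2)])
        out = sage_layer(h_tgt, h_src, [0, 1], [0, 0], w,
                         aggregator="mean")
        np.testing.assert_allclose(out.data, [[2.0, 0.0]], atol=1e-12)

    def test_no_neighbors_aggregates_zero(self):
        h = np.array([[1.0, 1.0], [2.0, 2.0]])
        w = np.vstack([np.eye(2), np.eye(2)])
        out = sage_layer(h, h, [0], [0], w, aggregator="mean")
        # node 1 has no in-edges: output = relu(h_1 @ I + 0)
        np.testing.assert_allclose(out.data[1], [2.0, 2.0])

    def test_mean_equals_pool_for_single_neighbor(self):
        rng = np.random.default_rng(2)
        h_src = rng.normal(size=(3, 4))
        h_tgt = rng.normal(size=(2, 4))
        w = rng.normal(size=(8, 4))
        a = sage_layer(h_tgt, h_src, [1], [0], w, "mean").data
        b = sage_layer(h_tgt, h_src, [1], [0], w, "pool").data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="input rows"):
            sage_layer(np.ones((2, 3)), np.ones((2, 3)), [0], [1],
                       np.ones((3, 3)))


def _block(seed=0, d=4, heads=2):
    from hrnetx.hegt import _hgt_block
    return _hgt_block(np.random.default_rng(seed), d, heads)


class TestHGT:
    def test_single_neighbor_attention_is_one(self):
        h = np.random.default_rng(0).normal(size=(3, 4))
        _, att = hgt_layer(h, h, [1], [2], _block())
        np.testing.assert_allclose(att, 1.0, atol=1e-12)

    def test_identical_neighbors_share_attention_equally(self):
        h = np.random.default_rng(0).normal(size=(3, 4))
        h[1] = h[0]
        _, att = hgt_layer(h, h, [0, 1], [2, 2], _block())
        np.testing.assert_allclose(att, 0.5, atol=1e-12)

    def test_attention_sums_to_one_per_target(self):
        rng = np.random.default_rng(1)
        h_src = rng.normal(size=(6, 4))
        h_tgt = rng.normal(size=(4, 4))
        src = np.array([0, 1, 2, 3, 4, 5, 0, 1])
        tgt = np.array([0, 0, 0, 1, 1, 2, 2, 3])
        _, att = hgt_layer(h_src, h_tgt, src, tgt, _block(3))
        sums = np.zeros((4, att.shape[1]))
        np.add.at(sums, tgt, att)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_target_without_inedges_keeps_residual(self):
        h_src = np.random.default_rng(0).normal(size=(2, 4))
        h_tgt = np.random.default_rng(1).normal(size=(2, 4))
        block = _block()
        out, _ = hgt_layer(h_src, h_tgt, [0], [0], block)
        g = 1 / (1 + np.exp(-block["theta"].data))
        np.testing.assert_allclose(out.data[1], (1 - g) * h_tgt[1],
                                   atol=1e-10)


def _tiny_system(rng_seed=0, zero_tf=False):
    """1 TF -> 1 CRE -> 1 TG chain with 4 metacells."""
    rng = np.random.default_rng(rng_seed)
    cells = [f"c{i}" for i in range(4)]
    nodes = {"TF": NodeSet("TF", ["t"]), "CRE": NodeSet("CRE", ["c"]),
             "TG": NodeSet("TG", ["g"])}
    graph = HeteroRegGraph(nodes, {
        "TF-TF": TypedEdgeSet("TF-TF", []),
        "TF-CRE": TypedEdgeSet("TF-CRE", [("t", "c")]),
        "CRE-CRE": TypedEdgeSet("CRE-CRE", []),
        "CRE-TG": TypedEdgeSet("CRE-TG", [("c", "g")]),
        "TG-TG": TypedEdgeSet("TG-TG", []),
    })
    tf_draw = rng.random((4, 1)) * 2 + 0.5
    tf_vals = np.zeros((4, 1)) if zero_tf else tf_draw
    feats = {
        "TF": FeatureMatrix(tf_vals, cells, ["t"], "TF_expr"),
        "CRE": FeatureMatrix(rng.random((4, 1)), cells, ["c"], "CRE_acc"),
        "TG": FeatureMatrix(rng.random((4, 1)), cells, ["g"], "TG_expr"),
    }
    return graph, feats


class TestMetapath:
    def test_information_flows_from_tf_to_tg(self):
        cfg = EncoderConfig(embedding_dim=4, heads=2, layers=1)
        graph, feats = _tiny_system(0)
        params = init_encoder_params(4, cfg, seed=0)
        emb, _ = metapath_forward(graph, feats, params)
        graph2, feats2 = _tiny_system(0, zero_tf=True)
        emb2, _ = metapath_forward(graph2, feats2, params)
        assert not np.allclose(emb["TG"].data, emb2["TG"].data)

    def test_blocked_path_isolates_tg(self):
        cfg = EncoderConfig(embedding_dim=4, heads=2, layers=1)
        graph, feats = _tiny_system(0)
        graph.edges["CRE-TG"] = TypedEdgeSet("CRE-TG", [])
        params = init_encoder_params(4, cfg, seed=0)
        emb, _ = metapath_forward(graph, feats, params)
        graph2, feats2 = _tiny_system(0, zero_tf=True)
        graph2.edges["CRE-TG"] = TypedEdgeSet("CRE-TG", [])
        emb2, _ = metapath_forward(graph2, feats2, params)
        np.testing.assert_allclose(emb["TG"].data, emb2["TG"].data,
                                   atol=1e-12)

    def test_permutation_equivariance(self, dataset):
        cfg = EncoderConfig()
        feats = dataset.features
        params = init_encoder_params(feats["TG"].n_cells, cfg, seed=0)
        emb, _ = metapath_forward(dataset.graph, feats, params)

        # permute the TG node order everywhere
        perm = np.random.default_rng(0).permutation(
            len(dataset.graph.nodes["TG"]))
        tg_ids = [dataset.graph.nodes["TG"].ids[i] for i in perm]
        nodes = dict(dataset.graph.nodes)
        nodes["TG"] = NodeSet("TG", tg_ids)
        graph2 = HeteroRegGraph(nodes, dataset.graph.edges)
        feats2 = dict(feats)
        feats2["TG"] = feats["TG"].aligned_to(nodes["TG"])
        emb2, _ = metapath_forward(graph2, feats2, params)
        np.testing.assert_allclose(emb2["TG"].data, emb["TG"].data[perm],
                                   atol=1e-8)

    def test_missing_tf_cre_edges_rejected(self):
        graph, feats = _tiny_system(0)
        graph.edges["TF-CRE"] = TypedEdgeSet("TF-CRE", [])
        params = init_encoder_params(4, EncoderConfig(embedding_dim=4),
                                     seed=0)
        with pytest.raises(ValueError, match="TF-CRE"):
            metapath_forward(graph, feats, params)

    def test_attention_record_averaged_in_unit_interval(self, trained):
        for rec in trained["attention"].values():
            a = rec.averaged()
            assert ((a >= 0) & (a <= 1 + 1e-9)).all()
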