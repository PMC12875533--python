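import numpy as np
import pandas as pd
import pytest

from hrnetx.io_graph import HRNet, NodeSet, TypedEdgeSet
from hrnetx.mrwr import TransitionMatrix, build_transition, filter_degs, \
    mrwr_cts, mrwr_pert, rwr_solve

import scipy.sparse as sp


def _chain(weights=(1.0, 1.0)):
    nodes = {"TF": NodeSet("TF", ["T"]), "CRE": NodeSet("CRE", ["C"]),
             "TG": NodeSet("TG", ["G"])}
    return HRNet({
        "TF-TF": TypedEdgeSet("TF-TF", []),
        "TF-CRE": TypedEdgeSet("TF-CRE", [("T", "C")], [weights[0]]),
        "CRE-CRE": TypedEdgeSet("CRE-CRE", []),
        "CRE-TG": TypedEdgeSet("CRE-TG", [("C", "G")], [weights[1]]),
    }, nodes=nodes)


class TestBuildTransition:
    def test_chain_forward_routes_all_mass(self):
        tm = build_transition(_chain(), "forward")
        w = tm.W.toarray()
        # column of T puts mass 1 on C; column of C mass 1 on G
        assert w[tm.node_ids.index("C"), 0] == 1.0
        assert tm.dangling[tm.node_ids.index("G")]

    def test_columns_sum_to_one(self, trained):
        for direction in ("forward", "reverse"):
            tm = build_transition(trained["hrnet"], direction)
            sums = np.asarray(tm.W.sum(axis=0)).ravel()
            np.testing.assert_allclose(sums[~tm.dangling], 1.0,
                                       atol=1e-9)

    def test_scale_invariance_of_normalization(self, trained):
        hrnet = trained["hrnet"]
        doubled = HRNet(
            {et: es.reweighted(np.clip(es.weights, 0, 0.5) * 2)
             for et, es in hrnet.layers.items()}, nodes=hrnet.nodes)
        halved = HRNet(
            {et: es.reweighted(np.clip(es.weights, 0, 0.5))
             for et, es in hrnet.layers.items()}, nodes=hrnet.nodes)
        a = build_transition(doubled, "forward").W.toarray()
        b = build_transition(halved, "forward").W.toarray()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_reverse_transposes_flow(self):
        tm = build_transition(_chain(), "reverse")
        w = tm.W.toarray()
        assert w[tm.node_ids.index("C"), tm.node_ids.index("G")] == 1.0
        assert tm.dangling[0]  # TF has no reverse out-edges


def _random_stochastic(n, rng):
    w = rng.random((n, n))
    return w / w.sum(axis=0, keepdims=True)


def _tm_from_dense(w):
    n = w.shape[0]
    return TransitionMatrix(sp.csc_matrix(w),
                            [f"n{i}" for i in range(n)],
                            np.array(["TF"] * n),
                            np.zeros(n, dtype=bool))


class TestRwrSolve:
    def test_single_node_fixed_point(self):
        tm = _tm_from_dense(np.array([[1.0]]))
        s = rwr_solve(tm, np.array([1.0]), beta=0.4)
        np.testing.assert_allclose(s, [1.0], atol=1e-12)

    def test_two_node_swap_hand_solution(self):
        # W = [[0,1],[1,0]], s0 = [1,0], beta = 0.5 -> s = [2/3, 1/3]
        tm = _tm_from_dense(np.array([[0.0, 1.0], [1.0, 0.0]]))
        s = rwr_solve(tm, np.array([1.0, 0.0]), beta=0.5, tol=1e-12)
        np.testing.assert_allclose(s, [2 / 3, 1 / 3], atol=1e-9)

    def test_iterative_matches_direct_solver(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            tm = _tm_from_dense(_random_stochastic(50, rng))
            s0 = rng.random(50)
            s0 /= s0.sum()
            it = rwr_solve(tm, s0, beta=0.3, tol=1e-12)
            ex = rwr_solve(tm, s0, beta=0.3, method="direct")
            np.testing.assert_allclose(it, ex, atol=1e-8)

    def test_beta_one_returns_seed(self):
        rng = np.random.default_rng(1)
        tm = _tm_from_dense(_random_stochastic(10, rng))
        s0 = np.zeros(10)
        s0[3] = 1.0
        np.testing.assert_allclose(rwr_solve(tm, s0, beta=1.0), s0,
                                   atol=1e-12)

    def test_scores_conserved_and_nonnegative(self, trained):
        tm = build_transition(trained["hrnet"], "forward")
        s0 = np.zeros(tm.n)
        s0[0] = 1.0
        s = rwr_solve(tm, s0, beta=0.3)
        assert abs(s.sum() - 1.0) < 1e-9
        assert (s >= 0).all()

    def test_invalid_seed_distribution(self):
        tm = _tm_from_dense(np.array([[1.0]]))
        with pytest.raises(ValueError, match="probability"):
            rwr_solve(tm, np.array([2.0]))

    def test_non_stochastic_matrix_rejected(self):
        tm = _tm_from_dense(np.array([[0.5]]))
        with pytest.raises(ValueError, match="sum to 1"):
            rwr_solve(tm, np.array([1.0]))


class TestMrwrPert:
    def test_single_path_ranks_reachable_tg_first(self):
        nodes = {"TF": NodeSet("TF", ["T"]),
                 "CRE": NodeSet("CRE", ["C"]),
                 "TG": NodeSet("TG", ["G1", "G2"])}
        hrnet = HRNet({
            "TF-TF": TypedEdgeSet("TF-TF", []),
            "TF-CRE": TypedEdgeSet("TF-CRE", [("T", "C")], [1.0]),
            "CRE-CRE": TypedEdgeSet("CRE-CRE", []),
            "CRE-TG": TypedEdgeSet("CRE-TG", [("C", "G1")], [1.0]),
        }, nodes=nodes)
        ranked = mrwr_pert(hrnet, "T", beta=0.3)
        assert ranked.iloc[0]["node"] == "G1"
        assert ranked.iloc[0]["score"] > ranked.iloc[1]["score"]

    def test_unknown_tf(self, trained):
        with pytest.raises(KeyError):
            mrwr_pert(trained["hrnet"], "NOPE")

    def test_planted_downstream_targets_enriched_in_top_decile(
            self, dataset, trained):
        from scipy.stats import hypergeom
        tf = dataset.master_tfs[0]
        ranked = mrwr_pert(trained["hrnet"], tf, beta=0.3)
        downstream = {t for (s, c), w in
                      zip(dataset.truth["TF-CRE"].pairs,
                          dataset.truth["TF-CRE"].weights) if s == tf
                      for (c2, t) in dataset.truth["CRE-TG"].pairs
                      if c2 == c}
        k = max(1, len(ranked) // 10)
        top = set(ranked["node"].head(k))
        hits = len(top & downstream)
        expected = hypergeom.mean(len(ranked), len(downstream), k)
        assert hits > expected


class TestMrwrCts:
    def test_deg_filter_thresholds(self):
        degs = pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "log2FC": [1.0, 0.4, 1.0, 1.0],
            "FDR": [0.001, 0.001, 0.05, 0.001],
            "pct1": [0.9, 0.9, 0.9, 0.5],
            "pct2": [0.1, 0.1, 0.1, 0.4],
        })
        assert list(filter_degs(degs)["gene"]) == ["a"]

    def test_unique_ancestor_is_top_driver(self):
        nodes = {"TF": NodeSet("TF", ["T1", "T2"]),
                 "CRE": NodeSet("CRE", ["C"]),
                 "TG": NodeSet("TG", ["G"])}
        hrnet = HRNet({
            "TF-TF": TypedEdgeSet("TF-TF", [("T1", "T2")], [1.0]),
            "TF-CRE": TypedEdgeSet("TF-CRE", [("T1", "C")], [1.0]),
            "CRE-CRE": TypedEdgeSet("CRE-CRE", []),
            "CRE-TG": TypedEdgeSet("CRE-TG", [("C", "G")], [1.0]),
        }, nodes=nodes)
        degs = pd.DataFrame({"gene": ["G"], "log2FC": [2.0],
                             "FDR": [1e-5], "pct1": [0.9], "pct2": [0.1]})
        ranked = mrwr_cts(hrnet, degs, target_layer="TF", beta=0.3)
        assert ranked.iloc[0]["node"] == "T1"

    def test_duplicate_seed_rows_leave_scores_unchanged(self):
        hrnet = _chain()
        degs = pd.DataFrame({"gene": ["G"], "log2FC": [2.0],
                             "FDR": [1e-5], "pct1": [0.9], "pct2": [0.1]})
        once = mrwr_cts(hrnet, degs, "TF")
        twice = mrwr_cts(hrnet, pd.concat([degs, degs]), "TF")
        np.testing.assert_allclose(once["score"], twice["score"],
                                   atol=1e-12)

    def test_no_deg_after_filtering(self):
        degs = pd.DataFrame({"gene": ["G"], "log2FC": [0.1],
                             "FDR": [0.5], "pct1": [0.5], "pct2": [0.5]})
        with pytest.raises(ValueError, match="no DEG"):
            mrwr_cts(_chain(), degs, "TF")

    def test_planted_master_tf_in_top3_per_cluster(self, dataset,
                                                   trained):
        for clu, master in dataset.master_tfs.items():
            sub = dataset.deg_table[dataset.deg_table["cluster"] == clu]
            ranked = mrwr_cts(trained["hrnet"], sub, target_layer="TF")
            assert master in list(ranked["node"].head(3)), \
                f"cluster {clu}: {list(ranked['node'].head(3))}"
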