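import copy

import numpy as np
import pytest

from hrnetx.biostreamnet import Perturbation, build_masks, fit, \
    perturb_predict, vector_field
from hrnetx.io_graph import FeatureMatrix, HRNet, NodeSet, TypedEdgeSet

from conftest import truth_hrnet


def _chain_hrnet():
    nodes = {"TF": NodeSet("TF", ["TF1", "TF2"]),
             "CRE": NodeSet("CRE", ["CRE1", "CRE2"]),
             "TG": NodeSet("TG", ["G", "H"])}
    return HRNet({
        "TF-TF": TypedEdgeSet("TF-TF", []),
        "TF-CRE": TypedEdgeSet("TF-CRE", [("TF1", "CRE1")], [0.9]),
        "CRE-CRE": TypedEdgeSet("CRE-CRE", []),
        "CRE-TG": TypedEdgeSet("CRE-TG", [("CRE1", "G")], [0.8]),
    }, nodes=nodes)


class TestBuildMasks:
    def test_chain_has_two_internode_weights(self):
        net = build_masks(_chain_hrnet(), "G")
        assert net.n_mask_weights() == 2
        assert net.tfs == ["TF1"] and net.cres == ["CRE1"]

    def test_unreachable_cre_excluded(self):
        hrnet = _chain_hrnet()
        hrnet.layers["TF-CRE"] = TypedEdgeSet(
            "TF-CRE", [("TF1", "CRE1"), ("TF2", "CRE2")], [0.9, 0.9])
        net = build_masks(hrnet, "G")
        assert "CRE2" not in net.cres and "TF2" not in net.tfs

    def test_gene_without_cre_edges_is_unpredictable(self):
        with pytest.raises(ValueError, match="unpredictable"):
            build_masks(_chain_hrnet(), "H")

    def test_gene_net_threshold_filters_weights(self):
        """|w| > 0.15 on weights {0.1, 0.2, 0.3} keeps exactly 2."""
        net = build_masks(_chain_hrnet(), "G")
        net.init_params(seed=0)
        net.fitted = True
        net.params["W_tc"].data[0, 0] = 0.1
        net.params["w_ct"].data[0] = 0.2
        net.params["b_out"].data = np.array(0.0)
        gh = net.extract_gene_hrnet(threshold=0.15)
        assert len(gh.tf_cre) == 0 and len(gh.cre_tg) == 1
        net.params["W_tc"].data[0, 0] = 0.3
        gh = net.extract_gene_hrnet(threshold=0.15)
        assert len(gh.tf_cre) == 1 and len(gh.cre_tg) == 1


@pytest.fixture(scope="module")
def noiseless_fit(noiseless_dataset):
    """Fit a two-CRE master gene on the noiseless fixture.

    Accessibility dropout is off: with zero noise the accessibility is
    the exact mediator, and this fixture probes capacity, not the
    redundant-input regularization.
    """
    hrnet = truth_hrnet(noiseless_dataset)
    net = build_masks(hrnet, "TG000")
    return fit(net, noiseless_dataset.features["TF"],
               noiseless_dataset.features["CRE"],
               noiseless_dataset.features["TG"],
               epochs=600, lr=5e-3, seed=1, acc_dropout=0.0), hrnet


class TestFit:
    def test_noiseless_linear_gene_is_learnable(self, noiseless_fit):
        net, _ = noiseless_fit
        assert net.test_pcc > 0.95

    def test_mask_zero_weights_stay_exactly_zero(self, noiseless_fit):
        net, _ = noiseless_fit
        assert np.all(net.params["W_tc"].data * (1 - net.mask_tc) == 0)
        assert np.all(net.params["W_cc"].data * (1 - net.mask_cc) == 0)
        assert np.all(net.params["w_ct"].data * (1 - net.mask_ct) == 0)

    def test_shuffled_target_control_has_low_pcc(self, noiseless_dataset):
        hrnet = truth_hrnet(noiseless_dataset)
        fm = copy.deepcopy(noiseless_dataset.features["TG"])
        gi = fm.node_ids.index("TG000")
        fm.values[:, gi] = np.random.default_rng(5).permutation(
            fm.values[:, gi])
        net = build_masks(hrnet, "TG000")
        net = fit(net, noiseless_dataset.features["TF"],
                  noiseless_dataset.features["CRE"], fm,
                  epochs=600, lr=5e-3, seed=1)
        assert abs(net.test_pcc) < 0.3

    def test_too_few_metacells(self):
        net = build_masks(_chain_hrnet(), "G")
        cells = [f"c{i}" for i in range(5)]
        tf = FeatureMatrix(np.ones((5, 1)), cells, ["TF1"], "TF_expr")
        acc = FeatureMatrix(np.ones((5, 1)), cells, ["CRE1"], "CRE_acc")
        tg = FeatureMatrix(np.ones((5, 2)), cells, ["G", "H"], "TG_expr")
        with pytest.raises(ValueError, match="10 metacells"):
            fit(net, tf, acc, tg)


class TestPerturb:
    def test_fold_one_is_exact_noop(self, noiseless_fit,
                                    noiseless_dataset):
        net, _ = noiseless_fit
        d = perturb_predict(net, noiseless_dataset.features["TF"],
                            noiseless_dataset.features["CRE"],
                            Perturbation([("TF000", "TF", 1.0)]))
        assert np.all(d == 0.0)

    def test_node_outside_gene_net_gives_exact_zero(self, noiseless_fit,
                                                    noiseless_dataset):
        net, _ = noiseless_fit
        outside = [t for t in noiseless_dataset.graph.nodes["TF"].ids
                   if t not in net.tfs][0]
        d = perturb_predict(net, noiseless_dataset.features["TF"],
                            noiseless_dataset.features["CRE"],
                            Perturbation([(outside, "TF", 0.0)]))
        assert np.all(d == 0.0)

    def test_negative_fold_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            Perturbation([("TF1", "TF", -1.0)])

    def test_knockout_of_planted_activator_lowers_expression(
            self, dataset, trained):
        """On the noisy fixture, knocking out the master TF of a master
        gene should lower its predicted expression in >= 90% of
        metacells (sign of the planted positive cascade)."""
        gene = next(f"TG{gi:03d}" for gi in range(8)
                    if "TF000" in build_masks(trained["hrnet"],
                                              f"TG{gi:03d}").tfs)
        net = build_masks(trained["hrnet"], gene)
        net = fit(net, dataset.features["TF"], dataset.features["CRE"],
                  dataset.features["TG"], epochs=400, lr=5e-3, seed=1)
        d = perturb_predict(net, dataset.features["TF"],
                            dataset.features["CRE"],
                            Perturbation([("TF000", "TF", 0.0)]))
        assert (d < 0).mean() >= 0.9

    def test_monotone_dose_response_for_master_activator(
            self, noiseless_dataset):
        """Scaling the master TF from knockout through overexpression
        moves the predicted program-gene expression monotonically."""
        hrnet = truth_hrnet(noiseless_dataset)
        net = build_masks(hrnet, "TG000")
        net = fit(net, noiseless_dataset.features["TF"],
                  noiseless_dataset.features["CRE"],
                  noiseless_dataset.features["TG"],
                  epochs=600, lr=5e-3, seed=1)
        means = []
        for fold in (0.0, 0.5, 1.0, 2.0, 3.0):
            d = perturb_predict(net, noiseless_dataset.features["TF"],
                                noiseless_dataset.features["CRE"],
                                Perturbation([("TF000", "TF", fold)]))
            means.append(d.mean())
        assert means[0] <= means[1] <= 0.0 <= means[3] <= means[4]
        assert means[2] == 0.0


class TestVectorField:
    def _coords(self, n=20, seed=0):
        return np.random.default_rng(seed).normal(size=(n, 2))

    def test_zero_delta_gives_zero_displacement(self):
        x = np.random.default_rng(1).random((20, 5))
        disp = vector_field(np.zeros((20, 5)), x, self._coords(), k=4)
        np.testing.assert_array_equal(disp, 0.0)

    def test_delta_toward_one_neighbor_points_there(self):
        rng = np.random.default_rng(2)
        coords = self._coords()
        x = rng.random((20, 30))
        delta = np.zeros_like(x)
        i = 0
        d2 = ((coords - coords[i]) ** 2).sum(1)
        d2[i] = np.inf
        j = int(np.argmin(d2))
        delta[i] = x[j] - x[i]
        disp = vector_field(delta, x, coords, k=5)
        direction = coords[j] - coords[i]
        assert disp[i] @ direction > 0

    def test_displacement_linear_in_coordinates(self):
        rng = np.random.default_rng(3)
        coords = self._coords()
        x = rng.random((20, 10))
        delta = rng.normal(size=(20, 10))
        a = vector_field(delta, x, coords, k=4)
        b = vector_field(delta, x, 2 * coords, k=4)
        np.testing.assert_allclose(b, 2 * a, atol=1e-10)

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="below"):
            vector_field(np.zeros((5, 2)), np.zeros((5, 2)),
                         self._coords(5), k=5)
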