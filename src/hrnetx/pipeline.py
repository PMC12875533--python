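"""End-to-end pipeline: simulate, label, train, evaluate, downstream.

Every stage reads and writes plain-text artifacts in a run directory, is
deterministic given the global seed, and records a stamp of the config it
ran with; re-running a completed stage with an identical config is a
no-op unless forced. Stage order and dependencies:

    simulate -> train -> {eval, drivers, predict_expression, perturb,
                          pert_targets, cocre}
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import time

import numpy as np
import pandas as pd

from . import biostreamnet as bsn
from . import cocre as cocre_mod
from . import mrwr
from .hegt import EncoderConfig
from .io_graph import HeteroRegGraph, NodeSet, export_hrnet, \
    import_hrnet, read_cre_bed, read_edge_list, read_feature_matrix, \
    write_cre_bed, write_edge_list, write_feature_matrix
from .pseudo_labels import EdgeLabelSet, build_labels, edge_correlations, \
    split_labels
from .synthetic import SyntheticSpec, generate
from .training import LossConfig, RetentionConfig, build_hrnet, \
    ensemble_attention, ensemble_candidate_probabilities, \
    ensemble_label_probabilities, train

DEFAULT_CONFIG = {
    "seed": 7,
    "out_dir": "run",
    "synthetic": {f: getattr(SyntheticSpec, f)
                  for f in ("n_tf", "n_cre", "n_tg", "n_metacells",
                            "n_clusters", "noise_sd", "decoy_multiplier")},
    "labels": {
        "pcc_threshold": {"tf_cre": 0.3, "cre_cre": 0.3},
        "neg_ratio": 5.0,
        "holdout_fraction": 0.2,
        "split": [0.8, 0.1, 0.1],
    },
    "encoder": {"embedding_dim": 16, "hidden_dim": 32, "layers": 2,
                "heads": 2, "dropout": 0.0, "tf_tf_encoder": "gcn",
                "sage_aggregator": "mean", "gate_mode": "signed",
                "gcn_activation": "tanh", "init": "random"},
    "training": {"lam": 0.5, "lr": 1e-3, "weight_decay": 1e-5,
                 "epochs": 300, "patience": 60, "restarts": 5,
                 "resample_negatives": True},
    "retention": {"tf_cre_prob": 0.8, "cre_cre_top_frac": 0.02},
    "mrwr": {"beta": 0.3, "within_layer_weight": 0.5, "tol": 1e-8,
             "max_iter": 1000},
    "biostreamnet": {"epochs": 400, "lr": 5e-3, "test_fraction": 0.25,
                     "acc_dropout": 0.3, "gene_net_threshold": 0.15,
                     "max_genes": 20},
    "cocre": {"n_network": 100, "n_module": 100, "n_degree": 50,
              "n_perm": 1000},
    "vector_field": {"k": 15},
}

STAGES = ("simulate", "train", "eval", "drivers", "predict_expression",
          "perturb", "pert_targets", "cocre")
_STAGE_DEPS = {
    "simulate": (),
    "train": ("simulate",),
    "eval": ("train",),
    "drivers": ("train",),
    "predict_expression": ("train",),
    "perturb": ("train",),
    "pert_targets": ("train",),
    "cocre": ("train",),
}


def make_config(overrides: dict | None = None) -> dict:
    """Defaults merged with overrides; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base, over, path=""):
        for key, val in over.items():
            if key not in base:
                raise KeyError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict) and isinstance(val, dict):
                merge(base[key], val, path + key + ".")
            else:
                base[key] = val

    if overrides:
        merge(cfg, overrides)
    return cfg


def _dump_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def prepare_labels(graph: HeteroRegGraph, feats, label_cfg: dict,
                   seed: int):
    """Hold out candidates, pseudo-label the rest, split for training.

    A seeded fraction of each labeled edge type's candidates is held out
    of the labeling entirely (for candidate-level evaluation); labels are
    built from the remainder and split train/val/test. Returns
    ``(labels, heldout)``.
    """
    rng = np.random.default_rng(seed + 11)
    labels, heldout = {}, {}
    feat_of = {"TF-CRE": ("TF", "CRE"), "CRE-CRE": ("CRE", "CRE")}
    thr_key = {"TF-CRE": "tf_cre", "CRE-CRE": "cre_cre"}
    for etype, (fa, fb) in feat_of.items():
        cands = graph.edges[etype]
        n = len(cands)
        mask = np.ones(n, dtype=bool)
        n_hold = int(round(label_cfg["holdout_fraction"] * n))
        hold_idx = rng.choice(n, size=n_hold, replace=False)
        mask[hold_idx] = False
        pool = cands.subset(mask)
        heldout[etype] = cands.subset(~mask)
        pcc = edge_correlations(feats[fa], feats[fb], pool)
        st, tt = etype.split("-")
        lab = build_labels(
            pcc, pool, label_cfg["pcc_threshold"][thr_key[etype]],
            label_cfg["neg_ratio"], seed + 13,
            (graph.nodes[st], graph.nodes[tt]),
            exclude=cands.pair_set())
        tr, va, te = split_labels(lab, tuple(label_cfg["split"]),
                                  seed + 17)
        labels[etype] = {"train": tr, "val": va, "test": te}
    return labels, heldout


class Pipeline:
    """Stage runner bound to one run directory."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.out = cfg["out_dir"]
        os.makedirs(self.out, exist_ok=True)
        self.fixture_dir = os.path.join(self.out, "fixture")
        self.hrnet_dir = os.path.join(self.out, "hrnet")
        self.log_path = os.path.join(self.out, "pipeline.log")

    # -- plumbing ------------------------------------------------------
    def _log(self, msg: str):
        with open(self.log_path, "a") as fh:
            fh.write(msg + "\n")

    def _stamp_path(self, stage):
        return os.path.join(self.out, f".{stage}.stamp")

    def _is_done(self, stage) -> bool:
        p = self._stamp_path(stage)
        return os.path.exists(p) and open(p).read().strip() \
            == _config_hash(self.cfg)

    def _mark_done(self, stage):
        with open(self._stamp_path(stage), "w") as fh:
            fh.write(_config_hash(self.cfg))

    def run(self, stages=None, force: bool = False):
        stages = list(stages or STAGES)
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            for dep in _STAGE_DEPS[stage]:
                if not self._is_done(dep) and dep not in stages[
                        :stages.index(stage)]:
                    raise RuntimeError(
                        f"stage {stage!r} requires {dep!r}; run it first")
        _dump_json(self.cfg, os.path.join(self.out, "config.json"))
        for stage in stages:
            if self._is_done(stage) and not force:
                self._log(f"{stage}: up to date, skipped")
                continue
            t0 = time.time()
            getattr(self, "stage_" + stage)()
            self._mark_done(stage)
            self._log(f"{stage}: done in {time.time() - t0:.1f}s")
        return self.out

    # -- fixture I/O ---------------------------------------------------
    def _load_fixture(self):
        d = self.fixture_dir
        cre_nodes = read_cre_bed(os.path.join(d, "cres.bed"))
        feats = {}
        for nt, role in (("TF", "TF_expr"), ("CRE", "CRE_acc"),
                         ("TG", "TG_expr")):
            feats[nt] = read_feature_matrix(
                os.path.join(d, f"{nt.lower()}_matrix.tsv"),
                os.path.join(d, f"{nt.lower()}_rows.txt"),
                os.path.join(d, f"{nt.lower()}_cols.txt"), role)
        nodes = {
            "TF": NodeSet("TF", list(feats["TF"].node_ids)),
            "CRE": NodeSet("CRE", list(cre_nodes.ids), cre_nodes.intervals),
            "TG": NodeSet("TG", list(feats["TG"].node_ids)),
        }
        edges = {}
        for etype in ("TF-TF", "TF-CRE", "CRE-CRE", "CRE-TG", "TG-TG"):
            fname = "prior_" + etype.lower().replace("-", "_") + ".tsv"
            edges[etype] = read_edge_list(os.path.join(d, fname), etype,
                                          header=True)
        graph = HeteroRegGraph(nodes, edges)
        degs = pd.read_csv(os.path.join(d, "degs.tsv"), sep="\t")
        return graph, feats, degs

    def _load_truth(self, etype):
        fname = "truth_" + etype.lower().replace("-", "_") + ".tsv"
        return read_edge_list(os.path.join(self.fixture_dir, fname), etype,
                              header=True)

    # -- stages --------------------------------------------------------
    def stage_simulate(self):
        cfg = self.cfg
        spec = SyntheticSpec(seed=cfg["seed"], **cfg["synthetic"])
        data = generate(spec)
        d = self.fixture_dir
        os.makedirs(d, exist_ok=True)
        write_cre_bed(data.graph.nodes["CRE"], os.path.join(d, "cres.bed"))
        for nt in ("TF", "CRE", "TG"):
            write_feature_matrix(
                data.features[nt],
                os.path.join(d, f"{nt.lower()}_matrix.tsv"),
                os.path.join(d, f"{nt.lower()}_rows.txt"),
                os.path.join(d, f"{nt.lower()}_cols.txt"))
        for etype, eset in data.graph.edges.items():
            fname = "prior_" + etype.lower().replace("-", "_") + ".tsv"
            write_edge_list(eset, os.path.join(d, fname))
        for etype, eset in data.truth.items():
            fname = "truth_" + etype.lower().replace("-", "_") + ".tsv"
            write_edge_list(eset, os.path.join(d, fname))
        data.deg_table.to_csv(os.path.join(d, "degs.tsv"), sep="\t",
                              index=False, float_format="%.8g")
        data.loci.to_csv(os.path.join(d, "loci.bed"), sep="\t", index=False,
                         header=False)
        data.tss.to_csv(os.path.join(d, "tss.tsv"), sep="\t", index=False)
        np.savetxt(os.path.join(d, "embedding.tsv"), data.embedding,
                   delimiter="\t", fmt="%.8g")
        np.savetxt(os.path.join(d, "clusters.txt"),
                   data.clusters, fmt="%d")
        meta = {"master_tfs": {str(k): v for k, v in data.master_tfs.items()},
                "hub_cres": data.hub_cres}
        _dump_json(meta, os.path.join(d, "meta.json"))

    def _prepare_labels(self, graph, feats):
        return prepare_labels(graph, feats, self.cfg["labels"],
                              self.cfg["seed"])

    def stage_train(self):
        graph, feats, _ = self._load_fixture()
        labels, heldout = self._prepare_labels(graph, feats)
        tcfg = self.cfg["training"]
        loss_cfg = LossConfig(seed=self.cfg["seed"], **tcfg)
        enc_cfg = EncoderConfig(**{k: v for k, v in
                                   self.cfg["encoder"].items()
                                   if k != "hidden_dim"},
                                hidden_dim=self.cfg["encoder"]["hidden_dim"])
        result = train(graph, feats, labels, loss_cfg, enc_cfg)

        # shuffled-label control: identical training on label sets whose
        # positive/negative membership is permuted (seeded)
        sh_rng = np.random.default_rng(self.cfg["seed"] + 101)
        sh_labels = {}
        for etype, parts in labels.items():
            sh_parts = {}
            for part, lab in parts.items():
                pairs = lab.pairs
                k = len(lab.positives)
                idx = sh_rng.permutation(len(pairs))
                sh_parts[part] = EdgeLabelSet(
                    etype, [pairs[i] for i in idx[:k]],
                    [pairs[i] for i in idx[k:]])
            sh_labels[etype] = sh_parts
        ctl_cfg = LossConfig(seed=self.cfg["seed"],
                             **{**tcfg, "resample_negatives": False})
        control = train(graph, feats, sh_labels, ctl_cfg, enc_cfg)

        # held-out labels (val + test, unseen by gradient training)
        # scored by both models with ensemble-averaged probabilities
        for etype in ("TF-CRE", "CRE-CRE"):
            va, te = labels[etype]["val"], labels[etype]["test"]
            lab = EdgeLabelSet(etype, va.positives + te.positives,
                               va.negatives + te.negatives)
            df = pd.DataFrame(lab.pairs, columns=["source", "target"])
            df["pseudo_y"] = lab.y.astype(int)
            df["score"] = ensemble_label_probabilities(
                graph, feats, result, lab)
            df["score_shuffled_control"] = ensemble_label_probabilities(
                graph, feats, control, lab)
            fname = etype.lower().replace("-", "_") + "_label_test.tsv"
            df.to_csv(os.path.join(self.out, fname), sep="\t",
                      index=False, float_format="%.6f")
        hrnet = build_hrnet(graph, feats, result,
                            RetentionConfig(**self.cfg["retention"]))
        export_hrnet(hrnet, self.hrnet_dir)

        # per-candidate scores for later evaluation
        ens_att = ensemble_attention(graph, feats, result)
        for etype in ("TF-CRE", "CRE-CRE"):
            probs = ensemble_candidate_probabilities(graph, feats,
                                                     result, etype)
            att = ens_att.get(etype)
            held = heldout[etype].pair_set()
            df = pd.DataFrame(graph.edges[etype].pairs,
                              columns=["source", "target"])
            df["probability"] = probs
            if att is not None:
                df["attention"] = att
            df["heldout"] = [int(p in held)
                             for p in graph.edges[etype].pairs]
            fname = etype.lower().replace("-", "_") + "_scores.tsv"
            df.to_csv(os.path.join(self.out, fname), sep="\t", index=False,
                      float_format="%.6f")
        metrics = {
            "best_val_aupr": result.best_val_aupr,
            "best_epoch": result.best_epoch,
            "epochs_run": len(result.log),
            "final_train_loss": result.log[-1]["train_loss"],
            "hrnet_edges": {et: len(es) for et, es in hrnet.layers.items()},
        }
        _dump_json(metrics, os.path.join(self.out, "train_metrics.json"))
        pd.DataFrame(result.log).to_csv(
            os.path.join(self.out, "training_log.tsv"), sep="\t",
            index=False, float_format="%.6f")

    def stage_eval(self):
        """Held-out planted-edge recovery of the trained edge scores."""
        from .evaluation import aupr_auc, max_f1, precision_at_n

        metrics = {}
        # primary protocol: planted-edge recovery on the held-out label
        # test split, against the shuffled-label control
        for etype in ("TF-CRE", "CRE-CRE"):
            fname = etype.lower().replace("-", "_") + "_label_test.tsv"
            df = pd.read_csv(os.path.join(self.out, fname), sep="\t")
            truth_pairs = self._load_truth(etype).pair_set()
            truth = np.array([(s, t) in truth_pairs for s, t in
                              zip(df["source"], df["target"])]).astype(int)
            if truth.sum() in (0, len(truth)):
                continue
            aupr, auroc = aupr_auc(df["score"].to_numpy(), truth)
            ctl_aupr, _ = aupr_auc(
                df["score_shuffled_control"].to_numpy(), truth)
            prev = float(truth.mean())
            key = etype.lower().replace("-", "_")
            metrics[key + "_label_test"] = {
                "planted_aupr": aupr,
                "planted_auroc": auroc,
                "prevalence": prev,
                "aupr_over_prevalence": aupr / prev,
                "shuffled_control_aupr": ctl_aupr,
            }
        # secondary: ranking within the never-labeled candidate holdout
        for etype in ("TF-CRE", "CRE-CRE"):
            fname = etype.lower().replace("-", "_") + "_scores.tsv"
            df = pd.read_csv(os.path.join(self.out, fname), sep="\t")
            truth_pairs = self._load_truth(etype).pair_set()
            df["planted"] = [
                int((s, t) in truth_pairs)
                for s, t in zip(df["source"], df["target"])]
            held = df[df["heldout"] == 1]
            if held["planted"].nunique() < 2:
                continue
            scores = held["probability"].to_numpy()
            truth = held["planted"].to_numpy()
            aupr, auroc = aupr_auc(scores, truth)
            prevalence = float(truth.mean())
            key = etype.lower().replace("-", "_")
            metrics[key] = {
                "heldout_aupr": aupr,
                "heldout_auroc": auroc,
                "prevalence": prevalence,
                "aupr_over_prevalence": aupr / prevalence,
                "max_f1": max_f1(scores, truth),
                "precision_at_50": precision_at_n(
                    scores, truth, [min(50, len(held))])[
                        min(50, len(held))],
            }
        _dump_json(metrics, os.path.join(self.out, "eval_metrics.json"))

    def _hrnet(self):
        hrnet = import_hrnet(self.hrnet_dir)
        graph, _, _ = self._load_fixture()
        hrnet.nodes = graph.nodes
        return hrnet, graph

    def stage_drivers(self):
        hrnet, _ = self._hrnet()
        degs = pd.read_csv(os.path.join(self.fixture_dir, "degs.tsv"),
                           sep="\t")
        mcfg = self.cfg["mrwr"]
        out = {}
        for clu in sorted(degs["cluster"].unique()):
            sub = degs[degs["cluster"] == clu]
            ranked = mrwr.mrwr_cts(hrnet, sub, target_layer="TF",
                                   beta=mcfg["beta"],
                                   within_layer_weight=mcfg[
                                       "within_layer_weight"],
                                   tol=mcfg["tol"],
                                   max_iter=mcfg["max_iter"])
            ranked.to_csv(os.path.join(self.out,
                                       f"drivers_cluster{clu}.tsv"),
                          sep="\t", index=False, float_format="%.8g")
            out[f"cluster_{clu}_top3"] = list(ranked["node"].head(3))
        meta = json.load(open(os.path.join(self.fixture_dir, "meta.json")))
        hits = sum(meta["master_tfs"][str(c)] in out[f"cluster_{c}_top3"]
                   for c in range(len(meta["master_tfs"])))
        out["planted_master_in_top3"] = hits
        _dump_json(out, os.path.join(self.out, "driver_metrics.json"))

    def stage_pert_targets(self, tf: str | None = None):
        hrnet, graph = self._hrnet()
        mcfg = self.cfg["mrwr"]
        meta = json.load(open(os.path.join(self.fixture_dir, "meta.json")))
        tf = tf or meta["master_tfs"]["0"]
        ranked = mrwr.mrwr_pert(hrnet, tf, beta=mcfg["beta"],
                                within_layer_weight=mcfg[
                                    "within_layer_weight"],
                                tol=mcfg["tol"], max_iter=mcfg["max_iter"])
        ranked.to_csv(os.path.join(self.out, f"pert_targets_{tf}.tsv"),
                      sep="\t", index=False, float_format="%.8g")

    def _fit_gene(self, hrnet, feats, gene, seed):
        bcfg = self.cfg["biostreamnet"]
        net = bsn.build_masks(hrnet, gene)
        return bsn.fit(net, feats["TF"], feats["CRE"], feats["TG"],
                       epochs=bcfg["epochs"], lr=bcfg["lr"],
                       test_fraction=bcfg["test_fraction"], seed=seed,
                       acc_dropout=bcfg["acc_dropout"])

    def stage_predict_expression(self):
        hrnet, graph = self._hrnet()
        _, feats, _ = self._load_fixture()
        predictable = sorted({t for _, t in
                              hrnet.layers["CRE-TG"].pairs})
        genes = predictable[: self.cfg["biostreamnet"]["max_genes"]]
        rows = []
        for gene in genes:
            net = self._fit_gene(hrnet, feats, gene, self.cfg["seed"] + 23)
            rows.append((gene, net.test_pcc, net.n_mask_weights()))
        df = pd.DataFrame(rows, columns=["gene", "test_pcc", "n_weights"])
        df.to_csv(os.path.join(self.out, "expression_pcc.tsv"), sep="\t",
                  index=False, float_format="%.6f")
        _dump_json({"median_test_pcc": float(df["test_pcc"].median()),
                    "n_genes": len(df)},
                   os.path.join(self.out, "expression_metrics.json"))

    def stage_perturb(self, targets=None, gene=None):
        hrnet, graph = self._hrnet()
        _, feats, _ = self._load_fixture()
        meta = json.load(open(os.path.join(self.fixture_dir, "meta.json")))
        tf = meta["master_tfs"]["0"]
        targets = targets or [(tf, "TF", 0.0)]
        if gene is None:
            # first gene reachable from the perturbed TF via TF-CRE -> CRE-TG
            tf_cres = {t for s, t in hrnet.layers["TF-CRE"].pairs
                       if s == targets[0][0]}
            reachable = sorted(t for s, t in hrnet.layers["CRE-TG"].pairs
                               if s in tf_cres)
            gene = reachable[0] if reachable else sorted(
                {t for _, t in hrnet.layers["CRE-TG"].pairs})[0]
        net = self._fit_gene(hrnet, feats, gene, self.cfg["seed"] + 29)
        delta = bsn.perturb_predict(net, feats["TF"], feats["CRE"],
                                    bsn.Perturbation(targets))
        np.savetxt(os.path.join(self.out, f"perturb_delta_{gene}.tsv"),
                   delta, delimiter="\t", fmt="%.8g")

    def stage_cocre(self):
        hrnet, graph = self._hrnet()
        ccfg = self.cfg["cocre"]
        cre_edges = hrnet.layers["CRE-CRE"]
        partition = cocre_mod.louvain_modules(cre_edges,
                                              seed=self.cfg["seed"])
        hubs = cocre_mod.extract_hubs(cre_edges, partition,
                                      ccfg["n_network"], ccfg["n_module"],
                                      ccfg["n_degree"])
        loci = pd.read_csv(os.path.join(self.fixture_dir, "loci.bed"),
                           sep="\t", header=None,
                           names=["chrom", "start", "end"])
        enrich = cocre_mod.locus_enrichment(
            hubs.network_hubs, loci, graph.nodes["CRE"],
            n_perm=ccfg["n_perm"], seed=self.cfg["seed"])
        meta = json.load(open(os.path.join(self.fixture_dir, "meta.json")))
        planted_enrich = cocre_mod.locus_enrichment(
            meta["hub_cres"], loci, graph.nodes["CRE"],
            n_perm=ccfg["n_perm"], seed=self.cfg["seed"])
        tss = pd.read_csv(os.path.join(self.fixture_dir, "tss.tsv"),
                          sep="\t")
        hcgs = cocre_mod.assign_hcg(hubs.degree_hubs, graph.nodes["CRE"],
                                    tss)
        pd.DataFrame(sorted(partition.module_of.items()),
                     columns=["cre", "module"]).to_csv(
            os.path.join(self.out, "cocre_modules.tsv"), sep="\t",
            index=False)
        _dump_json({
            "n_modules": partition.n_modules,
            "modularity": partition.modularity,
            "n_network_hubs": len(hubs.network_hubs),
            "n_module_hubs": len(hubs.module_hubs),
            "n_degree_hubs": len(hubs.degree_hubs),
            "network_hub_enrichment": enrich,
            "planted_hub_enrichment": planted_enrich,
            "n_hcgs": len(hcgs),
        }, os.path.join(self.out, "cocre_metrics.json"))


def run_pipeline(cfg: dict, stages=None, force: bool = False) -> str:
    """Run the requested stages (all by default); returns the run dir."""
    return Pipeline(cfg).run(stages=stages, force=force)
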