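"""Seeded generator of a ground-truth hierarchical regulatory system.

The generator plants a causal TF -> CRE -> TG hierarchy and samples
metacell matrices from it, so every stage of the pipeline can be tested
against known structure without external data:

* metacells belong to one of ``n_clusters`` states; TF expression is
  cluster-specific lognormal, with one designated master TF per cluster
  strongly upregulated in its own cluster;
* CRE accessibility is a logistic function of the (standardized)
  expression of the CRE's planted regulator TFs, coupled across planted
  CRE-CRE pairs by averaging, plus Gaussian noise, clipped to [0, 1];
* TG expression is a linear combination of planted CRE accessibilities
  (intercept chosen so values stay non-negative) plus noise;
* each cluster's master TF drives a dedicated block of CREs that in turn
  drive a dedicated block of TGs — the cluster's differential-expression
  program, recovered by rank-sum tests with Benjamini-Hochberg FDR;
* candidate prior edge lists are the planted edges plus seeded decoys;
* loci (GWAS-like intervals) are planted inside a designated hub CRE
  subset; a 2-D embedding comes from a PCA of TG expression; a TSS table
  places every gene on a small synthetic genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_graph import FeatureMatrix, HeteroRegGraph, NodeSet, TypedEdgeSet


@dataclass
class SyntheticSpec:
    n_tf: int = 20
    n_cre: int = 200
    n_tg: int = 100
    n_metacells: int = 200
    n_clusters: int = 3
    #: CREs / TGs dedicated to each cluster's master-TF program
    master_cres_per_cluster: int = 10
    master_tgs_per_cluster: int = 8
    tf_tf_density: float = 0.08
    tg_tg_density: float = 0.03
    max_tfs_per_cre: int = 2
    max_cres_per_tg: int = 3
    #: |weight| range for planted regulatory edges; sign drawn separately
    effect_low: float = 0.8
    effect_high: float = 1.6
    positive_fraction: float = 0.8
    #: latent cell-state factors driving within-cluster covariation
    n_latent_factors: int = 4
    latent_sd: float = 0.35
    noise_sd: float = 0.3
    decoy_multiplier: float = 5.0
    cre_tg_decoy_multiplier: float = 2.0
    seed: int = 7

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.decoy_multiplier < 1 or self.cre_tg_decoy_multiplier < 1:
            raise ValueError("decoy multipliers must be >= 1")
        if not (0 < self.tf_tf_density <= 1 and 0 < self.tg_tg_density <= 1):
            raise ValueError("densities must lie in (0, 1]")
        if self.n_clusters * self.master_cres_per_cluster > self.n_cre:
            raise ValueError("more master CREs than CREs")
        if self.n_clusters * self.master_tgs_per_cluster > self.n_tg:
            raise ValueError("more master TGs than TGs")
        if self.n_clusters > self.n_tf:
            raise ValueError("need one master TF per cluster")


@dataclass
class SyntheticDataset:
    graph: HeteroRegGraph                      # candidate priors incl. decoys
    features: dict[str, FeatureMatrix]
    truth: dict[str, TypedEdgeSet]             # planted edges with weights
    deg_table: pd.DataFrame
    loci: pd.DataFrame
    embedding: np.ndarray                      # metacell x 2
    tss: pd.DataFrame
    clusters: np.ndarray                       # cluster id per metacell
    master_tfs: dict[int, str]
    hub_cres: list[str]
    spec: SyntheticSpec = field(default=None)


def _random_undirected(ids, density, rng) -> list[tuple[str, str]]:
    n = len(ids)
    pairs = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    k = int(round(density * len(pairs)))
    take = rng.choice(len(pairs), size=k, replace=False)
    return [pairs[i] for i in sorted(take)]


def _decoys(rng, src_ids, tgt_ids, planted: set, n: int,
            undirected: bool = False) -> list[tuple[str, str]]:
    total = len(src_ids) * (len(src_ids) - 1) // 2 if undirected \
        else len(src_ids) * len(tgt_ids)
    if n > total - len(planted):
        raise ValueError(
            f"infeasible densities: {n} decoys requested but only "
            f"{total - len(planted)} non-planted pairs exist")
    out, seen = [], set(planted)
    while len(out) < n:
        s = src_ids[rng.integers(len(src_ids))]
        t = tgt_ids[rng.integers(len(tgt_ids))]
        if undirected:
            if s == t:
                continue
            if s > t:
                s, t = t, s
        if (s, t) in seen:
            continue
        seen.add((s, t))
        out.append((s, t))
    return out


def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Sample one complete synthetic regulatory system (seeded)."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n_clu = spec.n_clusters

    tf_ids = [f"TF{i:03d}" for i in range(spec.n_tf)]
    tg_ids = [f"TG{i:03d}" for i in range(spec.n_tg)]
    master_tfs = {c: tf_ids[c] for c in range(n_clu)}

    # ---- genome layout: one chromosome per cluster-ish arm -----------
    chroms = [f"chr{c + 1}" for c in range(max(3, n_clu))]
    tss_rows = []
    tg_chrom, tg_tss = {}, {}
    for i, g in enumerate(tg_ids):
        chrom = chroms[i % len(chroms)]
        pos = 1_000_000 + (i // len(chroms)) * 600_000
        tg_chrom[g], tg_tss[g] = chrom, pos
        tss_rows.append((g, chrom, pos))
    for i, g in enumerate(tf_ids):
        chrom = chroms[i % len(chroms)]
        pos = 60_000_000 + (i // len(chroms)) * 400_000
        tss_rows.append((g, chrom, pos))
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss"])

    # ---- planted wiring ----------------------------------------------
    n_master_cre = spec.master_cres_per_cluster
    n_master_tg = spec.master_tgs_per_cluster
    master_cre_idx = {c: list(range(c * n_master_cre, (c + 1) * n_master_cre))
                      for c in range(n_clu)}
    master_tg_idx = {c: list(range(c * n_master_tg, (c + 1) * n_master_tg))
                    for c in range(n_clu)}
    all_master_cres = [i for c in range(n_clu) for i in master_cre_idx[c]]

    def effect(sign_positive_prob=None):
        mag = rng.uniform(spec.effect_low, spec.effect_high)
        p = spec.positive_fraction if sign_positive_prob is None \
            else sign_positive_prob
        return mag if rng.random() < p else -mag

    # TF -> CRE weights (n_tf x n_cre)
    w_tc = np.zeros((spec.n_tf, spec.n_cre))
    for c in range(n_clu):
        for j in master_cre_idx[c]:
            w_tc[c, j] = rng.uniform(spec.effect_low, spec.effect_high)
    free_tfs = list(range(n_clu, spec.n_tf))
    for j in range(spec.n_cre):
        if j in all_master_cres:
            continue
        k = rng.integers(1, spec.max_tfs_per_cre + 1)
        for i in rng.choice(free_tfs, size=min(k, len(free_tfs)),
                            replace=False):
            w_tc[i, j] = effect()

    # CRE -> TG weights (n_cre x n_tg)
    w_ct = np.zeros((spec.n_cre, spec.n_tg))
    for c in range(n_clu):
        for g in master_tg_idx[c]:
            picks = rng.choice(master_cre_idx[c], size=2, replace=False)
            for j in picks:
                w_ct[j, g] = rng.uniform(spec.effect_low, spec.effect_high)
    master_tg_set = {g for c in range(n_clu) for g in master_tg_idx[c]}
    for g in range(spec.n_tg):
        if g in master_tg_set:
            continue
        k = rng.integers(1, spec.max_cres_per_tg + 1)
        for j in rng.choice(spec.n_cre, size=k, replace=False):
            w_ct[j, g] = effect()

    # CRE intervals near the TSS of a TG they regulate
    cre_ids, cre_intervals = [], {}
    width = 800
    for j in range(spec.n_cre):
        targets = np.flatnonzero(w_ct[j])
        if len(targets):
            g = tg_ids[targets[0]]
            chrom = tg_chrom[g]
            center = tg_tss[g] + int(rng.integers(-400_000, 400_000))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            center = int(rng.integers(2_000_000, 50_000_000))
        start = max(0, center - width // 2) + j  # +j keeps ids unique
        nid = f"{chrom}:{start}-{start + width}"
        cre_ids.append(nid)
        cre_intervals[nid] = (chrom, start, start + width)

    # planted CRE-CRE pairs: chained master CREs + CREs sharing a TG
    cc_pairs: set[tuple[int, int]] = set()
    for c in range(n_clu):
        idxs = master_cre_idx[c]
        for a, b in zip(idxs[:-1], idxs[1:]):
            cc_pairs.add((min(a, b), max(a, b)))
    for g in range(spec.n_tg):
        regs = np.flatnonzero(w_ct[:, g])
        for ai in range(len(regs)):
            for bi in range(ai + 1, len(regs)):
                a, b = int(regs[ai]), int(regs[bi])
                cc_pairs.add((min(a, b), max(a, b)))

    # ---- sampling ----------------------------------------------------
    n_cells = spec.n_metacells
    clusters = np.arange(n_cells) % n_clu
    # cluster-specific lognormal expression: each TF has a per-cluster
    # mean; within-cluster covariation follows a few latent cell-state
    # factors (metacells vary along a low-dimensional state manifold),
    # plus independent per-cell noise
    base_mu = rng.normal(1.0, 0.3, size=spec.n_tf)
    cluster_shift = rng.normal(0.0, 0.5, size=(n_clu, spec.n_tf))
    # a master TF's cluster profile is its upregulation in its own
    # cluster; random shifts would dilute that identity
    cluster_shift[:, :n_clu] = 0.0
    mu = base_mu[None, :] + cluster_shift[clusters]
    latent = rng.normal(size=(n_cells, spec.n_latent_factors))
    loading = rng.normal(0.0, spec.latent_sd,
                         size=(spec.n_latent_factors, spec.n_tf))
    log_expr = mu + latent @ loading + rng.normal(
        0.0, 0.2, size=(n_cells, spec.n_tf))
    for c in range(n_clu):
        log_expr[clusters == c, c] += np.log(4.0)  # master TF upregulated
    tf_expr = np.exp(log_expr)

    z = (log_expr - log_expr.mean(axis=0)) / log_expr.std(axis=0)
    logits = z @ w_tc  # (cells x cre)
    acc_raw = 1.0 / (1.0 + np.exp(-logits))
    # couple linked CREs by averaging partner accessibility
    partners: dict[int, list[int]] = {}
    for a, b in cc_pairs:
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)
    acc = acc_raw.copy()
    for j, ps in partners.items():
        acc[:, j] = 0.5 * acc_raw[:, j] + 0.5 * acc_raw[:, ps].mean(axis=1)
    if spec.noise_sd > 0:
        acc = acc + rng.normal(0, spec.noise_sd, size=acc.shape)
    acc = np.clip(acc, 0.0, 1.0)

    # intercept = -(sum of negative weights) keeps expression >= 0
    intercept = -w_ct.clip(max=0).sum(axis=0)
    tg_expr = acc @ w_ct + intercept[None, :]
    if spec.noise_sd > 0:
        tg_expr = tg_expr + rng.normal(0, spec.noise_sd, size=tg_expr.shape)
    tg_expr = np.clip(tg_expr, 0.0, None)

    # ---- DEG table (rank-sum + BH per cluster) -----------------------
    # both TGs and TFs are tested: cluster-specific TFs carry the
    # differential-expression weights of the driver-ranking walks
    deg_rows = []
    eps = 1e-6
    all_expr = np.concatenate([tg_expr, tf_expr], axis=1)
    all_genes = tg_ids + tf_ids
    detected = all_expr > all_expr.mean(axis=0)[None, :]
    for c in range(n_clu):
        in_c = clusters == c
        pvals, stats_rows = [], []
        for g in range(all_expr.shape[1]):
            a, b = all_expr[in_c, g], all_expr[~in_c, g]
            p = ranksums(a, b).pvalue
            l2fc = np.log2((a.mean() + eps) / (b.mean() + eps))
            pct1 = detected[in_c, g].mean()
            pct2 = detected[~in_c, g].mean()
            pvals.append(p)
            stats_rows.append((all_genes[g], c, l2fc, pct1, pct2))
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for (g, clu, l2fc, p1, p2), q in zip(stats_rows, fdr):
            deg_rows.append((g, clu, l2fc, q, p1, p2))
    deg_table = pd.DataFrame(
        deg_rows, columns=["gene", "cluster", "log2FC", "FDR", "pct1",
                           "pct2"])

    # ---- candidate priors: planted + decoys --------------------------
    planted_tc = [(tf_ids[i], cre_ids[j], w_tc[i, j])
                  for i, j in zip(*np.nonzero(w_tc))]
    planted_ct = [(cre_ids[j], tg_ids[g], w_ct[j, g])
                  for j, g in zip(*np.nonzero(w_ct))]
    planted_cc = sorted(
        (min(cre_ids[a], cre_ids[b]), max(cre_ids[a], cre_ids[b]))
        for a, b in cc_pairs)

    tc_set = {(s, t) for s, t, _ in planted_tc}
    ct_set = {(s, t) for s, t, _ in planted_ct}
    cc_set = set(planted_cc)
    n_tc_dec = int(round((spec.decoy_multiplier - 1) * len(tc_set)))
    n_cc_dec = int(round((spec.decoy_multiplier - 1) * len(cc_set)))
    n_ct_dec = int(round((spec.cre_tg_decoy_multiplier - 1) * len(ct_set)))
    cand_tc = sorted(tc_set) + _decoys(rng, tf_ids, cre_ids, tc_set, n_tc_dec)
    cand_cc = sorted(cc_set) + _decoys(rng, cre_ids, cre_ids, cc_set,
                                       n_cc_dec, undirected=True)
    cand_ct = sorted(ct_set) + _decoys(rng, cre_ids, tg_ids, ct_set, n_ct_dec)

    tf_tf = _random_undirected(tf_ids, spec.tf_tf_density, rng)
    tg_tg = _random_undirected(tg_ids, spec.tg_tg_density, rng)

    nodes = {
        "TF": NodeSet("TF", tf_ids),
        "CRE": NodeSet("CRE", cre_ids, cre_intervals),
        "TG": NodeSet("TG", tg_ids),
    }
    graph = HeteroRegGraph(nodes, {
        "TF-TF": TypedEdgeSet("TF-TF", tf_tf),
        "TF-CRE": TypedEdgeSet("TF-CRE", cand_tc),
        "CRE-CRE": TypedEdgeSet("CRE-CRE", cand_cc),
        "CRE-TG": TypedEdgeSet("CRE-TG", cand_ct),
        "TG-TG": TypedEdgeSet("TG-TG", tg_tg),
    })
    truth = {
        "TF-CRE": TypedEdgeSet("TF-CRE", [(s, t) for s, t, _ in planted_tc],
                               [w for _, _, w in planted_tc]),
        "CRE-CRE": TypedEdgeSet("CRE-CRE", planted_cc),
        "CRE-TG": TypedEdgeSet("CRE-TG", [(s, t) for s, t, _ in planted_ct],
                               [w for _, _, w in planted_ct]),
    }
    cell_ids = [f"mc{i:03d}" for i in range(n_cells)]
    features = {
        "TF": FeatureMatrix(tf_expr, cell_ids, tf_ids, "TF_expr"),
        "CRE": FeatureMatrix(acc, cell_ids, cre_ids, "CRE_acc"),
        "TG": FeatureMatrix(tg_expr, cell_ids, tg_ids, "TG_expr"),
    }

    # ---- loci planted in the designated hub subset -------------------
    hub_cres = [cre_ids[j] for j in all_master_cres]
    loci_rows = []
    for nid in hub_cres[: max(1, int(0.7 * len(hub_cres)))]:
        chrom, start, end = cre_intervals[nid]
        loci_rows.append((chrom, start + 100, start + 200))
    others = [c for c in cre_ids if c not in set(hub_cres)]
    bg = rng.choice(len(others), size=max(1, len(others) // 20),
                    replace=False)
    for k in sorted(bg):
        chrom, start, end = cre_intervals[others[k]]
        loci_rows.append((chrom, start + 100, start + 200))
    loci = pd.DataFrame(loci_rows, columns=["chrom", "start", "end"])

    embedding = PCA(n_components=2, random_state=0).fit_transform(tg_expr)

    return SyntheticDataset(graph, features, truth, deg_table, loci,
                            embedding, tss, clusters, master_tfs, hub_cres,
                            spec)
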