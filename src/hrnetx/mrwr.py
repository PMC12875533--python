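"""Multilayer random walk with restart over the HRNet.

Nodes of the three layers (TF, CRE, TG) form one multilayer state space.
The column-stochastic transition matrix W follows the HRNet edge weights;
at a node with both within-layer and cross-layer out-edges the walk mass
is split between the two groups (default 0.5/0.5) before edge-level
normalization. The stationary scores solve

    s = (1 - beta) W s + beta s0

with restart probability beta. Forward walks seeded at a TF rank its
perturbation targets among TGs; reverse walks seeded at a cluster's
differentially expressed genes (DEGs), with transition weights scaled by
differential expression, rank driver TFs or CREs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io_graph import HRNet

#: DEG filtering thresholds used before seeding the reverse walk
DEG_LOG2FC_MIN = 0.5
DEG_FDR_MAX = 0.01
DEG_PCT_DIFF_MIN = 0.3

_FORWARD_EDGES = (
    ("TF-TF", "TF", "TF", True),
    ("TF-CRE", "TF", "CRE", False),
    ("CRE-CRE", "CRE", "CRE", True),
    ("CRE-TG", "CRE", "TG", False),
)


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over the multilayer node set."""

    W: sp.csc_matrix
    node_ids: list[str]
    layers: np.ndarray          # layer name per node
    dangling: np.ndarray        # nodes with zero out-weight (bool)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def check(self, tol: float = 1e-9):
        col_sums = np.asarray(self.W.sum(axis=0)).ravel()
        bad = ~self.dangling & (np.abs(col_sums - 1.0) > tol)
        if bad.any():
            raise ValueError(
                f"{bad.sum()} non-dangling column(s) do not sum to 1")
        if (self.W.data < 0).any():
            raise ValueError("negative transition entries")


def filter_degs(degs: pd.DataFrame,
                log2fc_min: float = DEG_LOG2FC_MIN,
                fdr_max: float = DEG_FDR_MAX,
                pct_diff_min: float = DEG_PCT_DIFF_MIN) -> pd.DataFrame:
    """Apply the DEG thresholds (log2FC, FDR, pct1 - pct2)."""
    d = degs
    keep = (d["log2FC"] > log2fc_min) & (d["FDR"] < fdr_max) \
        & ((d["pct1"] - d["pct2"]) > pct_diff_min)
    return d.loc[keep]


def build_transition(hrnet: HRNet, direction: str = "forward",
                     within_layer_weight: float = 0.5,
                     deg_weights: pd.DataFrame | None = None
                     ) -> TransitionMatrix:
    """Column-stochastic transition matrix from the HRNet layers.

    ``forward`` walks TF -> CRE -> TG (within-layer TF-TF / CRE-CRE edges
    traversable in both directions); ``reverse`` transposes every block.
    With ``deg_weights`` each edge weight is multiplied by
    ``(1 + |log2FC|)`` of any DEG endpoint before normalization. Nodes
    with zero out-weight are flagged dangling; the solver redirects their
    mass to the restart distribution.
    """
    if direction not in {"forward", "reverse"}:
        raise ValueError(f"unknown direction {direction!r}")
    if hrnet.nodes is None:
        raise ValueError("HRNet must carry its node sets")
    node_ids, layers = [], []
    offset = {}
    for lt in ("TF", "CRE", "TG"):
        offset[lt] = len(node_ids)
        node_ids.extend(hrnet.nodes[lt].ids)
        layers.extend([lt] * len(hrnet.nodes[lt]))
    layers = np.asarray(layers)
    n = len(node_ids)
    index = {lt: hrnet.nodes[lt].index for lt in ("TF", "CRE", "TG")}

    fc = {}
    if deg_weights is not None:
        fc = {str(g): 1.0 + abs(float(f))
              for g, f in zip(deg_weights["gene"], deg_weights["log2FC"])}

    rows, cols, vals = [], [], []
    for etype, st, tt, undirected in _FORWARD_EDGES:
        eset = hrnet.layers.get(etype)
        if eset is None or len(eset) == 0:
            continue
        for (s, t), w in zip(eset.pairs, eset.weights):
            si = offset[st] + index[st][s]
            ti = offset[tt] + index[tt][t]
            w = float(w) * fc.get(s, 1.0) * fc.get(t, 1.0)
            if w <= 0:
                continue
            arcs = [(si, ti)]
            if undirected and si != ti:
                arcs.append((ti, si))
            for a, b in arcs:
                if direction == "reverse":
                    a, b = b, a
                rows.append(b)   # row = destination
                cols.append(a)   # column = source
                vals.append(w)

    raw = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    raw.sum_duplicates()

    # group-wise column normalization: within-layer vs cross-layer mass
    W = raw.tolil()
    dangling = np.zeros(n, dtype=bool)
    raw_csc = raw.tocsc()
    for j in range(n):
        start, end = raw_csc.indptr[j], raw_csc.indptr[j + 1]
        idx = raw_csc.indices[start:end]
        w = raw_csc.data[start:end].astype(float)
        if len(idx) == 0 or w.sum() <= 0:
            dangling[j] = True
            continue
        within = layers[idx] == layers[j]
        col = np.zeros(len(idx))
        if within.any() and (~within).any():
            col[within] = within_layer_weight * w[within] / w[within].sum()
            col[~within] = (1 - within_layer_weight) * w[~within] \
                / w[~within].sum()
        else:
            col = w / w.sum()
        for i, v in zip(idx, col):
            W[i, j] = v
    tm = TransitionMatrix(sp.csc_matrix(W), node_ids, layers, dangling)
    tm.check()
    return tm


def rwr_solve(tm: TransitionMatrix, s0: np.ndarray, beta: float = 0.3,
              tol: float = 1e-8, max_iter: int = 1000,
              method: str = "iterative") -> np.ndarray:
    """Stationary restart-walk scores.

    Iterates ``s <- (1 - beta)(W s + s0 * dangling_mass) + beta s0`` to an
    L1 residual below ``tol``; mass at dangling nodes restarts. The
    ``direct`` method solves the equivalent linear system
    ``s = beta (I - (1-beta) W')^{-1} s0`` with dangling columns replaced
    by the restart distribution, and serves as a cross-check.
    """
    s0 = np.asarray(s0, dtype=float)
    if (s0 < 0).any() or abs(s0.sum() - 1.0) > 1e-9:
        raise ValueError("s0 must be a probability distribution")
    if not (0 < beta <= 1):
        raise ValueError("beta must lie in (0, 1]")
    tm.check()
    W = tm.W

    if method == "direct":
        Wd = W.tolil(copy=True)
        for j in np.flatnonzero(tm.dangling):
            Wd[:, j] = s0[:, None]
        A = sp.eye(tm.n, format="csc") - (1 - beta) * sp.csc_matrix(Wd)
        s = spla.spsolve(A, beta * s0)
        return s / s.sum()

    s = s0.copy()
    for _ in range(max_iter):
        dangling_mass = s[tm.dangling].sum()
        s_new = (1 - beta) * (W @ s + dangling_mass * s0) + beta * s0
        s_new /= s_new.sum()
        if np.abs(s_new - s).sum() < tol:
            return s_new
        s = s_new
    return s


def _ranked(node_ids, scores, mask) -> pd.DataFrame:
    ids = [nid for nid, m in zip(node_ids, mask) if m]
    sc = scores[mask]
    order = sorted(range(len(ids)), key=lambda i: (-sc[i], ids[i]))
    return pd.DataFrame({"node": [ids[i] for i in order],
                         "score": [float(sc[i]) for i in order]})


def mrwr_pert(hrnet: HRNet, tf: str, beta: float = 0.3,
              within_layer_weight: float = 0.5, tol: float = 1e-8,
              max_iter: int = 1000) -> pd.DataFrame:
    """Forward walk from one TF; TG scores ranked descending.

    Ties are broken lexicographically by node id.
    """
    tm = build_transition(hrnet, "forward",
                          within_layer_weight=within_layer_weight)
    tf_index = hrnet.nodes["TF"].index
    if tf not in tf_index:
        raise KeyError(f"unknown TF {tf!r}")
    s0 = np.zeros(tm.n)
    s0[tf_index[tf]] = 1.0  # TF layer occupies the first positions
    s = rwr_solve(tm, s0, beta=beta, tol=tol, max_iter=max_iter)
    return _ranked(tm.node_ids, s, tm.layers == "TG")


def mrwr_cts(hrnet: HRNet, degs: pd.DataFrame, target_layer: str = "TF",
             beta: float = 0.3, within_layer_weight: float = 0.5,
             tol: float = 1e-8, max_iter: int = 1000,
             prefiltered: bool = False) -> pd.DataFrame:
    """Reverse DEG-seeded walk; driver scores for one layer, descending.

    ``degs`` must carry gene, log2FC, FDR, pct1, pct2 columns; rows are
    filtered by the standard thresholds unless ``prefiltered``. The seed
    distribution is uniform over filtered DEG genes present in the TG
    layer; transition weights and the final walk scores of the requested
    layer are both scaled by ``(1 + |log2FC|)`` of any filtered DEG node
    (cluster-specific TFs in the table thus weight the driver ranking;
    transition-level weighting alone is nullified wherever a node has a
    single out-edge, because column normalization absorbs the factor).
    """
    if target_layer not in {"TF", "CRE"}:
        raise ValueError("target_layer must be TF or CRE")
    use = degs if prefiltered else filter_degs(degs)
    if len(use) == 0:
        raise ValueError("no DEG passes the filtering thresholds")
    tm = build_transition(hrnet, "reverse",
                          within_layer_weight=within_layer_weight,
                          deg_weights=use)
    tg_index = hrnet.nodes["TG"].index
    seeds = sorted(set(map(str, use["gene"])) & set(tg_index))
    if not seeds:
        raise ValueError("no filtered DEG is present in the TG layer")
    tg_offset = len(hrnet.nodes["TF"]) + len(hrnet.nodes["CRE"])
    s0 = np.zeros(tm.n)
    for g in seeds:
        s0[tg_offset + tg_index[g]] = 1.0 / len(seeds)
    s = rwr_solve(tm, s0, beta=beta, tol=tol, max_iter=max_iter)
    fc = {str(g): 1.0 + abs(float(l))
          for g, l in zip(use["gene"], use["log2FC"])}
    layer_ids = np.asarray(tm.node_ids, dtype=object)
    weighted = s.copy()
    mask = tm.layers == target_layer
    weighted[mask] *= np.array([fc.get(n, 1.0) for n in layer_ids[mask]])
    return _ranked(tm.node_ids, weighted, mask)
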