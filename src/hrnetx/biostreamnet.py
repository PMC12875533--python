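"""Biologically masked expression networks and in-silico perturbation.

For each target gene a sparse 4-layer feed-forward network is built whose
connectivity is the gene's HRNet sub-network: TF expression feeds a
TF->CRE masked layer, each CRE unit additionally receives its own
accessibility, a CRE->CRE masked layer (with self connections) propagates
between elements, and a CRE->TG masked readout predicts the gene's
expression per metacell. Weights exist only where the mask is 1, so the
parameter count equals the gene's HRNet edge count (plus the per-CRE
accessibility input and biases).

Perturbations multiply the inputs of targeted TFs (expression) or CREs
(accessibility) by a fold: 0 = knockout, 1 = identity, >1 =
overexpression. The reported effect is the per-metacell change in
predicted expression relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, constant, parameter
from .io_graph import FeatureMatrix, HRNet


@dataclass
class Perturbation:
    """In-silico intervention: (node id, node type, fold) triples."""

    targets: list[tuple[str, str, float]]

    def __post_init__(self):
        for nid, ntype, fold in self.targets:
            if ntype not in {"TF", "CRE"}:
                raise ValueError(f"perturbation type must be TF or CRE, "
                                 f"got {ntype!r} for {nid}")
            if not np.isfinite(fold) or fold < 0:
                raise ValueError(f"fold for {nid} must be finite and >= 0")


@dataclass
class GeneHRNet:
    """The retained regulatory sub-network of one target gene."""

    gene: str
    tfs: list[str]
    cres: list[str]
    tf_cre: list[tuple[str, str, float]]
    cre_cre: list[tuple[str, str, float]]
    cre_tg: list[tuple[str, float]]


@dataclass
class MaskedNet:
    """Per-gene layered network with sparsity masks.

    Masks are fixed 0/1 matrices; trainable weights are multiplied by the
    mask in the forward pass, so mask-0 positions carry exactly zero
    weight and zero gradient at all times.
    """

    gene: str
    tfs: list[str]
    cres: list[str]
    mask_tc: np.ndarray      # (n_tf, n_cre)
    mask_cc: np.ndarray      # (n_cre, n_cre), includes self connections
    mask_ct: np.ndarray      # (n_cre,)
    params: dict = field(default_factory=dict)
    fitted: bool = False
    test_pcc: float = float("nan")
    # input standardization (set at fit time); perturbations act on raw
    # inputs, which are standardized with these fixed statistics
    tf_mu: np.ndarray = None
    tf_sd: np.ndarray = None

    def n_mask_weights(self) -> int:
        """Trainable inter-node weights = mask-1 count on the three layers."""
        # the CRE-CRE self connections are structural, not HRNet edges
        return int(self.mask_tc.sum()
                   + (self.mask_cc.sum() - np.trace(self.mask_cc))
                   + self.mask_ct.sum())

    def init_params(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        n_tf, n_cre = self.mask_tc.shape

        def init(shape, fan_in):
            w = rng.normal(0, np.sqrt(1.0 / max(fan_in, 1)), size=shape)
            return w

        self.params = {
            "W_tc": parameter(init((n_tf, n_cre), n_tf) * self.mask_tc),
            "a_acc": parameter(np.ones(n_cre)),   # per-CRE accessibility gain
            "b_cre": parameter(np.zeros(n_cre)),
            "W_cc": parameter(init((n_cre, n_cre), n_cre) * self.mask_cc),
            "b_cc": parameter(np.zeros(n_cre)),
            "w_ct": parameter(init(n_cre, n_cre) * self.mask_ct),
            "b_out": parameter(0.0),
        }

    def forward(self, tf_expr: np.ndarray, cre_acc: np.ndarray) -> Tensor:
        """Predict gene expression for (n_cells, n_tf) / (n_cells, n_cre)."""
        p = self.params
        x = np.atleast_2d(np.asarray(tf_expr, dtype=float))
        if self.tf_mu is not None and x.shape[1]:
            x = (x - self.tf_mu) / self.tf_sd
        x_tf = constant(x)
        x_acc = constant(np.atleast_2d(cre_acc))
        h1 = x_tf @ (p["W_tc"] * constant(self.mask_tc)) \
            + x_acc * p["a_acc"] + p["b_cre"]
        h1 = h1.leaky_relu()  # leaky: masked paths are narrow, dead units
        h2 = (h1 @ (p["W_cc"] * constant(self.mask_cc))  # would be fatal
              + p["b_cc"]).leaky_relu()
        out = (h2 * (p["w_ct"] * constant(self.mask_ct))).sum(axis=1) \
            + p["b_out"]
        return out

    def predict(self, tf_expr: np.ndarray, cre_acc: np.ndarray,
                clamp_nonnegative: bool = False) -> np.ndarray:
        y = self.forward(tf_expr, cre_acc).data
        return np.maximum(y, 0.0) if clamp_nonnegative else y

    def extract_gene_hrnet(self, threshold: float = 0.15) -> GeneHRNet:
        """Connections with |weight| above the gene-net threshold."""
        if not self.fitted:
            raise RuntimeError("fit the network before extracting weights")
        p = self.params
        w_tc = p["W_tc"].data * self.mask_tc
        w_cc = p["W_cc"].data * self.mask_cc
        w_ct = p["w_ct"].data * self.mask_ct
        tf_cre = [(self.tfs[i], self.cres[j], float(w_tc[i, j]))
                  for i, j in zip(*np.nonzero(np.abs(w_tc) > threshold))]
        cre_cre = [(self.cres[i], self.cres[j], float(w_cc[i, j]))
                   for i, j in zip(*np.nonzero(np.abs(w_cc) > threshold))
                   if i != j]
        cre_tg = [(self.cres[j], float(w_ct[j]))
                  for j in np.flatnonzero(np.abs(w_ct) > threshold)]
        keep_cres = sorted({c for _, c, _ in tf_cre}
                           | {c for pair in cre_cre for c in pair[:2]}
                           | {c for c, _ in cre_tg})
        keep_tfs = sorted({t for t, _, _ in tf_cre})
        return GeneHRNet(self.gene, keep_tfs, keep_cres,
                         tf_cre, cre_cre, cre_tg)


def build_masks(hrnet: HRNet, gene: str) -> MaskedNet:
    """Masks for one gene from its HRNet sub-network.

    Retained CREs are those reaching the gene through CRE-TG directly or
    via one CRE-CRE hop; retained TFs are those wired to a retained CRE.
    Inputs with no path to the gene are dropped.
    """
    if hrnet.nodes is None or gene not in hrnet.nodes["TG"].index:
        raise KeyError(f"{gene!r} is not a TG node")
    direct = {s for s, t in hrnet.layers["CRE-TG"].pairs if t == gene}
    if not direct:
        raise ValueError(
            f"gene {gene!r} has no incoming CRE-TG edge; unpredictable")
    cc_pairs = hrnet.layers.get("CRE-CRE")
    cc_pairs = list(cc_pairs.pairs) if cc_pairs is not None else []
    upstream = {s for s, t in cc_pairs if t in direct} \
        | {t for s, t in cc_pairs if s in direct}
    cres = sorted(direct | upstream)
    cre_pos = {c: i for i, c in enumerate(cres)}
    tc = [(s, t, w) for (s, t), w in
          zip(hrnet.layers["TF-CRE"].pairs, hrnet.layers["TF-CRE"].weights)
          if t in cre_pos]
    tfs = sorted({s for s, _, _ in tc})
    tf_pos = {t: i for i, t in enumerate(tfs)}

    mask_tc = np.zeros((len(tfs), len(cres)))
    for s, t, _ in tc:
        mask_tc[tf_pos[s], cre_pos[t]] = 1.0
    mask_cc = np.eye(len(cres))  # self connections pass each CRE through
    for s, t in cc_pairs:
        if s in cre_pos and t in cre_pos:
            mask_cc[cre_pos[s], cre_pos[t]] = 1.0
            mask_cc[cre_pos[t], cre_pos[s]] = 1.0
    mask_ct = np.zeros(len(cres))
    for c in direct:
        mask_ct[cre_pos[c]] = 1.0
    return MaskedNet(gene, tfs, cres, mask_tc, mask_cc, mask_ct)


def _slice_features(fm: FeatureMatrix, ids: list[str]) -> np.ndarray:
    idx = {nid: i for i, nid in enumerate(fm.node_ids)}
    missing = [i for i in ids if i not in idx]
    if missing:
        raise KeyError(f"features missing ids: {missing[:5]}")
    return fm.values[:, [idx[i] for i in ids]]


def fit(masked: MaskedNet, tf_expr: FeatureMatrix, cre_acc: FeatureMatrix,
        tg_expr: FeatureMatrix, epochs: int = 400, lr: float = 5e-3,
        test_fraction: float = 0.25, seed: int = 0,
        acc_dropout: float = 0.3) -> MaskedNet:
    """Fit the masked network by Adam on MSE with a metacell split.

    Reports the held-out Pearson correlation between predicted and
    observed expression in ``masked.test_pcc``. Mask-0 weights stay
    exactly zero: the forward pass multiplies by the mask, so their
    gradients vanish identically.

    ``acc_dropout`` randomly zeroes accessibility inputs during training
    (seeded). TF expression and a CRE's own accessibility are collinear
    by construction, so an unregularized fit can place arbitrary-signed
    weight on the redundant TF path; dropping accessibility forces the
    network to also carry the signal through its TF inputs, which is what
    makes TF perturbations meaningful.
    """
    n_cells = tg_expr.n_cells
    if n_cells < 10:
        raise ValueError("need at least 10 metacells to fit")
    x_tf = _slice_features(tf_expr, masked.tfs) if masked.tfs \
        else np.zeros((n_cells, 0))
    x_acc = _slice_features(cre_acc, masked.cres)
    y = tg_expr.column(masked.gene)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    n_test = max(1, int(round(test_fraction * n_cells)))
    test_idx, train_idx = order[:n_test], order[n_test:]

    if x_tf.shape[1]:
        masked.tf_mu = x_tf[train_idx].mean(axis=0)
        sd = x_tf[train_idx].std(axis=0)
        masked.tf_sd = np.where(sd > 0, sd, 1.0)
    masked.init_params(seed=seed + 1)
    opt = Adam(list(masked.params.values()), lr=lr)
    y_train = constant(y[train_idx])
    for _ in range(epochs):
        acc_in = x_acc[train_idx]
        if acc_dropout > 0:
            keep = rng.random(acc_in.shape) >= acc_dropout
            acc_in = acc_in * keep
        pred = masked.forward(x_tf[train_idx], acc_in)
        loss = (pred - y_train).square().mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    masked.fitted = True
    pred_test = masked.predict(x_tf[test_idx], x_acc[test_idx])
    if np.std(pred_test) > 0 and np.std(y[test_idx]) > 0:
        masked.test_pcc = float(np.corrcoef(pred_test, y[test_idx])[0, 1])
    else:
        masked.test_pcc = 0.0
    return masked


def perturb_predict(masked: MaskedNet, tf_expr: FeatureMatrix,
                    cre_acc: FeatureMatrix,
                    pert: Perturbation) -> np.ndarray:
    """Per-metacell expression change of the gene under a perturbation.

    Inputs of targeted nodes are multiplied by the fold; nodes absent
    from the gene's network contribute exactly zero change.
    """
    n_cells = tf_expr.n_cells
    x_tf = _slice_features(tf_expr, masked.tfs) if masked.tfs \
        else np.zeros((n_cells, 0))
    x_acc = _slice_features(cre_acc, masked.cres)
    x_tf_p, x_acc_p = x_tf.copy(), x_acc.copy()
    touched = False
    tf_pos = {t: i for i, t in enumerate(masked.tfs)}
    cre_pos = {c: i for i, c in enumerate(masked.cres)}
    for nid, ntype, fold in pert.targets:
        if fold == 1.0:
            continue
        if ntype == "TF" and nid in tf_pos:
            x_tf_p[:, tf_pos[nid]] *= fold
            touched = True
        elif ntype == "CRE" and nid in cre_pos:
            x_acc_p[:, cre_pos[nid]] *= fold
            touched = True
    if not touched:
        return np.zeros(n_cells)
    base = masked.predict(x_tf, x_acc)
    pert_pred = masked.predict(x_tf_p, x_acc_p)
    return pert_pred - base


def vector_field(delta: np.ndarray, expression: np.ndarray,
                 embedding_2d: np.ndarray, k: int = 15) -> np.ndarray:
    """Project per-metacell expression shifts onto a 2-D embedding.

    For each metacell the predicted shift ``delta`` (cells x genes) is
    correlated against the expression difference to each of its k nearest
    embedding neighbors; the softmax-normalized scores weight the neighbor
    directions, and the uniform-kernel displacement is subtracted so a
    non-informative shift yields zero. Cells with a zero or constant
    shift get exactly zero displacement.
    """
    delta = np.asarray(delta, dtype=float)
    x = np.asarray(expression, dtype=float)
    coords = np.asarray(embedding_2d, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be below the {n} metacells")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    disp = np.zeros_like(coords)
    for i in range(n):
        nbr = np.argsort(d2[i], kind="stable")[:k]
        diffs = x[nbr] - x[i]                      # (k, genes)
        dv = delta[i]
        sd = diffs.std(axis=1)
        if dv.std() == 0 or not np.isfinite(dv).all():
            continue
        corr = np.zeros(k)
        ok = sd > 0
        if ok.any():
            dz = (dv - dv.mean()) / dv.std()
            dd = diffs[ok] - diffs[ok].mean(axis=1, keepdims=True)
            corr[ok] = (dd * dz).mean(axis=1) / sd[ok]
        e = np.exp(corr - corr.max())
        p = e / e.sum()
        directions = coords[nbr] - coords[i]
        disp[i] = (p[:, None] * directions).sum(axis=0) \
            - directions.mean(axis=0)
    return disp
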