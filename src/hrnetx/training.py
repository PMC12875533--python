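"""Dual-task decoding, combined loss, optimization, HRNet extraction.

The encoder is trained against two objectives at once: reconstruction of
labeled edges (dot-product decoder with sigmoid, balanced cross-entropy
with class weight alpha) and regression of target-gene expression per
metacell (4-layer fully connected decoder, mean squared error). The total
loss is ``lambda * MSE + (1 - lambda) * BLCE``.

After training, the hierarchical regulatory network (HRNet) is extracted:
TF-CRE candidates are retained by decoder probability, CRE-CRE candidates
by top-quantile attention, while the prior TF-TF and CRE-TG layers are
carried over re-weighted by decoder probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Adam, Tensor, constant, parameter
from .evaluation import aupr_auc
from .hegt import EncoderConfig, EncoderParams, init_encoder_params, \
    metapath_forward
from .io_graph import FeatureMatrix, HeteroRegGraph, HRNet, TypedEdgeSet
from .pseudo_labels import EdgeLabelSet, sample_negative_pairs

LABELED_EDGE_TYPES = ("TF-CRE", "CRE-CRE")


@dataclass
class LossConfig:
    lam: float = 0.5            # weight of the expression-regression task
    lr: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 300
    patience: int = 60
    restarts: int = 5           # independent runs, ensembled downstream
    seed: int = 0
    resample_negatives: bool = True
    clamp: float = 1e-7
    edge_decoder_mode: str = "cosine"   # {dot, cosine}
    tau_init: float = 5.0               # cosine temperature (trainable)

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")


@dataclass
class RetentionConfig:
    """Rules keeping edges in the extracted HRNet."""

    tf_cre_prob: float = 0.8       # decoder probability threshold
    cre_cre_top_frac: float = 0.02  # top fraction of candidates by attention


# ----------------------------------------------------------------------
# decoders
# ----------------------------------------------------------------------

def edge_decoder(z_u, z_v):
    """Edge probability: sigmoid of the embedding dot product."""
    z_u = np.asarray(z_u, dtype=float)
    z_v = np.asarray(z_v, dtype=float)
    return 1.0 / (1.0 + np.exp(-np.clip(z_u @ z_v, -60, 60)))


def edge_probabilities(z_src: Tensor, z_tgt: Tensor, src_idx, tgt_idx,
                       mode: str = "dot", tau=None) -> Tensor:
    """Vectorized edge decoder on the autodiff tape.

    ``dot`` is sigmoid of the raw dot product; ``cosine`` L2-normalizes
    the embeddings first (removing norm shortcuts) and scales by a
    temperature ``tau`` (Tensor or float) before the sigmoid.
    """
    zu = z_src.take_rows(np.asarray(src_idx, dtype=np.intp))
    zv = z_tgt.take_rows(np.asarray(tgt_idx, dtype=np.intp))
    dots = (zu * zv).sum(axis=1)
    if mode == "dot":
        return dots.sigmoid()
    if mode == "cosine":
        inv_norm = (((zu.square().sum(axis=1) + 1e-12).log() * -0.5).exp()
                    * ((zv.square().sum(axis=1) + 1e-12).log() * -0.5).exp())
        cos = dots * inv_norm
        if tau is None:
            tau = 5.0
        return (cos * tau).sigmoid()
    raise ValueError(f"unknown decoder mode {mode!r}")


def init_expr_decoder(embedding_dim: int, hidden_dims: tuple,
                      raw_dim: int, seed: int = 0) -> dict:
    """Parameters of the 4-layer expression decoder.

    Layer sizes embedding_dim -> hidden -> hidden2 -> hidden3 -> raw_dim
    (number of metacells), ReLU between layers, linear output.
    """
    rng = np.random.default_rng(seed)
    dims = (embedding_dim,) + tuple(hidden_dims) + (raw_dim,)
    layers = []
    for i in range(len(dims) - 1):
        s = np.sqrt(2.0 / (dims[i] + dims[i + 1]))
        layers.append({
            "W": parameter(rng.normal(0, s, size=(dims[i], dims[i + 1]))),
            "b": parameter(np.zeros(dims[i + 1])),
        })
    return {"layers": layers}


def expr_decoder(z, decoder: dict) -> Tensor:
    """Predict per-metacell expression from node embeddings."""
    h = z if isinstance(z, Tensor) else constant(np.atleast_2d(z))
    layers = decoder["layers"]
    for i, layer in enumerate(layers):
        h = h @ layer["W"] + layer["b"]
        if i < len(layers) - 1:
            h = h.relu()
    return h


def _decoder_parameters(decoder: dict) -> list[Tensor]:
    out = []
    for layer in decoder["layers"]:
        out.extend([layer["W"], layer["b"]])
    return out


# ----------------------------------------------------------------------
# loss
# ----------------------------------------------------------------------

def balanced_bce(y_hat: Tensor, y: np.ndarray, alpha: float,
                 clamp: float = 1e-7) -> Tensor:
    """Class-weighted binary cross-entropy over L labeled edges.

    ``-(1/L) sum[alpha*y*log(p) + (1-alpha)*(1-y)*log(1-p)]``; predicted
    probabilities are clamped away from 0/1.
    """
    p = y_hat.clip(clamp, 1.0 - clamp)
    y = np.asarray(y, dtype=float)
    pos = constant(alpha * y) * p.log()
    neg = constant((1.0 - alpha) * (1.0 - y)) * (1.0 - p).log()
    return -(pos + neg).mean()


def mse_loss(x: np.ndarray, x_hat: Tensor) -> Tensor:
    """Mean squared error over all predicted expression entries."""
    diff = x_hat - constant(np.asarray(x, dtype=float))
    return diff.square().mean()


def total_loss(x, x_hat, y_hat, y, alpha: float,
               cfg: LossConfig) -> Tensor:
    """``lambda * L_MSE + (1 - lambda) * L_BLCE``."""
    lam = cfg.lam
    parts = []
    if lam > 0:
        parts.append(mse_loss(x, x_hat) * lam)
    if lam < 1:
        x_hat_t = y_hat if isinstance(y_hat, Tensor) else constant(y_hat)
        parts.append(balanced_bce(x_hat_t, y, alpha, cfg.clamp) * (1 - lam))
    out = parts[0]
    for p in parts[1:]:
        out = out + p
    return out


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

@dataclass
class TrainResult:
    params: EncoderParams
    expr_decoder: dict
    log: list[dict] = field(default_factory=list)
    best_val_aupr: float = float("nan")
    best_epoch: int = -1
    edge_scorer: dict = field(default_factory=lambda: {"mode": "dot",
                                                       "tau": 1.0})
    #: all restart runs (ensemble members); downstream edge scores and
    #: attention are averaged over them
    ensemble: list = field(default_factory=list)


def _label_indices(labels: EdgeLabelSet, graph: HeteroRegGraph):
    st, tt = labels.edge_type.split("-")[0], labels.edge_type.split("-")[1]
    si = graph.nodes[st].index
    ti = graph.nodes[tt].index
    pairs = labels.pairs
    src = np.array([si[s] for s, _ in pairs], dtype=np.intp)
    tgt = np.array([ti[t] for _, t in pairs], dtype=np.intp)
    return src, tgt, labels.y, labels.alpha


def _edge_task(emb, graph, labels: EdgeLabelSet, mode: str = "dot",
               tau=None):
    src, tgt, y, alpha = _label_indices(labels, graph)
    st, tt = labels.edge_type.split("-")
    return edge_probabilities(emb[st], emb[tt], src, tgt, mode, tau), \
        y, alpha


def train(graph: HeteroRegGraph, features: dict[str, FeatureMatrix],
          labels: dict[str, dict[str, EdgeLabelSet]],
          cfg: LossConfig | None = None,
          encoder_cfg: EncoderConfig | None = None,
          verbose: bool = False) -> TrainResult:
    """Full-graph training of the encoder plus both decoders.

    ``labels`` maps edge type to ``{"train": ..., "val": ..., "test": ...}``
    EdgeLabelSets (only TF-CRE and CRE-CRE carry labels). Runs
    ``cfg.restarts`` independent trainings (seeded) and returns the one
    with the best validation AUPR — full-batch training of a small graph
    transformer is sensitive to initialization, and validation selection
    is the standard guard.
    """
    cfg = cfg or LossConfig()
    encoder_cfg = encoder_cfg or EncoderConfig()
    members = []
    best = None
    for r in range(max(1, cfg.restarts)):
        run_cfg = replace(cfg, seed=cfg.seed + 9973 * r, restarts=1)
        result = _train_once(graph, features, labels, run_cfg,
                             encoder_cfg, verbose)
        members.append(result)
        if best is None or (np.isfinite(result.best_val_aupr)
                            and result.best_val_aupr
                            > best.best_val_aupr):
            best = result
    best.ensemble = members
    return best


def _train_once(graph, features, labels, cfg: LossConfig,
                encoder_cfg: EncoderConfig,
                verbose: bool = False) -> TrainResult:
    """One seeded optimization run with early stopping.

    Per-epoch train loss, validation loss and validation AUPR are logged;
    the parameters with the best validation AUPR are returned. Training
    pseudo-negatives are re-drawn each epoch (endpoint corruption,
    seeded) when ``resample_negatives`` is set.
    """
    n_cells = features["TG"].n_cells
    params = init_encoder_params(n_cells, encoder_cfg, seed=cfg.seed,
                                 features=features)
    decoder = init_expr_decoder(
        encoder_cfg.embedding_dim,
        (encoder_cfg.hidden_dim, encoder_cfg.hidden_dim,
         encoder_cfg.hidden_dim),
        n_cells, seed=cfg.seed + 1)
    mode = cfg.edge_decoder_mode
    tau = parameter(cfg.tau_init) if mode == "cosine" else None
    all_params = params.all_parameters() + _decoder_parameters(decoder)
    if tau is not None:
        all_params.append(tau)
    opt = Adam(all_params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 2)

    tg_x = features["TG"].values.T  # node x cell regression target
    # pairs that epoch-resampled negatives must avoid: candidate priors and
    # every pair already fixed in any split
    avoid = {}
    for etype in LABELED_EDGE_TYPES:
        if etype not in labels:
            continue
        st, tt = etype.split("-")
        banned = graph.edges[etype].pair_set()
        for part in labels[etype].values():
            banned |= set(part.pairs)
        avoid[etype] = (banned, (graph.nodes[st], graph.nodes[tt]))

    def corrupt_negatives(etype: str, positives, n: int, banned,
                          universe, rng_ep) -> list:
        """Hard negatives: corrupt one endpoint of a positive pair.

        Keeps the other endpoint fixed so node identity alone cannot
        separate the classes; corrupted pairs falling into the candidate
        prior or a fixed split are rejected.
        """
        src_ids, tgt_ids = universe[0].ids, universe[1].ids
        undirected = etype == "CRE-CRE"
        out, seen = [], set()
        guard = 0
        while len(out) < n and guard < 50 * n:
            guard += 1
            s, t = positives[int(rng_ep.integers(len(positives)))]
            if rng_ep.random() < 0.5:
                s = src_ids[int(rng_ep.integers(len(src_ids)))]
            else:
                t = tgt_ids[int(rng_ep.integers(len(tgt_ids)))]
            if undirected:
                if s == t:
                    continue
                if s > t:
                    s, t = t, s
            if (s, t) in banned or (s, t) in seen:
                continue
            seen.add((s, t))
            out.append((s, t))
        if len(out) < n:  # fall back to uniform sampling for the remainder
            out += sample_negative_pairs(universe, n - len(out),
                                         banned | seen, rng_ep,
                                         undirected=undirected)
        return out

    def epoch_labels(epoch: int) -> dict[str, EdgeLabelSet]:
        out = {}
        for etype in LABELED_EDGE_TYPES:
            if etype not in labels:
                continue
            tr = labels[etype]["train"]
            if cfg.resample_negatives:
                banned, universe = avoid[etype]
                rng_ep = np.random.default_rng(cfg.seed + 1000 * epoch + 17)
                neg = corrupt_negatives(etype, tr.positives,
                                        len(tr.negatives), banned,
                                        universe, rng_ep)
                out[etype] = EdgeLabelSet(etype, tr.positives, neg)
            else:
                out[etype] = tr
        return out

    def evaluate(emb, part: str):
        """Loss and AUPR over a held-out split."""
        losses, scores, truths = [], [], []
        for etype in LABELED_EDGE_TYPES:
            if etype not in labels or labels[etype][part].L == 0:
                continue
            y_hat, y, alpha = _edge_task(emb, graph, labels[etype][part],
                                         mode, tau)
            losses.append(balanced_bce(y_hat, y, alpha, cfg.clamp).item())
            scores.append(y_hat.data)
            truths.append(y)
        if not scores:
            return float("nan"), float("nan")
        s = np.concatenate(scores)
        t = np.concatenate(truths)
        aupr = aupr_auc(s, t)[0] if 0 < t.sum() < len(t) else float("nan")
        return float(np.mean(losses)), aupr

    best_state = None
    best_dec_state = None
    best_val = -np.inf
    best_epoch = -1
    log = []
    since_best = 0
    for epoch in range(cfg.epochs):
        ep_labels = epoch_labels(epoch)
        emb, _ = metapath_forward(graph, features, params,
                                  dropout_rng=rng if encoder_cfg.dropout > 0
                                  else None)
        x_hat = expr_decoder(emb["TG"], decoder)
        loss = None
        if cfg.lam > 0:
            loss = mse_loss(tg_x, x_hat) * cfg.lam
        if cfg.lam < 1:
            bce_terms = []
            for etype, lab in ep_labels.items():
                y_hat, y, alpha = _edge_task(emb, graph, lab, mode, tau)
                bce_terms.append(balanced_bce(y_hat, y, alpha, cfg.clamp))
            if bce_terms:
                bce = bce_terms[0]
                for t in bce_terms[1:]:
                    bce = bce + t
                bce = bce * (1.0 / len(bce_terms))
                term = bce * (1 - cfg.lam)
                loss = term if loss is None else loss + term
        if loss is None or not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={loss}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        # validate with the updated parameters (no dropout)
        val_emb, _ = metapath_forward(graph, features, params)
        val_loss, val_aupr = evaluate(val_emb, "val")
        log.append({"epoch": epoch, "train_loss": float(loss.item()),
                    "val_loss": val_loss, "val_aupr": val_aupr})
        if verbose and epoch % 20 == 0:
            print(f"epoch {epoch:4d} loss {loss.item():.4f} "
                  f"val_aupr {val_aupr:.4f}")
        improved = np.isfinite(val_aupr) and val_aupr > best_val
        if improved or best_state is None:
            if improved:
                best_val = val_aupr
                best_epoch = epoch
                since_best = 0
            best_state = params.state()
            best_dec_state = [p.data.copy()
                              for p in _decoder_parameters(decoder)]
            best_tau = float(tau.data) if tau is not None else 1.0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    params.load_state(best_state)
    for p, s in zip(_decoder_parameters(decoder), best_dec_state):
        p.data = s.copy()
    scorer = {"mode": mode, "tau": best_tau}
    return TrainResult(params, decoder, log,
                       best_val_aupr=float(best_val), best_epoch=best_epoch,
                       edge_scorer=scorer)


# ----------------------------------------------------------------------
# HRNet extraction
# ----------------------------------------------------------------------

def candidate_probabilities(graph: HeteroRegGraph, emb, edge_type: str,
                            scorer: dict | None = None) -> np.ndarray:
    """Decoder probabilities for every candidate edge of a type."""
    scorer = scorer or {"mode": "dot", "tau": 1.0}
    st, tt = edge_type.split("-")
    si = graph.nodes[st].index
    ti = graph.nodes[tt].index
    pairs = graph.edges[edge_type].pairs
    if not pairs:
        return np.zeros(0)
    src = np.array([si[s] for s, _ in pairs], dtype=np.intp)
    tgt = np.array([ti[t] for _, t in pairs], dtype=np.intp)
    zs = emb[st].data if isinstance(emb[st], Tensor) else emb[st]
    zt = emb[tt].data if isinstance(emb[tt], Tensor) else emb[tt]
    dots = (zs[src] * zt[tgt]).sum(axis=1)
    if scorer["mode"] == "cosine":
        norms = np.linalg.norm(zs[src], axis=1) \
            * np.linalg.norm(zt[tgt], axis=1)
        dots = scorer["tau"] * dots / np.maximum(norms, 1e-12)
    return 1.0 / (1.0 + np.exp(-np.clip(dots, -60, 60)))


def extract_hrnet(attention, priors: dict[str, TypedEdgeSet], emb,
                  graph: HeteroRegGraph,
                  retain: RetentionConfig | None = None,
                  scorer: dict | None = None) -> HRNet:
    """Build the four-layer HRNet from attention, probabilities and priors.

    TF-CRE keeps candidates whose decoder probability passes the
    threshold (weight = probability); CRE-CRE keeps the top fraction of
    candidates by averaged attention (weight = attention); the TF-TF and
    CRE-TG prior layers are carried over re-weighted by decoder
    probability. An empty retained layer warns but does not fail.
    """
    import warnings

    retain = retain or RetentionConfig()
    layers: dict[str, TypedEdgeSet] = {}

    # TF-CRE: decoder probability threshold; additionally every CRE keeps
    # its maximum-attention in-edge so no element loses its best-supported
    # regulator. Edge weight is the averaged attention (the per-CRE
    # routing distribution used by the downstream walks).
    probs = candidate_probabilities(graph, emb, "TF-CRE", scorer)
    att_tc = attention["TF-CRE"].averaged()
    pairs_tc = priors["TF-CRE"].pairs
    keep = probs >= retain.tf_cre_prob
    best_for_cre: dict[str, int] = {}
    for i, (s, t) in enumerate(pairs_tc):
        j = best_for_cre.get(t)
        if j is None or att_tc[i] > att_tc[j]:
            best_for_cre[t] = i
    keep[list(best_for_cre.values())] = True
    if not keep.any():
        warnings.warn("no TF-CRE edge passes the retention rule")
    layers["TF-CRE"] = TypedEdgeSet(
        "TF-CRE",
        [p for p, k in zip(pairs_tc, keep) if k],
        att_tc[keep])

    # CRE-CRE: top fraction by averaged attention
    att = attention["CRE-CRE"].averaged()
    n_keep = int(round(retain.cre_cre_top_frac * len(att)))
    if n_keep == 0 and retain.cre_cre_top_frac > 0 and len(att):
        n_keep = 1
    if retain.cre_cre_top_frac <= 0:
        n_keep = len(att)
    order = np.argsort(-att, kind="stable")[:n_keep]
    mask = np.zeros(len(att), dtype=bool)
    mask[order] = True
    layers["CRE-CRE"] = TypedEdgeSet(
        "CRE-CRE",
        [p for p, k in zip(priors["CRE-CRE"].pairs, mask) if k],
        att[mask])

    # prior layers re-weighted by decoder probability
    for etype in ("TF-TF", "CRE-TG"):
        probs = candidate_probabilities(graph, emb, etype, scorer)
        layers[etype] = priors[etype].reweighted(probs)

    return HRNet(layers, nodes=graph.nodes)


# ----------------------------------------------------------------------
# ensemble scoring
# ----------------------------------------------------------------------

def _members(result: TrainResult) -> list[TrainResult]:
    return result.ensemble or [result]


def ensemble_candidate_probabilities(graph: HeteroRegGraph, features,
                                     result: TrainResult,
                                     edge_type: str) -> np.ndarray:
    """Decoder probability per candidate edge, averaged over restarts."""
    from .hegt import metapath_forward

    probs = []
    for m in _members(result):
        emb, _ = metapath_forward(graph, features, m.params)
        probs.append(candidate_probabilities(graph, emb, edge_type,
                                             m.edge_scorer))
    return np.mean(probs, axis=0)


def ensemble_label_probabilities(graph: HeteroRegGraph, features,
                                 result: TrainResult,
                                 labels: EdgeLabelSet) -> np.ndarray:
    """Edge probability per labeled pair, averaged over restarts."""
    from .hegt import metapath_forward

    probs = []
    for m in _members(result):
        emb, _ = metapath_forward(graph, features, m.params)
        y_hat, _, _ = _edge_task(emb, graph, labels,
                                 m.edge_scorer["mode"],
                                 m.edge_scorer["tau"])
        probs.append(y_hat.data)
    return np.mean(probs, axis=0)


def ensemble_attention(graph: HeteroRegGraph, features,
                       result: TrainResult) -> dict[str, np.ndarray]:
    """Per-pair averaged attention for each HGT edge type, over restarts."""
    from .hegt import metapath_forward

    acc: dict[str, list] = {}
    for m in _members(result):
        _, attention = metapath_forward(graph, features, m.params)
        for etype, rec in attention.items():
            acc.setdefault(etype, []).append(rec.averaged())
    return {etype: np.mean(v, axis=0) for etype, v in acc.items()}


def build_hrnet(graph: HeteroRegGraph, features, result: TrainResult,
                retain: RetentionConfig | None = None) -> HRNet:
    """Extract the HRNet from ensemble-averaged scores and attention.

    TF-CRE retention is the decoder-probability threshold plus every
    CRE's single best edge; the retained edges are weighted by the
    decoder's per-CRE routing distribution (odds normalized within each
    CRE, i.e. a softmax of the decoder logits restricted to the CRE's
    retained candidates). CRE-CRE keeps the top attention fraction; the
    prior TF-TF and CRE-TG layers are re-weighted by decoder probability.
    """
    import warnings

    retain = retain or RetentionConfig()
    att = ensemble_attention(graph, features, result)
    layers: dict[str, TypedEdgeSet] = {}

    probs = ensemble_candidate_probabilities(graph, features, result,
                                             "TF-CRE")
    pairs_tc = graph.edges["TF-CRE"].pairs
    keep = probs >= retain.tf_cre_prob
    best_for_cre: dict[str, int] = {}
    for i, (s, t) in enumerate(pairs_tc):
        j = best_for_cre.get(t)
        if j is None or probs[i] > probs[j]:
            best_for_cre[t] = i
    keep[list(best_for_cre.values())] = True
    if not keep.any():
        warnings.warn("no TF-CRE edge passes the retention rule")
    odds = probs / np.clip(1.0 - probs, 1e-9, None)
    odds_sum: dict[str, float] = {}
    for i, (s, t) in enumerate(pairs_tc):
        if keep[i]:
            odds_sum[t] = odds_sum.get(t, 0.0) + odds[i]
    weights_tc = np.array([
        odds[i] / odds_sum[pairs_tc[i][1]] if keep[i] else 0.0
        for i in range(len(pairs_tc))])
    layers["TF-CRE"] = TypedEdgeSet(
        "TF-CRE", [p for p, k in zip(pairs_tc, keep) if k],
        weights_tc[keep])

    att_cc = att["CRE-CRE"]
    n_keep = int(round(retain.cre_cre_top_frac * len(att_cc)))
    if retain.cre_cre_top_frac <= 0:
        n_keep = len(att_cc)
    elif n_keep == 0 and len(att_cc):
        n_keep = 1
    order = np.argsort(-att_cc, kind="stable")[:n_keep]
    mask = np.zeros(len(att_cc), dtype=bool)
    mask[order] = True
    layers["CRE-CRE"] = TypedEdgeSet(
        "CRE-CRE",
        [p for p, k in zip(graph.edges["CRE-CRE"].pairs, mask) if k],
        att_cc[mask])

    for etype in ("TF-TF", "CRE-TG"):
        p = ensemble_candidate_probabilities(graph, features, result,
                                             etype)
        layers[etype] = graph.edges[etype].reweighted(p)
    return HRNet(layers, nodes=graph.nodes)
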