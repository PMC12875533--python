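"""Hierarchical epigenetic graph-transformer encoder.

Node embeddings for the three types (TF, CRE, TG) are updated per layer in
the fixed meta-path order that mirrors the flow of regulatory information:

1. TF embeddings by a GCN pass over the TF-TF layer;
2. CRE embeddings by heterogeneous graph-transformer (HGT) attention over
   TF -> CRE edges;
3. CRE embeddings again by HGT attention over CRE <-> CRE edges (each
   undirected pair expanded to both directions);
4. TG embeddings by HGT attention over CRE -> TG edges;
5. TG embeddings by a GraphSAGE pass over the TG-TG (protein-interaction)
   loop layer.

The HGT blocks use type-specific key/query/value projections, an
edge-type-specific bilinear attention with scaled dot product, softmax over
in-neighbors, multi-head concatenation and an output projection. The
residual combination is a convex gate ``g = sigmoid(theta)``:
``H_t = g * ReLU(H~_t) + (1 - g) * H_prev`` with a trainable scalar
``theta`` per block and layer.

Per-edge attention (softmax-normalized per target node, so summing to 1
over each target's in-neighbors) is recorded at every layer and head; the
average over layers and heads is the attention weight used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, constant, parameter, segment_max, \
    segment_softmax
from .io_graph import FeatureMatrix, HeteroRegGraph

HGT_EDGE_TYPES = ("TF-CRE", "CRE-CRE", "CRE-TG")


@dataclass
class EncoderConfig:
    embedding_dim: int = 16
    hidden_dim: int = 32
    layers: int = 2
    heads: int = 2
    dropout: float = 0.0
    tf_tf_encoder: str = "gcn"      # {gcn, hgt}
    sage_aggregator: str = "mean"   # {mean, pool}
    gate_mode: str = "signed"       # {signed, relu} residual gate form
    gcn_activation: str = "tanh"    # sigma of the TF-TF convolution
    init: str = "random"            # {random, spectral} parameter init

    def __post_init__(self):
        if self.embedding_dim % self.heads:
            raise ValueError("embedding_dim must be divisible by heads")
        if self.tf_tf_encoder not in {"gcn", "hgt"}:
            raise ValueError(f"unknown TF-TF encoder {self.tf_tf_encoder!r}")
        if self.sage_aggregator not in {"mean", "pool"}:
            raise ValueError(f"unknown aggregator {self.sage_aggregator!r}")


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(2.0 / (fan_in + fan_out))
    return parameter(rng.normal(0.0, s, size=(fan_in, fan_out)))


def _hgt_block(rng, d, heads, identity_init: bool = False):
    # with identity_init the output projection starts at zero, so the
    # block is initially a pure residual pass-through (ReZero-style);
    # attention/message maps still start random and shape the gradients
    dh = d // heads
    return {
        "Wk": [_glorot(rng, d, dh) for _ in range(heads)],
        "Wq": [_glorot(rng, d, dh) for _ in range(heads)],
        "Wv": [_glorot(rng, d, dh) for _ in range(heads)],
        "Watt": [_glorot(rng, dh, dh) for _ in range(heads)],
        "Wmsg": [_glorot(rng, dh, dh) for _ in range(heads)],
        "Wout": parameter(np.zeros((d, d))) if identity_init
        else _glorot(rng, d, d),
        "theta": parameter(rng.uniform(0.05, 0.95)),
    }


@dataclass
class EncoderParams:
    """All trainable tensors of the encoder, by role and layer."""

    proj: dict
    layers: list
    config: EncoderConfig

    def all_parameters(self) -> list[Tensor]:
        out = []

        def walk(obj):
            if isinstance(obj, Tensor):
                out.append(obj)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self.proj)
        walk(self.layers)
        return out

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.all_parameters()]

    def load_state(self, state: list[np.ndarray]):
        for p, s in zip(self.all_parameters(), state):
            p.data = s.copy()


def standardized_profiles(fm: FeatureMatrix) -> np.ndarray:
    """Per-node z-scored profiles, cells x nodes (constant columns -> 0)."""
    v = fm.values
    sd = v.std(axis=0)
    return np.where(sd > 0, (v - v.mean(axis=0)) / np.where(sd > 0, sd, 1),
                    0.0)


def init_encoder_params(n_cells: int, cfg: EncoderConfig, seed: int = 0,
                        features: dict[str, FeatureMatrix] | None = None
                        ) -> EncoderParams:
    """Initialize all encoder parameters.

    With ``features`` supplied, the input projections start from the
    shared principal-component basis of all standardized node profiles
    (spectral initialization): initial embeddings are then the rank-d
    denoised profiles in one common latent space, which training refines.
    Otherwise the projections start from Glorot noise.
    """
    rng = np.random.default_rng(seed)
    d = cfg.embedding_dim
    identity_init = cfg.init == "spectral" and features is not None
    if identity_init:
        # shared spectral basis of all standardized profiles, scaled so
        # typical embedding norms stay near 1 (keeps tanh/attention in
        # their linear range)
        allz = np.concatenate(
            [standardized_profiles(features[nt])
             for nt in ("TF", "CRE", "TG")], axis=1)
        u, _, _ = np.linalg.svd(allz, full_matrices=False)
        basis = u[:, :d]
        if basis.shape[1] < d:
            basis = np.pad(basis, ((0, 0), (0, d - basis.shape[1])))
        basis = basis / np.sqrt(n_cells)
        proj = {nt: {"W": parameter(basis.copy()),
                     "b": parameter(np.zeros(d))}
                for nt in ("TF", "CRE", "TG")}
    else:
        proj = {nt: {"W": _glorot(rng, n_cells, d),
                     "b": parameter(np.zeros(d))}
                for nt in ("TF", "CRE", "TG")}
    layers = []
    eye = np.eye(d)
    for _ in range(cfg.layers):
        layer = {"tf_tf": {"W": parameter(eye.copy()) if identity_init
                           else _glorot(rng, d, d)}}
        for etype in HGT_EDGE_TYPES:
            layer[etype] = _hgt_block(rng, d, cfg.heads, identity_init)
        if cfg.tf_tf_encoder == "hgt":
            layer["tf_tf_hgt"] = _hgt_block(rng, d, cfg.heads,
                                            identity_init)
        layer["tg_tg"] = {"W": parameter(np.vstack([eye, 0.0 * eye]))
                          if identity_init else _glorot(rng, 2 * d, d)}
        layers.append(layer)
    return EncoderParams(proj, layers, cfg)


@dataclass
class AttentionRecord:
    """Per-edge attention for one edge type, all layers and heads.

    ``raw`` holds one (n_directed_edges, heads) array per layer over the
    directed expansion of the layer's edges; ``tgt_idx`` are the matching
    target-node indices (segments of the softmax). ``averaged`` maps back
    to the canonical (possibly undirected) pair order, averaging the two
    directions of an undirected pair.
    """

    edge_type: str
    pairs: list[tuple[str, str]]
    raw: list[np.ndarray]
    src_idx: np.ndarray
    tgt_idx: np.ndarray
    n_tgt: int
    pair_slots: np.ndarray = field(default=None)  # directed edge -> pair id

    def averaged(self) -> np.ndarray:
        """Mean attention per canonical pair over layers, heads, directions."""
        acc = np.zeros(len(self.pairs))
        cnt = np.zeros(len(self.pairs))
        for layer_att in self.raw:
            mean_heads = layer_att.mean(axis=1)
            np.add.at(acc, self.pair_slots, mean_heads)
            np.add.at(cnt, self.pair_slots, 1.0)
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)

    def per_target_sums(self) -> list[np.ndarray]:
        """For each layer, the (n_tgt, heads) per-target attention sums.

        Targets with at least one in-neighbor must sum to 1 per head.
        """
        out = []
        for layer_att in self.raw:
            s = np.zeros((self.n_tgt, layer_att.shape[1]))
            np.add.at(s, self.tgt_idx, layer_att)
            out.append(s)
        return out


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------

_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
    "sigmoid": lambda t: t.sigmoid(),
    "tanh": lambda t: (t * 2.0).sigmoid() * 2.0 - 1.0,
}


def gcn_layer(h_prev, adj: np.ndarray, weight,
              activation: str = "relu"):
    """Graph-convolution pass: ``sigma(D^-1/2 (A+I) D^-1/2 H W)``.

    ``adj`` is the raw square adjacency (no self-loops); the symmetric
    normalization with self-loops is applied internally, so isolated
    nodes keep their own features.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("GCN adjacency must be square")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    norm = a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    h_prev = h_prev if isinstance(h_prev, Tensor) else constant(h_prev)
    weight = weight if isinstance(weight, Tensor) else constant(weight)
    out = constant(norm) @ h_prev @ weight
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite GCN output (exploding weights)")
    return _ACTIVATIONS[activation](out)


def sage_layer(h_tgt, h_src, src_idx, tgt_idx, weight,
               aggregator: str = "mean"):
    """GraphSAGE pass: ``W . concat(H_t, aggregate(neighbor features))``.

    Nodes without neighbors aggregate a zero vector.
    """
    h_tgt = h_tgt if isinstance(h_tgt, Tensor) else constant(h_tgt)
    h_src = h_src if isinstance(h_src, Tensor) else constant(h_src)
    weight = weight if isinstance(weight, Tensor) else constant(weight)
    n_tgt, d = h_tgt.shape
    if weight.shape[0] != 2 * d:
        raise ValueError(f"SAGE weight must have {2 * d} input rows")
    src_idx = np.asarray(src_idx, dtype=np.intp)
    tgt_idx = np.asarray(tgt_idx, dtype=np.intp)
    msgs = h_src.take_rows(src_idx)
    if aggregator == "mean":
        sums = msgs.segment_sum(tgt_idx, n_tgt)
        counts = np.bincount(tgt_idx, minlength=n_tgt).astype(float)
        agg = sums * constant((1.0 / np.maximum(counts, 1.0))[:, None])
    elif aggregator == "pool":
        agg = segment_max(msgs, tgt_idx, n_tgt)
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return (concat([h_tgt, agg], axis=1) @ weight).relu()


def hgt_layer(h_src, h_tgt, src_idx, tgt_idx, block: dict,
              n_tgt: int | None = None, gate_mode: str = "signed"):
    """One heterogeneous graph-transformer block.

    Returns the gated target embeddings and the per-edge attention array
    (n_edges, heads); attention is softmax-normalized per target node.
    Targets without in-edges keep ``(1 - g) * H_prev`` (residual path).
    """
    h_src = h_src if isinstance(h_src, Tensor) else constant(h_src)
    h_tgt = h_tgt if isinstance(h_tgt, Tensor) else constant(h_tgt)
    if n_tgt is None:
        n_tgt = h_tgt.shape[0]
    src_idx = np.asarray(src_idx, dtype=np.intp)
    tgt_idx = np.asarray(tgt_idx, dtype=np.intp)
    heads = len(block["Wk"])
    dh = block["Wk"][0].shape[1]
    scale = 1.0 / np.sqrt(dh)
    per_head, att_cols = [], []
    for h in range(heads):
        k = h_src @ block["Wk"][h]
        q = h_tgt @ block["Wq"][h]
        v = h_src @ block["Wv"][h]
        ke = k.take_rows(src_idx)
        qe = q.take_rows(tgt_idx)
        logits = ((ke @ block["Watt"][h]) * qe).sum(axis=1) * scale
        att = segment_softmax(logits, tgt_idx, n_tgt)
        msg = v.take_rows(src_idx) @ block["Wmsg"][h]
        weighted = msg * att.reshape(-1, 1)
        per_head.append(weighted.segment_sum(tgt_idx, n_tgt))
        att_cols.append(att.data.copy())
    h_tilde = concat(per_head, axis=1) @ block["Wout"]
    gate = block["theta"].sigmoid()
    if gate_mode == "signed":
        # gate strength modulated by the activated message, applied to the
        # signed message itself; preserves anti-correlation in embeddings
        h_out = h_tilde * gate + h_tgt * (1.0 - gate)
    elif gate_mode == "relu":
        h_out = h_tilde.relu() * gate + h_tgt * (1.0 - gate)
    else:
        raise ValueError(f"unknown gate mode {gate_mode!r}")
    return h_out, np.column_stack(att_cols)


# ----------------------------------------------------------------------
# full meta-path forward pass
# ----------------------------------------------------------------------

def _directed_expansion(graph: HeteroRegGraph, edge_type: str):
    """Directed edge arrays plus a directed-edge -> canonical-pair map."""
    src, tgt, _ = graph.edge_index(edge_type, expand_undirected=True)
    n_pairs = len(graph.edges[edge_type])
    slots = np.arange(len(src)) % n_pairs if n_pairs else np.zeros(0, np.intp)
    # expansion order is [pairs..., reversed non-loops...]; recover slots
    if len(src) > n_pairs:
        base_src, base_tgt, _ = graph.edge_index(edge_type)
        loops = base_src == base_tgt
        slots = np.concatenate([np.arange(n_pairs),
                                np.arange(n_pairs)[~loops]])
    else:
        slots = np.arange(n_pairs)
    return src, tgt, slots.astype(np.intp)


def metapath_forward(graph: HeteroRegGraph,
                     features: dict[str, FeatureMatrix],
                     params: EncoderParams,
                     dropout_rng: np.random.Generator | None = None):
    """Run the full hierarchical encoder.

    ``features`` maps node type to a FeatureMatrix whose columns follow
    that node set's order. Returns ``(embeddings, attention)`` where
    ``embeddings`` maps node type to a Tensor (node x embedding_dim) and
    ``attention`` maps each HGT edge type to an :class:`AttentionRecord`.
    """
    cfg = params.config
    if "TF" not in features:
        raise ValueError("TF features are required")
    if len(graph.edges.get("TF-CRE", [])) == 0:
        raise ValueError("TF-CRE edge set must not be empty")

    emb = {}
    for nt in ("TF", "CRE", "TG"):
        fm = features[nt]
        # profiles are standardized across metacells before projection
        x = constant(standardized_profiles(fm).T)  # node x cell
        emb[nt] = x @ params.proj[nt]["W"] + params.proj[nt]["b"]

    def maybe_dropout(t: Tensor) -> Tensor:
        if dropout_rng is None or cfg.dropout <= 0:
            return t
        keep = 1.0 - cfg.dropout
        mask = dropout_rng.random(t.shape) < keep
        return t * constant(mask / keep)

    edge_arrays = {et: _directed_expansion(graph, et)
                   for et in HGT_EDGE_TYPES if et in graph.edges}
    att_layers: dict[str, list[np.ndarray]] = {et: [] for et in edge_arrays}
    tf_adj = graph.adjacency("TF-TF", dense=True) \
        if "TF-TF" in graph.edges else np.zeros((len(graph.nodes["TF"]),) * 2)

    for layer in params.layers:
        # (1) TF <- TF-TF
        if cfg.tf_tf_encoder == "gcn":
            emb["TF"] = gcn_layer(emb["TF"], tf_adj, layer["tf_tf"]["W"],
                                  activation=cfg.gcn_activation)
        else:
            src, tgt, _ = graph.edge_index("TF-TF", expand_undirected=True)
            emb["TF"], _ = hgt_layer(emb["TF"], emb["TF"], src, tgt,
                                     layer["tf_tf_hgt"],
                                     gate_mode=cfg.gate_mode)
        emb["TF"] = maybe_dropout(emb["TF"])
        # (2)-(4) HGT along the meta-path
        stages = (("TF-CRE", "TF", "CRE"), ("CRE-CRE", "CRE", "CRE"),
                  ("CRE-TG", "CRE", "TG"))
        for etype, st, tt in stages:
            if etype not in edge_arrays:
                continue
            src, tgt, _ = edge_arrays[etype]
            emb[tt], att = hgt_layer(emb[st], emb[tt], src, tgt,
                                     layer[etype],
                                     gate_mode=cfg.gate_mode)
            emb[tt] = maybe_dropout(emb[tt])
            att_layers[etype].append(att)
        # (5) TG <- TG-TG loop encoder
        if "TG-TG" in graph.edges and len(graph.edges["TG-TG"]):
            src, tgt, _ = graph.edge_index("TG-TG", expand_undirected=True)
            emb["TG"] = sage_layer(emb["TG"], emb["TG"], src, tgt,
                                   layer["tg_tg"]["W"],
                                   aggregator=cfg.sage_aggregator)
            emb["TG"] = maybe_dropout(emb["TG"])

    attention = {}
    for etype, (src, tgt, slots) in edge_arrays.items():
        _, tt = etype.split("-")[0], etype.split("-")[1]
        n_tgt = len(graph.nodes["CRE" if etype != "CRE-TG" else "TG"])
        attention[etype] = AttentionRecord(
            edge_type=etype,
            pairs=list(graph.edges[etype].pairs),
            raw=att_layers[etype],
            src_idx=src, tgt_idx=tgt, n_tgt=n_tgt,
            pair_slots=slots)
    return emb, attention
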