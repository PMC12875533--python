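"""Data model and I/O for the heterogeneous regulatory graph.

Node types are transcription factors (TF), cis-regulatory elements (CRE,
genomic intervals such as ATAC peaks) and target genes (TG). Edges come in
five typed layers: TF-TF, TF-CRE, CRE-CRE, CRE-TG and TG-TG. Within-type
layers (TF-TF, CRE-CRE, TG-TG) are undirected and stored canonically with
``source <= target`` lexicographically.

File formats are plain text: TSV edge lists, BED (0-based half-open) for
CRE intervals, and MatrixMarket or dense TSV for metacell feature matrices.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

EDGE_TYPES = ("TF-TF", "TF-CRE", "CRE-CRE", "CRE-TG", "TG-TG")
UNDIRECTED_TYPES = frozenset({"TF-TF", "CRE-CRE", "TG-TG"})
#: (source node type, target node type) per edge type
EDGE_ENDPOINTS = {
    "TF-TF": ("TF", "TF"),
    "TF-CRE": ("TF", "CRE"),
    "CRE-CRE": ("CRE", "CRE"),
    "CRE-TG": ("CRE", "TG"),
    "TG-TG": ("TG", "TG"),
}
NODE_TYPES = ("TF", "CRE", "TG")
FEATURE_ROLES = ("TF_expr", "TG_expr", "CRE_acc")


@dataclass
class NodeSet:
    """Ordered, unique identifiers of one node type.

    CRE nodes additionally carry a genomic interval per id
    (``intervals[id] = (chrom, start, end)``, 0-based half-open).
    """

    node_type: str
    ids: list[str]
    intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {self.node_type!r}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate ids in {self.node_type} node set")
        for nid, (chrom, start, end) in self.intervals.items():
            if not (0 <= start < end):
                raise ValueError(
                    f"invalid interval for {nid}: {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.ids)}


@dataclass
class TypedEdgeSet:
    """Weighted edge list of a single type.

    Undirected types are held canonically (``source <= target``); duplicate
    pairs are dropped on construction, keeping the first occurrence.
    """

    edge_type: str
    pairs: list[tuple[str, str]]
    weights: np.ndarray = None

    def __post_init__(self):
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
        if self.weights is None:
            self.weights = np.ones(len(self.pairs))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.pairs):
            raise ValueError("weights length does not match pairs")
        pairs, weights, seen = [], [], set()
        undirected = self.edge_type in UNDIRECTED_TYPES
        for (s, t), w in zip(self.pairs, self.weights):
            if undirected and s > t:
                s, t = t, s
            if (s, t) in seen:
                continue
            seen.add((s, t))
            pairs.append((s, t))
            weights.append(w)
        self.pairs = pairs
        self.weights = np.asarray(weights, dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def subset(self, keep: np.ndarray) -> "TypedEdgeSet":
        keep = np.asarray(keep)
        return TypedEdgeSet(
            self.edge_type,
            [p for p, k in zip(self.pairs, keep) if k],
            self.weights[keep.astype(bool)],
        )

    def reweighted(self, weights) -> "TypedEdgeSet":
        return TypedEdgeSet(self.edge_type, list(self.pairs),
                            np.asarray(weights, dtype=float))


@dataclass
class FeatureMatrix:
    """Metacell x node matrix of non-negative expression/accessibility.

    ``values`` is dense (metacells on axis 0). Initial node embeddings use
    the node x metacell orientation, i.e. ``values.T``.
    """

    values: np.ndarray
    cell_ids: list[str]
    node_ids: list[str]
    role: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in FEATURE_ROLES:
            raise ValueError(f"unknown feature role {self.role!r}")
        if self.values.shape != (len(self.cell_ids), len(self.node_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.node_ids)} nodes")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def column(self, node_id: str) -> np.ndarray:
        return self.values[:, self.node_ids.index(node_id)]

    def aligned_to(self, nodes: NodeSet) -> "FeatureMatrix":
        """Reorder columns to match a node set; error on missing ids."""
        idx = {nid: i for i, nid in enumerate(self.node_ids)}
        missing = [nid for nid in nodes.ids if nid not in idx]
        if missing:
            raise KeyError(
                f"feature matrix missing node id(s): {missing[:5]}")
        cols = [idx[nid] for nid in nodes.ids]
        return FeatureMatrix(self.values[:, cols], self.cell_ids,
                             list(nodes.ids), self.role)


@dataclass
class HeteroRegGraph:
    """Typed node sets plus one weighted edge set per edge type."""

    nodes: dict[str, NodeSet]
    edges: dict[str, TypedEdgeSet]

    def __post_init__(self):
        for etype, eset in self.edges.items():
            st, tt = EDGE_ENDPOINTS[etype]
            sidx = self.nodes[st].index
            tidx = self.nodes[tt].index
            for s, t in eset.pairs:
                if s not in sidx:
                    raise KeyError(
                        f"{etype} source {s!r} not a {st} node")
                if t not in tidx:
                    raise KeyError(
                        f"{etype} target {t!r} not a {tt} node")

    def edge_index(self, edge_type: str,
                   expand_undirected: bool = False):
        """Integer (src_idx, tgt_idx, weight) arrays for an edge type.

        With ``expand_undirected`` each undirected pair yields both
        directed edges.
        """
        eset = self.edges[edge_type]
        st, tt = EDGE_ENDPOINTS[edge_type]
        sidx = self.nodes[st].index
        tidx = self.nodes[tt].index
        src = np.array([sidx[s] for s, _ in eset.pairs], dtype=np.intp)
        tgt = np.array([tidx[t] for _, t in eset.pairs], dtype=np.intp)
        w = eset.weights.copy()
        if expand_undirected and edge_type in UNDIRECTED_TYPES:
            loops = src == tgt
            src, tgt = (np.concatenate([src, tgt[~loops]]),
                        np.concatenate([tgt, src[~loops]]))
            w = np.concatenate([w, w[~loops]])
        return src, tgt, w

    def adjacency(self, edge_type: str, dense: bool = False):
        """Weighted adjacency, source x target; symmetric for undirected."""
        st, tt = EDGE_ENDPOINTS[edge_type]
        src, tgt, w = self.edge_index(edge_type, expand_undirected=True)
        a = sp.coo_matrix((w, (src, tgt)),
                          shape=(len(self.nodes[st]), len(self.nodes[tt])))
        a = a.tocsr()
        return a.toarray() if dense else a

    def normalized_adjacency(self, edge_type: str) -> np.ndarray:
        """Symmetric GCN normalization D^-1/2 (A+I) D^-1/2.

        Only defined for within-type (square) adjacencies; self-loops make
        every degree strictly positive.
        """
        if edge_type not in UNDIRECTED_TYPES:
            raise ValueError(
                f"normalized adjacency requires a within-type layer, "
                f"got {edge_type}")
        a = self.adjacency(edge_type, dense=True)
        a_tilde = a + np.eye(a.shape[0])
        d = a_tilde.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(d)
        return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass
class HRNet:
    """Attention-weighted four-layer hierarchical regulatory network.

    Layers TF-TF, TF-CRE, CRE-CRE and CRE-TG; per-edge weights in [0, 1]
    (attention or decoder probability). The scaffold for expression
    prediction, random-walk prioritization and co-CRE module discovery.
    """

    layers: dict[str, TypedEdgeSet]
    nodes: dict[str, NodeSet] = None

    def __post_init__(self):
        for etype, eset in self.layers.items():
            if etype == "TG-TG":
                raise ValueError("HRNet holds only the four regulatory layers")
            if len(eset) and ((eset.weights < 0).any()
                              or (eset.weights > 1).any()):
                raise ValueError(
                    f"{etype} layer has weights outside [0, 1]")


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_edge_list(path, edge_type: str, header: bool = False,
                   default_weight: float = 1.0) -> TypedEdgeSet:
    """Read a TSV edge list (source, target[, weight])."""
    if edge_type not in EDGE_TYPES:
        raise ValueError(f"unknown edge type {edge_type!r}")
    df = pd.read_csv(path, sep="\t", header=0 if header else None,
                     dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least source and target columns")
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if df.shape[1] >= 3:
        weights = df.iloc[:, 2].astype(float).to_numpy()
    else:
        weights = np.full(len(pairs), default_weight)
    return TypedEdgeSet(edge_type, pairs, weights)


def write_edge_list(eset: TypedEdgeSet, path, header: bool = True,
                    weight_col: str = "weight"):
    df = pd.DataFrame(eset.pairs, columns=["source", "target"])
    df[weight_col] = eset.weights
    df.to_csv(path, sep="\t", index=False, header=header,
              float_format="%.6f")


def read_cre_bed(path) -> NodeSet:
    """Read CRE intervals from a BED file (0-based half-open).

    Ids are rendered ``chrom:start-end``; file order is preserved; lines
    with ``start >= end`` are rejected with a warning naming them.
    """
    ids, intervals, bad = [], {}, []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                bad.append((lineno, "fewer than 3 columns"))
                continue
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                bad.append((lineno, f"start {start} >= end {end}"))
                continue
            nid = f"{chrom}:{start}-{end}"
            if nid in intervals:
                continue
            ids.append(nid)
            intervals[nid] = (chrom, start, end)
    if bad:
        warnings.warn(
            f"{path}: rejected {len(bad)} line(s): "
            + "; ".join(f"line {ln} ({why})" for ln, why in bad[:5]))
    return NodeSet("CRE", ids, intervals)


def write_cre_bed(nodes: NodeSet, path):
    with open(path, "w") as fh:
        for nid in nodes.ids:
            chrom, start, end = nodes.intervals[nid]
            fh.write(f"{chrom}\t{start}\t{end}\n")


def _read_names(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_feature_matrix(matrix, rows=None, cols=None,
                        role: str = "TG_expr") -> FeatureMatrix:
    """Read a metacell x node matrix from MTX or dense TSV.

    MTX requires ``rows``/``cols`` name files (one id per line). A dense
    TSV may carry its own header/index, or use the name files.
    """
    matrix = os.fspath(matrix)
    if matrix.endswith(".mtx"):
        if rows is None or cols is None:
            raise ValueError("MTX input requires row and column name files")
        mat = scipy.io.mmread(matrix)
        values = np.asarray(mat.todense() if sp.issparse(mat) else mat,
                            dtype=float)
        cell_ids, node_ids = _read_names(rows), _read_names(cols)
    elif rows is not None and cols is not None:
        values = pd.read_csv(matrix, sep="\t", header=None).to_numpy(float)
        cell_ids, node_ids = _read_names(rows), _read_names(cols)
    else:
        df = pd.read_csv(matrix, sep="\t", index_col=0)
        values = df.to_numpy(float)
        cell_ids = [str(i) for i in df.index]
        node_ids = [str(c) for c in df.columns]
    if values.shape != (len(cell_ids), len(node_ids)):
        raise ValueError(
            f"{matrix}: shape {values.shape} does not match "
            f"{len(cell_ids)} row names x {len(node_ids)} column names")
    return FeatureMatrix(values, cell_ids, node_ids, role)


def write_feature_matrix(fm: FeatureMatrix, matrix, rows, cols):
    """Write a dense TSV plus row/column name files (round-trips)."""
    np.savetxt(matrix, fm.values, delimiter="\t", fmt="%.10g")
    with open(rows, "w") as fh:
        fh.write("\n".join(fm.cell_ids) + "\n")
    with open(cols, "w") as fh:
        fh.write("\n".join(fm.node_ids) + "\n")


def export_hrnet(hrnet: HRNet, out_dir) -> dict[str, str]:
    """Write one TSV per HRNet layer: source, target, attention_weight.

    Weights must already satisfy the [0, 1] invariant; files round-trip
    through :func:`read_edge_list`.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for etype, eset in hrnet.layers.items():
        if len(eset) and ((eset.weights < 0).any()
                          or (eset.weights > 1).any()):
            raise ValueError(f"{etype} weights outside [0, 1]; refusing")
        fname = etype.lower().replace("-", "_") + ".tsv"
        path = os.path.join(out_dir, fname)
        df = pd.DataFrame(eset.pairs, columns=["source", "target"])
        df["attention_weight"] = eset.weights
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written[etype] = path
    return written


def import_hrnet(in_dir) -> HRNet:
    layers = {}
    for etype in ("TF-TF", "TF-CRE", "CRE-CRE", "CRE-TG"):
        path = os.path.join(in_dir, etype.lower().replace("-", "_") + ".tsv")
        if os.path.exists(path):
            layers[etype] = read_edge_list(path, etype, header=True)
    return HRNet(layers)
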