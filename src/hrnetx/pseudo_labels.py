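"""Semi-supervised edge labels from expression/accessibility correlation.

True regulatory pairs tend to show higher correlation across metacells
than random pairs, so high-PCC candidate edges serve as pseudo-positives.
Pseudo-negatives are sampled, at a controlled ratio, from node pairs that
are absent from the candidate prior for that edge type. The class weight
``alpha = |neg| / (|pos| + |neg|)`` balances the two classes in the
weighted cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_graph import FeatureMatrix, NodeSet, TypedEdgeSet


@dataclass
class EdgeLabelSet:
    """Pseudo-positive / pseudo-negative labels for one edge type."""

    edge_type: str
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    alpha: float = field(init=False)

    def __post_init__(self):
        total = len(self.positives) + len(self.negatives)
        self.alpha = len(self.negatives) / total if total else 0.5

    @property
    def L(self) -> int:
        return len(self.positives) + len(self.negatives)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return self.positives + self.negatives

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.positives)),
                               np.zeros(len(self.negatives))])


def edge_correlations(features_a: FeatureMatrix, features_b: FeatureMatrix,
                      candidates: TypedEdgeSet) -> np.ndarray:
    """Pearson correlation across metacells for each candidate pair.

    Source endpoints are looked up in ``features_a``, targets in
    ``features_b``; both must share the metacell axis. Constant columns
    yield PCC 0 (no linear association evidence).
    """
    if features_a.n_cells != features_b.n_cells:
        raise ValueError("feature matrices must share the metacell axis")
    if features_a.n_cells < 3:
        raise ValueError("need at least 3 metacells for correlation")

    def standardized(fm: FeatureMatrix):
        x = fm.values
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        z = np.zeros_like(x)
        ok = sd > 0
        z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
        return z

    za, zb = standardized(features_a), standardized(features_b)
    ia = {nid: i for i, nid in enumerate(features_a.node_ids)}
    ib = {nid: i for i, nid in enumerate(features_b.node_ids)}
    try:
        src = np.array([ia[s] for s, _ in candidates.pairs])
        tgt = np.array([ib[t] for _, t in candidates.pairs])
    except KeyError as exc:
        raise KeyError(f"candidate endpoint missing from features: {exc}")
    if len(candidates) == 0:
        return np.zeros(0)
    return (za[:, src] * zb[:, tgt]).mean(axis=0)


def build_labels(pcc: np.ndarray, candidates: TypedEdgeSet,
                 threshold: float, neg_ratio: float, seed: int,
                 universe: tuple[NodeSet, NodeSet],
                 exclude: set[tuple[str, str]] | None = None) -> EdgeLabelSet:
    """Select pseudo-positives by PCC threshold and sample pseudo-negatives.

    Positives are candidates with ``PCC >= threshold``; negatives are a
    seeded uniform sample of ``round(neg_ratio * |positives|)`` node pairs
    outside the candidate set (and outside ``exclude``, e.g. pairs already
    used by a held-out split).
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be positive")
    pcc = np.asarray(pcc)
    if len(pcc) != len(candidates):
        raise ValueError("one PCC per candidate pair required")
    positives = [p for p, r in zip(candidates.pairs, pcc) if r >= threshold]
    if not positives:
        raise ValueError(
            f"no candidate reaches PCC {threshold}; lower the threshold")
    n_neg = int(round(neg_ratio * len(positives)))
    forbidden = candidates.pair_set()
    if exclude:
        forbidden = forbidden | set(exclude)
    negatives = sample_negative_pairs(
        universe, n_neg, forbidden, np.random.default_rng(seed),
        undirected=candidates.edge_type in {"TF-TF", "CRE-CRE", "TG-TG"})
    return EdgeLabelSet(candidates.edge_type, positives, negatives)


def sample_negative_pairs(universe: tuple[NodeSet, NodeSet], n: int,
                          forbidden: set[tuple[str, str]],
                          rng: np.random.Generator,
                          undirected: bool = False) -> list[tuple[str, str]]:
    """Uniform sample of ``n`` distinct node pairs outside ``forbidden``."""
    src_ids, tgt_ids = universe[0].ids, universe[1].ids
    total = len(src_ids) * len(tgt_ids)
    if total - len(forbidden) < n:
        raise ValueError(
            f"negative universe too small: need {n}, "
            f"have at most {total - len(forbidden)}")
    out: list[tuple[str, str]] = []
    chosen: set[tuple[str, str]] = set()
    # rejection sampling; the universe is far larger than the prior
    while len(out) < n:
        batch = max(64, 2 * (n - len(out)))
        si = rng.integers(0, len(src_ids), size=batch)
        ti = rng.integers(0, len(tgt_ids), size=batch)
        for a, b in zip(si, ti):
            s, t = src_ids[a], tgt_ids[b]
            if undirected:
                if s == t:
                    continue
                if s > t:
                    s, t = t, s
            if (s, t) in forbidden or (s, t) in chosen:
                continue
            chosen.add((s, t))
            out.append((s, t))
            if len(out) == n:
                break
    return out


def split_labels(labels: EdgeLabelSet, fractions=(0.8, 0.1, 0.1),
                 seed: int = 0) -> tuple[EdgeLabelSet, EdgeLabelSet,
                                         EdgeLabelSet]:
    """Seeded edge-level train/val/test split, stratified by class."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)

    def split_list(items):
        items = list(items)
        order = rng.permutation(len(items))
        n_tr = int(round(fractions[0] * len(items)))
        n_va = int(round(fractions[1] * len(items)))
        tr = [items[i] for i in order[:n_tr]]
        va = [items[i] for i in order[n_tr:n_tr + n_va]]
        te = [items[i] for i in order[n_tr + n_va:]]
        return tr, va, te

    pos = split_list(labels.positives)
    neg = split_list(labels.negatives)
    return tuple(EdgeLabelSet(labels.edge_type, p, n)
                 for p, n in zip(pos, neg))


def grid_search_threshold(thresholds, score_fn) -> tuple[float, dict]:
    """Pick the PCC threshold maximizing a validation score.

    ``score_fn(threshold)`` returns a scalar (e.g. validation AUPR);
    thresholds that raise (e.g. zero positives) are skipped.
    """
    results = {}
    for th in thresholds:
        try:
            results[th] = float(score_fn(th))
        except ValueError:
            continue
    if not results:
        raise ValueError("no threshold produced a valid label set")
    best = max(results, key=lambda th: (results[th], -th))
    return best, results
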