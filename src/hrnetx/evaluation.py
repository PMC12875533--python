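"""Benchmark metrics for edge and expression prediction.

AUPR uses the step-wise (non-interpolated) precision-recall area, AUROC
uses midrank tie handling; both delegate to scikit-learn. Maximal F1 is
the best harmonic mean of precision and recall over all score thresholds,
computed per grouping key (e.g. per TF). Precision@N ranks candidates by
score with lexicographic tie-breaking on edge id.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, \
    roc_auc_score


def aupr_auc(scores, truth) -> tuple[float, float]:
    """Area under the precision-recall and ROC curves."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if truth.sum() == 0 or truth.sum() == len(truth):
        raise ValueError("truth must contain both classes")
    return (float(average_precision_score(truth, scores)),
            float(roc_auc_score(truth, scores)))


def max_f1(scores, truth) -> float:
    """Maximum F1 over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    prec, rec, _ = precision_recall_curve(truth, scores)
    denom = prec + rec
    f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1),
                  0.0)
    return float(f1.max())


def max_f1_per_group(scores, truth, groups) -> dict:
    """Per-group maximal F1; groups without positives are skipped."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        m = groups == g
        if truth[m].sum() == 0:
            warnings.warn(f"group {g!r} has no positives; skipped")
            continue
        out[g] = max_f1(scores[m], truth[m])
    return out


def precision_at_n(scores, truth, n_list, ids=None) -> dict[int, float]:
    """Precision among the top-N candidates by score.

    Ties are broken lexicographically on ``ids`` (or input order when ids
    are absent); N larger than the candidate count is clamped with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if ids is None:
        order = np.argsort(-scores, kind="stable")
    else:
        ids = np.asarray(ids, dtype=object)
        order = sorted(range(len(scores)), key=lambda i: (-scores[i], ids[i]))
        order = np.asarray(order)
    out = {}
    for n in n_list:
        k = int(n)
        if k > len(scores):
            warnings.warn(f"N={k} exceeds {len(scores)} candidates; clamped")
            k = len(scores)
        out[int(n)] = float(truth[order[:k]].mean()) if k else float("nan")
    return out


def deg_enrichment_of_predictions(ranked_genes, deg_genes, universe,
                                  k: int) -> float:
    """Fold enrichment of the top-k predicted genes in a DEG set.

    ``(|top-k ∩ DEG| / k) / (|DEG| / |universe|)``.
    """
    ranked = list(ranked_genes)
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds {len(ranked)} ranked genes")
    degs = set(deg_genes) & set(universe)
    if not degs:
        raise ValueError("no DEG overlaps the universe")
    top = set(ranked[:k])
    return (len(top & degs) / k) / (len(degs) / len(set(universe)))
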