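"""Naive, independent reference implementations used as test oracles.

Everything here is deliberately written per-pair / per-threshold with plain
Python sets and loops, independent of the vectorised implementations in the
package.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_network_contribution(matrix: np.ndarray) -> dict[int, float]:
    """Per-partner (column) contribution -ln(deg/total); degree-0 excluded."""
    m = np.asarray(matrix)
    degs = {k: int(m[:, k].sum()) for k in range(m.shape[1])}
    total = sum(degs.values())
    return {k: -math.log(d / total) for k, d in degs.items() if d > 0}


def oracle_network_similarity(matrix: np.ndarray) -> np.ndarray:
    """Per-pair sum of shared-partner contributions (diagonal = own partners)."""
    m = np.asarray(matrix)
    nc = oracle_network_contribution(m) if m.sum() else {}
    partners = [set(np.flatnonzero(row)) for row in m]
    n = m.shape[0]
    out = np.zeros((n, n))
    for u in range(n):
        for v in range(n):
            out[u, v] = sum(nc[k] for k in partners[u] & partners[v] if k in nc)
    return out


def _oracle_entropy_terms(matrix: np.ndarray, partners_are_cols: bool) -> dict[int, float]:
    m = np.asarray(matrix)
    counts = m.sum(axis=0) if partners_are_cols else m.sum(axis=1)
    total = m.sum()
    terms = {}
    for i, c in enumerate(counts):
        if c > 0:
            p = c / total
            terms[i] = -p * math.log2(p)
    return terms


def oracle_entropy_similarity(matrix: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Set-based Dice-of-pseudo-entropy similarity."""
    m = np.asarray(matrix)
    if axis == "cols":
        ents = [set(np.flatnonzero(m[:, j])) for j in range(m.shape[1])]
        terms = _oracle_entropy_terms(m, partners_are_cols=False)
    else:
        ents = [set(np.flatnonzero(m[i, :])) for i in range(m.shape[0])]
        terms = _oracle_entropy_terms(m, partners_are_cols=True)

    def h(partner_set: set[int]) -> float:
        return sum(terms.get(i, 0.0) for i in partner_set)

    n = len(ents)
    out = np.zeros((n, n))
    for u in range(n):
        for v in range(n):
            denom = h(ents[u]) + h(ents[v])
            if denom > 0:
                out[u, v] = 2.0 * h(ents[u] & ents[v]) / denom
            else:
                out[u, v] = 1.0 if u == v else 0.0
    return out


def oracle_auc(scores, labels) -> float:
    """Brute-force Mann-Whitney AUC over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_aupr(scores, labels) -> float:
    """Step-wise average precision by exhaustive threshold enumeration."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    ap, r_prev = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        calls = scores >= t
        tp = int(np.sum(calls & (labels == 1)))
        precision = tp / int(calls.sum())
        recall = tp / n_pos
        ap += (recall - r_prev) * precision
        r_prev = recall
    return ap
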