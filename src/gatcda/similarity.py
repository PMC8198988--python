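"""Topological similarity measures used as node features.

Two families of similarity are computed for circRNAs and diseases:

* **Network similarity** (CNS / DNS). Each partner node (a miRNA in the
  circRNA-miRNA network, an mRNA in the disease-mRNA network) carries a
  *network contribution* ``nc = -ln(deg / total)`` — the information content
  of its relative interaction frequency, so rare partners are worth more.
  The similarity of two entities is the summed contribution of their shared
  partners.

* **Information-entropy similarity** (CES / DES). Each entity's partner set
  in the circRNA-disease matrix defines a pseudo-entropy
  ``H = -sum p log2 p`` with ``p`` the partner's share of all known
  associations; the similarity of two entities is a Dice-style ratio
  ``2 H(shared partners) / (H_u + H_v)`` in [0, 1].

The integrated similarities ICS (circRNAs) and IDS (diseases) are convex
mixtures controlled by adjusting parameters ``beta`` and ``alpha``; the
disease mixture additionally folds in the symptom-based similarity DSS.

Note the ``p`` values are relative to the total association count, so they
generally do not sum to one over one entity's partners; ``H`` is used exactly
as written, as a non-negative pseudo-entropy, without renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BipartiteNetwork, DataError, EntityIndex, SimilarityMatrix

__all__ = [
    "NetworkContribution",
    "EntropyProfile",
    "FusionWeights",
    "network_contribution",
    "network_similarity",
    "entropy_profile",
    "entropy_similarity",
    "integrate_circ",
    "integrate_dis",
]


@dataclass
class NetworkContribution:
    """Per-partner contribution ``nc``; zero-degree partners carry 0 (excluded)."""

    index: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index),):
            raise DataError("contribution length does not match partner index")


@dataclass
class EntropyProfile:
    """Partner interaction counts, rates and pseudo-entropy of one entity."""

    owner: str
    partners: tuple[str, ...]
    counts: np.ndarray
    rates: np.ndarray
    total: int
    entropy: float


@dataclass(frozen=True)
class FusionWeights:
    """Adjusting parameters for similarity integration, both in [0, 1]."""

    alpha: float = 0.1
    beta: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise DataError("alpha and beta must lie in [0, 1]")


def network_contribution(
    net: BipartiteNetwork, interpretation: str = "relative"
) -> NetworkContribution:
    """Contribution of each column partner (miRNA / mRNA) of ``net``.

    ``interpretation="relative"`` (default) reads the contribution as
    ``-ln(deg_k / sum_j deg_j)``, the information content of the partner's
    relative frequency, which is always >= 0. The alternative ``"scaled"``
    reading ``(-ln deg_k) / sum_j deg_j`` is kept for sensitivity analysis
    only; it goes negative for partners of degree >= 2.
    """
    deg = net.matrix.sum(axis=0).astype(float)
    total = deg.sum()
    values = np.zeros_like(deg)
    if total == 0:
        import warnings

        warnings.warn(
            f"{net.name or 'network'} has no interactions; contributions are zero",
            stacklevel=2,
        )
        return NetworkContribution(net.col_index, values)
    pos = deg > 0
    if interpretation == "relative":
        values[pos] = -np.log(deg[pos] / total)
    elif interpretation == "scaled":
        values[pos] = -np.log(deg[pos]) / total
    else:
        raise DataError(f"unknown nc interpretation {interpretation!r}")
    return NetworkContribution(net.col_index, values)


def network_similarity(
    net: BipartiteNetwork,
    contrib: NetworkContribution | None = None,
    kind: str = "CNS",
    interpretation: str = "relative",
) -> SimilarityMatrix:
    """Shared-partner similarity: S(u, v) = sum of nc over common partners.

    The diagonal S(u, u) is the sum over the entity's own partners. Computed
    as B diag(nc) B^T with B the binary interaction matrix.
    """
    if contrib is None:
        contrib = network_contribution(net, interpretation)
    if contrib.index is not net.col_index and contrib.index != net.col_index:
        raise DataError("contribution computed from a different partner index")
    b = net.matrix.astype(float)
    sim = (b * contrib.values) @ b.T
    sim = (sim + sim.T) / 2.0  # exact up to fp rounding; enforce symmetry
    return SimilarityMatrix(net.row_index, sim, kind)


def _partner_terms(y: np.ndarray, axis: int) -> tuple[np.ndarray, float]:
    """Per-partner entropy terms -p log2 p with p = count / total ones in y."""
    counts = y.sum(axis=0 if axis == 0 else 1).astype(float)
    # axis=0: entities are rows, partners are columns (column counts);
    # axis=1: entities are columns, partners are rows.
    total = float(y.sum())
    terms = np.zeros_like(counts)
    if total > 0:
        p = counts / total
        pos = counts > 0
        terms[pos] = -p[pos] * np.log2(p[pos])
    return terms, total


def entropy_profile(
    y: BipartiteNetwork, entity: str, axis: str = "rows"
) -> EntropyProfile:
    """Entropy profile of one circRNA (``axis="rows"``) or disease (``"cols"``).

    The profile lists the entity's partners with, for each, the number of
    interactions that partner has with *all* entities on the other side, the
    corresponding rate p = n / N, and the pseudo-entropy H = -sum p log2 p.
    """
    if axis == "rows":
        own = y.matrix[y.row_index.position(entity)]
        partner_index, mat_axis = y.col_index, 0
    elif axis == "cols":
        own = y.matrix[:, y.col_index.position(entity)]
        partner_index, mat_axis = y.row_index, 1
    else:
        raise DataError("axis must be 'rows' or 'cols'")
    terms, total = _partner_terms(y.matrix, mat_axis)
    counts = y.matrix.sum(axis=0 if mat_axis == 0 else 1).astype(float)
    sel = own.astype(bool)
    partners = tuple(partner_index.names[i] for i in np.flatnonzero(sel))
    c = counts[sel]
    rates = c / total if total > 0 else np.zeros_like(c)
    return EntropyProfile(
        owner=entity,
        partners=partners,
        counts=c,
        rates=rates,
        total=int(total),
        entropy=float(terms[sel].sum()),
    )


def entropy_similarity(y: BipartiteNetwork, axis: str = "rows") -> SimilarityMatrix:
    """Dice-style entropy similarity (CES for circRNAs, DES for diseases).

    CES(u, v) = 2 H(shared partners) / (H_u + H_v), with the convention that a
    pair whose entropies are both zero scores 0 off the diagonal and 1 on it
    (two isolated entities carry no evidence either way).
    """
    if axis == "rows":
        b = y.matrix.astype(float)
        index, kind, mat_axis = y.row_index, "CES", 0
    elif axis == "cols":
        b = y.matrix.T.astype(float)
        index, kind, mat_axis = y.col_index, "DES", 1
    else:
        raise DataError("axis must be 'rows' or 'cols'")
    terms, _ = _partner_terms(y.matrix, mat_axis)
    h = b @ terms
    h_shared = (b * terms) @ b.T
    denom = h[:, None] + h[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, 2.0 * h_shared / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sim, np.where(h > 0, np.diag(sim), 1.0))
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(index, sim, kind)


def _minmax(mat: np.ndarray) -> np.ndarray:
    lo, hi = mat.min(), mat.max()
    if hi <= lo:
        return np.zeros_like(mat)
    return (mat - lo) / (hi - lo)


def integrate_circ(
    cns: SimilarityMatrix,
    ces: SimilarityMatrix,
    weights: FusionWeights,
    scale: str = "none",
) -> SimilarityMatrix:
    """ICS = beta * CNS + (1 - beta) * CES, elementwise.

    ``scale="minmax"`` rescales the unbounded network similarity to [0, 1]
    before mixing; the default leaves both terms on their native scales.
    """
    if cns.index != ces.index:
        raise DataError("CNS and CES indices differ")
    cns_m = _minmax(cns.matrix) if scale == "minmax" else cns.matrix
    b = weights.beta
    return SimilarityMatrix(cns.index, b * cns_m + (1.0 - b) * ces.matrix, "ICS")


def integrate_dis(
    dns: SimilarityMatrix,
    dss: SimilarityMatrix,
    des: SimilarityMatrix,
    weights: FusionWeights,
    scale: str = "none",
) -> SimilarityMatrix:
    """IDS = alpha * (DNS + DSS) + (1 - alpha) * DES, elementwise."""
    if not (dns.index == dss.index == des.index):
        raise DataError("DNS/DSS/DES indices differ")
    dns_m = _minmax(dns.matrix) if scale == "minmax" else dns.matrix
    a = weights.alpha
    return SimilarityMatrix(
        dns.index, a * (dns_m + dss.matrix) + (1.0 - a) * des.matrix, "IDS"
    )
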