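"""The GATCDA estimator: similarity features + graph attention + bilinear scores.

:class:`GatcdaPredictor` is a scikit-learn style estimator. ``fit`` takes the
binary circRNA-disease matrix ``Y`` (nc x nd) together with optional side
information — a circRNA-miRNA interaction matrix, a disease-mRNA interaction
matrix and a symptom-based disease similarity matrix — computes the fused
similarity features ICS/IDS, trains a multi-head graph attention encoder on
the association graph and exposes the dense score matrix ``S = U V^T``.

Feature construction: ICS rows (length nc) and IDS rows (length nd) live in
different spaces, so each node's raw feature is the zero-padded block
concatenation ``[ICS_row || 0]`` for circRNAs and ``[0 || IDS_row]`` for
diseases (common width F = nc + nd). This preserves all similarity
information without inventing a cross-type map.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import BipartiteNetwork, DataError, EntityIndex, SimilarityMatrix
from .gat import GatConfig, build_graph, score_pairs, train_gat
from .similarity import (
    FusionWeights,
    entropy_similarity,
    integrate_circ,
    integrate_dis,
    network_similarity,
)

__all__ = ["GatcdaPredictor", "make_index", "as_network"]


_PREFIX = {"circRNA": "c", "disease": "d", "miRNA": "mi", "mRNA": "g"}


def make_index(kind: str, n: int, prefix: str | None = None) -> EntityIndex:
    """Placeholder index with zero-padded names (lexicographic == positional)."""
    prefix = prefix or _PREFIX[kind]
    width = max(len(str(max(n - 1, 0))), 1)
    return EntityIndex(kind, tuple(f"{prefix}{i:0{width}d}" for i in range(n)))


def as_network(
    x: BipartiteNetwork | np.ndarray,
    row_kind: str,
    col_kind: str,
    name: str,
    row_index: EntityIndex | None = None,
    col_index: EntityIndex | None = None,
) -> BipartiteNetwork:
    """Wrap a plain array into a BipartiteNetwork (pass networks through)."""
    if isinstance(x, BipartiteNetwork):
        return x
    x = np.asarray(x)
    rows = row_index if row_index is not None else make_index(row_kind, x.shape[0])
    cols = col_index if col_index is not None else make_index(col_kind, x.shape[1])
    return BipartiteNetwork(rows, cols, x, name=name)


class GatcdaPredictor(BaseEstimator):
    """Predict circRNA-disease associations with a graph attention network.

    Parameters
    ----------
    alpha, beta : float
        Adjusting parameters of the similarity fusion: the disease feature is
        ``alpha * (DNS + DSS) + (1 - alpha) * DES`` and the circRNA feature is
        ``beta * CNS + (1 - beta) * CES``. Defaults (0.1, 0.1) are the
        best-performing grid point in cross-validation.
    embed_dim, n_heads, n_layers, leaky_slope, dropout, edge_dropout,
    learning_rate, epochs, weight_decay, neg_ratio : GAT architecture and
        training settings, see :class:`~gatcda.gat.GatConfig`. In particular
        ``edge_dropout`` hides a random fraction of the association edges
        from the attention graph each epoch so the encoder generalises to
        pairs whose edge is absent — the condition under which held-out
        pairs are scored.
    nc_interpretation : {"relative", "scaled"}
        Reading of the network-contribution formula; see
        :func:`~gatcda.similarity.network_contribution`.
    scale_similarities : {"none", "minmax"}
        Optional min-max rescaling of the unbounded network similarities
        before fusion.
    feature_norm : {"l2", "none"}
        L2-normalise each node's feature row (default); raw ICS/IDS rows
        have norms spanning orders of magnitude, which destabilises
        attention training.
    random_state : int
        Seed for parameter initialisation and negative sampling.

    Attributes
    ----------
    score_matrix_ : ndarray of shape (nc, nd)
        Bilinear association scores S = U V^T.
    U_, V_ : circRNA and disease embeddings (nc x F', nd x F').
    ics_, ids_ : fused similarity matrices used as node features.
    cns_, ces_, dns_, des_, dss_ : the individual similarity components.
    loss_history_ : per-epoch training loss (non-increasing start to end on
        well-posed problems).
    """

    def __init__(
        self,
        alpha: float = 0.1,
        beta: float = 0.1,
        embed_dim: int = 32,
        n_heads: int = 2,
        n_layers: int = 2,
        leaky_slope: float = 0.2,
        dropout: float = 0.1,
        edge_dropout: float = 0.9,
        learning_rate: float = 5e-3,
        epochs: int = 300,
        weight_decay: float = 0.0,
        neg_ratio: float = 5.0,
        nc_interpretation: str = "relative",
        scale_similarities: str = "none",
        feature_norm: str = "l2",
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.leaky_slope = leaky_slope
        self.dropout = dropout
        self.edge_dropout = edge_dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.neg_ratio = neg_ratio
        self.nc_interpretation = nc_interpretation
        self.scale_similarities = scale_similarities
        self.feature_norm = feature_norm
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _gat_config(self) -> GatConfig:
        return GatConfig(
            embed_dim=self.embed_dim,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            leaky_slope=self.leaky_slope,
            dropout=self.dropout,
            edge_dropout=self.edge_dropout,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            weight_decay=self.weight_decay,
            neg_ratio=self.neg_ratio,
            seed=self.random_state,
        )

    def build_features(
        self,
        Y: BipartiteNetwork,
        circ_mirna: BipartiteNetwork | None,
        dis_mrna: BipartiteNetwork | None,
        symptom_sim: SimilarityMatrix | None,
    ) -> np.ndarray:
        """Compute CNS/DNS/CES/DES/DSS, fuse into ICS/IDS, block-pad to (N, F)."""
        nc, nd = Y.shape
        w = FusionWeights(alpha=self.alpha, beta=self.beta)

        def zero_sim(index: EntityIndex, kind: str) -> SimilarityMatrix:
            m = np.zeros((len(index), len(index)))
            return SimilarityMatrix(index, m, kind)

        if circ_mirna is not None:
            cns = network_similarity(
                circ_mirna, kind="CNS", interpretation=self.nc_interpretation
            )
        else:
            cns = zero_sim(Y.row_index, "CNS")
        if dis_mrna is not None:
            dns = network_similarity(
                dis_mrna, kind="DNS", interpretation=self.nc_interpretation
            )
        else:
            dns = zero_sim(Y.col_index, "DNS")
        if symptom_sim is None:
            m = np.eye(nd)
            symptom_sim = SimilarityMatrix(Y.col_index, m, "DSS")
        ces = entropy_similarity(Y, axis="rows")
        des = entropy_similarity(Y, axis="cols")
        ics = integrate_circ(cns, ces, w, scale=self.scale_similarities)
        ids = integrate_dis(dns, symptom_sim, des, w, scale=self.scale_similarities)

        self.cns_, self.ces_, self.dns_, self.des_, self.dss_ = cns, ces, dns, des, symptom_sim
        self.ics_, self.ids_ = ics, ids

        feats = np.zeros((nc + nd, nc + nd))
        feats[:nc, :nc] = ics.matrix
        feats[nc:, nc:] = ids.matrix
        if self.feature_norm == "l2":
            norms = np.linalg.norm(feats, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            feats = feats / norms
        elif self.feature_norm != "none":
            raise DataError(f"unknown feature_norm {self.feature_norm!r}")
        return feats

    def fit(
        self,
        Y: BipartiteNetwork | np.ndarray,
        y=None,
        *,
        circ_mirna: BipartiteNetwork | np.ndarray | None = None,
        dis_mrna: BipartiteNetwork | np.ndarray | None = None,
        symptom_sim: SimilarityMatrix | np.ndarray | None = None,
    ) -> "GatcdaPredictor":
        """Fit on a binary association matrix plus optional side information.

        ``Y`` is nc x nd with rows = circRNAs, columns = diseases; the
        auxiliary matrices must share the corresponding axis (rows of
        ``circ_mirna`` are circRNAs, rows of ``dis_mrna`` are diseases).
        """
        net = as_network(Y, "circRNA", "disease", "Y")
        nc, nd = net.shape
        cm = (
            as_network(circ_mirna, "circRNA", "miRNA", "cm", row_index=net.row_index)
            if circ_mirna is not None
            else None
        )
        if cm is not None and len(cm.row_index) != nc:
            raise DataError("circ_mirna row count differs from Y")
        dm = (
            as_network(dis_mrna, "disease", "mRNA", "dm", row_index=net.col_index)
            if dis_mrna is not None
            else None
        )
        if dm is not None and len(dm.row_index) != nd:
            raise DataError("dis_mrna row count differs from Y")
        dss = symptom_sim
        if dss is not None and not isinstance(dss, SimilarityMatrix):
            dss = SimilarityMatrix(net.col_index, np.asarray(dss, dtype=float), "DSS")

        features = self.build_features(net, cm, dm, dss)
        cfg = self._gat_config()
        model, scores, history = train_gat(net.matrix, features, cfg)

        self.n_circ_, self.n_dis_ = nc, nd
        self.row_index_, self.col_index_ = net.row_index, net.col_index
        self.features_ = features
        self.graph_ = build_graph(net.matrix)
        self.model_ = model
        emb = model.forward(features, self.graph_, training=False)
        self.U_, self.V_ = emb[:nc], emb[nc:]
        self.score_matrix_ = score_pairs(emb, nc)
        self.loss_history_ = history
        return self

    # ------------------------------------------------------------------
    def decision_function(self, pairs: np.ndarray | None = None) -> np.ndarray:
        """Raw bilinear scores; ``pairs`` is an (n, 2) array of (row, col)
        indices, or None for the full nc x nd matrix."""
        check_is_fitted(self, "score_matrix_")
        if pairs is None:
            return self.score_matrix_
        pairs = np.asarray(pairs)
        return self.score_matrix_[pairs[:, 0], pairs[:, 1]]

    def predict_proba(self, pairs: np.ndarray | None = None) -> np.ndarray:
        """Sigmoid of the bilinear scores."""
        s = self.decision_function(pairs)
        return 1.0 / (1.0 + np.exp(-s))

    def predict(self, pairs: np.ndarray | None = None, threshold: float = 0.5) -> np.ndarray:
        """Binary calls at a probability threshold (default 0.5)."""
        return (self.predict_proba(pairs) >= threshold).astype(int)
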