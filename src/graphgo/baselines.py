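"""Formula-defined competitors sharing the homology-fallback contract.

BLAST-KNN transfers GO terms from training homologs weighted by bit-score:

    S_B(p_i, GO_j) = Σ_{p_k ∈ Z_i} I(p_k, GO_j)·B(p_i, p_k) / Σ_{p_k ∈ Z_i} B(p_i, p_k)

with Z_i the training proteins homologous to p_i at the e-value cutoff.
Net-KNN does the same over weighted network neighbors:

    S_N(p_i, GO_j) = Σ_k I(p_k, GO_j)·ω(p_i, p_k) / Σ_k ω(p_i, p_k)

summing over annotated training neighbors of p_i (the indicator applies to
the neighbor p_k). Both are convex combinations of {0,1} indicators, hence
in [0,1] and invariant to rescaling all bit-scores or edge weights.
LR-InterPro fits one L2-regularized logistic regression per GO term on the
binary InterPro feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .features import SignatureMatrix
from .graph import ProteinGraph
from .homology import HomologyTable
from .ontology import AnnotationTable
from .scores import ScoreMatrix

DEFAULT_E_CUTOFF = 1e-3


def blast_knn_score(queries: Sequence[str], homology: HomologyTable,
                    train_table: AnnotationTable, e_cutoff: float = DEFAULT_E_CUTOFF) -> ScoreMatrix:
    """Bit-score-weighted GO transfer from training homologs (Z_i empty →
    zero row with coverage stratum NONE)."""
    train_set = set(train_table.proteins)
    y = train_table.dense().astype(np.float64)
    row_of = {p: i for i, p in enumerate(train_table.proteins)}
    values = np.zeros((len(queries), train_table.n_terms))
    strata = {}
    for i, q in enumerate(queries):
        hits = homology.hits(q, train_set, e_cutoff=e_cutoff)
        if not hits:
            strata[q] = "NONE"
            continue
        strata[q] = "HOMO"
        weights = np.array([h.bit_score for h in hits.values()])
        rows = y[[row_of[s] for s in hits]]
        values[i] = (weights @ rows) / weights.sum()
    # convex combinations of {0,1}; clip float rounding at the boundary
    return ScoreMatrix(queries, train_table.terms, np.clip(values, 0.0, 1.0), strata)


def net_knn_score(queries: Sequence[str], graph: ProteinGraph,
                  train_table: AnnotationTable, homology: HomologyTable | None = None) -> ScoreMatrix:
    """Edge-weight-weighted GO transfer from annotated training neighbors.

    Sums are restricted to neighbors carrying at least one training annotation
    in the target domain (all-zero row when there are none). Operates on the
    unpruned network. A query absent from the graph falls back to the row of
    its highest-bit-score in-graph protein.
    """
    train_rows = {p: i for i, p in enumerate(train_table.proteins)}
    y = train_table.dense().astype(np.float64)
    annotated = {p for p, i in train_rows.items() if y[i].any()}

    def row_for(node: str) -> np.ndarray:
        num = np.zeros(train_table.n_terms)
        den = 0.0
        for nbr, w in graph.neighbors(node):
            if nbr in annotated:
                num += w * y[train_rows[nbr]]
                den += w
        return num / den if den > 0 else num

    values = np.zeros((len(queries), train_table.n_terms))
    strata = {}
    in_graph = set(graph.nodes)
    for i, q in enumerate(queries):
        if q in graph:
            values[i] = row_for(q)
            strata[q] = "STRI"
        else:
            best = homology.best_homolog(q, in_graph) if homology is not None else None
            if best is not None:
                values[i] = row_for(best)
                strata[q] = "HOMO"
            else:
                strata[q] = "NONE"
    return ScoreMatrix(queries, train_table.terms, np.clip(values, 0.0, 1.0), strata)


@dataclass
class LrModel:
    """One logistic regression per GO term over a shared signature vocabulary.

    ``weights`` is (K, m); ``intercepts`` is (K,). Terms that could not be fit
    (single-class training columns) get zero weights and an intercept equal to
    the logit of the positive rate, i.e. a constant model.
    """

    terms: list
    weights: np.ndarray
    intercepts: np.ndarray
    m: int
    regularization: float = 1.0


def lr_train(features: SignatureMatrix, train_table: AnnotationTable,
             regularization: float = 1.0) -> LrModel:
    """Fit K independent L2-penalized logistic regressions on the training
    proteins' binary feature vectors."""
    x = features.rows(train_table.proteins)
    y = train_table.dense()
    K, m = train_table.n_terms, features.m
    weights = np.zeros((K, m))
    intercepts = np.zeros(K)
    for j in range(K):
        col = y[:, j]
        pos = int(col.sum())
        if pos == 0 or pos == len(col):
            rate = np.clip(pos / len(col), 1e-6, 1 - 1e-6)
            intercepts[j] = np.log(rate / (1 - rate))
            continue
        clf = LogisticRegression(C=1.0 / regularization, solver="lbfgs", max_iter=1000)
        clf.fit(x, col)
        weights[j] = clf.coef_[0]
        intercepts[j] = clf.intercept_[0]
    return LrModel(list(train_table.terms), weights, intercepts, m, regularization)


def lr_predict(model: LrModel, features: SignatureMatrix, proteins: Sequence[str]) -> ScoreMatrix:
    if features.m != model.m:
        raise ValueError("feature vocabulary does not match the fitted model")
    x = features.rows(proteins)
    logits = np.asarray(x @ model.weights.T) + model.intercepts
    values = 1.0 / (1.0 + np.exp(-logits))
    return ScoreMatrix(proteins, model.terms, values, {p: "STRI" for p in proteins})
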