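"""CAFA-style evaluation: protein-centric Fmax, pooled-pair AUPR, term-centric
M-AUPR, set-level F1 for case studies, difficulty stratification and bootstrap
significance comparison.

Fmax sweeps a score threshold τ; precision at τ averages per-protein precision
over the h(τ) proteins that predict at least one term at τ, while recall
averages per-protein recall over all N_T benchmark proteins. Truth tables are
assumed propagated with the domain root excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

from .homology import HomologyTable
from .ontology import AnnotationTable
from .scores import ScoreMatrix


@dataclass
class EvalResult:
    fmax: float
    tau_star: float
    pr_curve: list  # (tau, precision, recall, h)
    aupr: float | None = None
    m_aupr: float | None = None
    n_benchmark: int = 0


def _aligned(scores: ScoreMatrix, truth: AnnotationTable) -> tuple[np.ndarray, np.ndarray]:
    """Score and truth arrays on the truth table's axes, benchmark proteins only
    (those with at least one true term)."""
    s = scores.restrict(truth.proteins, truth.terms).values
    y = truth.dense().astype(bool)
    keep = y.any(axis=1)
    if not keep.any():
        raise ValueError("empty benchmark: no protein has a true term")
    return s[keep], y[keep]


def _fmax_from_arrays(s: np.ndarray, y: np.ndarray, grid_step: float | None = 0.01):
    if grid_step is not None:
        taus = np.round(np.arange(grid_step, 1.0 + grid_step / 2, grid_step), 10)
    else:
        taus = np.unique(s[s > 0])  # every distinct positive score as threshold
        if taus.size == 0:
            taus = np.array([1.0])
    n_truth = y.sum(axis=1)
    curve = []
    best_f, best_tau = 0.0, float(taus[0])
    for tau in taus:
        pred = s >= tau
        npred = pred.sum(axis=1)
        tp = (pred & y).sum(axis=1)
        h = npred > 0
        n_h = int(h.sum())
        pr = float(np.mean(tp[h] / npred[h])) if n_h else 0.0
        rc = float(np.mean(tp / n_truth))
        f = 2 * pr * rc / (pr + rc) if (pr + rc) > 0 else 0.0
        curve.append((float(tau), pr, rc, n_h))
        if f > best_f:
            best_f, best_tau = f, float(tau)
    return best_f, best_tau, curve


def fmax(scores: ScoreMatrix, truth: AnnotationTable, grid_step: float | None = 0.01) -> EvalResult:
    """Protein-centric Fmax over the threshold grid (step 0.01 by default;
    ``grid_step=None`` sweeps every distinct score instead)."""
    s, y = _aligned(scores, truth)
    best_f, best_tau, curve = _fmax_from_arrays(s, y, grid_step)
    return EvalResult(fmax=best_f, tau_star=best_tau, pr_curve=curve, n_benchmark=len(y))


def aupr_pairs(scores: ScoreMatrix, truth: AnnotationTable) -> float:
    """Area under the tie-grouped, step-interpolated PR curve over all pooled
    protein–GO-term pairs sorted by score."""
    s, y = _aligned(scores, truth)
    flat_y = y.ravel().astype(int)
    if flat_y.sum() == 0:
        raise ValueError("no positive protein-term pair")
    return float(average_precision_score(flat_y, s.ravel()))


def m_aupr(scores: ScoreMatrix, truth: AnnotationTable, min_count: int = 3) -> float:
    """Mean per-term AUPR over terms with >= ``min_count`` annotated benchmark
    proteins ('appearing more than twice' reads as >= 3)."""
    s, y = _aligned(scores, truth)
    counts = y.sum(axis=0)
    cols = np.flatnonzero(counts >= min_count)
    if cols.size == 0:
        raise ValueError(f"no term annotated to >= {min_count} benchmark proteins")
    return float(np.mean([average_precision_score(y[:, j].astype(int), s[:, j]) for j in cols]))


def f1_set(predicted: Iterable[str], truth: Iterable[str]) -> float:
    """Set-level F1 between a predicted and a true term set (root excluded).

    Precision = |∩|/|predicted|, recall = |∩|/|truth|; an empty prediction
    scores 0; an empty truth set is an error.
    """
    pred, true = set(predicted), set(truth)
    if not true:
        raise ValueError("truth term set is empty")
    if not pred:
        return 0.0
    inter = len(pred & true)
    pr, rc = inter / len(pred), inter / len(true)
    return 2 * pr * rc / (pr + rc) if inter else 0.0


def stratify_difficult(test_proteins: Sequence[str], homology: HomologyTable,
                       train_proteins: Iterable[str], identity_threshold: float = 60.0) -> dict:
    """Label each test protein 'difficult' iff its best percent identity against
    any training protein is strictly below the threshold (no hit → difficult)."""
    train = set(train_proteins)
    out = {}
    for p in test_proteins:
        best = homology.max_identity(p, train)
        out[p] = "difficult" if best is None or best < identity_threshold else "easy"
    return out


def stratify_coverage(test_proteins: Sequence[str], graph_nodes: Iterable[str],
                      homology: HomologyTable | None = None) -> dict:
    """STRI / HOMO / NONE partition of test proteins (network membership,
    in-network homolog, or neither)."""
    nodes = set(graph_nodes)
    out = {}
    for p in test_proteins:
        if p in nodes:
            out[p] = "STRI"
        elif homology is not None and homology.best_homolog(p, nodes) is not None:
            out[p] = "HOMO"
        else:
            out[p] = "NONE"
    return out


@dataclass
class BootstrapResult:
    mean_difference: float
    p_value: float
    differences: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False


_METRICS: dict[str, Callable] = {
    "fmax": lambda s, t: fmax(s, t).fmax,
    "aupr": aupr_pairs,
}


def bootstrap_compare(scores_a: ScoreMatrix, scores_b: ScoreMatrix, truth: AnnotationTable,
                      n_resamples: int = 100, metric: str | Callable = "fmax",
                      seed: int = 0) -> BootstrapResult:
    """Resample the benchmark proteins with replacement ``n_resamples`` times,
    evaluate both methods per resample, and paired-t-test the differences.

    Zero-variance differences are flagged degenerate: the p-value is 0 when
    the common difference is nonzero (the t → ∞ limit) and NaN when both
    methods coincide on every resample.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    metric_fn = _METRICS[metric] if isinstance(metric, str) else metric
    rng = np.random.default_rng(seed)
    sa = scores_a.restrict(truth.proteins, truth.terms)
    sb = scores_b.restrict(truth.proteins, truth.terms)
    y = truth.dense()
    n = len(truth.proteins)
    diffs = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        prots = [f"r{k}" for k in range(n)]  # resampled rows are distinct instances
        t_r = AnnotationTable(prots, truth.terms, y[idx])
        a_r = ScoreMatrix(prots, truth.terms, sa.values[idx])
        b_r = ScoreMatrix(prots, truth.terms, sb.values[idx])
        diffs[r] = metric_fn(a_r, t_r) - metric_fn(b_r, t_r)
    mean = float(diffs.mean())
    if np.allclose(diffs, diffs[0]):
        p = float("nan") if math.isclose(diffs[0], 0.0, abs_tol=1e-15) else 0.0
        return BootstrapResult(mean, p, diffs, degenerate=True)
    t_res = stats.ttest_1samp(diffs, 0.0)
    return BootstrapResult(mean, float(t_res.pvalue), diffs)
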