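"""Ranking metrics and the nested cross-validation protocol.

Two metrics are used throughout: AUROC (the probability that a randomly
chosen positive outranks a randomly chosen negative; ties get half credit)
and average precision (AUP: the mean, over positives, of the precision at
each positive's rank).  Evaluation follows the positive-unlabeled setting:
non-positive nodes serve as negatives because true negatives are rarely
available for node-labeling tasks.

``cross_validate`` implements the comparison protocol: positives are split
into ``outer_folds`` stratified folds; per fold the held-out positives'
labels are zeroed in the training vector, GLP's lambda is chosen by an inner
2-fold CV over a grid (by mean AUP), NProp weights are fitted by LDA on the
training fold, and metrics are computed over held-out positives versus all
never-positive nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .graph import WeightedGraph
from .model import fit_weights, score_nprop, select_normalization
from .propagation import glp_exact

__all__ = ["auroc", "average_precision", "EvalResult", "CVProtocol",
           "cross_validate", "nprop_sweep", "DEFAULT_LAM_GRID"]

DEFAULT_LAM_GRID = (0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99)


def _masked(scores, labels, eval_mask):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if eval_mask is not None:
        idx = np.asarray(eval_mask)
        scores, labels = scores[idx], labels[idx]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"degenerate evaluation set: {n_pos} positives, {n_neg} negatives")
    return scores, labels


def auroc(scores, labels, eval_mask=None) -> float:
    """Rank-based AUROC with midrank tie handling."""
    s, l = _masked(scores, labels, eval_mask)
    return float(roc_auc_score(l, s))


def average_precision(scores, labels, eval_mask=None, method: str = "step") -> float:
    """Average precision over the ranked node list.

    ``method='step'`` (default): mean over positives of the precision at
    each positive's rank, with ties broken deterministically by position in
    the (node-ordered) input.  ``method='trapezoid'``: area under the
    precision-recall curve by trapezoidal integration, for comparison.
    """
    s, l = _masked(scores, labels, eval_mask)
    order = np.lexsort((np.arange(s.size), -s))  # score desc, stable in node order
    hits = l[order] == 1
    ranks = np.flatnonzero(hits) + 1
    precision_at_pos = np.cumsum(hits)[hits] / ranks
    if method == "step":
        return float(precision_at_pos.mean())
    if method == "trapezoid":
        recall = np.arange(1, ranks.size + 1) / ranks.size
        r = np.concatenate([[0.0], recall])
        p = np.concatenate([[1.0], precision_at_pos])
        return float(np.trapezoid(p, r))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CVProtocol:
    """Nested cross-validation settings."""

    outer_folds: int = 3
    inner_folds: int = 2
    lam_grid: tuple = DEFAULT_LAM_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")


@dataclass
class FoldResult:
    fold: int
    auroc: float
    aup: float
    n_pos: int
    n_neg: int
    chosen_lam: float | None = None
    weights: list[float] | None = None


@dataclass
class EvalResult:
    """Per-fold metrics plus their mean."""

    auroc: float
    aup: float
    n_pos: int
    n_neg: int
    per_fold: list[FoldResult] = field(default_factory=list)


def _partition_positives(pos: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Seeded, deterministic partition of positive indices into folds."""
    perm = rng.permutation(pos)
    return [np.sort(perm[k::n_folds]) for k in range(n_folds)]


def _eval_indices(test_pos: np.ndarray, never_pos: np.ndarray) -> np.ndarray:
    return np.sort(np.concatenate([test_pos, never_pos]))


def cross_validate(G: WeightedGraph, labels: np.ndarray, method: str = "nprop",
                   R: int = 3, protocol: CVProtocol | None = None,
                   variant: str = "symmetric") -> EvalResult:
    """Nested CV comparison harness for GLP and NProp.

    Per outer fold the test positives' labels are zeroed in the training
    vector.  For ``method='glp'`` lambda is selected on an inner
    ``inner_folds``-fold CV over ``protocol.lam_grid`` by mean AUP; for
    ``method='nprop'`` weights are fitted on the training fold.  Metrics are
    computed over the held-out positives versus all never-positive nodes
    (negatives are shared across folds and never removed).
    """
    if protocol is None:
        protocol = CVProtocol()
    if method not in ("glp", "nprop"):
        raise ValueError(f"unknown method {method!r}")
    labels = np.asarray(labels, dtype=float).ravel()
    pos = np.flatnonzero(labels == 1)
    never_pos = np.flatnonzero(labels == 0)
    if pos.size < protocol.outer_folds:
        raise ValueError(
            f"{pos.size} positives cannot fill {protocol.outer_folds} outer folds")

    M = select_normalization(G, variant)
    rng = np.random.default_rng(protocol.seed)
    outer = _partition_positives(pos, protocol.outer_folds, rng)

    per_fold: list[FoldResult] = []
    for k, test_pos in enumerate(outer):
        train_pos = np.setdiff1d(pos, test_pos)
        y_train = np.zeros_like(labels)
        y_train[train_pos] = 1.0
        eval_idx = _eval_indices(test_pos, never_pos)

        if method == "glp":
            lam = _select_lambda(M, train_pos, labels, protocol, rng)
            f = glp_exact(M, y_train, lam)
            fr = FoldResult(fold=k, chosen_lam=lam,
                            auroc=auroc(f, labels, eval_idx),
                            aup=average_precision(f, labels, eval_idx),
                            n_pos=test_pos.size, n_neg=never_pos.size)
        else:
            split_seed = int(rng.integers(0, 2**31 - 1))
            w, _ = fit_weights(M, y_train, R=R, split_seed=split_seed)
            f = score_nprop(M, y_train, w)
            fr = FoldResult(fold=k, weights=w.w.tolist(),
                            auroc=auroc(f, labels, eval_idx),
                            aup=average_precision(f, labels, eval_idx),
                            n_pos=test_pos.size, n_neg=never_pos.size)
        per_fold.append(fr)

    return EvalResult(
        auroc=float(np.mean([f.auroc for f in per_fold])),
        aup=float(np.mean([f.aup for f in per_fold])),
        n_pos=pos.size, n_neg=never_pos.size, per_fold=per_fold)


def _select_lambda(M, train_pos, labels, protocol: CVProtocol,
                   rng: np.random.Generator) -> float:
    """Inner-CV lambda selection by mean AUP over the grid."""
    inner = _partition_positives(train_pos, protocol.inner_folds, rng)
    n = labels.shape[0]
    # inner evaluation sees only the outer training labels: outer test
    # positives count as unlabeled (negative) here, as they would in a run
    y_outer_train = np.zeros(n)
    y_outer_train[train_pos] = 1.0
    non_train = np.flatnonzero(y_outer_train == 0)
    mean_aup = []
    for lam in protocol.lam_grid:
        aups = []
        for held in inner:
            fit_pos = np.setdiff1d(train_pos, held)
            y_fit = np.zeros(n)
            y_fit[fit_pos] = 1.0
            f = glp_exact(M, y_fit, lam)
            idx = _eval_indices(held, non_train)
            aups.append(average_precision(f, y_outer_train, idx))
        mean_aup.append(np.mean(aups))
    return float(protocol.lam_grid[int(np.argmax(mean_aup))])


def slp_lambda_sweep(G: WeightedGraph, labels: np.ndarray,
                     lam_grid=DEFAULT_LAM_GRID, outer_folds: int = 3,
                     seed: int = 0, variant: str = "symmetric") -> dict:
    """Mean held-out AUROC of exact GLP per lambda over stratified folds.

    Gives propagation its most favourable setting (the per-lambda test
    performance, no inner selection); used to bound what any lambda choice
    could achieve on a labeling regime.
    """
    labels = np.asarray(labels, dtype=float).ravel()
    pos = np.flatnonzero(labels == 1)
    never_pos = np.flatnonzero(labels == 0)
    M = select_normalization(G, variant)
    rng = np.random.default_rng(seed)
    folds = _partition_positives(pos, outer_folds, rng)
    out = {}
    for lam in lam_grid:
        vals = []
        for test_pos in folds:
            y_train = np.zeros_like(labels)
            y_train[np.setdiff1d(pos, test_pos)] = 1.0
            f = glp_exact(M, y_train, lam)
            vals.append(auroc(f, labels, _eval_indices(test_pos, never_pos)))
        out[float(lam)] = float(np.mean(vals))
    return out


def nprop_sweep(G: WeightedGraph, labels: np.ndarray, R_values=(1, 2, 3, 4, 5, 6),
                protocol: CVProtocol | None = None,
                variant: str = "symmetric") -> list[dict]:
    """Cross-validated NProp performance per maximum walk length.

    Returns one row per R with pooled AUROC and AUP — the walk-length sweep
    used to justify truncating at three steps.
    """
    rows = []
    for R in R_values:
        res = cross_validate(G, labels, method="nprop", R=R, protocol=protocol,
                             variant=variant)
        rows.append({"R": R, "auroc": res.auroc, "aup": res.aup})
    return rows
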