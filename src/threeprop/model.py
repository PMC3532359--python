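"""3Prop/NProp: short random walks with independently fitted weights.

Plain label propagation ties the weight of a length-``r`` walk to ``lam^r``
— positive and exponentially decaying — which hard-codes the assumption that
directly linked nodes share labels.  3Prop drops that assumption: node
scores are

    f = w_1 M y + w_2 M^2 y + w_3 M^3 y

with real (possibly negative) weights fitted to the task by linear
discriminant analysis (LDA), ``w = C^-1 (mu_pos - mu_neg)``, where the class
means and covariance are taken over the rows of the walk-feature matrix.
Negative weights let the method handle disassortative mixing (direct links
are evidence *against* sharing a label) and shared-neighbor structure (same
labels co-occur two steps apart but rarely one), where geometric-weight
propagation can rank worse than random.  NProp is the same construction on
walks of length up to N.

To stop a positive's own training label from inflating its features, the
training positives are split: a 2/3 fraction populates the label vector that
the walks propagate, and only the held-out 1/3 (plus the non-positives)
enters the LDA means and covariance.

The scikit-learn-style estimators :class:`ThreeProp` and :class:`GLP` are
transductive, like ``sklearn.semi_supervised.LabelSpreading``: ``fit`` takes
the affinity matrix and the 0/1 label vector and stores per-node scores in
``scores_``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .graph import (NormalizedMatrix, WeightedGraph, normalize_asymmetric,
                    normalize_symmetric)
from .propagation import glp_exact, glp_truncated, walk_features

__all__ = ["PropWeights", "LDAFitReport", "lda_direction", "fit_weights",
           "score_nprop", "select_normalization", "ThreeProp", "GLP"]


@dataclass
class LDAFitReport:
    """Sufficient statistics of an LDA weight fit, serializable to JSON."""

    mu_pos: list[float]
    mu_neg: list[float]
    C: list[list[float]]
    n_pos: int
    n_neg: int
    split_seed: int
    propagation_fraction: float
    ridge: float
    covariance: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PropWeights:
    """Walk-length weights w_1..w_R in canonical normalization.

    Canonical means unit Euclidean norm with the sign fixed so the fitted
    direction increases the mean positive score; scores themselves are
    scale-free, so the normalization only matters for reporting and
    comparing weights across tasks.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")
        if not self.w.any():
            raise ValueError("weights must not all be zero")

    @property
    def R(self) -> int:
        return self.w.shape[0]


def _canonicalize(w: np.ndarray, delta: np.ndarray) -> np.ndarray:
    w = w / np.linalg.norm(w)
    if w @ delta < 0:
        w = -w
    return w


def lda_direction(Xp: np.ndarray, Xn: np.ndarray, ridge: float | None = None,
                  covariance: str = "pooled"):
    """LDA discriminant direction ``w = (C + ridge I)^-1 (mu_pos - mu_neg)``.

    ``C`` is the pooled within-class sample covariance by default (each
    class's covariance weighted by its count minus one), or the total
    covariance of all rows with ``covariance='total'``.  Returns the
    canonically normalized ``w`` together with the class means, ``C`` and
    the ridge actually used.
    """
    Xp, Xn = np.atleast_2d(Xp), np.atleast_2d(Xn)
    R = Xp.shape[1]
    mu_pos, mu_neg = Xp.mean(axis=0), Xn.mean(axis=0)
    if covariance == "pooled":
        Cp = np.cov(Xp, rowvar=False, ddof=1) if Xp.shape[0] > 1 else np.zeros((R, R))
        Cn = np.cov(Xn, rowvar=False, ddof=1) if Xn.shape[0] > 1 else np.zeros((R, R))
        n_p, n_n = Xp.shape[0], Xn.shape[0]
        C = (max(n_p - 1, 0) * np.atleast_2d(Cp) + max(n_n - 1, 0) * np.atleast_2d(Cn))
        C /= max(n_p + n_n - 2, 1)
    elif covariance == "total":
        C = np.atleast_2d(np.cov(np.vstack([Xp, Xn]), rowvar=False, ddof=1))
    else:
        raise ValueError(f"unknown covariance {covariance!r}")

    if ridge is None:
        ridge = 1e-8 * np.trace(C) / R
    delta = mu_pos - mu_neg
    try:
        w = np.linalg.solve(C + ridge * np.eye(R), delta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; pass ridge > 0") from exc
    if not w.any():
        raise ValueError("degenerate fit: class means coincide")
    return _canonicalize(w, delta), mu_pos, mu_neg, C, float(ridge)


def fit_weights(M: NormalizedMatrix, y_train: np.ndarray, R: int = 3,
                split_seed: int = 0, ridge: float | None = None,
                propagation_fraction: float = 2 / 3,
                covariance: Literal["pooled", "total"] = "pooled",
                ) -> tuple[PropWeights, LDAFitReport]:
    """Fit NProp weights by LDA with an internal propagation/estimation split.

    The training positives are split at random (seeded): a
    ``propagation_fraction`` portion forms the propagation set, whose labels
    populate the vector the walk features are computed from; the remaining
    positives together with all training non-positives form the estimation
    set that supplies the class means and covariance.  The split prevents a
    node's own label from leaking into its features.

    Parameters
    ----------
    M : NormalizedMatrix
        Symmetric or asymmetric normalization of the network.
    y_train : array of 0/1
        Training labels; non-positives are treated as negatives (true
        negatives are generally unavailable in function-prediction tasks).
    R : int
        Maximum walk length (3 for 3Prop).
    split_seed : int
        Seed for the propagation/estimation split; required and recorded.
    ridge : float, optional
        Added to the diagonal of C before inversion.  Defaults to
        ``1e-8 * trace(C)/R``.
    covariance : {'pooled', 'total'}
        Pooled within-class covariance (default) or total covariance of all
        estimation rows.

    Returns
    -------
    (PropWeights, LDAFitReport)
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    pos = np.flatnonzero(y_train == 1)
    if pos.size < 3:
        raise ValueError(f"need at least 3 training positives, got {pos.size}")
    if not 0 < propagation_fraction < 1:
        raise ValueError("propagation_fraction must lie in (0, 1)")

    rng = check_random_state(split_seed)
    perm = rng.permutation(pos)
    n_prop = int(np.ceil(propagation_fraction * pos.size))
    n_prop = min(n_prop, pos.size - 1)  # keep both parts non-empty
    prop_pos, est_pos = perm[:n_prop], perm[n_prop:]

    y_prop = np.zeros_like(y_train)
    y_prop[prop_pos] = 1.0
    X = walk_features(M, y_prop, R)

    neg = np.flatnonzero(y_train == 0)
    Xp, Xn = X[est_pos], X[neg]
    w, mu_pos, mu_neg, C, ridge = lda_direction(Xp, Xn, ridge=ridge,
                                                covariance=covariance)

    report = LDAFitReport(
        mu_pos=mu_pos.tolist(), mu_neg=mu_neg.tolist(), C=C.tolist(),
        n_pos=int(Xp.shape[0]), n_neg=int(Xn.shape[0]),
        split_seed=int(split_seed), propagation_fraction=propagation_fraction,
        ridge=float(ridge), covariance=covariance)
    return PropWeights(w), report


def score_nprop(M: NormalizedMatrix, y: np.ndarray, w: "PropWeights | np.ndarray") -> np.ndarray:
    """NProp scores ``f = sum_{r=1}^R w_r M^r y`` (no r = 0 self-term).

    At prediction time ``y`` carries the full set of training positives
    (both halves of the fitting split).
    """
    wv = w.w if isinstance(w, PropWeights) else np.asarray(w, dtype=float).ravel()
    X = walk_features(M, y, wv.shape[0])
    return X @ wv


def select_normalization(G: WeightedGraph, variant: str = "symmetric") -> NormalizedMatrix:
    """Pick S (default; the better-performing variant) or row-stochastic P."""
    if variant == "symmetric":
        return normalize_symmetric(G)
    if variant == "asymmetric":
        return normalize_asymmetric(G)
    raise ValueError(f"unknown variant {variant!r}")


def _as_normalized(X, variant: str) -> NormalizedMatrix:
    if isinstance(X, NormalizedMatrix):
        return X
    if isinstance(X, WeightedGraph):
        return select_normalization(X, variant)
    import scipy.sparse as sp
    A = sp.csr_array(X)
    G = WeightedGraph([str(i) for i in range(A.shape[0])], A)
    return select_normalization(G, variant)


class ThreeProp(BaseEstimator):
    """Transductive node scorer with LDA-fitted short-walk weights.

    Parameters
    ----------
    n_steps : int, default 3
        Maximum walk length R (NProp for other values).
    variant : {'symmetric', 'asymmetric'}, default 'symmetric'
        Normalization used for both fitting and scoring.
    ridge : float or None
        Ridge added to the LDA covariance; None picks 1e-8 tr(C)/R.
    propagation_fraction : float, default 2/3
        Fraction of training positives whose labels drive propagation.
    covariance : {'pooled', 'total'}
        Covariance estimator used in the LDA solve.
    random_state : int, RandomState or None
        Controls the propagation/estimation split.

    Attributes
    ----------
    weights_ : ndarray of shape (n_steps,)
        Canonical fitted walk weights.
    scores_ : ndarray of shape (n_nodes,)
        Discriminant scores for every node, computed with the full training
        positives.
    fit_report_ : LDAFitReport
        Class means, covariance, counts and split seed of the fit.

    Examples
    --------
    >>> from threeprop.synthetic import default_spec, generate
    >>> G, y = generate(default_spec("assortative", seed=0))
    >>> model = ThreeProp(random_state=0).fit(G.A, y)
    >>> model.weights_.shape
    (3,)
    """

    def __init__(self, n_steps: int = 3, variant: str = "symmetric",
                 ridge: float | None = None,
                 propagation_fraction: float = 2 / 3,
                 covariance: str = "pooled", random_state=None):
        self.n_steps = n_steps
        self.variant = variant
        self.ridge = ridge
        self.propagation_fraction = propagation_fraction
        self.covariance = covariance
        self.random_state = random_state

    def fit(self, X, y):
        """Fit weights and score all nodes.

        X is an n x n affinity matrix (or WeightedGraph / NormalizedMatrix);
        y is the 0/1 training label vector over the same node ordering.
        """
        M = _as_normalized(X, self.variant)
        rng = check_random_state(self.random_state)
        split_seed = int(rng.randint(0, 2**31 - 1))
        w, report = fit_weights(
            M, y, R=self.n_steps, split_seed=split_seed, ridge=self.ridge,
            propagation_fraction=self.propagation_fraction,
            covariance=self.covariance)
        self.M_ = M
        self.weights_ = w.w
        self.fit_report_ = report
        self.scores_ = score_nprop(M, np.asarray(y, dtype=float), w)
        return self

    def decision_function(self, indices=None):
        """Fitted node scores, optionally restricted to ``indices``."""
        if indices is None:
            return self.scores_
        return self.scores_[np.asarray(indices)]


class GLP(BaseEstimator):
    """Generic label propagation (transductive) in sklearn form.

    Scores are the geometric series ``f = sum_r lam^r M^r y``, either summed
    to ``n_steps`` terms (``mode='truncated'``) or solved exactly from
    ``(I - lam M) f = y`` (``mode='exact'``, the default).
    """

    def __init__(self, lam: float = 0.5, variant: str = "symmetric",
                 mode: str = "exact", n_steps: int = 3,
                 tol: float = 1e-10, max_iter: int = 1000):
        self.lam = lam
        self.variant = variant
        self.mode = mode
        self.n_steps = n_steps
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        M = _as_normalized(X, self.variant)
        y = np.asarray(y, dtype=float).ravel()
        if self.mode == "exact":
            f = glp_exact(M, y, self.lam, tol=self.tol, max_iter=self.max_iter)
        elif self.mode == "truncated":
            f = glp_truncated(M, y, self.lam, self.n_steps)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.M_ = M
        self.scores_ = f
        return self

    def decision_function(self, indices=None):
        if indices is None:
            return self.scores_
        return self.scores_[np.asarray(indices)]
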