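"""Generic label propagation: truncated series, exact solves, walk features.

Given a normalized matrix ``M`` (symmetric ``S`` or row-stochastic ``P``) and
a 0/1 label vector ``y`` marking the positive nodes, generic label
propagation (GLP) scores every node by the geometric series

    f = sum_{r>=0} lam^r M^r y,        0 < lam < 1,

equivalently the solution of the sparse linear system ``(I - lam M) f = y``.
For ``M = P`` the term ``(P^r y)_i`` is the probability that a length-``r``
random walk started at node ``i`` ends in a positive node, so GLP is an
exponentially-decaying weighted sum of short-walk hitting probabilities.

The symmetric and asymmetric variants are exactly interconvertible: because
``P = D^-1/2 S D^1/2`` the symmetric scores can be obtained from an
asymmetric run on degree-modified labels (see :func:`slp_via_alp`).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import bicgstab, cg

from .graph import NormalizedMatrix

__all__ = ["walk_features", "glp_truncated", "glp_exact", "slp_via_alp"]


def _check_labels(M: NormalizedMatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != M.n_nodes:
        raise ValueError(f"label vector length {y.shape[0]} != n_nodes {M.n_nodes}")
    return y


def walk_features(M: NormalizedMatrix, y: np.ndarray, R: int) -> np.ndarray:
    """Feature matrix whose column r-1 is ``x^(r) = M^r y``, r = 1..R.

    Computed by R successive sparse matrix-vector products; ``M^r`` is never
    formed.  For the asymmetric normalization and binary ``y`` the entries
    are random-walk hitting probabilities and lie in [0, 1].
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    y = _check_labels(M, y)
    X = np.empty((M.n_nodes, R))
    x = y
    for r in range(R):
        x = M.M @ x
        X[:, r] = x
    return X


def glp_truncated(M: NormalizedMatrix, y: np.ndarray, lam: float, R: int) -> np.ndarray:
    """Partial-sum GLP scores ``f^(R) = sum_{r=0}^R lam^r M^r y``.

    The r = 0 term is ``y`` itself, so ``R = 0`` returns the labels
    unchanged.  Accumulated incrementally in O(R) sparse products.
    """
    if not 0 < lam < 1:
        raise ValueError("lam must lie in (0, 1)")
    if R < 0:
        raise ValueError("R must be >= 0")
    y = _check_labels(M, y)
    f = y.copy()
    term = y
    for _ in range(R):
        term = lam * (M.M @ term)
        f += term
    return f


def _solve_spd(S: sp.csr_array, lam: float, b: np.ndarray,
               tol: float, max_iter: int) -> np.ndarray:
    """Conjugate-gradient solve of the SPD system (I - lam S) f = b."""
    n = S.shape[0]
    op = sp.identity(n, format="csr") - lam * S
    f, info = cg(op, b, rtol=0.0, atol=tol * max(np.linalg.norm(b), 1e-300),
                 maxiter=max_iter)
    if info != 0:
        res = np.linalg.norm(op @ f - b)
        raise RuntimeError(f"conjugate gradient did not converge (residual {res:.3e})")
    return f


def glp_exact(M: NormalizedMatrix, y: np.ndarray, lam: float,
              tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Fixed-point GLP scores: solve ``(I - lam M) f = y``.

    Both normalizations have spectral radius <= 1, so the system is
    invertible for 0 < lam < 1.  The symmetric system is solved directly by
    conjugate gradient; the asymmetric one through the similarity transform
    ``I - lam P = D^-1/2 (I - lam S) D^1/2``, which reduces it to the same
    SPD solve on ``g = D^1/2 f``.  Isolated nodes decouple (zero rows) and
    keep ``f_i = y_i``.
    """
    if not 0 < lam < 1:
        raise ValueError("lam must lie in (0, 1)")
    y = _check_labels(M, y)
    if M.kind == "symmetric":
        return _solve_spd(M.M, lam, y, tol, max_iter)
    # asymmetric: P = D^-1/2 S D^1/2 with sentinel sqrt(d)=1 on isolated nodes
    sqrt_d = np.sqrt(M.degrees)
    sqrt_d[M.degrees == 0] = 1.0
    S = sp.csr_array(sp.diags_array(sqrt_d) @ M.M @ sp.diags_array(1.0 / sqrt_d))
    g = _solve_spd(S, lam, sqrt_d * y, tol, max_iter)
    return g / sqrt_d


def slp_via_alp(M_asym: NormalizedMatrix, y: np.ndarray, lam: float,
                tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Symmetric-variant scores computed through an asymmetric-style run.

    The recipe: replace the labels by ``y'_i = sqrt(d_i)`` on positives (0
    elsewhere), propagate with the walk operator written from the asymmetric
    normalization, and rescale the result elementwise by ``1/sqrt(d_i)``.
    For an undirected network the operator that makes this exact is the
    adjoint walk matrix ``A D^-1`` (evidence flows out of each node split by
    the *receiving* node's degree), since

        (I - lam S)^-1 y  =  D^-1/2 (I - lam A D^-1)^-1 D^1/2 y.

    Returns scores equal to ``glp_exact`` on the symmetric normalization up
    to solver tolerance.
    """
    if M_asym.kind != "asymmetric":
        raise ValueError("slp_via_alp expects the asymmetric normalization")
    if not 0 < lam < 1:
        raise ValueError("lam must lie in (0, 1)")
    y = _check_labels(M_asym, y)
    sqrt_d = np.sqrt(M_asym.degrees)
    sentinel = sqrt_d.copy()
    sentinel[M_asym.degrees == 0] = 1.0
    y_mod = sqrt_d * y
    # the adjoint walk operator A D^-1 is P^T for an undirected network;
    # solved nonsymmetrically so this route is independent of the CG-on-S one
    n = M_asym.n_nodes
    op = sp.identity(n, format="csr") - lam * M_asym.M.T.tocsr()
    f_tilde, info = bicgstab(op, y_mod, rtol=0.0,
                             atol=tol * max(np.linalg.norm(y_mod), 1e-300),
                             maxiter=max_iter)
    if info != 0:
        res = np.linalg.norm(op @ f_tilde - y_mod)
        raise RuntimeError(f"bicgstab did not converge (residual {res:.3e})")
    return f_tilde / sentinel
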