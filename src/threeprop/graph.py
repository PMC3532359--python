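"""Weighted undirected graphs and the two propagation normalizations.

A network is held as a :class:`WeightedGraph`: an ordered list of node
identifiers plus a sparse symmetric non-negative affinity matrix ``A`` with
zero diagonal.  Two normalizations of ``A`` drive all propagation in this
package:

* symmetric, ``S = D^-1/2 A D^-1/2`` — eigenvalues in [-1, 1];
* asymmetric, ``P = D^-1 A`` — row-stochastic, row ``i`` is the one-step
  random-walk distribution out of node ``i``.

``S`` and ``P`` are similar matrices (``P = D^-1/2 S D^1/2``) and therefore
share their spectrum; the package exploits that similarity to solve the
asymmetric linear systems through a symmetric positive-definite transform.

Isolated nodes (weighted degree zero) are retained in the node ordering but
carry zero rows/columns in either normalized matrix, so propagation leaves
their scores at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedGraph",
    "NormalizedMatrix",
    "load_edge_list",
    "load_labels",
    "degree_vector",
    "normalize_symmetric",
    "normalize_asymmetric",
    "write_scores",
]


class EdgeListError(ValueError):
    """Malformed or invalid edge-list input."""


@dataclass
class WeightedGraph:
    """Undirected weighted network.

    Parameters
    ----------
    node_ids : list of str
        Node identifiers in the fixed ordering shared by every vector and
        matrix derived from this graph.
    A : scipy.sparse.csr_array
        n x n symmetric non-negative affinity matrix with zero diagonal.
    """

    node_ids: list[str]
    A: sp.csr_array

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.A = sp.csr_array(self.A)
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError("affinity matrix must be square")
        if len(self.node_ids) != self.A.shape[0]:
            raise ValueError("node_ids length does not match matrix size")
        self._index = {v: i for i, v in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def validate(self, tol: float = 0.0) -> None:
        """Check symmetry, non-negative weights and zero diagonal."""
        if self.A.diagonal().any():
            raise ValueError("affinity matrix has non-zero diagonal (self-links)")
        if self.A.nnz and self.A.data.min() <= 0:
            raise ValueError("affinity matrix has non-positive stored weights")
        asym = abs(self.A - self.A.T)
        if asym.nnz and asym.max() > tol:
            raise ValueError("affinity matrix is not symmetric")

    def label_vector(self, positives: "list[str] | set[str]") -> np.ndarray:
        """0/1 vector marking the given node identifiers as positives."""
        y = np.zeros(self.n_nodes)
        missing = [p for p in positives if p not in self._index]
        if missing:
            logger.warning("%d label ids absent from graph (e.g. %r)",
                           len(missing), missing[:3])
        for p in positives:
            i = self._index.get(p)
            if i is not None:
                y[i] = 1.0
        return y


@dataclass
class NormalizedMatrix:
    """Normalized propagation matrix with its kind tag.

    ``kind='symmetric'`` holds ``S = D^-1/2 A D^-1/2``; ``kind='asymmetric'``
    holds the row-stochastic ``P = D^-1 A``.  ``degrees`` keeps the weighted
    degree vector of the source graph, needed for the SLP/ALP rescaling.
    """

    M: sp.csr_array
    kind: str
    degrees: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n_nodes(self) -> int:
        return self.M.shape[0]


def load_edge_list(path, symmetrize_rule: str = "max") -> WeightedGraph:
    """Read a 2- or 3-column TSV edge list into a :class:`WeightedGraph`.

    Columns are ``node_a  node_b  [weight]``; the weight defaults to 1.0.
    Lines starting with ``#`` are skipped.  Self-links are dropped with a
    logged count.  Duplicate or reciprocal entries are resolved by
    ``symmetrize_rule``: ``max`` (default), ``sum``, or ``error``.  Node
    ordering is lexicographic by identifier, fixed at load time.
    """
    if symmetrize_rule not in ("max", "sum", "error"):
        raise ValueError(f"unknown symmetrize_rule {symmetrize_rule!r}")

    edges: dict[tuple[str, str], float] = {}
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (2, 3):
                raise EdgeListError(f"line {lineno}: expected 2 or 3 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise EdgeListError(f"line {lineno}: non-numeric weight {parts[2]!r}") from exc
            else:
                w = 1.0
            if w < 0:
                raise EdgeListError(f"line {lineno}: negative weight {w}")
            if a == b:
                n_self += 1
                continue
            if w == 0:
                continue
            key = (a, b) if a < b else (b, a)
            if key in edges:
                n_dup += 1
                if symmetrize_rule == "error":
                    raise EdgeListError(f"line {lineno}: duplicate edge {a}--{b}")
                if symmetrize_rule == "max":
                    edges[key] = max(edges[key], w)
                else:
                    edges[key] += w
            else:
                edges[key] = w

    if n_self:
        logger.warning("dropped %d self-link(s)", n_self)
    if n_dup:
        logger.warning("resolved %d duplicate/reciprocal edge entr(ies) by rule=%s",
                       n_dup, symmetrize_rule)

    node_ids = sorted({v for pair in edges for v in pair})
    index = {v: i for i, v in enumerate(node_ids)}
    n = len(node_ids)
    if edges:
        rows, cols, vals = [], [], []
        for (a, b), w in edges.items():
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        A = sp.coo_array((vals, (rows, cols)), shape=(n, n)).tocsr()
    else:
        A = sp.csr_array((n, n))
    g = WeightedGraph(node_ids, A)
    g.validate()
    return g


def load_labels(path) -> dict[str, list[str]]:
    """Read a label file: one node id per line, or ``node<TAB>category``.

    Returns a mapping from category name to list of positive node ids; the
    single-column form is returned under the category ``"default"``.
    """
    cats: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 1:
                cats.setdefault("default", []).append(parts[0])
            else:
                cats.setdefault(parts[1], []).append(parts[0])
    return cats


def degree_vector(G: WeightedGraph) -> np.ndarray:
    """Weighted degrees d_i = sum_j A_ij."""
    return np.asarray(G.A.sum(axis=1)).ravel()


def _inv_sqrt_degrees(d: np.ndarray, on_isolated: str, what: str) -> np.ndarray:
    iso = np.flatnonzero(d == 0)
    if iso.size and on_isolated == "error":
        raise ValueError(f"isolated node at index {iso[0]} cannot be {what}-normalized")
    with np.errstate(divide="ignore"):
        inv = 1.0 / np.sqrt(d)
    inv[d == 0] = 0.0
    return inv


def normalize_symmetric(G: WeightedGraph, on_isolated: str = "zero") -> NormalizedMatrix:
    """S = D^-1/2 A D^-1/2; rows/columns of isolated nodes are zero."""
    d = degree_vector(G)
    inv_sqrt = _inv_sqrt_degrees(d, on_isolated, "symmetric")
    S = sp.csr_array(sp.diags_array(inv_sqrt) @ G.A @ sp.diags_array(inv_sqrt))
    return NormalizedMatrix(S, "symmetric", d)


def normalize_asymmetric(G: WeightedGraph, on_isolated: str = "zero") -> NormalizedMatrix:
    """Row-stochastic P = D^-1 A; rows of isolated nodes are zero."""
    d = degree_vector(G)
    iso = np.flatnonzero(d == 0)
    if iso.size and on_isolated == "error":
        raise ValueError(f"isolated node at index {iso[0]} cannot be walk-normalized")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[d == 0] = 0.0
    P = sp.csr_array(sp.diags_array(inv) @ G.A)
    return NormalizedMatrix(P, "asymmetric", d)


def write_scores(path, G: WeightedGraph, scores: np.ndarray) -> None:
    """Write a two-column TSV (node, score) sorted by descending score.

    Ties are broken by node identifier so output is byte-stable.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (G.n_nodes,):
        raise ValueError("score vector length does not match graph")
    order = sorted(range(G.n_nodes), key=lambda i: (-scores[i], G.node_ids[i]))
    with open(path, "w") as fh:
        fh.write("node\tscore\n")
        for i in order:
            fh.write(f"{G.node_ids[i]}\t{scores[i]:.10g}\n")
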