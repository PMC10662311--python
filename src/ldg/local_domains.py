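"""Exemplar-centered local domains and their graph Laplacians.

A *local domain* is the elementary training unit of local domain
generalization: one positive sample (the exemplar) together with its ``k1``
nearest positive neighbours and ``k2`` nearest negative neighbours, all
measured in Euclidean distance.  Each local domain carries a kNN-graph
normalized Laplacian over its member samples, used by the solver's manifold
regularizer.

Data matrices are ``d x n`` with columns as samples; labels are ±1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .exceptions import (
    DegenerateLabelsError,
    InvalidExemplarError,
    InvalidGraphError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-8


@dataclass
class LocalDomain:
    """One exemplar-centered subdomain.

    ``sample_indices`` orders the members as exemplar first, then positive
    neighbours (ascending distance), then negative neighbours; ``labels``
    follows the same order with +1 for the exemplar and positives, -1 for
    negatives.  ``data_block`` holds the member samples as columns and
    ``laplacian`` is the normalized graph Laplacian over the block.
    """

    exemplar_index: int
    positive_neighbor_indices: np.ndarray
    negative_neighbor_indices: np.ndarray
    sample_indices: np.ndarray
    labels: np.ndarray
    laplacian: np.ndarray
    data_block: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.positive_neighbor_indices = np.asarray(
            self.positive_neighbor_indices, dtype=int
        )
        self.negative_neighbor_indices = np.asarray(
            self.negative_neighbor_indices, dtype=int
        )
        self.sample_indices = np.asarray(self.sample_indices, dtype=int)
        self.labels = np.asarray(self.labels, dtype=float)
        self.laplacian = np.asarray(self.laplacian, dtype=float)
        self.data_block = np.asarray(self.data_block, dtype=float)
        if self.validate:
            self._check_invariants()

    def _check_invariants(self) -> None:
        k = self.size
        n_pos = len(self.positive_neighbor_indices)
        n_neg = len(self.negative_neighbor_indices)
        expected = np.concatenate(
            (
                [self.exemplar_index],
                self.positive_neighbor_indices,
                self.negative_neighbor_indices,
            )
        )
        if not np.array_equal(self.sample_indices, expected):
            raise InvalidParameterError(
                "sample_indices must be exemplar, positives, negatives in order"
            )
        if len(np.unique(self.sample_indices)) != k:
            raise InvalidParameterError("local domain indices must be distinct")
        expected_labels = np.concatenate(
            (np.ones(1 + n_pos), -np.ones(n_neg))
        )
        if not np.array_equal(self.labels, expected_labels):
            raise InvalidParameterError(
                "labels must be +1 for exemplar/positives and -1 for negatives"
            )
        if self.data_block.shape[1] != k:
            raise InvalidParameterError(
                f"data_block has {self.data_block.shape[1]} columns, expected {k}"
            )
        L = self.laplacian
        if L.shape != (k, k) or not np.allclose(L, L.T, atol=_EIG_TOL):
            raise InvalidGraphError("laplacian must be k x k symmetric")
        eigs = np.linalg.eigvalsh(L)
        if eigs.min() < -_EIG_TOL or eigs.max() > 2.0 + _EIG_TOL:
            raise InvalidGraphError(
                f"laplacian eigenvalues outside [0, 2]: [{eigs.min()}, {eigs.max()}]"
            )

    @property
    def size(self) -> int:
        """Number of member samples, ``k = 1 + k1 + k2`` (minus any shortfall)."""
        return len(self.sample_indices)


def _nearest_by_index_tiebreak(d2: np.ndarray, candidates: np.ndarray, k: int):
    """Indices of the ``k`` candidates with smallest distance.

    Stable sort on the distances keeps candidates in ascending-index order at
    exact ties, making neighbour selection deterministic.
    """
    order = np.argsort(d2[candidates], kind="stable")
    return candidates[order[:k]]


def find_local_domain(
    X: np.ndarray,
    y: np.ndarray,
    v: int,
    k1: int,
    k2: int,
    k_graph: int | None = None,
    bandwidth_mode: float | str = "median",
) -> LocalDomain:
    """Build the local domain centred on positive sample ``v``.

    Neighbours are the ``k1`` nearest other positives and ``k2`` nearest
    negatives in Euclidean distance (ascending).  If fewer candidates exist
    than requested, all of them are used and the shortfall is logged rather
    than raised, so that tiny datasets remain usable.

    ``k_graph`` (default ``min(5, k - 1)``) and ``bandwidth_mode`` control the
    kNN graph behind the domain's Laplacian; see :func:`graph_weight_matrix`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[1]
    if n < 2:
        raise DegenerateLabelsError("need at least two samples")
    if y[v] != 1:
        raise InvalidExemplarError(f"sample {v} has label {y[v]}, expected +1")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelsError("both classes must be present")
    pos = pos[pos != v]
    if len(pos) == 0:
        logger.warning("exemplar %d has no other positive sample", v)

    d2 = np.sum((X - X[:, [v]]) ** 2, axis=0)
    if len(pos) < k1:
        logger.warning(
            "exemplar %d: only %d positive candidates for k1=%d", v, len(pos), k1
        )
    if len(neg) < k2:
        logger.warning(
            "exemplar %d: only %d negative candidates for k2=%d", v, len(neg), k2
        )
    pos_nn = _nearest_by_index_tiebreak(d2, pos, k1)
    neg_nn = _nearest_by_index_tiebreak(d2, neg, k2)

    members = np.concatenate(([v], pos_nn, neg_nn))
    block = X[:, members]
    k = len(members)
    kg = min(5, k - 1) if k_graph is None else k_graph
    S = graph_weight_matrix(block, kg, bandwidth_mode)
    L = normalized_laplacian(S)
    labels = np.concatenate((np.ones(1 + len(pos_nn)), -np.ones(len(neg_nn))))
    return LocalDomain(
        exemplar_index=int(v),
        positive_neighbor_indices=pos_nn,
        negative_neighbor_indices=neg_nn,
        sample_indices=members,
        labels=labels,
        laplacian=L,
        data_block=block,
    )


def build_all_local_domains(
    X: np.ndarray,
    y: np.ndarray,
    k1: int,
    k2: int,
    k_graph: int | None = None,
    bandwidth_mode: float | str = "median",
) -> list[LocalDomain]:
    """One local domain per positive sample, ordered by exemplar index."""
    y = np.asarray(y, dtype=float)
    positives = np.flatnonzero(y == 1)
    if len(positives) == 0:
        raise DegenerateLabelsError("no positive samples: cannot build local domains")
    return [
        find_local_domain(X, y, int(v), k1, k2, k_graph, bandwidth_mode)
        for v in positives
    ]


def graph_weight_matrix(
    X_v: np.ndarray,
    k_graph: int,
    bandwidth_mode: float | str = "median",
) -> np.ndarray:
    """Gaussian kNN graph weights over the columns of a ``d x k`` block.

    Entry ``(i, j)`` is ``exp(-||x_i - x_j||^2 / sigma)`` when ``x_i`` is
    among the ``k_graph`` nearest neighbours of ``x_j`` *or* vice versa
    (the either-neighbour rule), and 0 otherwise; the diagonal is 0.

    ``bandwidth_mode`` is either ``"median"`` — the median of the nonzero
    pairwise squared distances within the block, falling back to 1 when all
    points coincide — or a fixed positive number.
    """
    X_v = np.asarray(X_v, dtype=float)
    k = X_v.shape[1]
    if k < 2:
        raise InvalidParameterError("graph needs at least two samples")
    if k_graph >= k:
        raise InvalidParameterError(
            f"k_graph={k_graph} must be smaller than the block size k={k}"
        )
    if k_graph < 1:
        raise InvalidParameterError("k_graph must be >= 1")
    D2 = squareform(pdist(X_v.T, metric="sqeuclidean"))
    if bandwidth_mode == "median":
        nz = D2[np.triu_indices(k, 1)]
        nz = nz[nz > 0]
        sigma = float(np.median(nz)) if nz.size else 1.0
    else:
        sigma = float(bandwidth_mode)
        if sigma <= 0:
            raise InvalidParameterError("fixed graph bandwidth must be positive")
    # kNN mask per column; self excluded, ties broken by lowest index.
    mask = np.zeros((k, k), dtype=bool)
    for j in range(k):
        cand = np.delete(np.arange(k), j)
        nn = _nearest_by_index_tiebreak(D2[:, j], cand, k_graph)
        mask[nn, j] = True
    either = mask | mask.T
    S = np.where(either, np.exp(-D2 / sigma), 0.0)
    np.fill_diagonal(S, 0.0)
    return S


def normalized_laplacian(S_v: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian ``E^{-1/2} (E - S) E^{-1/2}``.

    ``E`` is the diagonal degree matrix of ``S``.  Zero-degree (isolated)
    nodes use the convention ``0^{-1/2} = 0``, zeroing their row and column.
    """
    S = np.asarray(S_v, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidGraphError("S_v must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise InvalidGraphError("S_v must be symmetric")
    if S.min() < 0:
        raise InvalidGraphError("S_v must be nonnegative")
    deg = S.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = -S * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(L, np.where(deg > 0, 1.0, 0.0))
    return (L + L.T) / 2.0
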