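"""Kernel functions, empirical kernel maps and multiple-kernel concatenation.

Data matrices are oriented with columns as samples (``d x n``).  Five kernel
families are supported; all distance-based families use the Euclidean metric,
consistent with the neighbour geometry used to build local domains:

========================  =======================================
family                    K(x, z)
========================  =======================================
``linear``                ``x^T z``
``gaussian``              ``exp(-sigma * ||x - z||^2)``
``inv_square_distance``   ``1 / (1 + sigma * ||x - z||^2)``
``laplacian``             ``exp(-sigma * ||x - z||)``
``inv_distance``          ``1 / (1 + sigma * ||x - z||)``
========================  =======================================

The sentinel bandwidth ``"auto"`` resolves to ``sigma = 1/d`` where ``d`` is
the feature dimension, the standard default for differential-entropy EEG
features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InvalidParameterError

KERNEL_FAMILIES = (
    "linear",
    "gaussian",
    "inv_square_distance",
    "laplacian",
    "inv_distance",
)

#: Families entering the multiple-kernel (MKL) concatenation, in stack order.
MKL_FAMILIES = ("gaussian", "inv_square_distance", "laplacian", "inv_distance")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its bandwidth.

    Parameters
    ----------
    family:
        One of :data:`KERNEL_FAMILIES`.
    bandwidth:
        Positive real ``sigma``, or the sentinel ``"auto"`` meaning
        ``sigma = 1/d``.  Ignored by the linear family.
    """

    family: str = "gaussian"
    bandwidth: float | str = "auto"

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise InvalidParameterError(
                f"unknown kernel family {self.family!r}; "
                f"expected one of {KERNEL_FAMILIES}"
            )
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "auto":
                raise InvalidParameterError(
                    f"bandwidth must be positive or 'auto', got {self.bandwidth!r}"
                )
        elif not self.bandwidth > 0:
            raise InvalidParameterError(
                f"bandwidth must be positive, got {self.bandwidth}"
            )

    @property
    def is_linear(self) -> bool:
        return self.family == "linear"

    def resolve_bandwidth(self, d: int) -> float:
        """Return the numeric ``sigma``, resolving ``"auto"`` to ``1/d``."""
        if self.bandwidth == "auto":
            return 1.0 / d
        return float(self.bandwidth)


def _as_2d(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.ndim != 2:
        raise ValueError(f"{name} must be a d x n matrix, got shape {A.shape}")
    return A


def kernel_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix between the columns of ``A`` (d x n1) and ``B`` (d x n2)."""
    A = _as_2d(A, "A")
    B = _as_2d(B, "B")
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"feature dimensions differ: A has {A.shape[0]}, B has {B.shape[0]}"
        )
    if spec.is_linear:
        return A.T @ B
    sigma = spec.resolve_bandwidth(A.shape[0])
    if spec.family in ("gaussian", "inv_square_distance"):
        D = cdist(A.T, B.T, metric="sqeuclidean")
    else:
        D = cdist(A.T, B.T, metric="euclidean")
    if spec.family in ("gaussian", "laplacian"):
        return np.exp(-sigma * D)
    return 1.0 / (1.0 + sigma * D)


def empirical_kernel_map(
    X_train: np.ndarray, X_query: np.ndarray, spec: KernelSpec
) -> np.ndarray:
    """Empirical kernel map of query samples against a reference block.

    Column ``j`` of the result is ``(K(x_1, q_j), ..., K(x_n, q_j))`` for
    reference columns ``x_i`` of ``X_train``.  The linear family passes
    ``X_query`` through unchanged, so linear fitting operates on the raw
    features.
    """
    X_query = _as_2d(X_query, "X_query")
    if spec.is_linear:
        return X_query.copy()
    return kernel_matrix(X_train, X_query, spec)


def mkl_concatenate(maps: list[np.ndarray]) -> np.ndarray:
    """Vertically stack per-kernel representations into one feature block.

    All maps must share the same shape ``n x q``; the result is ``(U*n) x q``
    where ``U = len(maps)``, preserving the listed order.
    """
    if not maps:
        raise ValueError("need at least one kernel map to concatenate")
    arrays = [np.atleast_2d(np.asarray(m, dtype=float)) for m in maps]
    shape = arrays[0].shape
    for i, a in enumerate(arrays[1:], start=1):
        if a.shape != shape:
            raise ValueError(
                f"kernel map {i} has shape {a.shape}, expected {shape}"
            )
    return np.vstack(arrays)


def mkl_kernel_map(
    X_train: np.ndarray,
    X_query: np.ndarray,
    bandwidth: float | str = "auto",
) -> np.ndarray:
    """Concatenated empirical kernel map over the four MKL families.

    Each family is mapped with the same bandwidth policy and the maps are
    stacked in :data:`MKL_FAMILIES` order, yielding a ``(4*n) x q`` block that
    can replace the raw data matrix in the solver.
    """
    maps = [
        empirical_kernel_map(X_train, X_query, KernelSpec(fam, bandwidth))
        for fam in MKL_FAMILIES
    ]
    return mkl_concatenate(maps)
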