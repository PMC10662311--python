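"""Fusing local classifiers for prediction on target domains.

Two regimes are supported:

* **DG** (domain generalization) — no target data was seen: each binary
  model's local classifiers are fused with their learned contribution
  weights, ``score(x) = sum_v theta_v^2 (x^T w_v + b_v)``.
* **LDA** (local domain adaptation) — unlabeled target features are
  available: each local classifier is reweighted by the kernel maximum mean
  discrepancy (MMD) between its local domain and the target sample,
  ``zeta_v ∝ exp(-Psi_v)``, and the fused score is
  ``sum_v zeta_v (x^T w_v + b_v)``.

Multiclass decisions use one-vs-rest: the class whose binary score is
maximal wins, ties broken by class order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import DegenerateLabelsError, InvalidParameterError
from .kernels import KernelSpec, empirical_kernel_map, kernel_matrix, mkl_kernel_map
from .optimizer import BinaryLDGModel, LDGHyperparams, fit_binary


@dataclass
class FittedLDGModel:
    """One-vs-rest ensemble: one converged binary model per class."""

    classes: np.ndarray
    binary_models: list[BinaryLDGModel]
    kernel: KernelSpec | str
    reference_block: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.binary_models) != len(self.classes):
            raise InvalidParameterError("need exactly one binary model per class")
        dims = {bm.W.shape[0] for bm in self.binary_models}
        if len(dims) != 1:
            raise InvalidParameterError("binary models disagree on dimension")


def fit_ldg(
    X: np.ndarray,
    y: np.ndarray,
    hyper: LDGHyperparams | None = None,
) -> FittedLDGModel:
    """Train the one-vs-rest ensemble on a labeled source domain.

    ``X`` is ``d x n`` (columns = samples) and ``y`` holds arbitrary class
    labels; each class is trained against the rest with +1/-1 coding.  The
    kernel map (when nonlinear) is computed once and shared by all classes.
    """
    hyper = hyper if hyper is not None else LDGHyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelsError("need at least two classes")

    from .optimizer import _effective_data  # shared mapping logic

    X_eff, reference = _effective_data(X, hyper.kernel)
    models = []
    for c in classes:
        y_bin = np.where(y == c, 1.0, -1.0)
        models.append(
            fit_binary(
                X_eff, y_bin, hyper, premapped=True, reference_block=reference
            )
        )
    return FittedLDGModel(
        classes=classes,
        binary_models=models,
        kernel=hyper.kernel,
        reference_block=reference,
    )


def _map_queries(model: FittedLDGModel, X_query: np.ndarray) -> np.ndarray:
    """Bring query samples into the model's effective feature space."""
    X_query = np.asarray(X_query, dtype=float)
    if X_query.ndim == 1:
        X_query = X_query[:, None]
    if isinstance(model.kernel, str):  # "mkl"
        return mkl_kernel_map(model.reference_block, X_query)
    if model.kernel.is_linear:
        return X_query
    return empirical_kernel_map(model.reference_block, X_query, model.kernel)


def predict_dg_score(x: np.ndarray, bm: BinaryLDGModel) -> float | np.ndarray:
    """Fused generalization score ``sum_v theta_v^2 (x^T w_v + b_v)``.

    The square on theta follows the fused prediction rule regardless of the
    exponent ``r`` used during training.  Accepts a single d-vector or a
    ``d x q`` batch (already in the effective space).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xq = x[:, None] if single else x
    if Xq.shape[0] != bm.W.shape[0]:
        raise ValueError(
            f"dimension mismatch: query has {Xq.shape[0]}, model has {bm.W.shape[0]}"
        )
    scores_per_domain = bm.W.T @ Xq + bm.b_local[:, None]  # m x q
    w2 = bm.theta ** 2
    out = w2 @ scores_per_domain
    return float(out[0]) if single else out


def mmd_distance(
    X_v: np.ndarray, X_t: np.ndarray, spec: KernelSpec | None = None
) -> float:
    """Kernel maximum mean discrepancy between two sample sets.

    Biased estimator: ``Psi = sqrt(mean(K_vv) - 2 mean(K_vt) + mean(K_tt))``,
    clipped at zero before the root.  The default kernel is Gaussian with the
    median heuristic over the pooled pairwise squared distances.
    """
    X_v = np.atleast_2d(np.asarray(X_v, dtype=float))
    X_t = np.atleast_2d(np.asarray(X_t, dtype=float))
    if X_v.shape[0] != X_t.shape[0]:
        raise ValueError("X_v and X_t must share the feature dimension")
    if X_t.shape[1] < 1 or X_v.shape[1] < 1:
        raise ValueError("both sample sets must be non-empty")
    if spec is None:
        pooled = np.concatenate((X_v, X_t), axis=1)
        D2 = cdist(pooled.T, pooled.T, metric="sqeuclidean")
        nz = D2[np.triu_indices(D2.shape[0], 1)]
        nz = nz[nz > 0]
        sigma = 1.0 / float(np.median(nz)) if nz.size else 1.0
        spec = KernelSpec("gaussian", sigma)
    K_vv = kernel_matrix(X_v, X_v, spec)
    K_vt = kernel_matrix(X_v, X_t, spec)
    K_tt = kernel_matrix(X_t, X_t, spec)
    val = K_vv.mean() - 2.0 * K_vt.mean() + K_tt.mean()
    return float(np.sqrt(max(val, 0.0)))


def lda_weights(psi: np.ndarray) -> np.ndarray:
    """Classifier weights ``zeta_v = exp(-Psi_v) / sum_u exp(-Psi_u)``."""
    z = -np.asarray(psi, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def predict_lda_score(
    x_j: np.ndarray, bm: BinaryLDGModel, zeta: np.ndarray
) -> float | np.ndarray:
    """Adaptation score ``sum_v zeta_v (x^T w_v + b_v)`` for given weights."""
    zeta = np.asarray(zeta, dtype=float)
    if zeta.shape != (bm.W.shape[1],):
        raise ValueError("zeta must have one weight per local domain")
    x_j = np.asarray(x_j, dtype=float)
    single = x_j.ndim == 1
    Xq = x_j[:, None] if single else x_j
    if Xq.shape[0] != bm.W.shape[0]:
        raise ValueError("dimension mismatch between query and model")
    scores = bm.W.T @ Xq + bm.b_local[:, None]
    out = zeta @ scores
    return float(out[0]) if single else out


def _binary_scores(
    model: FittedLDGModel,
    X_query_eff: np.ndarray,
    mode: str,
    X_target_eff: np.ndarray | None,
) -> np.ndarray:
    """Per-class score matrix (n_classes x q) in the requested mode."""
    rows = []
    for bm in model.binary_models:
        if mode == "dg":
            rows.append(predict_dg_score(X_query_eff, bm))
        else:
            psi = np.array(
                [
                    mmd_distance(dom.data_block, X_target_eff)
                    for dom in bm.local_domains
                ]
            )
            rows.append(predict_lda_score(X_query_eff, bm, lda_weights(psi)))
    return np.asarray(rows)


def predict_label(
    x: np.ndarray,
    model: FittedLDGModel,
    mode: str = "dg",
    X_target: np.ndarray | None = None,
):
    """Predict class labels for one sample (d-vector) or a batch (d x q).

    ``mode="dg"`` fuses with the learned theta^2 weights; ``mode="lda"``
    requires the unlabeled target features ``X_target`` and reweights each
    local classifier by its MMD proximity to the target.  Only target
    *features* enter the weighting — labels are never touched.
    """
    if mode not in ("dg", "lda"):
        raise InvalidParameterError(f"mode must be 'dg' or 'lda', got {mode!r}")
    if mode == "lda" and X_target is None:
        raise InvalidParameterError("lda mode requires X_target")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xq = _map_queries(model, x)
    Xt = _map_queries(model, X_target) if mode == "lda" else None
    scores = _binary_scores(model, Xq, mode, Xt)
    winners = model.classes[np.argmax(scores, axis=0)]
    return winners[0] if single else winners
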