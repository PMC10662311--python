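"""Feature-table and model (de)serialization.

Feature tables are delimited text with a header row: feature columns in file
order, a ``label`` column and a ``subject`` column.  Models are stored as a
versioned, self-describing JSON container holding every field needed for
DG and LDA prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .kernels import KernelSpec
from .local_domains import LocalDomain
from .optimizer import BinaryLDGModel, LDGHyperparams
from .inference import FittedLDGModel

MODEL_FORMAT = "ldg-model"
MODEL_VERSION = 1


@dataclass
class FeatureTable:
    """In-memory feature table: ``d x n`` features plus labels and subjects."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = self.X.shape[1]
        if len(self.y) != n or len(self.subject_ids) != n:
            raise FormatError("labels and subject ids must match the sample count")
        if not np.all(np.isfinite(self.X)):
            raise FormatError("feature table contains non-finite values")
        if len(np.unique(self.y)) < 2:
            raise FormatError("feature table must contain at least two classes")
        if len(self.subject_ids) == 0:
            raise FormatError("feature table must contain at least one subject")

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[0]


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def load_feature_table(path: str | Path, delimiter: str | None = None) -> FeatureTable:
    """Read a delimited feature table.

    Every non-``label``, non-``subject`` column is a feature, in file order;
    rows are samples (transposed to ``d x n`` internally).  Missing cells and
    non-numeric features raise :class:`FormatError` naming the offending
    row/column.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, delimiter=_infer_delimiter(path, delimiter))
    for required in ("label", "subject"):
        if required not in df.columns:
            raise FormatError(f"missing required column {required!r} in {path}")
    feature_names = [c for c in df.columns if c not in ("label", "subject")]
    if not feature_names:
        raise FormatError(f"no feature columns found in {path}")
    feats = df[feature_names]
    if feats.isna().any().any():
        col = feats.columns[feats.isna().any()][0]
        row = int(feats[col].isna().idxmax())
        raise FormatError(f"missing value at row {row}, column {col!r}")
    try:
        X = feats.to_numpy(dtype=float).T
    except (TypeError, ValueError):
        for col in feature_names:
            coerced = pd.to_numeric(feats[col], errors="coerce")
            if coerced.isna().any():
                row = int(coerced.isna().idxmax())
                raise FormatError(
                    f"non-numeric feature at row {row}, column {col!r}"
                ) from None
        raise
    if df["label"].isna().any() or df["subject"].isna().any():
        raise FormatError("missing label or subject values")
    return FeatureTable(
        X=X,
        y=df["label"].to_numpy(),
        subject_ids=df["subject"].to_numpy(),
        feature_names=feature_names,
    )


def save_feature_table(
    table: FeatureTable, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a table in the standard ``f1..fd,label,subject`` layout."""
    df = pd.DataFrame(table.X.T, columns=table.feature_names)
    df["label"] = table.y
    df["subject"] = table.subject_ids
    df.to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------


def _kernel_to_json(kernel: KernelSpec | str):
    if isinstance(kernel, str):
        return {"family": "mkl"}
    return {"family": kernel.family, "bandwidth": kernel.bandwidth}


def _kernel_from_json(obj) -> KernelSpec | str:
    if obj["family"] == "mkl":
        return "mkl"
    return KernelSpec(obj["family"], obj["bandwidth"])


def _domain_to_json(dom: LocalDomain):
    return {
        "exemplar_index": int(dom.exemplar_index),
        "positive_neighbor_indices": dom.positive_neighbor_indices.tolist(),
        "negative_neighbor_indices": dom.negative_neighbor_indices.tolist(),
        "labels": dom.labels.tolist(),
        "laplacian": dom.laplacian.tolist(),
        "data_block": dom.data_block.tolist(),
    }


def _domain_from_json(obj) -> LocalDomain:
    pos = np.asarray(obj["positive_neighbor_indices"], dtype=int)
    neg = np.asarray(obj["negative_neighbor_indices"], dtype=int)
    return LocalDomain(
        exemplar_index=obj["exemplar_index"],
        positive_neighbor_indices=pos,
        negative_neighbor_indices=neg,
        sample_indices=np.concatenate(([obj["exemplar_index"]], pos, neg)),
        labels=np.asarray(obj["labels"], dtype=float),
        laplacian=np.asarray(obj["laplacian"], dtype=float),
        data_block=np.asarray(obj["data_block"], dtype=float),
        validate=False,
    )


def _binary_to_json(bm: BinaryLDGModel):
    return {
        "W": bm.W.tolist(),
        "b_local": bm.b_local.tolist(),
        "theta": bm.theta.tolist(),
        "lambda": bm.lambda_.tolist(),
        "w_tilde": bm.w_tilde.tolist(),
        "b_global": bm.b_global,
        "domains": [_domain_to_json(d) for d in bm.local_domains],
    }


def _binary_from_json(obj, kernel, reference) -> BinaryLDGModel:
    return BinaryLDGModel(
        local_domains=[_domain_from_json(d) for d in obj["domains"]],
        W=np.asarray(obj["W"], dtype=float),
        b_local=np.asarray(obj["b_local"], dtype=float),
        theta=np.asarray(obj["theta"], dtype=float),
        lambda_=np.asarray(obj["lambda"], dtype=float),
        w_tilde=np.asarray(obj["w_tilde"], dtype=float),
        b_global=float(obj["b_global"]),
        kernel=kernel,
        reference_block=reference,
        objective_trace=[],
        full_objective_trace=[],
        per_domain_iterations=np.zeros(0, dtype=int),
        iterations=0,
        converged=True,
        state=None,
    )


def save_model(
    model: FittedLDGModel,
    path: str | Path,
    hyper: LDGHyperparams | None = None,
) -> None:
    """Persist a fitted model (and optionally its hyperparameters) as JSON."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "kernel": _kernel_to_json(model.kernel),
        "classes": np.asarray(model.classes).tolist(),
        "reference_block": (
            None if model.reference_block is None else model.reference_block.tolist()
        ),
        "binary_models": [_binary_to_json(bm) for bm in model.binary_models],
    }
    if hyper is not None:
        payload["hyperparams"] = {
            "alpha": hyper.alpha,
            "beta": hyper.beta,
            "mu": hyper.mu,
            "r": hyper.r,
            "k1": hyper.k1,
            "k2": hyper.k2,
            "k_graph": hyper.k_graph,
            "kernel": _kernel_to_json(hyper.kernel),
            "tol": hyper.tol,
            "max_iter": hyper.max_iter,
            "jitter": hyper.jitter,
            "sweeps": hyper.sweeps,
            "init": hyper.init,
            "seed": hyper.seed,
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FittedLDGModel:
    """Load a model previously written by :func:`save_model`."""
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path} is not an {MODEL_FORMAT} file")
    if obj.get("version") != MODEL_VERSION:
        raise FormatError(
            f"unsupported model version {obj.get('version')} (expected {MODEL_VERSION})"
        )
    kernel = _kernel_from_json(obj["kernel"])
    reference = (
        None
        if obj["reference_block"] is None
        else np.asarray(obj["reference_block"], dtype=float)
    )
    return FittedLDGModel(
        classes=np.asarray(obj["classes"]),
        binary_models=[
            _binary_from_json(bm, kernel, reference) for bm in obj["binary_models"]
        ],
        kernel=kernel,
        reference_block=reference,
    )
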