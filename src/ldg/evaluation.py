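"""Evaluation protocols: leave-one-subject-out, chance level, grid search.

Accuracies are fractions in [0, 1] throughout the API; multiply by 100 for
the percentage convention used when reporting recognition rates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.metrics import accuracy_score

from .exceptions import InvalidParameterError, ProtocolError
from .inference import fit_ldg, predict_label
from .io import FeatureTable
from .optimizer import LDGHyperparams

logger = logging.getLogger(__name__)


def loso_splits(subject_ids: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out index splits, ordered by subject identifier.

    Each split holds out all samples of one subject as the test domain and
    trains on everything else.
    """
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if len(subjects) < 2:
        raise ProtocolError("leave-one-subject-out needs at least two subjects")
    splits = []
    for s in subjects:
        test = np.flatnonzero(subject_ids == s)
        train = np.flatnonzero(subject_ids != s)
        splits.append((train, test))
    return splits


def empirical_chance_level(
    y_test: np.ndarray,
    n_repeats: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical chance level of uniformly random prediction.

    Repeats random label predictions over the test labels and returns the
    mean accuracy together with the upper bound of the chance level (UBCL):
    the upper end of the ``confidence`` interval of the repeat distribution
    under a normal approximation.  For ``c`` balanced classes the mean
    approaches ``1/c`` as the test set grows.
    """
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise InvalidParameterError("y_test must be non-empty")
    if n_repeats < 100:
        raise InvalidParameterError("need at least 100 repeats")
    classes = np.unique(y_test)
    rng = np.random.default_rng(seed)
    preds = rng.choice(classes, size=(n_repeats, y_test.size))
    accs = (preds == y_test[None, :]).mean(axis=1)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    mean = float(accs.mean())
    ubcl = float(mean + z * accs.std(ddof=1))
    return mean, ubcl


@dataclass
class LosoReport:
    """Per-subject accuracies of a leave-one-subject-out run."""

    subjects: np.ndarray
    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0


def evaluate_loso(
    table: FeatureTable,
    hyper: LDGHyperparams | None = None,
    mode: str = "dg",
) -> LosoReport:
    """Leave-one-subject-out evaluation of the full multiclass pipeline.

    For each held-out subject the one-vs-rest ensemble is fitted on the
    remaining subjects and evaluated on the held-out samples.  In ``lda``
    mode the held-out subject's *features* (never its labels) serve as the
    unlabeled target for MMD reweighting.
    """
    hyper = hyper if hyper is not None else LDGHyperparams()
    subjects = np.unique(table.subject_ids)
    accs = []
    for train, test in loso_splits(table.subject_ids):
        model = fit_ldg(table.X[:, train], table.y[train], hyper)
        X_test = table.X[:, test]
        pred = predict_label(
            X_test, model, mode=mode, X_target=X_test if mode == "lda" else None
        )
        acc = accuracy_score(table.y[test], pred)
        accs.append(acc)
        logger.info(
            "held-out subject %s: accuracy %.4f (%d test samples)",
            table.subject_ids[test[0]],
            acc,
            len(test),
        )
    return LosoReport(subjects=subjects, accuracies=np.asarray(accs))


def _subject_folds(subject_ids: np.ndarray, p: int) -> list[np.ndarray]:
    """Group subjects into ``p`` folds (round-robin over sorted subjects)."""
    subjects = np.unique(subject_ids)
    if p > len(subjects):
        raise ProtocolError(
            f"cannot form {p} subject-stratified folds from {len(subjects)} subjects"
        )
    folds = [[] for _ in range(p)]
    for i, s in enumerate(subjects):
        folds[i % p].append(s)
    return [
        np.flatnonzero(np.isin(subject_ids, fold_subjects))
        for fold_subjects in folds
    ]


def grid_search(
    table: FeatureTable,
    param_grids: dict[str, list],
    p: int = 5,
    base_hyper: LDGHyperparams | None = None,
    mode: str = "dg",
) -> tuple[LDGHyperparams, list[dict]]:
    """Exhaustive hyperparameter search by subject-stratified cross-validation.

    ``param_grids`` maps :class:`LDGHyperparams` field names to candidate
    lists; every combination is scored by ``p``-fold cross-validation with
    folds formed by grouping source subjects, and the configuration with the
    highest mean fold accuracy wins (ties: first in grid order).  Degenerate
    configurations (e.g. a graph-kNN size not smaller than the local-domain
    size) are skipped with a warning.

    Returns the winning hyperparameters and the per-configuration records.
    """
    if not param_grids or any(len(v) == 0 for v in param_grids.values()):
        raise InvalidParameterError("param_grids must be non-empty")
    base = base_hyper if base_hyper is not None else LDGHyperparams()
    folds = _subject_folds(table.subject_ids, p)

    keys = list(param_grids)
    results: list[dict] = []
    best: LDGHyperparams | None = None
    best_score = -np.inf
    for combo in itertools.product(*(param_grids[k] for k in keys)):
        params = dict(zip(keys, combo))
        try:
            hyper = replace(base, **params)
        except InvalidParameterError as exc:
            logger.warning("skipping invalid configuration %s: %s", params, exc)
            continue
        if hyper.k_graph >= 1 + hyper.k1 + hyper.k2:
            logger.warning(
                "skipping degenerate configuration %s: k_graph >= local domain size",
                params,
            )
            continue
        fold_accs = []
        try:
            for i, test in enumerate(folds):
                train = np.concatenate([f for j, f in enumerate(folds) if j != i])
                model = fit_ldg(table.X[:, train], table.y[train], hyper)
                X_test = table.X[:, test]
                pred = predict_label(
                    X_test,
                    model,
                    mode=mode,
                    X_target=X_test if mode == "lda" else None,
                )
                fold_accs.append(accuracy_score(table.y[test], pred))
        except Exception as exc:  # noqa: BLE001 - degenerate cells are skipped
            logger.warning("skipping failing configuration %s: %s", params, exc)
            continue
        score = float(np.mean(fold_accs))
        results.append({"params": params, "fold_accuracies": fold_accs, "mean": score})
        if score > best_score:
            best, best_score = hyper, score
    if best is None:
        raise ProtocolError("no valid configuration in the grid")
    return best, results
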