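"""Seeded generator of multi-subject, multimodal, domain-shifted features.

The generator emulates the structure that local domain generalization
assumes in cross-subject EEG emotion recognition: several subjects share the
same class semantics (cluster centers are common), each class is multimodal
(several clusters per class), and every subject's distribution is shifted by
an additive per-subject mean offset — the covariate shift that makes
leave-one-subject-out evaluation nontrivial.

A minimal differential-entropy feature utility is included so that the full
pipeline (signal -> DE feature -> classifier) can be exercised without any
external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSignalError, InvalidParameterError


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the multi-subject generator.

    class_separation is the distance between class center groups in units of
    the noise standard deviation; subject_shift_scale is the standard
    deviation of each subject's additive mean shift (absolute units);
    cluster_spread scales the dispersion of a class's cluster centers around
    its group center (units of noise_sigma).
    """

    n_subjects: int = 4
    n_classes: int = 3
    samples_per_class_per_subject: int = 40
    d: int = 6
    clusters_per_class: int = 2
    class_separation: float = 6.0
    subject_shift_scale: float = 1.0
    noise_sigma: float = 1.0
    cluster_spread: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_subjects,
            self.n_classes,
            self.samples_per_class_per_subject,
            self.d,
            self.clusters_per_class,
        )
        if min(counts) < 1:
            raise InvalidParameterError("all counts must be >= 1")
        if min(self.class_separation, self.subject_shift_scale, self.noise_sigma) < 0:
            raise InvalidParameterError("separation, shift and noise must be >= 0")
        if self.cluster_spread < 0:
            raise InvalidParameterError("cluster_spread must be >= 0")


def _class_group_centers(config: SyntheticConfig, rng: np.random.Generator):
    """Class-group centers with pairwise distance ``class_separation * sigma``.

    The centers sit at the vertices of a regular simplex embedded in the
    feature space (random orientation), so every pair of classes is equally
    separated.  Requires ``d >= n_classes - 1``.
    """
    c, d = config.n_classes, config.d
    if c == 1:
        return np.zeros((1, d))
    if d < c - 1:
        raise InvalidParameterError(
            f"d={d} too small to separate {c} classes equally (need d >= {c - 1})"
        )
    # Regular simplex on c points in (c-1) dims with unit pairwise distance.
    simplex = np.eye(c)[:, : c - 1]
    simplex -= simplex.mean(axis=0, keepdims=True)
    simplex /= np.linalg.norm(simplex[0] - simplex[1])
    # Random orthonormal embedding into d dims.
    basis, _ = np.linalg.qr(rng.standard_normal((d, c - 1)))
    return (
        config.class_separation * config.noise_sigma * simplex @ basis.T
    )  # c x d


def generate_multisubject_dataset(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the dataset; returns ``(X (d x n), y (n,), subject_ids (n,))``.

    Cluster centers are drawn once and shared across subjects; each subject
    adds its own mean-shift vector; each sample adds isotropic noise.  Class
    counts are balanced within every subject, and samples cycle through the
    class's clusters so the multimodal structure is represented evenly.
    Output is fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    group = _class_group_centers(config, rng)
    spread = config.cluster_spread * config.noise_sigma
    centers = (
        group[:, None, :]
        + spread * rng.standard_normal((config.n_classes, config.clusters_per_class, config.d))
    )  # class x cluster x d
    shifts = config.subject_shift_scale * rng.standard_normal(
        (config.n_subjects, config.d)
    )

    blocks, labels, subjects = [], [], []
    npc = config.samples_per_class_per_subject
    for s in range(config.n_subjects):
        for c in range(config.n_classes):
            cluster_idx = np.arange(npc) % config.clusters_per_class
            base = centers[c, cluster_idx, :]  # npc x d
            noise = config.noise_sigma * rng.standard_normal((npc, config.d))
            blocks.append(base + shifts[s] + noise)
            labels.append(np.full(npc, c))
            subjects.append(np.full(npc, s))
    X = np.concatenate(blocks, axis=0).T
    y = np.concatenate(labels)
    subject_ids = np.concatenate(subjects)
    return X, y, subject_ids


def differential_entropy_feature(
    window: np.ndarray,
    band: tuple[float, float],
    sample_rate: float,
) -> float:
    """Differential entropy ``0.5 * ln(2*pi*e*var)`` of a band-limited window.

    The window is band-limited by masking its Fourier coefficients outside
    ``band`` (Hz) and transforming back; the Gaussian differential-entropy
    formula is then applied to the filtered signal's variance.  This is the
    standard DE feature of EEG emotion recognition.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise InvalidParameterError("window must be a 1-D signal of length >= 8")
    lo, hi = band
    nyquist = sample_rate / 2.0
    if not (0 <= lo < hi <= nyquist):
        raise InvalidParameterError(
            f"band {band} must satisfy 0 <= lo < hi <= Nyquist ({nyquist})"
        )
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    spec = np.fft.rfft(x)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    filtered = np.fft.irfft(spec, n=x.size)
    var = float(np.var(filtered))
    if var <= 0.0:
        raise DegenerateSignalError("signal has no variance in the requested band")
    return 0.5 * float(np.log(2.0 * np.pi * np.e * var))
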