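"""Seeded synthetic datasets and deterministic test signals.

Desk-scale stand-ins for the small classification tasks the conversion
pipeline is exercised on: multi-class Gaussian blobs with controllable
separation (in units of the within-cluster standard deviation) and simple
analog signals (step, ramp, sine) for the encoder.  Every generator is a
pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.datasets import make_blobs as _sk_make_blobs

__all__ = ["ToyDataset", "make_blobs", "make_signal"]


@dataclass
class ToyDataset:
    """Labeled feature matrix with a fixed train/test split."""

    features: np.ndarray
    labels: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 0
    tag: str = "blobs"

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train/test splits must be disjoint")

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def X_train(self) -> np.ndarray:
        return self.features[self.train_idx]

    @property
    def y_train(self) -> np.ndarray:
        return self.labels[self.train_idx]

    @property
    def X_test(self) -> np.ndarray:
        return self.features[self.test_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.labels[self.test_idx]


def make_blobs(
    n: int = 240,
    d: int = 4,
    K: int = 3,
    separation: float = 6.0,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> ToyDataset:
    """K Gaussian clusters (unit within-cluster std) in d dimensions.

    Cluster centers are drawn at random and rescaled so the minimum pairwise
    center distance equals ``separation`` standard deviations; ``separation``
    around 6 gives an essentially separable task, 2-3 a genuinely noisy one.
    The split is stratified (``test_fraction`` per class) and deterministic
    per seed.
    """
    if n < K:
        raise ValueError("need at least one sample per class")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(K, d))
    min_dist = pdist(centers).min()
    if min_dist == 0:
        raise ValueError("degenerate centers; use another seed")
    centers *= separation / min_dist

    per_class = [n // K + (1 if c < n % K else 0) for c in range(K)]
    features, labels = _sk_make_blobs(
        n_samples=per_class,
        centers=centers,
        cluster_std=1.0,
        random_state=np.random.RandomState(seed),
    )

    train_parts, test_parts = [], []
    for c in range(K):
        idx = np.nonzero(labels == c)[0]
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * idx.size)))
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    return ToyDataset(
        features=features,
        labels=labels.astype(int),
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        seed=seed,
    )


def make_signal(
    kind: str,
    amplitude: float = 1.0,
    duration: float = 1000.0,
    dt: float = 1.0,
    onset: Optional[float] = None,
    freq_hz: float = 5.0,
) -> np.ndarray:
    """Deterministic analog test signal sampled at ``dt`` (all times in ms).

    ``step``: 0 before ``onset`` (default duration/4), ``amplitude`` after;
    ``ramp``: linear from 0 at t=0 to ``amplitude`` at the last sample;
    ``sine``: ``amplitude * sin(2 pi freq_hz t)`` (zero mean over full periods).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    if kind == "step":
        onset = duration / 4.0 if onset is None else onset
        return np.where(t < onset, 0.0, amplitude)
    if kind == "ramp":
        return amplitude * t / t[-1] if n > 1 else np.array([amplitude])
    if kind == "sine":
        return amplitude * np.sin(2.0 * np.pi * freq_hz * t / 1000.0)
    raise ValueError(f"unknown signal kind {kind!r}")
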