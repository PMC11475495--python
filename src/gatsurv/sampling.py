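"""SMOTE oversampling of the minority vital-status class.

Each synthetic sample is a convex combination of a minority sample and one of
its k nearest minority neighbors (Euclidean distance):

    x_syn = x_i + lambda * (x_i,nn - x_i),   lambda ~ U[0, 1].

The default configuration (k_neighbors = 1, seed = 42) mirrors the reference
pipeline's balancing step.  Synthetic samples inherit the survival outcome of
their base sample; attachment to the patient graph is handled downstream by
recomputing correlations (see :mod:`gatsurv.graphs`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 1
    seed: int = 42
    target_ratio: float = 1.0  # minority/majority ratio after oversampling

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ConfigurationError("target_ratio must lie in (0, 1]")


@dataclass(frozen=True)
class SmoteDraw:
    """Provenance of one synthetic sample."""

    base_index: int
    neighbor_index: int
    lam: float


def smote_oversample(
    X_minority: np.ndarray, n_new: int, config: SmoteConfig = SmoteConfig()
):
    """Generate ``n_new`` synthetic minority samples.

    Returns ``(X_syn, draws)`` where each row of ``X_syn`` lies on the closed
    segment between its base minority sample and the chosen neighbor, and
    ``draws`` records (base, neighbor, lambda) per row.
    """
    config.validate()
    X_minority = np.asarray(X_minority, dtype=float)
    if X_minority.ndim != 2:
        raise ConfigurationError("X_minority must be 2-d")
    if not np.all(np.isfinite(X_minority)):
        raise ConfigurationError("X_minority contains non-finite values")
    if n_new < 0:
        raise ConfigurationError("n_new must be non-negative")
    n_min = X_minority.shape[0]
    if n_min <= config.k_neighbors:
        raise ConfigurationError(
            f"minority class has {n_min} samples; need more than k_neighbors="
            f"{config.k_neighbors}"
        )
    if n_new == 0:
        return np.empty((0, X_minority.shape[1])), []

    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(X_minority)
    # column 0 is the point itself (distance 0); keep the k true neighbors
    neighbor_idx = nn.kneighbors(X_minority, return_distance=False)[:, 1:]

    rng = np.random.default_rng(config.seed)
    bases = rng.integers(0, n_min, size=n_new)
    picks = rng.integers(0, config.k_neighbors, size=n_new)
    lams = rng.random(n_new)
    neighbors = neighbor_idx[bases, picks]
    X_syn = X_minority[bases] + lams[:, None] * (X_minority[neighbors] - X_minority[bases])
    draws = [SmoteDraw(int(b), int(m), float(l)) for b, m, l in zip(bases, neighbors, lams)]
    return X_syn, draws


def n_synthetic_needed(n_minority: int, n_majority: int, target_ratio: float = 1.0) -> int:
    """Synthetic-sample count to reach minority/majority = target_ratio."""
    return max(0, int(np.ceil(target_ratio * n_majority)) - n_minority)


def balance_training_set(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    config: SmoteConfig = SmoteConfig(),
):
    """Oversample the minority vital-status class of a training matrix.

    Returns ``(X_syn, time_syn, event_syn, draws, minority_rows)``; synthetic
    rows carry their base sample's (time, event).  ``draws`` base/neighbor
    indices refer to rows of ``X`` via ``minority_rows``.
    """
    event = np.asarray(event, dtype=int)
    n1 = int(event.sum())
    n0 = len(event) - n1
    minority_label = 1 if n1 < n0 else 0
    minority_rows = np.nonzero(event == minority_label)[0]
    n_new = n_synthetic_needed(len(minority_rows), len(event) - len(minority_rows),
                               config.target_ratio)
    X_syn, draws = smote_oversample(X[minority_rows], n_new, config)
    base_rows = minority_rows[[d.base_index for d in draws]]
    return (
        X_syn,
        np.asarray(time, dtype=float)[base_rows],
        event[base_rows],
        draws,
        minority_rows,
    )
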