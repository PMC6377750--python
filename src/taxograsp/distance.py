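"""Mahalanobis distances between grasps via one-way MANOVA machinery.

Feature windows are grouped by movement; the distance between two grasps
is the Mahalanobis distance between their mean feature vectors under the
pooled within-group covariance

    W = sum_g sum_{i in g} (x_i - m_g)(x_i - m_g)^T / (N - G),

i.e. d(g, h) = sqrt((m_g - m_h)^T W^{-1} (m_g - m_h)).  The measure is
unitless and invariant under invertible affine maps of the feature space,
which is what lets feature families with different units feed one
clustering procedure.

When W is numerically singular (high-dimensional feature sets such as the
TD family on 22 glove sensors can exceed the usable rank), a ridge
W + lambda * tr(W)/p * I is applied and the event is recorded on the
result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .features import FeatureTable
from .io_formats import GraspSet

__all__ = ["GraspDistanceMatrix", "grasp_distances"]

log = logging.getLogger(__name__)


@dataclass
class GraspDistanceMatrix:
    """Symmetric G x G matrix of Mahalanobis distances between grasp means."""

    labels: tuple
    d: np.ndarray
    n_per_group: dict
    metadata: dict = field(default_factory=dict)
    regularized: bool = False

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        G = len(self.labels)
        if self.d.shape != (G, G):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels),
                            columns=list(self.labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def grasp_distances(table: FeatureTable, grasp_set: GraspSet,
                    ridge: float = 1e-6) -> GraspDistanceMatrix:
    """Mahalanobis distance matrix between grasps of one feature table.

    All windows of all repetitions of the subject are pooled per grasp;
    the within-group covariance is shared across grasps (the one-way
    MANOVA pooled estimate).  Every grasp in ``grasp_set`` must contribute
    at least two windows.
    """
    X = table.feature_matrix
    if not np.isfinite(X).all():
        raise ValueError("feature table contains non-finite values")
    gids = table.grasp_ids
    ids = list(grasp_set.grasp_ids)
    if len(ids) < 2:
        raise ValueError("need at least two grasps")
    groups = []
    for gid in ids:
        rows = X[gids == gid]
        if rows.shape[0] < 2:
            raise ValueError(
                f"grasp {grasp_set.name_of(gid)!r} (id {gid}) has "
                f"{rows.shape[0]} window(s); need >= 2"
            )
        groups.append(rows)

    p = X.shape[1]
    N = sum(g.shape[0] for g in groups)
    G = len(groups)
    means = np.stack([g.mean(axis=0) for g in groups])
    scatter = np.zeros((p, p))
    for g, m in zip(groups, means):
        centered = g - m
        scatter += centered.T @ centered
    W = scatter / (N - G)

    regularized = False
    try:
        cho = scipy.linalg.cho_factor(W)
        # explicit conditioning check: Cholesky can succeed on nearly
        # singular matrices and return garbage solves
        if np.linalg.cond(W) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        lam = ridge * (np.trace(W) / p if np.trace(W) > 0 else 1.0)
        W = W + lam * np.eye(p)
        cho = scipy.linalg.cho_factor(W)
        regularized = True
        log.info("pooled covariance singular (p=%d, N=%d, G=%d); "
                 "ridge lambda=%.3g applied", p, N, G, lam)

    d = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            diff = means[i] - means[j]
            q = float(diff @ scipy.linalg.cho_solve(cho, diff))
            d[i, j] = d[j, i] = np.sqrt(max(q, 0.0))

    labels = tuple(grasp_set.name_of(g) for g in ids)
    meta = {}
    if len(table):
        meta = {"subject": table.meta["subject"].iloc[0],
                "modality": table.meta["modality"].iloc[0],
                "family": table.family}
    return GraspDistanceMatrix(
        labels=labels, d=d,
        n_per_group={grasp_set.name_of(g): int(np.sum(gids == g)) for g in ids},
        metadata=meta, regularized=regularized,
    )
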