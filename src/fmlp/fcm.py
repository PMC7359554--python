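"""Fuzzy c-means clustering.

Minimizes the objective J = sum_j sum_i u_ij^m ||x_j - v_i||^2 by
alternating the membership update u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1))
with the centroid update v_i = sum_j u_ij^m x_j / sum_j u_ij^m.  The
fuzzifier m controls cluster softness (m = 2 by default).  Memberships are
the raw ingredient of the network's ambiguity factor, so the implementation
is written from first principles rather than delegated to a library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import DegenerateDataError, ValidationError

__all__ = ["FcmConfig", "MembershipMatrix", "fcm_cluster"]


@dataclass(frozen=True)
class FcmConfig:
    """FCM hyperparameters.

    tol is the convergence threshold on the maximum absolute centroid
    displacement between iterations; an exact "centroids identical" test
    never triggers in floating point.
    """

    c: int = 2
    m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValidationError("cluster count c must be >= 2")
        if self.m <= 1:
            raise ValidationError("fuzzifier m must be > 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValidationError("tol must be > 0 and max_iter >= 1")


@dataclass
class MembershipMatrix:
    """Fuzzy partition: u[j, i] is the membership of object j in cluster i.

    Rows sum to one; centroids holds the cluster centers, objective the
    value of J after each completed iteration (non-increasing).
    """

    u: np.ndarray
    centroids: np.ndarray
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances d2[j, i].

    Where an object coincides with a centroid (d = 0) the formula is
    undefined; such objects get crisp membership in the coincident
    cluster(s), which preserves row-stochasticity.
    """
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    # rows with a zero (or denormal-small) distance overflow; assign them
    # crisply to their nearest cluster(s), splitting exact ties
    bad = (d2 <= 0.0).any(axis=1) | ~np.isfinite(u).all(axis=1)
    if bad.any():
        crisp = (d2[bad] == d2[bad].min(axis=1, keepdims=True)).astype(float)
        u[bad] = crisp / crisp.sum(axis=1, keepdims=True)
    return u


def _centroids(X: np.ndarray, u: np.ndarray, m: float) -> np.ndarray:
    um = u**m
    return (um.T @ X) / um.sum(axis=0)[:, None]


def _objective(X: np.ndarray, u: np.ndarray, v: np.ndarray, m: float) -> float:
    d2 = cdist(X, v, metric="sqeuclidean")
    return float(np.sum(u**m * d2))


def fcm_cluster(X: np.ndarray, cfg: FcmConfig) -> MembershipMatrix:
    """Cluster the rows of X into cfg.c fuzzy clusters.

    Initialization picks c distinct objects as the starting centroids
    (seeded); iterations alternate membership and centroid updates until
    the centroids move less than cfg.tol or max_iter is reached.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < cfg.c:
        raise ValidationError(f"X must be 2-D with at least {cfg.c} rows")
    if not np.isfinite(X).all():
        raise ValidationError("X contains non-finite values")

    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < cfg.c:
        raise DegenerateDataError(
            f"need at least {cfg.c} distinct objects, found {distinct.shape[0]}"
        )
    rng = np.random.default_rng(cfg.seed)
    v = distinct[rng.choice(distinct.shape[0], size=cfg.c, replace=False)].copy()

    u = np.full((X.shape[0], cfg.c), 1.0 / cfg.c)
    objective: list[float] = []
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        d2 = cdist(X, v, metric="sqeuclidean")
        u = _memberships(d2, cfg.m)
        v_new = _centroids(X, u, cfg.m)
        objective.append(_objective(X, u, v_new, cfg.m))
        shift = np.max(np.abs(v_new - v))
        v = v_new
        if shift < cfg.tol:
            break
    return MembershipMatrix(u=u, centroids=v, objective=objective, n_iter=n_iter)
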