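"""Sample pools and Mahalanobis-distance update rules — the online core.

Two fixed-capacity pools hold the labelled training features: S_pre
(preictal, capacity N1) and S_inter (interictal, capacity N2).  The
Mahalanobis distance of a point x to a pool with mean mu and sample
covariance Sigma is sqrt((x-mu)^T Sigma^-1 (x-mu)); the distance of a sample
set to a pool is the mean of its points' distances.  An observed set S is
"abnormal" w.r.t. the pools when M(S, S_pre) <= lambda * M(S, S_inter)
(i.e. it sits at least as close to the preictal pool), and only normal sets
may refresh the interictal pool.  Updates pool the old samples with the new
ones, rank everything by distance to the *opposite* pool and retain the
capacity-many best-ranked samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from spredict.signal_io import ValidationError

COV_EPS_SCALE = 1e-6  # ridge on the covariance: eps = scale * trace / dim


@dataclass
class SamplePool:
    """Fixed-capacity labelled feature pool with insertion ages for ties."""

    features: np.ndarray  # (n, p)
    capacity: int
    role: str  # "pre" or "inter"
    ages: Optional[np.ndarray] = None  # monotone insertion ids, older = smaller
    _next_age: int = 0

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n = self.features.shape[0]
        if not (0 < n <= self.capacity):
            raise ValidationError(
                f"pool size {n} must be in (0, capacity={self.capacity}]"
            )
        if self.role not in ("pre", "inter"):
            raise ValidationError(f"pool role must be 'pre' or 'inter', got {self.role!r}")
        if self.ages is None:
            self.ages = np.arange(n, dtype=np.int64)
            self._next_age = n
        else:
            self.ages = np.asarray(self.ages, dtype=np.int64)
            self._next_age = int(self.ages.max()) + 1 if n else 0

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass
class ObservedSet:
    """Candidate samples for a pool update (the set S / S_obs)."""

    features: np.ndarray
    source: str = "false_alarm_window"  # or "pre_onset_span"

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass
class PoolStats:
    mu: np.ndarray
    sigma: np.ndarray
    sigma_inv: np.ndarray
    eps: float


def pool_stats(pool: SamplePool) -> PoolStats:
    """Mean and (n-1)-denominator covariance with a small trace-scaled ridge.

    A degenerate pool (zero covariance trace, e.g. identical samples) falls
    back to the pseudo-inverse.
    """
    X = pool.features
    if X.shape[0] < 2:
        raise ValidationError("pool statistics need at least 2 samples")
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    p = sigma.shape[0]
    tr = float(np.trace(sigma))
    if tr > 0:
        eps = COV_EPS_SCALE * tr / p
        sigma_inv = np.linalg.inv(sigma + eps * np.eye(p))
    else:
        eps = 0.0
        sigma_inv = np.linalg.pinv(sigma)
    return PoolStats(mu=mu, sigma=sigma, sigma_inv=sigma_inv, eps=eps)


def mahal_point(x: np.ndarray, stats: PoolStats) -> float:
    """sqrt((x - mu)^T Sigma^-1 (x - mu)); clipped at 0 against round-off."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != stats.mu.shape[0]:
        raise ValidationError(
            f"dimension mismatch: point has {x.shape[0]}, pool has {stats.mu.shape[0]}"
        )
    delta = x - stats.mu
    q = float(delta @ stats.sigma_inv @ delta)
    return float(np.sqrt(max(q, 0.0)))


def _point_distances(X: np.ndarray, stats: PoolStats) -> np.ndarray:
    delta = np.atleast_2d(X) - stats.mu
    q = np.einsum("ij,jk,ik->i", delta, stats.sigma_inv, delta)
    return np.sqrt(np.clip(q, 0.0, None))


def mahal_set(S: ObservedSet, stats: PoolStats) -> float:
    """Set-to-pool distance: arithmetic mean of the point distances."""
    if S.n == 0:
        raise ValidationError("observed set is empty")
    return float(_point_distances(S.features, stats).mean())


def is_abnormal(
    S: ObservedSet, pre: SamplePool, inter: SamplePool, lam: float = 1.0
) -> bool:
    """Abnormal iff M(S, S_pre) <= lam * M(S, S_inter) (normal on strict >)."""
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    d_pre = mahal_set(S, pool_stats(pre))
    d_inter = mahal_set(S, pool_stats(inter))
    return not (d_pre > lam * d_inter)


def _update(
    pool: SamplePool, obs: ObservedSet, opposite: SamplePool, order: str
) -> SamplePool:
    if order not in ("asc", "desc"):
        raise ValidationError(f"order must be 'asc' or 'desc', got {order!r}")
    if obs.n == 0:
        return pool
    union = np.vstack([pool.features, obs.features])
    ages = np.concatenate(
        [pool.ages, pool._next_age + np.arange(obs.n, dtype=np.int64)]
    )
    dist = _point_distances(union, pool_stats(opposite))
    key = dist if order == "asc" else -dist
    # stable rank by distance, ties broken by age (older first)
    idx = np.lexsort((ages, key))[: pool.capacity]
    idx = np.sort(idx)  # keep chronological storage order
    return SamplePool(
        features=union[idx], capacity=pool.capacity, role=pool.role, ages=ages[idx]
    )


def update_inter(
    inter: SamplePool, obs: ObservedSet, pre: SamplePool, order: str = "asc"
) -> SamplePool:
    """Refresh S_inter: rank S_inter u S_obs by distance to S_pre, keep N2."""
    return _update(inter, obs, pre, order)


def update_pre(
    pre: SamplePool, obs: ObservedSet, inter: SamplePool, order: str = "asc"
) -> SamplePool:
    """Refresh S_pre: rank S_pre u S_obs by distance to S_inter, keep N1."""
    return _update(pre, obs, inter, order)
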