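"""Extended binomial distributions for bounded test-score data.

The univariate family (Altham) multiplies the binomial pmf by a
dispersion factor ``theta**(y*(m-y))`` and renormalizes: ``theta > 1``
concentrates mass around the centre of the support (under-dispersion
relative to the binomial), ``theta < 1`` spreads it out.  The bivariate
family (Altham–Hankin) takes the product of two such univariate kernels
and multiplies by an association factor ``phi**(y1*y2)``: ``phi > 1``
induces positive correlation between the two counts, ``phi < 1``
negative, and ``phi = 1`` with unit thetas recovers two independent
binomials.

Supports here are small (test scores 0..10), so all quantities are
evaluated by exact enumeration of the ``(m1+1) x (m2+1)`` support, in
log space with log-sum-exp for the normalizers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp


def _log_binom(m: int, y: np.ndarray) -> np.ndarray:
    return gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)


@dataclass(frozen=True)
class ExtBinomParams:
    """Parameters of the univariate extended binomial distribution.

    m : number of trials (score range 0..m)
    p : success probability, 0 < p < 1
    theta : dispersion multiplier, > 0 (1 = standard binomial)
    """

    m: int
    p: float
    theta: float

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 0):
            raise ValueError(f"m must be a non-negative integer, got {self.m!r}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p!r}")
        if not (self.theta > 0.0):
            raise ValueError(f"theta must be positive, got {self.theta!r}")


@dataclass(frozen=True)
class BivBinomParams:
    """Parameters of the bivariate (Altham–Hankin) extended binomial.

    m1, m2 : per-response trial counts
    p1, p2 : per-response success probabilities, in (0, 1)
    theta1, theta2 : per-response dispersion multipliers, > 0
    phi : association multiplier, > 0 (1 = no cross-association)
    """

    m1: int
    m2: int
    p1: float
    p2: float
    theta1: float
    theta2: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("m1", "m2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        for name in ("theta1", "theta2", "phi"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ValueError(f"{name} must be positive, got {v!r}")

    def margin(self, j: int) -> ExtBinomParams:
        """Univariate kernel parameters of response j (1 or 2); note this is
        the *kernel*, not the marginal distribution, unless phi == 1."""
        if j == 1:
            return ExtBinomParams(self.m1, self.p1, self.theta1)
        if j == 2:
            return ExtBinomParams(self.m2, self.p2, self.theta2)
        raise ValueError("j must be 1 or 2")


def uni_log_weights(m: int, p: float, theta: float) -> np.ndarray:
    """Unnormalized log kernel over y = 0..m."""
    y = np.arange(m + 1, dtype=float)
    return (
        _log_binom(m, y)
        + y * math.log(p)
        + (m - y) * math.log1p(-p)
        + y * (m - y) * math.log(theta)
    )


@lru_cache(maxsize=4096)
def _uni_log_norm(m: int, p: float, theta: float) -> float:
    return float(logsumexp(uni_log_weights(m, p, theta)))


def uni_normalizer(params: ExtBinomParams) -> float:
    """Normalizing constant of the univariate family (sum of the kernel)."""
    return math.exp(_uni_log_norm(params.m, params.p, params.theta))


def uni_log_pmf(params: ExtBinomParams, y: int) -> float:
    """Log probability of score y under the univariate family."""
    if not (0 <= y <= params.m):
        raise ValueError(f"y={y} outside support 0..{params.m}")
    w = uni_log_weights(params.m, params.p, params.theta)
    return float(w[y] - _uni_log_norm(params.m, params.p, params.theta))


def uni_pmf(params: ExtBinomParams) -> np.ndarray:
    w = uni_log_weights(params.m, params.p, params.theta)
    return np.exp(w - logsumexp(w))


def _biv_log_weights(params: BivBinomParams) -> np.ndarray:
    w1 = uni_log_weights(params.m1, params.p1, params.theta1)
    w2 = uni_log_weights(params.m2, params.p2, params.theta2)
    y1 = np.arange(params.m1 + 1, dtype=float)[:, None]
    y2 = np.arange(params.m2 + 1, dtype=float)[None, :]
    return w1[:, None] + w2[None, :] + y1 * y2 * math.log(params.phi)


@lru_cache(maxsize=4096)
def _biv_log_norm_cached(key: tuple) -> float:
    m1, m2, p1, p2, t1, t2, phi = key
    return float(
        logsumexp(_biv_log_weights(BivBinomParams(m1, m2, p1, p2, t1, t2, phi)))
    )


def _biv_log_norm(params: BivBinomParams) -> float:
    key = (
        int(params.m1),
        int(params.m2),
        float(params.p1),
        float(params.p2),
        float(params.theta1),
        float(params.theta2),
        float(params.phi),
    )
    return _biv_log_norm_cached(key)


def biv_normalizer(params: BivBinomParams) -> float:
    """Normalizing constant C of the bivariate family."""
    return math.exp(_biv_log_norm(params))


def biv_log_pmf(params: BivBinomParams, y1: int, y2: int) -> float:
    """Log probability of the score pair (y1, y2)."""
    if not (0 <= y1 <= params.m1):
        raise ValueError(f"y1={y1} outside support 0..{params.m1}")
    if not (0 <= y2 <= params.m2):
        raise ValueError(f"y2={y2} outside support 0..{params.m2}")
    w = _biv_log_weights(params)
    return float(w[y1, y2] - _biv_log_norm(params))


def biv_pmf_table(params: BivBinomParams) -> np.ndarray:
    """Full probability table, shape (m1+1, m2+1), summing to 1."""
    w = _biv_log_weights(params)
    return np.exp(w - logsumexp(w))


def biv_moments(params: BivBinomParams) -> tuple[float, float, float, float, float]:
    """(mean1, mean2, var1, var2, correlation), exact from the full table."""
    tab = biv_pmf_table(params)
    y1 = np.arange(params.m1 + 1, dtype=float)
    y2 = np.arange(params.m2 + 1, dtype=float)
    p1 = tab.sum(axis=1)
    p2 = tab.sum(axis=0)
    m1 = float(p1 @ y1)
    m2 = float(p2 @ y2)
    v1 = float(p1 @ (y1 - m1) ** 2)
    v2 = float(p2 @ (y2 - m2) ** 2)
    cov = float((y1 - m1) @ tab @ (y2 - m2))
    if v1 <= 0.0 or v2 <= 0.0:
        corr = 0.0
    else:
        corr = cov / math.sqrt(v1 * v2)
    return m1, m2, v1, v2, corr


def biv_sample(
    params: BivBinomParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n i.i.d. pairs by exact inverse-CDF over the enumerated support.

    Returns an (n, 2) integer array. The support is at most a few hundred
    cells for score data, so full enumeration is both exact and fast.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    tab = biv_pmf_table(params)
    flat = tab.ravel()
    cdf = np.cumsum(flat)
    cdf[-1] = 1.0
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="right")
    y1, y2 = np.unravel_index(idx, tab.shape)
    return np.column_stack([y1, y2]).astype(np.int64)


def _mh_sample(
    params: BivBinomParams,
    n: int,
    rng: np.random.Generator,
    burn: int = 500,
    thin: int = 5,
) -> np.ndarray:
    """Metropolis–Hastings sampler over the support (cross-check only).

    Random-walk proposal on each coordinate; kept as an independent route
    for validating the exact inverse-CDF sampler, not for production use.
    """
    w = _biv_log_weights(params)
    state = np.array([params.m1 // 2, params.m2 // 2])
    out = np.empty((n, 2), dtype=np.int64)
    steps = burn + n * thin
    props = rng.integers(-2, 3, size=(steps, 2))
    logu = np.log(rng.random(steps))
    k = 0
    for i in range(steps):
        cand = state + props[i]
        if 0 <= cand[0] <= params.m1 and 0 <= cand[1] <= params.m2:
            if logu[i] < w[cand[0], cand[1]] - w[state[0], state[1]]:
                state = cand
        if i >= burn and (i - burn) % thin == 0:
            out[k] = state
            k += 1
    return out[:k]
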