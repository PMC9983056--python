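"""Logistic success-probability submodels and the visit-level log-likelihood.

Each bounded count Y_j at visit time t is modelled as extended-binomial
with success probability

    p_j(t) = logistic((eta0_j + b_j0) + (eta1_j + b_j1) * t + gammaL_j' x)

where (b_j0, b_j1) are subject-level random intercept/slope deviations
and x holds time-constant covariates. Restricted random-effect
structures tie or zero components of (b10, b11, b20, b21) so that at
most two free effects remain, keeping the marginal likelihood a
two-dimensional integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .extended_binomial import BivBinomParams, biv_log_pmf

# beyond this the logistic saturates to within 1e-15 of 0/1 and the
# bivariate pmf leaves its parameter domain
_LINPRED_CLIP = 35.0


class REStructure(Enum):
    """Restricted random-effect structures (at most 2 free effects)."""

    SHARED = "shared"              # b10=b20, b11=b21: common intercept+slope
    INTERCEPTS_ONLY = "intercepts"  # b11=b21=0: one intercept per response
    SLOPES_ONLY = "slopes"          # b10=b20=0: one slope per response
    Y2_FULL = "y2_full"             # Y1 fixed-effects only; Y2 intercept+slope


def expand_random_effects(
    structure: REStructure, b_raw: np.ndarray
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Map the 2-vector of free effects to ((b10, b11), (b20, b21))."""
    b_raw = np.asarray(b_raw, dtype=float)
    if b_raw.shape != (2,):
        raise ValueError(
            f"b_raw must have exactly 2 free components, got shape {b_raw.shape}"
        )
    a, b = float(b_raw[0]), float(b_raw[1])
    if structure is REStructure.SHARED:
        return (a, b), (a, b)
    if structure is REStructure.INTERCEPTS_ONLY:
        return (a, 0.0), (b, 0.0)
    if structure is REStructure.SLOPES_ONLY:
        return (0.0, a), (0.0, b)
    if structure is REStructure.Y2_FULL:
        return (0.0, 0.0), (a, b)
    raise ValueError(f"unknown structure {structure!r}")


def expand_random_effects_matrix(
    structure: REStructure, b_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized expansion: b_raw (K, 2) -> (b10, b11, b20, b21), each (K,)."""
    b_raw = np.atleast_2d(np.asarray(b_raw, dtype=float))
    a, b = b_raw[:, 0], b_raw[:, 1]
    z = np.zeros_like(a)
    if structure is REStructure.SHARED:
        return a, b, a, b
    if structure is REStructure.INTERCEPTS_ONLY:
        return a, z, b, z
    if structure is REStructure.SLOPES_ONLY:
        return z, a, z, b
    if structure is REStructure.Y2_FULL:
        return z, z, a, b
    raise ValueError(f"unknown structure {structure!r}")


@dataclass(frozen=True)
class LongitudinalSpec:
    """Fixed effects, dispersion/association and random-effect structure.

    eta0, eta1 : per-response intercepts and slopes (length-2)
    gammaL : optional per-response covariate coefficient vectors,
        ``(gamma_1, gamma_2)`` with one coefficient per covariate
    theta : per-response dispersion multipliers (length-2, positive)
    phi : association multiplier (positive)
    structure : which random effects are free (REStructure)
    """

    eta0: tuple[float, float]
    eta1: tuple[float, float]
    theta: tuple[float, float]
    phi: float
    structure: REStructure
    gammaL: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.theta):
            raise ValueError("theta components must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


@dataclass
class Subject:
    """One individual's longitudinal and survival record (rescaled time).

    t : ordered visit times; y1, y2 : matching score sequences
    t1 : truncation (baseline/entry) time; t_last : last recorded time
    delta : 1 if death at t_last, 0 if censored
    x : time-constant covariate values (e.g. sex), possibly empty
    """

    id: str
    t: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    t1: float
    t_last: float
    delta: int
    x: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y1 = np.asarray(self.y1, dtype=np.int64)
        self.y2 = np.asarray(self.y2, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        if not (len(self.t) == len(self.y1) == len(self.y2)):
            raise ValueError(f"subject {self.id}: visit sequences misaligned")
        if len(self.t) and np.any(np.diff(self.t) < 0):
            raise ValueError(f"subject {self.id}: visit times must be nondecreasing")
        if len(self.t) and not math.isclose(self.t1, float(self.t[0])):
            raise ValueError(f"subject {self.id}: t1 must equal the first visit time")
        if self.t_last < self.t1:
            raise ValueError(f"subject {self.id}: t_last earlier than entry t1")
        if self.delta not in (0, 1):
            raise ValueError(f"subject {self.id}: delta must be 0 or 1")

    @property
    def n_visits(self) -> int:
        return len(self.t)


def success_prob(
    eta0_j: float,
    eta1_j: float,
    gammaL_j: np.ndarray | None,
    b_j0: float,
    b_j1: float,
    t: float,
    x: np.ndarray | None = None,
) -> float:
    """Logistic success probability at time t for one response."""
    lp = (eta0_j + b_j0) + (eta1_j + b_j1) * t
    if gammaL_j is not None and x is not None and len(np.atleast_1d(gammaL_j)):
        lp += float(np.dot(np.atleast_1d(gammaL_j), np.atleast_1d(x)))
    if not np.isfinite(lp):
        raise FloatingPointError(f"non-finite linear predictor: {lp!r}")
    lp = min(max(lp, -_LINPRED_CLIP), _LINPRED_CLIP)
    return 1.0 / (1.0 + math.exp(-lp))


def visit_probs(
    spec: LongitudinalSpec, b_raw: np.ndarray, t: float, x: np.ndarray | None
) -> tuple[float, float]:
    """Success probabilities (p1, p2) at one visit given free effects."""
    (b10, b11), (b20, b21) = expand_random_effects(spec.structure, b_raw)
    g1 = spec.gammaL[0] if spec.gammaL is not None else None
    g2 = spec.gammaL[1] if spec.gammaL is not None else None
    p1 = success_prob(spec.eta0[0], spec.eta1[0], g1, b10, b11, t, x)
    p2 = success_prob(spec.eta0[1], spec.eta1[1], g2, b20, b21, t, x)
    return p1, p2


def longitudinal_loglik(
    subject: Subject,
    spec: LongitudinalSpec,
    m1: int,
    m2: int,
    b_raw: np.ndarray,
) -> float:
    """Sum of bivariate log-pmfs over a subject's visits, given effects.

    Visits are conditionally independent given the random effects, so
    the contribution is a plain sum; an empty visit sequence gives 0.
    """
    total = 0.0
    for v in range(subject.n_visits):
        y1, y2 = int(subject.y1[v]), int(subject.y2[v])
        if not (0 <= y1 <= m1 and 0 <= y2 <= m2):
            raise ValueError(
                f"subject {subject.id} visit {v}: scores ({y1},{y2}) outside "
                f"supports (0..{m1}, 0..{m2})"
            )
        p1, p2 = visit_probs(spec, b_raw, float(subject.t[v]), subject.x)
        params = BivBinomParams(
            m1, m2, p1, p2, spec.theta[0], spec.theta[1], spec.phi
        )
        total += biv_log_pmf(params, y1, y2)
    return total
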