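"""Marginal log-likelihood under left truncation via Gauss–Hermite quadrature.

Each subject contributes

    log L_i = log ∫ p(y_i | t_i, b) p(t_last,i | b, delta_i) p(b) db
            - log ∫ p(T >= t1_i | b) p(b) db

where b is the 2-vector of free random effects with N(0, Sigma) prior.
Both integrals are evaluated on the same product Gauss–Hermite grid
mapped through the Cholesky factor of Sigma (algebraically equivalent
to integrating the conditional-normal factorization dimension by
dimension), so the delayed-entry correction cancels exactly when
t1 = 0. All mixtures over nodes use log-sum-exp.

Two evaluation routes are provided: a per-subject scalar route
(`subject_loglik`) that composes the submodules literally, and a
vectorized route (`LikelihoodEvaluator`) used by the optimizer, which
evaluates all subjects, visits and nodes in stacked arrays. The two
agree to floating-point round-off and are cross-checked in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln, logsumexp

from .hazards import (
    HazardFamily,
    HazardSpec,
    LinkSpec,
    check_compatibility,
    delta_parts,
    log_survivor,
    surv_log_density,
)
from .longitudinal import (
    LongitudinalSpec,
    Subject,
    expand_random_effects_matrix,
    longitudinal_loglik,
    _LINPRED_CLIP,
)


@dataclass(frozen=True)
class RandomEffectsDist:
    """Bivariate normal random-effect distribution N(0, Sigma)."""

    sigma1: float
    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie strictly inside (-1, 1)")

    def cov(self) -> np.ndarray:
        off = self.rho * self.sigma1 * self.sigma2
        return np.array(
            [[self.sigma1**2, off], [off, self.sigma2**2]]
        )

    def chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.cov())

    def logpdf(self, b: np.ndarray) -> np.ndarray:
        b = np.atleast_2d(b)
        L = self.chol()
        z = np.linalg.solve(L, b.T).T
        logdet = 2.0 * np.log(np.diag(L)).sum()
        q = (z**2).sum(axis=1)
        out = -0.5 * (q + logdet + 2.0 * math.log(2.0 * math.pi))
        return out if out.shape[0] > 1 else float(out[0])


@dataclass(frozen=True)
class GHGrid:
    """2-D quadrature rule adapted to the random-effect covariance.

    nodes : (K, 2) points in raw random-effect space
    weights : (K,) positive weights summing to 1
    """

    nodes: np.ndarray
    weights: np.ndarray
    n_nodes_per_dim: int

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(self.weights)


def build_grid(re_dist: RandomEffectsDist, n: int = 7) -> GHGrid:
    """Product Gauss–Hermite rule mapped through the Cholesky factor.

    Exact for polynomials of total degree <= 2n-1 against the N(0, Sigma)
    density.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x, w = np.polynomial.hermite.hermgauss(n)
    z = math.sqrt(2.0) * x          # standard-normal abscissae
    wn = w / math.sqrt(math.pi)     # standard-normal weights
    Z1, Z2 = np.meshgrid(z, z, indexing="ij")
    W = np.outer(wn, wn).ravel()
    Zs = np.column_stack([Z1.ravel(), Z2.ravel()])
    try:
        L = re_dist.chol()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by ctor
        raise ValueError("random-effect covariance is not positive definite") from exc
    nodes = Zs @ L.T
    W = W / W.sum()
    return GHGrid(nodes=nodes, weights=W, n_nodes_per_dim=n)


@dataclass(frozen=True)
class ModelSpec:
    """Complete joint-model parameterization."""

    longitudinal: LongitudinalSpec
    hazard: HazardSpec
    link: LinkSpec
    re_dist: RandomEffectsDist
    m1: int
    m2: int

    def __post_init__(self) -> None:
        check_compatibility(self.link, self.longitudinal.structure, self.hazard.family)

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


def subject_loglik(subject: Subject, spec: ModelSpec, grid: GHGrid) -> float:
    """Marginal log-likelihood contribution of one subject (scalar route)."""
    if grid.nodes.shape[0] == 0:
        raise ValueError("empty quadrature grid")
    lw = grid.log_weights
    K = grid.nodes.shape[0]
    num = np.empty(K)
    den = np.empty(K)
    for k in range(K):
        b = grid.nodes[k]
        ll_long = longitudinal_loglik(
            subject, spec.longitudinal, spec.m1, spec.m2, b
        )
        d0, d1 = delta_parts(spec.link, spec.longitudinal, b, subject.x)
        ll_surv = surv_log_density(
            subject.t_last, subject.delta, spec.hazard, d0, d1
        )
        num[k] = ll_long + ll_surv
        den[k] = log_survivor(subject.t1, spec.hazard, d0, d1)
        if not np.isfinite(num[k]):
            raise FloatingPointError(
                f"non-finite likelihood contribution at node {k} "
                f"(subject {subject.id})"
            )
    return float(logsumexp(lw + num) - logsumexp(lw + den))


def total_loglik(
    dataset: list[Subject], spec: ModelSpec, grid: GHGrid
) -> float:
    """Sum of per-subject marginal log-likelihood contributions."""
    if not dataset:
        raise ValueError("dataset must be nonempty")
    total = 0.0
    for s in dataset:
        try:
            total += subject_loglik(s, spec, grid)
        except Exception as exc:
            raise type(exc)(f"subject {s.id}: {exc}") from exc
    return total


class LikelihoodEvaluator:
    """Vectorized marginal log-likelihood over a fixed dataset.

    Stacks all visits into flat arrays once, then evaluates the full
    (observation x node) likelihood table with dense numpy operations.
    Numerically identical to the scalar route up to summation order.
    """

    def __init__(self, dataset: list[Subject], m1: int, m2: int):
        if not dataset:
            raise ValueError("dataset must be nonempty")
        self.m1, self.m2 = m1, m2
        self.n_subjects = len(dataset)
        self.ids = [s.id for s in dataset]
        counts = np.array([s.n_visits for s in dataset])
        self.visit_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.has_visits = counts > 0
        self.t_obs = np.concatenate([s.t for s in dataset]) if counts.sum() else np.zeros(0)
        self.y1 = np.concatenate([s.y1 for s in dataset]).astype(int) if counts.sum() else np.zeros(0, int)
        self.y2 = np.concatenate([s.y2 for s in dataset]).astype(int) if counts.sum() else np.zeros(0, int)
        self.subj_of_obs = np.repeat(np.arange(self.n_subjects), counts)
        if np.any(self.y1 < 0) or np.any(self.y1 > m1) or np.any(self.y2 < 0) or np.any(self.y2 > m2):
            bad = np.where((self.y1 < 0) | (self.y1 > m1) | (self.y2 < 0) | (self.y2 > m2))[0][0]
            raise ValueError(
                f"subject {dataset[self.subj_of_obs[bad]].id}: score outside support"
            )
        self.t1 = np.array([s.t1 for s in dataset])
        self.t_last = np.array([s.t_last for s in dataset])
        self.delta = np.array([s.delta for s in dataset], dtype=float)
        ncov = len(dataset[0].x)
        self.x = np.vstack([s.x for s in dataset]) if ncov else np.zeros((self.n_subjects, 0))
        self.x_obs = self.x[self.subj_of_obs]
        self.sup1 = np.arange(m1 + 1, dtype=float)
        self.sup2 = np.arange(m2 + 1, dtype=float)
        self.lb1 = gammaln(m1 + 1) - gammaln(self.sup1 + 1) - gammaln(m1 - self.sup1 + 1)
        self.lb2 = gammaln(m2 + 1) - gammaln(self.sup2 + 1) - gammaln(m2 - self.sup2 + 1)
        self.cross = np.outer(self.sup1, self.sup2)  # y1*y2 exponent of phi

    def _log_kernel(self, lp, lb, sup, m, log_theta):
        """Log kernel table over the support: (n_obs, K, m+1)."""
        lp = np.clip(lp, -_LINPRED_CLIP, _LINPRED_CLIP)
        log_p = -np.log1p(np.exp(-lp))
        log_q = -np.log1p(np.exp(lp))
        return (
            lb[None, None, :]
            + sup[None, None, :] * log_p[:, :, None]
            + (m - sup)[None, None, :] * log_q[:, :, None]
            + (sup * (m - sup))[None, None, :] * log_theta
        )

    def loglik(self, spec: ModelSpec, grid: GHGrid) -> float:
        # extreme trial points during optimization can overflow exp();
        # the resulting non-finite contributions raise below instead
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._loglik(spec, grid)

    def _loglik(self, spec: ModelSpec, grid: GHGrid) -> float:
        ls = spec.longitudinal
        b10, b11, b20, b21 = expand_random_effects_matrix(ls.structure, grid.nodes)
        K = grid.nodes.shape[0]
        acc = np.zeros((self.n_subjects, K))
        if len(self.t_obs):
            lp1 = (ls.eta0[0] + b10)[None, :] + (ls.eta1[0] + b11)[None, :] * self.t_obs[:, None]
            lp2 = (ls.eta0[1] + b20)[None, :] + (ls.eta1[1] + b21)[None, :] * self.t_obs[:, None]
            if ls.gammaL is not None and self.x.shape[1]:
                lp1 = lp1 + (self.x_obs @ np.atleast_1d(ls.gammaL[0]))[:, None]
                lp2 = lp2 + (self.x_obs @ np.atleast_1d(ls.gammaL[1]))[:, None]
            lg1 = self._log_kernel(lp1, self.lb1, self.sup1, self.m1, math.log(ls.theta[0]))
            lg2 = self._log_kernel(lp2, self.lb2, self.sup2, self.m2, math.log(ls.theta[1]))
            # normalizer by shifted exponentials: log C = m1+m2 shifts + log einsum
            s1 = lg1.max(axis=2)
            s2 = lg2.max(axis=2)
            A = np.exp(lg1 - s1[:, :, None])
            B = np.exp(lg2 - s2[:, :, None])
            Phi = spec.longitudinal.phi ** self.cross
            C = np.einsum("oki,ij,okj->ok", A, Phi, B, optimize=True)
            logC = s1 + s2 + np.log(C)
            obs_idx = np.arange(len(self.t_obs))
            ll_obs = (
                lg1[obs_idx, :, self.y1]
                + lg2[obs_idx, :, self.y2]
                + (self.y1 * self.y2)[:, None] * math.log(ls.phi)
                - logC
            )
            acc_obs = np.add.reduceat(ll_obs, self.visit_starts, axis=0)
            # reduceat repeats the previous segment for zero-length segments
            acc_obs[~self.has_visits] = 0.0
            acc = acc_obs
        d0, d1 = delta_parts(spec.link, ls, grid.nodes)          # (K,)
        if spec.link.gammaS is not None and self.x.shape[1]:
            d0 = d0[None, :] + (self.x @ np.atleast_1d(spec.link.gammaS))[:, None]
        else:
            d0 = np.broadcast_to(d0[None, :], (self.n_subjects, K))
        hz = spec.hazard
        lam_log = hz.beta + d0                                   # (N, K)
        if hz.family is HazardFamily.WEIBULL:
            log_h = lam_log + math.log(hz.shape) + (hz.shape - 1.0) * np.log(
                np.maximum(self.t_last, 1e-300)
            )[:, None]
            log_S_last = -np.exp(lam_log) * (self.t_last**hz.shape)[:, None]
            log_S_entry = -np.exp(lam_log) * (self.t1**hz.shape)[:, None]
        else:
            xi_star = hz.shape + np.asarray(d1)                  # (K,)
            tiny = np.abs(xi_star) < 1e-8
            xi_safe = np.where(tiny, 1.0, xi_star)
            log_h = lam_log + xi_star[None, :] * self.t_last[:, None]
            lam = np.exp(lam_log)

            def _logS(t):
                ramp = np.where(
                    tiny[None, :],
                    t[:, None],
                    np.expm1(xi_safe[None, :] * t[:, None]) / xi_safe[None, :],
                )
                return -lam * ramp

            log_S_last = _logS(self.t_last)
            log_S_entry = _logS(self.t1)
        num = acc + self.delta[:, None] * log_h + log_S_last
        if not np.all(np.isfinite(num)):
            i, k = np.argwhere(~np.isfinite(num))[0]
            raise FloatingPointError(
                f"non-finite likelihood contribution (subject {self.ids[i]}, node {k})"
            )
        lw = grid.log_weights[None, :]
        per_subject = logsumexp(lw + num, axis=1) - logsumexp(lw + log_S_entry, axis=1)
        return float(per_subject.sum())
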