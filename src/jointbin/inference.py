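"""Maximum-likelihood fitting of the joint model in transform space.

Positivity-constrained parameters (theta, phi, tau/xi, sigma) are
optimized on the log scale, the random-effect correlation rho on the
inverse-hyperbolic-tangent scale, everything else (eta, beta, alpha,
gamma) on the identity scale. Standard errors come from the inverse
numerical Hessian of the negative log-likelihood in free space, mapped
to the natural scale by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .hazards import HazardFamily
from .likelihood import (
    LikelihoodEvaluator,
    ModelSpec,
    RandomEffectsDist,
    build_grid,
)

# inverse maps are clamped so extreme free values stay strictly inside
# the natural domain instead of overflowing or saturating to a boundary
_RHO_EPS = 1e-12


def _safe_exp(z: float) -> float:
    return math.exp(min(max(z, -500.0), 500.0))


def _safe_tanh(z: float) -> float:
    return min(max(math.tanh(z), -1.0 + _RHO_EPS), 1.0 - _RHO_EPS)


_TRANSFORMS = {
    "id": (lambda x: x, lambda z: z, lambda nat: 1.0),
    "log": (math.log, _safe_exp, lambda nat: nat),
    "atanh": (math.atanh, _safe_tanh, lambda nat: 1.0 - nat * nat),
}


@dataclass(frozen=True)
class _Param:
    name: str
    transform: str  # key into _TRANSFORMS


class ParameterMap:
    """Named, invertible mapping between a ModelSpec and a free vector."""

    def __init__(self, template: ModelSpec):
        self.template = template
        ls = template.longitudinal
        params: list[_Param] = [
            _Param("eta0_1", "id"),
            _Param("eta1_1", "id"),
            _Param("eta0_2", "id"),
            _Param("eta1_2", "id"),
        ]
        self._ncov = 0 if ls.gammaL is None else len(np.atleast_1d(ls.gammaL[0]))
        for j in (1, 2):
            for c in range(self._ncov):
                params.append(_Param(f"gammaL_{j}_{c}", "id"))
        params += [
            _Param("theta1", "log"),
            _Param("theta2", "log"),
            _Param("phi", "log"),
            _Param("beta", "id"),
            _Param(
                "tau" if template.hazard.family is HazardFamily.WEIBULL else "xi",
                "log",
            ),
        ]
        self._nalpha = len(template.link.alpha)
        if self._nalpha == 1:
            params.append(_Param("alpha", "id"))
        else:
            for a in range(self._nalpha):
                params.append(_Param(f"alpha_{a + 1}", "id"))
        self._ngs = 0 if template.link.gammaS is None else len(template.link.gammaS)
        for c in range(self._ngs):
            params.append(_Param(f"gammaS_{c}", "id"))
        params += [
            _Param("sigma1", "log"),
            _Param("sigma2", "log"),
            _Param("rho", "atanh"),
        ]
        self.params = params
        self.names = [p.name for p in params]

    @property
    def k(self) -> int:
        return len(self.params)

    def natural_values(self, spec: ModelSpec) -> np.ndarray:
        ls, hz, lk, re = spec.longitudinal, spec.hazard, spec.link, spec.re_dist
        vals = [ls.eta0[0], ls.eta1[0], ls.eta0[1], ls.eta1[1]]
        for j in range(2):
            if self._ncov:
                vals.extend(np.atleast_1d(ls.gammaL[j]).tolist())
        vals += [ls.theta[0], ls.theta[1], ls.phi, hz.beta, hz.shape]
        vals += list(lk.alpha)
        if self._ngs:
            vals += list(lk.gammaS)
        vals += [re.sigma1, re.sigma2, re.rho]
        return np.asarray(vals, dtype=float)

    def spec_from_natural(self, vals: np.ndarray) -> ModelSpec:
        vals = np.asarray(vals, dtype=float)
        i = 0
        eta0 = (vals[0], vals[2])
        eta1 = (vals[1], vals[3])
        i = 4
        gammaL = None
        if self._ncov:
            g1 = vals[i : i + self._ncov]
            g2 = vals[i + self._ncov : i + 2 * self._ncov]
            gammaL = (g1, g2)
            i += 2 * self._ncov
        theta = (vals[i], vals[i + 1])
        phi = vals[i + 2]
        beta = vals[i + 3]
        shape = vals[i + 4]
        i += 5
        alpha = tuple(vals[i : i + self._nalpha])
        i += self._nalpha
        gammaS = tuple(vals[i : i + self._ngs]) if self._ngs else None
        i += self._ngs
        sigma1, sigma2, rho = vals[i], vals[i + 1], vals[i + 2]
        ls = replace(
            self.template.longitudinal,
            eta0=eta0,
            eta1=eta1,
            theta=theta,
            phi=phi,
            gammaL=gammaL,
        )
        hz = replace(self.template.hazard, beta=beta, shape=shape)
        lk = replace(self.template.link, alpha=alpha, gammaS=gammaS)
        re = RandomEffectsDist(sigma1, sigma2, rho)
        return self.template.replace(
            longitudinal=ls, hazard=hz, link=lk, re_dist=re
        )

    def pack(self, spec: ModelSpec) -> np.ndarray:
        nat = self.natural_values(spec)
        return np.array(
            [_TRANSFORMS[p.transform][0](v) for p, v in zip(self.params, nat)]
        )

    def unpack(self, free: np.ndarray) -> ModelSpec:
        nat = np.array(
            [_TRANSFORMS[p.transform][1](v) for p, v in zip(self.params, free)]
        )
        return self.spec_from_natural(nat)

    def natural_from_free(self, free: np.ndarray) -> np.ndarray:
        return np.array(
            [_TRANSFORMS[p.transform][1](v) for p, v in zip(self.params, free)]
        )

    def jacobian_diag(self, free: np.ndarray) -> np.ndarray:
        """d(natural)/d(free), evaluated coordinate-wise."""
        nat = self.natural_from_free(free)
        return np.array(
            [_TRANSFORMS[p.transform][2](v) for p, v in zip(self.params, nat)]
        )


@dataclass
class FitResult:
    """Fitted joint model: natural-scale estimates, SEs and fit statistics."""

    estimates: dict[str, float]
    ses: dict[str, float | None]
    loglik: float
    minus2LL: float
    aic: float
    k: int
    converged: bool
    n_evals: int
    spec: ModelSpec
    free: np.ndarray
    names: list[str]
    dataset_signature: tuple = ()
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.estimates[n] for n in self.names],
                "se": [self.ses.get(n) for n in self.names],
            },
            index=self.names,
        )


def _marginal_logistic_start(t: np.ndarray, y: np.ndarray, m: int) -> tuple[float, float]:
    """Intercept/slope start values from a binomial logistic fit with no
    random effects (each count treated as m independent trials)."""
    if len(t) == 0:
        return 0.0, 0.0

    def nll(par):
        lp = np.clip(par[0] + par[1] * t, -30, 30)
        return -np.sum(y * lp - m * np.log1p(np.exp(lp)))

    res = minimize(nll, np.array([0.0, 0.0]), method="BFGS")
    return float(res.x[0]), float(res.x[1])


def default_start(dataset, template: ModelSpec) -> ModelSpec:
    """Cheap in-domain starting values.

    eta from per-response marginal logistic fits ignoring random effects;
    theta = phi = 1; sigma = 0.5; rho = 0; beta from the crude exponential
    rate log(deaths / total follow-up); shape 1 (Weibull) or 0.1 (Gompertz);
    alpha and covariate coefficients 0.
    """
    t = np.concatenate([s.t for s in dataset]) if dataset else np.zeros(0)
    y1 = np.concatenate([s.y1 for s in dataset]) if dataset else np.zeros(0)
    y2 = np.concatenate([s.y2 for s in dataset]) if dataset else np.zeros(0)
    e01, e11 = _marginal_logistic_start(t, y1, template.m1)
    e02, e12 = _marginal_logistic_start(t, y2, template.m2)
    deaths = sum(s.delta for s in dataset)
    exposure = sum(max(s.t_last - s.t1, 1e-8) for s in dataset)
    beta0 = math.log(max(deaths, 0.5) / exposure)
    shape0 = 1.0 if template.hazard.family is HazardFamily.WEIBULL else 0.1
    ncov = (
        0
        if template.longitudinal.gammaL is None
        else len(np.atleast_1d(template.longitudinal.gammaL[0]))
    )
    gammaL = (np.zeros(ncov), np.zeros(ncov)) if ncov else None
    ls = replace(
        template.longitudinal,
        eta0=(e01, e02),
        eta1=(e11, e12),
        theta=(1.0, 1.0),
        phi=1.0,
        gammaL=gammaL,
    )
    hz = replace(template.hazard, beta=beta0, shape=shape0)
    lk = replace(
        template.link,
        alpha=tuple(0.0 for _ in template.link.alpha),
        gammaS=None
        if template.link.gammaS is None
        else tuple(0.0 for _ in template.link.gammaS),
    )
    return template.replace(
        longitudinal=ls, hazard=hz, link=lk, re_dist=RandomEffectsDist(0.5, 0.5, 0.0)
    )


def _dataset_signature(dataset) -> tuple:
    return (
        len(dataset),
        float(sum(s.t_last for s in dataset)),
        int(sum(s.delta for s in dataset)),
        int(sum(s.n_visits for s in dataset)),
        float(sum(float(s.y1.sum() + s.y2.sum()) for s in dataset)),
    )


def fit(
    dataset,
    template: ModelSpec,
    start: ModelSpec | None = None,
    *,
    nodes: int = 7,
    compute_se: bool = True,
    gtol: float = 1e-6,
    ftol: float = 1e-7,
    maxiter: int = 500,
    multistart: int = 0,
    seed: int = 0,
) -> FitResult:
    """Maximize the left-truncation-corrected marginal likelihood.

    Quasi-Newton (BFGS) in free space with finite-difference gradients.
    `multistart` > 0 adds that many jittered restarts (fixed seed) and
    keeps the best local optimum; off by default.
    """
    pm = ParameterMap(template)
    ev = LikelihoodEvaluator(dataset, template.m1, template.m2)
    n_evals = 0

    def nll(free):
        nonlocal n_evals
        n_evals += 1
        try:
            spec = pm.unpack(free)
            grid = build_grid(spec.re_dist, nodes)
            val = -ev.loglik(spec, grid)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val

    x0 = pm.pack(start if start is not None else default_start(dataset, template))
    f0 = nll(x0)
    if not np.isfinite(f0) or f0 >= 1e12:
        raise ValueError("objective is non-finite at the starting values")
    # wide free-space box: roomy for any plausible fit, but keeps the
    # quasi-Newton search off the degenerate ridges (sigma -> 0 with
    # |alpha| -> inf) where the likelihood flattens out
    bounds = []
    for p in pm.params:
        if p.transform == "log":
            bounds.append((-7.0, 4.0))
        elif p.transform == "atanh":
            bounds.append((-6.0, 6.0))
        else:
            bounds.append((-30.0, 30.0))
    starts = [x0]
    if multistart:
        rng = np.random.default_rng(seed)
        starts += [x0 + rng.normal(0, 0.1, size=x0.shape) for _ in range(multistart)]
    best = None
    for s0 in starts:
        res = minimize(
            nll,
            np.clip(s0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"gtol": gtol, "ftol": ftol, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best
    gnorm = float(np.max(np.abs(res.jac)))
    at_bound = any(
        min(x - lo, hi - x) < 1e-6 for x, (lo, hi) in zip(res.x, bounds)
    )
    converged = bool(res.success) and not at_bound
    free_hat = np.asarray(res.x, dtype=float)
    nat = pm.natural_from_free(free_hat)
    estimates = dict(zip(pm.names, nat.tolist()))
    ses: dict[str, float | None] = {n: None for n in pm.names}
    if compute_se and converged:
        ses = standard_errors(nll, free_hat, pm)
    loglik = -float(res.fun)
    k = pm.k
    return FitResult(
        estimates=estimates,
        ses=ses,
        loglik=loglik,
        minus2LL=-2.0 * loglik,
        aic=-2.0 * loglik + 2 * k,
        k=k,
        converged=converged,
        n_evals=n_evals,
        spec=pm.unpack(free_hat),
        free=free_hat,
        names=pm.names,
        dataset_signature=_dataset_signature(dataset),
        message=str(res.message),
    )


def numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with step 1e-4 * (1 + |x_i|) per coordinate."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def standard_errors(nll, free_hat: np.ndarray, pm: ParameterMap) -> dict:
    """Delta-method natural-scale SEs from the free-space inverse Hessian.

    A non-positive-definite Hessian yields undefined (None) SEs with a
    warning rather than an exception: the fit itself is retained.
    """
    H = numerical_hessian(nll, free_hat)
    ses: dict[str, float | None] = {n: None for n in pm.names}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        free_se = np.sqrt(diag)
        nat_se = np.abs(pm.jacobian_diag(free_hat)) * free_se
        ses = dict(zip(pm.names, nat_se.tolist()))
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn(
            "Hessian not positive definite; standard errors undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return ses


def model_table(fits: list[FitResult], labels: list[str]) -> pd.DataFrame:
    """AIC comparison table for fits on the same dataset, sorted by AIC."""
    if len(fits) != len(labels):
        raise ValueError("labels must match fits")
    sigs = {f.dataset_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("model_table requires fits on the same dataset")
    rows = []
    for lab, f in zip(labels, fits):
        row = {"model": lab, "minus2LL": f.minus2LL, "AIC": f.aic, "k": f.k}
        for n, v in f.estimates.items():
            if n.startswith("alpha") or n == "rho":
                row[n] = v
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    return df
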