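"""Parametric hazards and the link carrying longitudinal effects into risk.

The hazard is ``h(t) = h0(t) * exp(Delta)`` with Weibull or Gompertz
baseline ``h0``. The link Delta is built from the longitudinal fixed and
random effects, association coefficients alpha and optional survival
covariates, and is affine in time: ``Delta(t) = delta0 + delta1 * t``.
Absorbing Delta into the baseline keeps the model in-family with
individual-specific parameters:

    Weibull:   lambda* = exp(beta + delta0),             tau unchanged
    Gompertz:  lambda* = exp(beta + delta0),  xi* = xi + delta1

Intercept links contribute only to delta0; slope links make delta1
nonzero, which a Weibull baseline cannot absorb (its shape would become
time-dependent), so slope links are Gompertz-only. The population-level
Gompertz shape xi is constrained positive, but an individual's xi* may
be negative once a slope link is added; the survivor function stays
valid on finite horizons and a series branch handles |xi*| ~ 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .longitudinal import LongitudinalSpec, REStructure, expand_random_effects_matrix

_XI_TINY = 1e-8


class ConfigurationError(ValueError):
    """An incompatible model configuration was requested."""


class HazardFamily(Enum):
    WEIBULL = "weibull"
    GOMPERTZ = "gompertz"


@dataclass(frozen=True)
class HazardSpec:
    """Baseline hazard: family, log-scale beta (lambda = exp(beta)), shape.

    shape is tau for Weibull, xi for Gompertz; both positive at the
    population level.
    """

    family: HazardFamily
    beta: float
    shape: float

    def __post_init__(self) -> None:
        if self.shape <= 0:
            name = "tau" if self.family is HazardFamily.WEIBULL else "xi"
            raise ValueError(f"{name} must be positive, got {self.shape!r}")


class LinkForm(Enum):
    NONE = "none"          # Delta = gammaS'x only (alpha absent)
    INT_ONE = "int_one"    # alpha * (eta0_j + b_j0), one response
    INT_BOTH = "int_both"  # sum_j alpha_j * (eta0_j + b_j0)
    SLO_ONE = "slo_one"    # alpha * (eta1_j + b_j1) * t, one response
    SLO_BOTH = "slo_both"  # sum_j alpha_j * (eta1_j + b_j1) * t


@dataclass(frozen=True)
class LinkSpec:
    """Association structure between the submodels.

    form : which random-effect terms enter the hazard
    alpha : () for NONE, (a,) for *_ONE, (a1, a2) for *_BOTH
    j : referenced response (1 or 2) for the *_ONE forms
    gammaS : optional survival covariate coefficients
    """

    form: LinkForm
    alpha: tuple[float, ...] = ()
    j: int | None = None
    gammaS: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        need = {
            LinkForm.NONE: 0,
            LinkForm.INT_ONE: 1,
            LinkForm.SLO_ONE: 1,
            LinkForm.INT_BOTH: 2,
            LinkForm.SLO_BOTH: 2,
        }[self.form]
        if len(self.alpha) != need:
            raise ConfigurationError(
                f"link {self.form.value} needs {need} alpha value(s), "
                f"got {len(self.alpha)}"
            )
        if self.form in (LinkForm.INT_ONE, LinkForm.SLO_ONE) and self.j not in (1, 2):
            raise ConfigurationError("single-response links need j in {1, 2}")


def _has_intercept_effect(structure: REStructure, j: int) -> bool:
    if structure in (REStructure.SHARED, REStructure.INTERCEPTS_ONLY):
        return True
    return structure is REStructure.Y2_FULL and j == 2


def _has_slope_effect(structure: REStructure, j: int) -> bool:
    if structure in (REStructure.SHARED, REStructure.SLOPES_ONLY):
        return True
    return structure is REStructure.Y2_FULL and j == 2


def check_compatibility(
    link: LinkSpec, structure: REStructure, family: HazardFamily
) -> None:
    """Raise ConfigurationError on invalid link/structure/family trios."""
    if link.form in (LinkForm.SLO_ONE, LinkForm.SLO_BOTH):
        if family is HazardFamily.WEIBULL:
            raise ConfigurationError(
                "slope links make the Weibull shape time-dependent and are "
                "not supported; use a Gompertz baseline"
            )
        js = (link.j,) if link.form is LinkForm.SLO_ONE else (1, 2)
        for j in js:
            if not _has_slope_effect(structure, j):
                raise ConfigurationError(
                    f"slope link references response {j} but structure "
                    f"{structure.value} has no slope effect for it"
                )
    if link.form in (LinkForm.INT_ONE, LinkForm.INT_BOTH):
        js = (link.j,) if link.form is LinkForm.INT_ONE else (1, 2)
        for j in js:
            if not _has_intercept_effect(structure, j):
                raise ConfigurationError(
                    f"intercept link references response {j} but structure "
                    f"{structure.value} has no intercept effect for it"
                )


def delta_parts(
    link: LinkSpec,
    long_spec: LongitudinalSpec,
    b_raw: np.ndarray,
    x: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the link into Delta(t) = delta0 + delta1 * t.

    Vectorized over random-effect nodes: b_raw may be (2,) or (K, 2);
    the returned delta0, delta1 are scalars-as-0d or (K,) arrays.
    gammaS covariate terms enter delta0.
    """
    b = np.asarray(b_raw, dtype=float)
    scalar_in = b.ndim == 1
    b10, b11, b20, b21 = expand_random_effects_matrix(long_spec.structure, b)
    K = b10.shape[0]
    delta0 = np.zeros(K)
    delta1 = np.zeros(K)
    if link.form is LinkForm.INT_ONE:
        bj0 = b10 if link.j == 1 else b20
        delta0 = link.alpha[0] * (long_spec.eta0[link.j - 1] + bj0)
    elif link.form is LinkForm.INT_BOTH:
        delta0 = link.alpha[0] * (long_spec.eta0[0] + b10) + link.alpha[1] * (
            long_spec.eta0[1] + b20
        )
    elif link.form is LinkForm.SLO_ONE:
        bj1 = b11 if link.j == 1 else b21
        delta1 = link.alpha[0] * (long_spec.eta1[link.j - 1] + bj1)
    elif link.form is LinkForm.SLO_BOTH:
        delta1 = link.alpha[0] * (long_spec.eta1[0] + b11) + link.alpha[1] * (
            long_spec.eta1[1] + b21
        )
    if link.gammaS is not None and x is not None and len(x):
        delta0 = delta0 + float(np.dot(link.gammaS, np.atleast_1d(x)))
    if scalar_in:
        return delta0[0], delta1[0]
    return delta0, delta1


def hazard(t, spec: HazardSpec, delta0=0.0, delta1=0.0):
    """Individual-specific hazard at time(s) t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if spec.family is HazardFamily.WEIBULL:
        if np.any(np.asarray(delta1) != 0.0):
            raise ConfigurationError(
                "Weibull baseline cannot carry a time-dependent link (delta1 != 0)"
            )
        tau = spec.shape
        lam_star = np.exp(spec.beta + np.asarray(delta0))
        with np.errstate(divide="ignore"):
            return lam_star * tau * t ** (tau - 1.0)
    xi_star = spec.shape + np.asarray(delta1)
    lam_star = np.exp(spec.beta + np.asarray(delta0))
    return lam_star * np.exp(xi_star * t)


def log_survivor(t, spec: HazardSpec, delta0=0.0, delta1=0.0):
    """log S(t) for the individual-specific hazard; 0 at t = 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam_star = np.exp(spec.beta + np.asarray(delta0))
    if spec.family is HazardFamily.WEIBULL:
        if np.any(np.asarray(delta1) != 0.0):
            raise ConfigurationError(
                "Weibull baseline cannot carry a time-dependent link (delta1 != 0)"
            )
        return -lam_star * t**spec.shape
    xi_star = np.asarray(spec.shape + np.asarray(delta1), dtype=float)
    tiny = np.abs(xi_star) < _XI_TINY
    xi_safe = np.where(tiny, 1.0, xi_star)
    # exponential-distribution limit as xi* -> 0 avoids the 0/0 form
    out = np.where(
        tiny,
        -lam_star * t,
        -(lam_star / xi_safe) * np.expm1(xi_safe * t),
    )
    if out.ndim == 0:
        return float(out)
    return out


def log_hazard(t, spec: HazardSpec, delta0=0.0, delta1=0.0):
    """log h(t), computed without forming h(t) (overflow-safe)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam_log = spec.beta + np.asarray(delta0)
    if spec.family is HazardFamily.WEIBULL:
        if np.any(np.asarray(delta1) != 0.0):
            raise ConfigurationError(
                "Weibull baseline cannot carry a time-dependent link (delta1 != 0)"
            )
        with np.errstate(divide="ignore"):
            return lam_log + math.log(spec.shape) + (spec.shape - 1.0) * np.log(t)
    return lam_log + (spec.shape + np.asarray(delta1)) * t


def surv_log_density(
    t_last, delta: int, spec: HazardSpec, delta0=0.0, delta1=0.0
):
    """log of h(t)^delta * S(t): death density if delta=1, else survival."""
    ls = log_survivor(t_last, spec, delta0, delta1)
    if delta:
        return log_hazard(t_last, spec, delta0, delta1) + ls
    return ls
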