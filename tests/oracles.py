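"""Deliberately naive reference implementations used only as test oracles.

Everything here is written in plain linear-space arithmetic with literal
loops, independent of the package's log-space/vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import dblquad


def naive_uni_kernel(m: int, p: float, theta: float, y: int) -> float:
    return math.comb(m, y) * p**y * (1 - p) ** (m - y) * theta ** (y * (m - y))


def naive_uni_pmf(m: int, p: float, theta: float) -> np.ndarray:
    w = [naive_uni_kernel(m, p, theta, y) for y in range(m + 1)]
    c = sum(w)
    return np.array([wi / c for wi in w])


def naive_biv_table(
    m1: int, m2: int, p1: float, p2: float, t1: float, t2: float, phi: float
) -> np.ndarray:
    tab = np.empty((m1 + 1, m2 + 1))
    for a in range(m1 + 1):
        for b in range(m2 + 1):
            tab[a, b] = (
                naive_uni_kernel(m1, p1, t1, a)
                * naive_uni_kernel(m2, p2, t2, b)
                * phi ** (a * b)
            )
    return tab / tab.sum()


def naive_biv_moments(tab: np.ndarray) -> tuple[float, float, float, float, float]:
    # two passes with centering: the uncentered E[y^2]-E[y]^2 form loses
    # all precision when the mass sits near a corner of the support
    m1, m2 = tab.shape[0] - 1, tab.shape[1] - 1
    e1 = e2 = 0.0
    for a in range(m1 + 1):
        for b in range(m2 + 1):
            e1 += a * tab[a, b]
            e2 += b * tab[a, b]
    v1 = v2 = cov = 0.0
    for a in range(m1 + 1):
        for b in range(m2 + 1):
            w = tab[a, b]
            v1 += (a - e1) ** 2 * w
            v2 += (b - e2) ** 2 * w
            cov += (a - e1) * (b - e2) * w
    corr = cov / math.sqrt(v1 * v2)
    return e1, e2, v1, v2, corr


def first_principles_subject_loglik(subject, spec, box_sd: float = 8.0) -> float:
    """Marginal log-likelihood by adaptive 2-D integration on a wide box.

    The integrand is rebuilt from scratch: literal binomial sums, plain
    logistic, closed-form Gompertz/Weibull survivor, bivariate-normal
    density — no calls into the package's likelihood machinery.
    """
    from jointbin.hazards import HazardFamily, LinkForm
    from jointbin.longitudinal import REStructure

    ls, hz, lk, re = spec.longitudinal, spec.hazard, spec.link, spec.re_dist
    s1, s2, rho = re.sigma1, re.sigma2, re.rho

    def norm2(b1, b2):
        q = (
            (b1 / s1) ** 2 - 2 * rho * (b1 / s1) * (b2 / s2) + (b2 / s2) ** 2
        ) / (1 - rho**2)
        return math.exp(-0.5 * q) / (
            2 * math.pi * s1 * s2 * math.sqrt(1 - rho**2)
        )

    def expand(b1, b2):
        st = ls.structure
        if st is REStructure.SHARED:
            return (b1, b2), (b1, b2)
        if st is REStructure.INTERCEPTS_ONLY:
            return (b1, 0.0), (b2, 0.0)
        if st is REStructure.SLOPES_ONLY:
            return (0.0, b1), (0.0, b2)
        return (0.0, 0.0), (b1, b2)

    def logistic(z):
        return 1.0 / (1.0 + math.exp(-z))

    def long_lik(b1, b2):
        (b10, b11), (b20, b21) = expand(b1, b2)
        out = 1.0
        for t, a, c in zip(subject.t, subject.y1, subject.y2):
            p1 = logistic(ls.eta0[0] + b10 + (ls.eta1[0] + b11) * t)
            p2 = logistic(ls.eta0[1] + b20 + (ls.eta1[1] + b21) * t)
            tab = naive_biv_table(
                spec.m1, spec.m2, p1, p2, ls.theta[0], ls.theta[1], ls.phi
            )
            out *= tab[int(a), int(c)]
        return out

    def link_parts(b1, b2):
        (b10, b11), (b20, b21) = expand(b1, b2)
        d0 = d1 = 0.0
        if lk.form is LinkForm.INT_ONE:
            d0 = lk.alpha[0] * (ls.eta0[lk.j - 1] + (b10 if lk.j == 1 else b20))
        elif lk.form is LinkForm.INT_BOTH:
            d0 = lk.alpha[0] * (ls.eta0[0] + b10) + lk.alpha[1] * (ls.eta0[1] + b20)
        elif lk.form is LinkForm.SLO_ONE:
            d1 = lk.alpha[0] * (ls.eta1[lk.j - 1] + (b11 if lk.j == 1 else b21))
        elif lk.form is LinkForm.SLO_BOTH:
            d1 = lk.alpha[0] * (ls.eta1[0] + b11) + lk.alpha[1] * (ls.eta1[1] + b21)
        return d0, d1

    def surv_density(t, delta, b1, b2):
        d0, d1 = link_parts(b1, b2)
        lam = math.exp(hz.beta + d0)
        if hz.family is HazardFamily.WEIBULL:
            S = math.exp(-lam * t**hz.shape)
            h = lam * hz.shape * t ** (hz.shape - 1) if t > 0 else lam * hz.shape * 1e-300
        else:
            xi = hz.shape + d1
            S = math.exp(-(lam / xi) * (math.exp(xi * t) - 1.0)) if abs(xi) > 1e-12 else math.exp(-lam * t)
            h = lam * math.exp(xi * t)
        return (h if delta else 1.0) * S

    def numerator(b2, b1):
        return long_lik(b1, b2) * surv_density(subject.t_last, subject.delta, b1, b2) * norm2(b1, b2)

    def denominator(b2, b1):
        return surv_density(subject.t1, 0, b1, b2) * norm2(b1, b2)

    lim1, lim2 = box_sd * s1, box_sd * s2
    num, _ = dblquad(numerator, -lim1, lim1, -lim2, lim2, epsabs=1e-13, epsrel=1e-10)
    den, _ = dblquad(denominator, -lim1, lim1, -lim2, lim2, epsabs=1e-13, epsrel=1e-10)
    return math.log(num) - math.log(den)
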