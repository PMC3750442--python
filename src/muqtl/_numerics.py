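"""Compiled numerical kernels for the Gibbs sampler and GEM iteration.

Single-site updates of the marker effects dominate the cost of both
algorithms: every update needs the three-component truncated-normal
mixture implied by the step-function prior, evaluated stably even when
the conditional likelihood sits a thousand standard deviations away
from the prior support.  These kernels are compiled with numba, so the
normal-distribution primitives they need (scaled complementary error
function, normal quantile, truncated-normal mean and quantile) are
implemented here in nopython-compatible form; they are cross-checked
against scipy in the test suite.

Conventions: weights are formed in log space with complementary-CDF
forms on the far side; truncated-normal draws use inverse CDF with
uniforms clamped to [1e-15, 1 - 1e-15]; a degenerate all-zero weight
vector falls back to the component nearest the conditional mean.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LN2 = math.log(2.0)
_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
_LN_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_U_EPS = 1e-15


@njit(cache=True)
def erfcx(x):
    """exp(x^2) * erfc(x) for x >= 0 without overflow."""
    if x < 12.0:
        return math.exp(x * x) * math.erfc(x)
    # asymptotic series: (1/(x sqrt(pi))) * sum (-1)^k (2k-1)!! / (2x^2)^k
    z = 1.0 / (2.0 * x * x)
    s = 1.0
    term = 1.0
    for k in range(1, 9):
        term *= -(2 * k - 1) * z
        s += term
    return s / (x * math.sqrt(math.pi))


@njit(cache=True)
def _log_phi_interval_upper(a, b):
    """log(Phi(b) - Phi(a)) for 0 <= a < b, via erfcx (no underflow)."""
    s = a / _SQRT2
    t = b / _SQRT2
    q = math.exp(-(t * t - s * s))
    d = erfcx(s) - q * erfcx(t)
    if d <= 0.0:
        return -np.inf
    return -_LN2 - s * s + math.log(d)


@njit(cache=True)
def log_phi_interval(a, b):
    """log(Phi(b) - Phi(a)) for a < b, stable in both far tails."""
    if a >= 0.0:
        return _log_phi_interval_upper(a, b)
    if b <= 0.0:
        return _log_phi_interval_upper(-b, -a)
    # interval straddles zero: 1 - (lower tail + upper tail)
    ta = 0.5 * math.erfc(-a / _SQRT2)
    tb = 0.5 * math.erfc(b / _SQRT2)
    s = ta + tb
    if s >= 1.0:
        return -np.inf
    return math.log1p(-s)


@njit(cache=True)
def _tn_mean_upper(a, b):
    """Mean of N(0,1) truncated to [a, b] with 0 <= a < b."""
    s = a / _SQRT2
    t = b / _SQRT2
    q = math.exp(-(t * t - s * s))
    d = erfcx(s) - q * erfcx(t)
    if d <= 0.0:
        return 0.5 * (a + b)
    m = _SQRT_2_OVER_PI * (1.0 - q) / d
    if m < a:
        return a
    if m > b:
        return b
    return m


@njit(cache=True)
def tn_mean(a, b):
    """Mean of the standard normal truncated to [a, b]."""
    if a >= 0.0:
        return _tn_mean_upper(a, b)
    if b <= 0.0:
        return -_tn_mean_upper(-b, -a)
    z = math.exp(log_phi_interval(a, b))
    if z <= 0.0:
        return 0.5 * (a + b)
    num = (math.exp(-0.5 * a * a) - math.exp(-0.5 * b * b)) / math.sqrt(2.0 * math.pi)
    m = num / z
    if m < a:
        return a
    if m > b:
        return b
    return m


@njit(cache=True)
def ndtri(p):
    """Quantile of the standard normal (Wichura's AS241, double precision)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    if q < 0.0:
        r = p
    else:
        r = 1.0 - p
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r -= 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r -= 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    val = num / den
    return -val if q < 0.0 else val


@njit(cache=True)
def _tn_ppf_upper(u, a, b):
    """Quantile of N(0,1) truncated to [a, b] with 0 <= a < b."""
    if a > 8.0:
        # exponential-tail inversion, refined by Newton on the exact CDF
        c = -math.expm1(-a * (b - a))
        x = a - math.log1p(-u * c) / a
        if x > b:
            x = b
        lz = _log_phi_interval_upper(a, b)
        for _ in range(6):
            g = math.exp(_log_phi_interval_upper(a, x) - lz) - u if x > a else -u
            dens = math.exp(-_LN_SQRT_2PI - 0.5 * x * x - lz)
            if dens <= 0.0:
                break
            x -= g / dens
            if x < a:
                x = a
            if x > b:
                x = b
        return x
    sa = 0.5 * math.erfc(a / _SQRT2)
    sb = 0.5 * math.erfc(b / _SQRT2)
    s = sa - u * (sa - sb)
    x = -ndtri(s)
    if x < a:
        x = a
    if x > b:
        x = b
    return x


@njit(cache=True)
def tn_ppf(u, a, b):
    """Quantile of the standard normal truncated to [a, b]."""
    if u < _U_EPS:
        u = _U_EPS
    if u > 1.0 - _U_EPS:
        u = 1.0 - _U_EPS
    if a >= 0.0:
        return _tn_ppf_upper(u, a, b)
    if b <= 0.0:
        return -_tn_ppf_upper(1.0 - u, -b, -a)
    pa = 0.5 * math.erfc(-a / _SQRT2)
    pb = 0.5 * math.erfc(-b / _SQRT2)
    x = ndtri(pa + u * (pb - pa))
    if x < a:
        x = a
    if x > b:
        x = b
    return x


@njit(cache=True)
def mu_log_weights(mu, tau, p0, b, l):
    """Log weights of the three truncated-normal components of the
    fully conditional distribution of one marker effect.

    Component order: spike (-b, b), negative slab [-l, -b], positive
    slab [b, l].  Weight_j = height_j * [Phi((hi-mu)/tau) - Phi((lo-mu)/tau)].
    """
    lw = np.empty(3)
    lh_spike = math.log(p0) - math.log(2.0 * b)
    lh_slab = math.log1p(-p0) - math.log(2.0 * (l - b))
    lw[0] = lh_spike + log_phi_interval((-b - mu) / tau, (b - mu) / tau)
    lw[1] = lh_slab + log_phi_interval((-l - mu) / tau, (-b - mu) / tau)
    lw[2] = lh_slab + log_phi_interval((b - mu) / tau, (l - mu) / tau)
    return lw


@njit(cache=True)
def _component_bounds(j, b, l):
    if j == 0:
        return -b, b
    if j == 1:
        return -l, -b
    return b, l


@njit(cache=True)
def _normalized_weights(lw, mu, b, l):
    """Exponentiate log weights; on total underflow put all mass on the
    component whose support is nearest the conditional mean."""
    w = np.zeros(3)
    mx = -np.inf
    for j in range(3):
        if lw[j] > mx:
            mx = lw[j]
    if mx == -np.inf:
        if mu <= -b:
            w[1] = 1.0
        elif mu >= b:
            w[2] = 1.0
        else:
            w[0] = 1.0
        return w
    tot = 0.0
    for j in range(3):
        w[j] = math.exp(lw[j] - mx)
        tot += w[j]
    for j in range(3):
        w[j] /= tot
    return w


@njit(cache=True)
def sample_beta_conditional(mu, tau, p0, b, l, u1, u2):
    """One draw from the fully conditional distribution of a marker effect."""
    lw = mu_log_weights(mu, tau, p0, b, l)
    w = _normalized_weights(lw, mu, b, l)
    j = 0
    acc = w[0]
    while j < 2 and u1 > acc:
        j += 1
        acc += w[j]
    lo, hi = _component_bounds(j, b, l)
    return mu + tau * tn_ppf(u2, (lo - mu) / tau, (hi - mu) / tau)


@njit(cache=True)
def mean_beta_conditional(mu, tau, p0, b, l):
    """Fully conditional posterior mean of a marker effect (GEM update)."""
    lw = mu_log_weights(mu, tau, p0, b, l)
    w = _normalized_weights(lw, mu, b, l)
    m = 0.0
    for j in range(3):
        if w[j] == 0.0:
            continue
        lo, hi = _component_bounds(j, b, l)
        m += w[j] * (mu + tau * tn_mean((lo - mu) / tau, (hi - mu) / tau))
    if m < -l:
        m = -l
    if m > l:
        m = l
    return m


@njit(cache=True)
def gibbs_sweep_beta(Xt, xx, e, beta, sigma2, p0, b, l, uni):
    """One systematic sweep over all marker effects, in index order.

    Xt is the (M, N) transposed genotype matrix (contiguous rows), e the
    running residual (updated in place together with beta), and uni an
    (M, 2) matrix of uniforms (component pick, truncated draw).
    """
    M, N = Xt.shape
    for m in range(M):
        if xx[m] <= 0.0:
            continue
        xe = 0.0
        for j in range(N):
            xe += Xt[m, j] * e[j]
        mu = xe / xx[m] + beta[m]
        tau = math.sqrt(sigma2 / xx[m])
        newb = sample_beta_conditional(mu, tau, p0, b, l, uni[m, 0], uni[m, 1])
        diff = newb - beta[m]
        if diff != 0.0:
            for j in range(N):
                e[j] -= diff * Xt[m, j]
            beta[m] = newb


@njit(cache=True)
def gem_sweep_beta(Xt, xx, e, beta, sigma2, p0, b, l):
    """One deterministic sweep replacing each beta_m by its conditional
    mean; returns the summed absolute parameter change."""
    M, N = Xt.shape
    dev = 0.0
    for m in range(M):
        if xx[m] <= 0.0:
            continue
        xe = 0.0
        for j in range(N):
            xe += Xt[m, j] * e[j]
        mu = xe / xx[m] + beta[m]
        tau = math.sqrt(sigma2 / xx[m])
        newb = mean_beta_conditional(mu, tau, p0, b, l)
        diff = newb - beta[m]
        dev += abs(diff)
        if diff != 0.0:
            for j in range(N):
                e[j] -= diff * Xt[m, j]
            beta[m] = newb
    return dev
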