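"""Single-site Gibbs sampler for the MU shrinkage regression.

Model: y_j = alpha + sum_m beta_m x_jm + u_{k(j)} + eps_j, with
alpha ~ N(0, c), beta_m ~ MU(p0, b, l), u_k ~ N(0, sigma_u^2) for
full-sib families (optional), eps_j ~ N(0, sigma^2), and inverse-gamma
priors on both variance components.

Fully conditional distributions (conjugate normal likelihood times the
step prior):

* beta_m | rest is a three-component mixture of truncated normals on
  the intervals (-b, b), [-l, -b], [b, l], all sharing location
  mu~ = x_m' r / (x_m' x_m) and scale tau^2 = sigma^2 / (x_m' x_m)
  (r the partial residual); component j has weight proportional to
  height_j * [Phi((hi_j - mu~)/tau) - Phi((lo_j - mu~)/tau)].
* alpha | rest ~ N(v * 1'r_a / sigma^2, v), v = (N/sigma^2 + 1/c)^-1.
* u_k | rest ~ N(v_k sum_{j in k} r_kj / sigma^2, v_k),
  v_k = (N_k/sigma^2 + 1/sigma_u^2)^-1.
* sigma^2 | rest ~ InvGamma(s + N/2, r + SSE/2) and
  sigma_u^2 | rest ~ InvGamma(s_u + K/2, r_u + sum u_k^2 / 2)
  (shape/rate parameterization, mode r/(s+1)).

Each iteration performs a fixed systematic sweep alpha -> beta_1..M ->
u_1..K -> sigma_u^2 -> sigma^2, maintaining the residual vector
incrementally so a beta update costs O(N).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import _numerics as nm
from .data import FamilyMap, GenotypePanel, PhenotypeSet
from .prior import HyperConfig, MUPriorSpec


@dataclass
class ParameterState:
    """One point in parameter space."""

    alpha: float
    beta: np.ndarray
    u: np.ndarray
    sigma2: float
    sigma2_u: float


@dataclass
class GibbsConfig:
    n_iter: int = 220_000
    burn_in: int = 20_000
    thin: int = 20
    seed: int = 0
    store_indicators: bool = True
    residual_check_every: int = 1000
    # diagnostics / oracle hooks: hold a parameter fixed at the given value
    fixed_alpha: float = None
    fixed_sigma2: float = None

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ChainSamples:
    """Thinned post-burn-in draws plus per-draw inclusion indicators."""

    alpha: np.ndarray          # (T,)
    beta: np.ndarray           # (T, M)
    u: np.ndarray              # (T, K) or (T, 0)
    sigma2: np.ndarray         # (T,)
    sigma2_u: np.ndarray       # (T,)
    S: np.ndarray              # (T, M) uint8, I(b <= |beta| <= l)
    spec: MUPriorSpec = None
    meta: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return self.beta.shape[0]

    @property
    def n_markers(self) -> int:
        return self.beta.shape[1]


@dataclass
class TruncNormMixture:
    """The fully conditional distribution of one marker effect."""

    mu_tilde: float
    tau: float
    intervals: np.ndarray      # (3, 2): spike, negative slab, positive slab
    weights: np.ndarray        # (3,), normalized
    heights: np.ndarray        # (3,) prior density heights

    def mean(self) -> float:
        m = 0.0
        for j in range(3):
            if self.weights[j] == 0.0:
                continue
            lo, hi = self.intervals[j]
            m += self.weights[j] * (self.mu_tilde + self.tau * nm.tn_mean(
                (lo - self.mu_tilde) / self.tau, (hi - self.mu_tilde) / self.tau))
        return m

    def prob_slab(self) -> float:
        """Conditional P(S_m = 1) = P(b <= |beta_m| <= l)."""
        return float(self.weights[1] + self.weights[2])


def _partial_residual_stats(x_m: np.ndarray, resid_m: np.ndarray, sigma2: float):
    xx = float(x_m @ x_m)
    if xx <= 0.0:
        raise ValueError("degenerate marker: column is identically zero")
    mu = float(x_m @ resid_m) / xx
    tau = np.sqrt(sigma2 / xx)
    return mu, tau


def full_conditional_beta(m: int, state: ParameterState, X: np.ndarray,
                          y: np.ndarray, spec: MUPriorSpec,
                          family_codes: np.ndarray = None) -> TruncNormMixture:
    """Fully conditional distribution of beta_m given all other parameters.

    X must be in the coding used for fitting; the partial residual
    excludes marker m's own contribution.
    """
    fitted = state.alpha + X @ state.beta
    if family_codes is not None and state.u.size:
        fitted = fitted + state.u[family_codes]
    resid_m = y - fitted + X[:, m] * state.beta[m]
    mu, tau = _partial_residual_stats(X[:, m], resid_m, state.sigma2)
    return _mixture_at(mu, tau, spec)


def _mixture_at(mu: float, tau: float, spec: MUPriorSpec) -> TruncNormMixture:
    p0, b, l = spec.p0, spec.b, spec.l
    lw = nm.mu_log_weights(mu, tau, p0, b, l)
    w = nm._normalized_weights(lw, mu, b, l)
    intervals = np.array([[-b, b], [-l, -b], [b, l]])
    heights = np.array([spec.spike_height, spec.slab_height, spec.slab_height])
    return TruncNormMixture(mu, float(tau), intervals, np.asarray(w), heights)


def sample_trunc_mixture(mix: TruncNormMixture, rng: np.random.Generator) -> float:
    """Draw from a truncated-normal mixture: component by weight, then
    inverse-CDF within the component.  The result lies in [-l, l]."""
    u1, u2 = rng.random(2)
    j = int(np.searchsorted(np.cumsum(mix.weights), u1))
    j = min(j, 2)
    lo, hi = mix.intervals[j]
    a = (lo - mix.mu_tilde) / mix.tau
    c = (hi - mix.mu_tilde) / mix.tau
    return mix.mu_tilde + mix.tau * nm.tn_ppf(u2, a, c)


def full_conditional_alpha(state: ParameterState, X: np.ndarray, y: np.ndarray,
                           hyper: HyperConfig, family_codes: np.ndarray = None):
    """Normal conditional of the intercept; returns (mean, var)."""
    n = y.shape[0]
    resid_a = y - X @ state.beta
    if family_codes is not None and state.u.size:
        resid_a = resid_a - state.u[family_codes]
    var = 1.0 / (n / state.sigma2 + 1.0 / hyper.c)
    mean = var * float(resid_a.sum()) / state.sigma2
    return mean, var

def full_conditional_u(k: int, state: ParameterState, X: np.ndarray,
                       y: np.ndarray, fam: FamilyMap, hyper: HyperConfig):
    """Normal conditional of family effect u_k; returns (mean, var)."""
    if not hyper.include_polygenic:
        raise ValueError("polygenic family effects are disabled in this configuration")
    members = fam.codes == k
    n_k = int(members.sum())
    var = 1.0 / (n_k / state.sigma2 + 1.0 / state.sigma2_u)
    if n_k == 0:
        return 0.0, state.sigma2_u
    resid_k = (y[members] - state.alpha - X[members] @ state.beta)
    mean = var * float(resid_k.sum()) / state.sigma2
    return mean, var


def full_conditional_sigma2(state: ParameterState, X: np.ndarray, y: np.ndarray,
                            hyper: HyperConfig, family_codes: np.ndarray = None):
    """Inverse-gamma conditional of the residual variance; returns
    (shape, rate) with shape = s + N/2, rate = r + SSE/2."""
    fitted = state.alpha + X @ state.beta
    if family_codes is not None and state.u.size:
        fitted = fitted + state.u[family_codes]
    sse = float(np.sum((y - fitted) ** 2))
    return hyper.s + y.shape[0] / 2.0, hyper.r + sse / 2.0


def initial_state(y: np.ndarray, M: int, K: int, spec: MUPriorSpec,
                  include_polygenic: bool) -> ParameterState:
    vy = float(np.var(y))
    if vy <= 0:
        vy = 1.0
    return ParameterState(
        alpha=float(np.mean(y)),
        beta=np.zeros(M),
        u=np.zeros(K if include_polygenic else 0),
        sigma2=vy / 2.0,
        sigma2_u=vy / 100.0,
    )


def run_gibbs(panel: GenotypePanel, phen: PhenotypeSet, spec: MUPriorSpec,
              hyper: HyperConfig = None, cfg: GibbsConfig = None,
              fam: FamilyMap = None, chain_id: int = 0,
              init: ParameterState = None) -> ChainSamples:
    """Run the single-site Gibbs sampler and return thinned samples.

    The chain id offsets the RNG seed so parallel chains are independent
    but individually reproducible.
    """
    hyper = hyper or HyperConfig()
    cfg = cfg or GibbsConfig()
    X = np.ascontiguousarray(panel.dosage)
    y = phen.y
    n, M = X.shape
    if y.shape[0] != n:
        raise ValueError(f"genotypes have {n} individuals but phenotypes {y.shape[0]}")
    use_u = hyper.include_polygenic and fam is not None
    if hyper.include_polygenic and fam is None:
        raise ValueError("include_polygenic=True requires a FamilyMap")
    K = fam.n_families if use_u else 0
    fam_codes = fam.codes if use_u else None
    if use_u and fam.n != n:
        raise ValueError("family map length does not match panel")

    rng = np.random.default_rng(cfg.seed + chain_id)
    Xt = np.ascontiguousarray(X.T)
    xx = np.einsum("ij,ij->i", Xt, Xt)
    state = init or initial_state(y, M, K, spec, use_u)
    alpha = state.alpha if cfg.fixed_alpha is None else cfg.fixed_alpha
    beta = state.beta.copy()
    u = state.u.copy() if use_u else np.zeros(0)
    sigma2 = state.sigma2 if cfg.fixed_sigma2 is None else cfg.fixed_sigma2
    sigma2_u = state.sigma2_u

    e = y - alpha - X @ beta
    if use_u:
        e -= u[fam_codes]

    T = (cfg.n_iter - cfg.burn_in) // cfg.thin
    out_alpha = np.empty(T)
    out_beta = np.empty((T, M))
    out_u = np.empty((T, K))
    out_s2 = np.empty(T)
    out_s2u = np.empty(T)

    p0, b, l = spec.p0, spec.b, spec.l
    t0 = time.time()
    stored = 0
    for it in range(cfg.n_iter):
        # intercept
        if cfg.fixed_alpha is None:
            var_a = 1.0 / (n / sigma2 + 1.0 / hyper.c)
            mean_a = var_a * (e.sum() + n * alpha) / sigma2
            new_alpha = mean_a + np.sqrt(var_a) * rng.standard_normal()
            e += alpha - new_alpha
            alpha = new_alpha

        # marker effects (compiled systematic sweep)
        uni = rng.random((M, 2))
        nm.gibbs_sweep_beta(Xt, xx, e, beta, sigma2, p0, b, l, uni)

        # family effects and their variance
        if use_u:
            fam_sums = np.bincount(fam_codes, weights=e, minlength=K)
            fam_sums += fam.sizes * u
            var_u = 1.0 / (fam.sizes / sigma2 + 1.0 / sigma2_u)
            mean_u = var_u * fam_sums / sigma2
            new_u = mean_u + np.sqrt(var_u) * rng.standard_normal(K)
            e += (u - new_u)[fam_codes]
            u = new_u
            shape_u = hyper.s_u + K / 2.0
            rate_u = hyper.r_u + 0.5 * float(u @ u)
            sigma2_u = rate_u / rng.gamma(shape_u)

        # residual variance
        if cfg.fixed_sigma2 is None:
            shape = hyper.s + n / 2.0
            rate = hyper.r + 0.5 * float(e @ e)
            sigma2 = rate / rng.gamma(shape)

        if not np.isfinite(e).all():
            raise FloatingPointError(f"non-finite residual at iteration {it}")

        if cfg.residual_check_every and (it + 1) % cfg.residual_check_every == 0:
            e_full = y - alpha - X @ beta
            if use_u:
                e_full -= u[fam_codes]
            if not np.allclose(e, e_full, atol=1e-8):
                raise FloatingPointError(
                    f"incremental residual drifted at iteration {it}")
            e = e_full

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and stored < T:
            out_alpha[stored] = alpha
            out_beta[stored] = beta
            if use_u:
                out_u[stored] = u
            out_s2[stored] = sigma2
            out_s2u[stored] = sigma2_u if use_u else 0.0
            stored += 1

    ab = np.abs(out_beta)
    S = ((ab >= b) & (ab <= l)).astype(np.uint8) if cfg.store_indicators \
        else np.zeros((0, M), dtype=np.uint8)
    meta = {
        "seed": cfg.seed, "chain_id": chain_id, "n_iter": cfg.n_iter,
        "burn_in": cfg.burn_in, "thin": cfg.thin,
        "include_polygenic": bool(use_u), "wall_time_s": time.time() - t0,
    }
    return ChainSamples(out_alpha[:stored], out_beta[:stored], out_u[:stored],
                        out_s2[:stored], out_s2u[:stored], S[:stored],
                        spec=spec, meta=meta)
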