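"""Generalized EM (GEM) point estimation for the MU shrinkage regression.

Instead of drawing from the fully conditional distributions as the
Gibbs sampler does, GEM replaces every parameter in turn by its fully
conditional expected value and iterates the sweep to a fixed point:

* beta_m <- mixture-weighted truncated-normal mean of its conditional,
* alpha  <- conditional normal mean,
* sigma^2 <- conditional inverse-gamma mean rate/(shape - 1)
  (shape = s + N/2 > 1 for any N >= 2).

Family effects are excluded by default (enable via
``HyperConfig.include_polygenic``); when enabled each u_k is updated to
its conditional mean and sigma_u^2 to rate_u/(shape_u - 1).

Convergence is declared when the sum of absolute parameter changes over
one sweep falls below tol_per_param * n_params, with n_params = M + 2
(beta, alpha, sigma^2) plus K + 1 when the polygenic block is active.
The iteration is deterministic: identical inputs give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _numerics as nm
from .data import FamilyMap, GenotypePanel, PhenotypeSet
from .gibbs import ParameterState
from .prior import HyperConfig, MUPriorSpec


@dataclass
class GEMResult:
    state: ParameterState
    n_iters: int
    final_deviation: float
    converged: bool
    deviation_trace: np.ndarray = None


def gem_fit(panel: GenotypePanel, phen: PhenotypeSet, spec: MUPriorSpec,
            hyper: HyperConfig = None, fam: FamilyMap = None,
            tol_per_param: float = 1e-7, max_iter: int = 2000) -> GEMResult:
    """Iterate fully conditional expectations to a (possibly local) MAP
    fixed point."""
    hyper = hyper or HyperConfig()
    X = np.ascontiguousarray(panel.dosage)
    y = phen.y
    n, M = X.shape
    if y.shape[0] != n:
        raise ValueError(f"genotypes have {n} individuals but phenotypes {y.shape[0]}")
    if n < 2:
        raise ValueError("need at least 2 individuals")
    use_u = hyper.include_polygenic and fam is not None
    if hyper.include_polygenic and fam is None:
        raise ValueError("include_polygenic=True requires a FamilyMap")
    K = fam.n_families if use_u else 0
    fam_codes = fam.codes if use_u else None

    Xt = np.ascontiguousarray(X.T)
    xx = np.einsum("ij,ij->i", Xt, Xt)
    alpha = float(np.mean(y))
    beta = np.zeros(M)
    u = np.zeros(K)
    sigma2 = float(np.var(y)) or 1.0
    sigma2_u = sigma2 / 100.0

    n_params = M + 2 + (K + 1 if use_u else 0)
    tol = tol_per_param * n_params
    e = y - alpha - X @ beta
    if use_u:
        e = e - u[fam_codes]

    p0, b, l = spec.p0, spec.b, spec.l
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dev = 0.0
        # intercept mean
        var_a = 1.0 / (n / sigma2 + 1.0 / hyper.c)
        new_alpha = var_a * (e.sum() + n * alpha) / sigma2
        dev += abs(new_alpha - alpha)
        e += alpha - new_alpha
        alpha = new_alpha

        dev += nm.gem_sweep_beta(Xt, xx, e, beta, sigma2, p0, b, l)

        if use_u:
            fam_sums = np.bincount(fam_codes, weights=e, minlength=K)
            fam_sums += fam.sizes * u
            var_u = 1.0 / (fam.sizes / sigma2 + 1.0 / sigma2_u)
            new_u = var_u * fam_sums / sigma2
            dev += float(np.abs(new_u - u).sum())
            e += (u - new_u)[fam_codes]
            u = new_u
            shape_u = hyper.s_u + K / 2.0
            if shape_u > 1.0:
                new_s2u = (hyper.r_u + 0.5 * float(u @ u)) / (shape_u - 1.0)
                dev += abs(new_s2u - sigma2_u)
                sigma2_u = new_s2u

        # residual variance mean rate/(shape-1); shape = s + n/2 > 1 for n >= 2
        new_sigma2 = (hyper.r + 0.5 * float(e @ e)) / (hyper.s + n / 2.0 - 1.0)
        dev += abs(new_sigma2 - sigma2)
        sigma2 = new_sigma2

        if not np.isfinite(dev):
            raise FloatingPointError(f"non-finite GEM update at iteration {it}")
        trace.append(dev)
        if dev < tol:
            converged = True
            break

    state = ParameterState(alpha=alpha, beta=beta, u=u if use_u else np.zeros(0),
                           sigma2=sigma2, sigma2_u=sigma2_u if use_u else 0.0)
    return GEMResult(state=state, n_iters=it, final_deviation=trace[-1],
                     converged=converged, deviation_trace=np.array(trace))
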