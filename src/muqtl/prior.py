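"""The mixture-of-uniforms (MU) shrinkage prior on marker effects.

Each additive marker effect beta_m is assigned the step-function density

    p(beta) = p0 / (2b)            on the spike (-b, b)
            = (1 - p0) / (2(l-b))  on the slabs [-l, -b] and [b, l]
            = 0                    outside [-l, l],

with spike mass p0, border b > 0 and effect-size limit l > b.  The
density at the boundary points +/-b takes the slab height (the slabs
carry the closed intervals).  The prior variance has the closed form

    Var(beta) = (1/3) [ b^2 + l (l + b) (1 - p0) ],

which calibrates the hyper-parameters against an expected heritability:
with allele frequencies f_m and phenotypic variance V_P,

    h^2 = 2 Var(beta) sum_m f_m (1 - f_m) / V_P       (centered codes)
    h^2 = Var(beta) M / V_P                            (standardized codes).

These prior heritabilities are deliberately not clipped to (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MUPriorSpec:
    """Hyper-parameter triple (p0, b, l) of the MU prior."""

    p0: float
    b: float
    l: float

    def __post_init__(self):
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")
        if not 0.0 < self.b < self.l:
            raise ValueError("must have 0 < b < l")

    @property
    def spike_height(self) -> float:
        return self.p0 / (2.0 * self.b)

    @property
    def slab_height(self) -> float:
        return (1.0 - self.p0) / (2.0 * (self.l - self.b))

    def scaled(self, factor: float) -> "MUPriorSpec":
        """Rescale the effect-size axis by 1/factor.

        A spec stated in phenotypic-standard-deviation units (l set to
        sd(Y)) maps to the standardized-analysis scale via
        ``spec.scaled(sd_y)``; if l was set to sd(Y) the result has l=1.
        """
        return MUPriorSpec(self.p0, self.b / factor, self.l / factor)


@dataclass(frozen=True)
class HyperConfig:
    """Fixed hyper-parameters of the non-marker model layers.

    c is the prior variance of the common intercept; (s, r) and
    (s_u, r_u) are the shape and rate of the inverse-gamma priors on the
    residual and family variances (mode r/(s+1); mean undefined for the
    default 0.01/0.01 choice, which approaches the scale-invariant
    1/sigma^2 prior).
    """

    c: float = 1e6
    s: float = 0.01
    r: float = 0.01
    s_u: float = 0.01
    r_u: float = 0.01
    include_polygenic: bool = False

    def __post_init__(self):
        for name in ("c", "s", "r", "s_u", "r_u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def mu_pdf(beta, spec: MUPriorSpec):
    """MU prior density, vectorized over beta."""
    beta = np.asarray(beta, dtype=float)
    a = np.abs(beta)
    out = np.zeros_like(a)
    out[a < spec.b] = spec.spike_height
    slab = (a >= spec.b) & (a <= spec.l)
    out[slab] = spec.slab_height
    return out if out.ndim else float(out)


def mu_sample(spec: MUPriorSpec, n: int, seed=None, rng=None) -> np.ndarray:
    """i.i.d. draws: spike w.p. p0, each slab w.p. (1-p0)/2, uniform within."""
    if rng is None:
        rng = np.random.default_rng(seed)
    comp = rng.random(n)
    u = rng.random(n)
    out = np.empty(n)
    spike = comp < spec.p0
    out[spike] = -spec.b + 2.0 * spec.b * u[spike]
    neg = (~spike) & (comp < spec.p0 + (1.0 - spec.p0) / 2.0)
    out[neg] = -spec.l + (spec.l - spec.b) * u[neg]
    pos = (~spike) & (~neg)
    out[pos] = spec.b + (spec.l - spec.b) * u[pos]
    return out


def mu_variance(spec: MUPriorSpec) -> float:
    """Closed-form prior variance (1/3)[b^2 + l(l+b)(1-p0)]."""
    return (spec.b ** 2 + spec.l * (spec.l + spec.b) * (1.0 - spec.p0)) / 3.0


def prior_h2_unstd(spec: MUPriorSpec, allele_freqs, V_P: float) -> float:
    """Prior heritability for centered (-1/0/1) genotype codes:
    2 Var(beta) sum f(1-f) / V_P.  Not clipped to (0, 1)."""
    if V_P <= 0:
        raise ValueError("V_P must be positive")
    f = np.asarray(allele_freqs, dtype=float)
    return 2.0 * mu_variance(spec) * float(np.sum(f * (1.0 - f))) / V_P


def prior_h2_std(spec: MUPriorSpec, M: int, V_P: float) -> float:
    """Prior heritability for standardized genotype codes: Var(beta) M / V_P."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if V_P <= 0:
        raise ValueError("V_P must be positive")
    return mu_variance(spec) * M / V_P


def prior_mean_nq(spec: MUPriorSpec, M: int) -> float:
    """Prior mean of the QTL count N_Q = sum_m I(|beta_m| >= b): M(1-p0)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return M * (1.0 - spec.p0)


def qtlmas_prior_specs() -> list[MUPriorSpec]:
    """The four canonical prior specifications for a QTLMAS-style
    analysis on the standardized scale: (p0, b) in
    {0.99, 0.999} x {0.01, 0.001} with l = 1.

    The same numbers read as phenotypic-standard-deviation units on the
    raw scale (l = sd(Y)); use ``MUPriorSpec.scaled`` to convert.
    """
    return [MUPriorSpec(p0, b, 1.0)
            for p0 in (0.99, 0.999) for b in (0.01, 0.001)]
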