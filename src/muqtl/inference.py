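"""Marker-association inference from Gibbs chains.

Per-marker evidence is summarized by the posterior inclusion
probability P(S_m = 1 | data) with S_m = I(b <= |beta_m| <= l), the
Bayes factor obtained by dividing the posterior odds of inclusion by
the prior odds (1 - p0)/p0, Kass-Raftery evidence categories on
2 ln BF, the percentage of phenotypic variance explained
2 MAF (1 - MAF) E[beta^2] / var(Y), and the whole-model summaries
N_Q = sum_m S_m and h_M^2 = 1 - (sigma^2 + 2 sigma_u^2)/var(Y) (the
factor 2 because the additive genetic covariance between full sibs is
one half).  Cross-chain robustness is measured by Spearman rank
correlations and mean ratios of 2 ln BF over a marker subset, and
consensus across chains by marker-specific mean ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .data import GenotypePanel, minor_allele_freq
from .gibbs import ChainSamples

#: Kass-Raftery evidence categories on 2 ln BF (upper bounds closed).
EVIDENCE_BOUNDS = ((10.0, "very strong"), (6.0, "strong"),
                   (2.0, "positive"), (0.0, "bare mention"))


def inclusion_prob(chain: ChainSamples, m: int = None, clip: bool = True):
    """Posterior fraction of draws with b <= |beta_m| <= l, clipped to
    [1/(2T), 1 - 1/(2T)] so that odds are finite."""
    if chain.n_stored == 0:
        raise ValueError("empty chain")
    S = chain.S if chain.S.size else (
        (np.abs(chain.beta) >= chain.spec.b) &
        (np.abs(chain.beta) <= chain.spec.l)).astype(float)
    p = S.mean(axis=0) if m is None else float(S[:, m].mean())
    if clip:
        lo = 1.0 / (2.0 * chain.n_stored)
        p = np.clip(p, lo, 1.0 - lo)
    return p


def bayes_factor(p_incl, p0: float):
    """BF = posterior odds of inclusion / prior odds (1-p0)/p0."""
    p = np.asarray(p_incl, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p_incl must be strictly inside (0, 1); clip it first")
    prior_odds = (1.0 - p0) / p0
    bf = (p / (1.0 - p)) / prior_odds
    return float(bf) if bf.ndim == 0 else bf


def evidence_category(two_ln_bf: float) -> str:
    """Kass-Raftery label for a 2 ln BF value."""
    for bound, label in EVIDENCE_BOUNDS:
        if two_ln_bf > bound:
            return label
    return "none"


def nq_summary(chain: ChainSamples):
    """Posterior mean and sd of N_Q = sum_m S_m."""
    if not chain.S.size:
        raise ValueError("indicators were not stored for this chain")
    nq = chain.S.sum(axis=1)
    return float(nq.mean()), float(nq.std())


def marker_h2(chain: ChainSamples, var_y: float):
    """Posterior mean and sd of h_M^2 = 1 - (sigma^2 + 2 sigma_u^2)/var(Y)."""
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    h = 1.0 - (chain.sigma2 + 2.0 * chain.sigma2_u) / var_y
    return float(h.mean()), float(h.std())


def pve(chain: ChainSamples, maf: np.ndarray, var_y: float) -> np.ndarray:
    """Per-marker posterior mean percentage of phenotypic variance
    explained: 2 MAF (1 - MAF) E_post[beta^2] / var(Y), in percent.

    Uses the posterior mean of beta^2, not the squared posterior mean.
    Summing over markers does not recover h_M^2 because LD covariances
    between markers are not included.
    """
    maf = np.asarray(maf, dtype=float)
    eb2 = (chain.beta ** 2).mean(axis=0)
    return 100.0 * 2.0 * maf * (1.0 - maf) * eb2 / var_y


def marker_report(chain: ChainSamples, panel: GenotypePanel = None,
                  var_y: float = 1.0, maf: np.ndarray = None) -> pd.DataFrame:
    """Assemble the per-marker posterior summary table."""
    p = inclusion_prob(chain)
    bf = bayes_factor(p, chain.spec.p0)
    two_ln = 2.0 * np.log(bf)
    if maf is None and panel is not None:
        maf = minor_allele_freq(panel) if panel.coding in ("raw", "centered") else None
    df = pd.DataFrame({
        "marker": panel.marker_ids if panel is not None
        else np.arange(chain.n_markers),
        "chrom": panel.chrom if panel is not None else 0,
        "pos_cM": panel.pos_cM if panel is not None else np.arange(chain.n_markers),
        "p_incl": p,
        "bf": bf,
        "two_ln_bf": two_ln,
        "beta_mean": chain.beta.mean(axis=0),
        "beta_sd": chain.beta.std(axis=0),
    })
    df["category"] = [evidence_category(v) for v in two_ln]
    if maf is not None:
        df["pve"] = pve(chain, maf, var_y)
    return df


def mean_rank_consensus(bf_tables: list[np.ndarray],
                        marker_ids=None) -> pd.DataFrame:
    """Consensus over chains: rank markers by descending 2 ln BF within
    each chain (average ranks on ties), then average the ranks across
    chains; also report the across-chain mean/min/max of 2 ln BF.

    The result is sorted by ascending mean rank (strongest first).
    """
    arr = np.asarray(bf_tables, dtype=float)
    if arr.ndim != 2:
        raise ValueError("need a list of equal-length 2lnBF vectors")
    ranks = np.vstack([rankdata(-row, method="average") for row in arr])
    df = pd.DataFrame({
        "marker": marker_ids if marker_ids is not None
        else np.arange(arr.shape[1]),
        "mean_rank": ranks.mean(axis=0),
        "avg_2lnbf": arr.mean(axis=0),
        "min_2lnbf": arr.min(axis=0),
        "max_2lnbf": arr.max(axis=0),
    })
    return df.sort_values("mean_rank", kind="stable").reset_index(drop=True)


@dataclass
class ChainComparison:
    """Pairwise robustness measures between chains over a marker subset.

    ``rank_corr[i, j]`` is the Spearman rank correlation of the subset's
    2 ln BF between chains i and j (symmetric, NaN diagonal);
    ``mean_ratio[i, j]`` is the mean over the subset of
    2lnBF(chain i) / 2lnBF(chain j) (unit diagonal).
    """

    rank_corr: np.ndarray
    mean_ratio: np.ndarray
    subset: np.ndarray


def chain_comparison(bf_tables: list[np.ndarray], subset) -> ChainComparison:
    """Compare chains' 2 ln BF values on a marker subset."""
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("marker subset must be non-empty")
    arr = np.asarray(bf_tables, dtype=float)[:, subset]
    if np.any(arr <= 0):
        raise ValueError("all 2lnBF on the subset must be positive for "
                         "ratio computation; choose a signal subset")
    C = arr.shape[0]
    rho = np.full((C, C), np.nan)
    ratio = np.ones((C, C))
    for i in range(C):
        for j in range(C):
            if i == j:
                continue
            rho[i, j] = spearmanr(arr[i], arr[j]).statistic
            ratio[i, j] = float(np.mean(arr[i] / arr[j]))
    return ChainComparison(rank_corr=rho, mean_ratio=ratio, subset=subset)
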