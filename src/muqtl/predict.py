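"""Genomic prediction: GEBV, accuracy/bias metrics, cross-validation.

GEBV_i = sum_m beta_hat_m x_im is the linear marker score (estimated
family effects are not carried into prediction).  Predictive ability is
measured by the Pearson correlation of GEBV with true breeding values
(simulated data) or with phenotypes divided by sqrt(h^2)
(cross-validation); by the Spearman rank correlation within the top
decile of TBV; and by the regression slope of the target on GEBV
(1 = unbiased).  Two 10-fold CV layouts are supported: whole full-sib
families per fold, or sibs of each family spread across folds.
Sure independence screening (SIS) pre-selects markers by ranked
absolute marginal correlation with the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .data import (FamilyMap, GenotypePanel, PhenotypeSet, maf_filter,
                   minor_allele_freq, standardize_fit)
from .gem import gem_fit
from .gibbs import GibbsConfig, run_gibbs
from .prior import HyperConfig, MUPriorSpec

CV_SCHEMES = ("family_blocked", "within_family", "random_individual")


def gebv(beta_hat: np.ndarray, panel: GenotypePanel, fit_coding: str = None) -> np.ndarray:
    """Linear marker score per individual, sum_m beta_hat_m x_im.

    ``fit_coding`` guards against scale mismatches: if given, the panel
    must be in the same coding the effects were estimated in.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_hat.shape[0] != panel.n_markers:
        raise ValueError("effect vector length does not match panel")
    if fit_coding is not None and panel.coding != fit_coding:
        raise ValueError(f"effects were fitted on {fit_coding!r} codes but the "
                         f"panel is {panel.coding!r}; recode/standardize first")
    return panel.dosage @ beta_hat


def accuracy_tbv(gebv_vec: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between GEBV and true breeding values."""
    gebv_vec = np.asarray(gebv_vec, float)
    tbv = np.asarray(tbv, float)
    if gebv_vec.shape[0] != tbv.shape[0] or gebv_vec.shape[0] < 3:
        raise ValueError("need matched vectors of length >= 3")
    if gebv_vec.std() == 0 or tbv.std() == 0:
        raise ValueError("zero variance input")
    return float(pearsonr(gebv_vec, tbv).statistic)


def accuracy_cv(gebv_vec: np.ndarray, phenotype: np.ndarray, h2: float) -> float:
    """cor(GEBV, phenotype) / sqrt(h2): the CV estimate of accuracy."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    return accuracy_tbv(gebv_vec, phenotype) / np.sqrt(h2)


def top_decile_rank_corr(gebv_vec: np.ndarray, tbv: np.ndarray) -> float:
    """Spearman rank correlation of GEBV vs TBV among the ceil(N/10)
    individuals with the largest TBV (ties broken by stable index order)."""
    gebv_vec = np.asarray(gebv_vec, float)
    tbv = np.asarray(tbv, float)
    n = tbv.shape[0]
    if n < 10:
        raise ValueError("need at least 10 individuals")
    k = int(np.ceil(n / 10.0))
    top = np.argsort(-tbv, kind="stable")[:k]
    return float(spearmanr(gebv_vec[top], tbv[top]).statistic)


def bias(gebv_vec: np.ndarray, target: np.ndarray) -> float:
    """Least-squares slope of regressing the target on GEBV (1 = unbiased)."""
    gebv_vec = np.asarray(gebv_vec, float)
    target = np.asarray(target, float)
    v = gebv_vec.var()
    if v <= 0:
        raise ValueError("GEBV have zero variance")
    return float(np.cov(gebv_vec, target)[0, 1] / gebv_vec.var(ddof=1))


def average_gebv(per_spec_gebv: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean across prior specifications (equal weights)."""
    arr = np.asarray(per_spec_gebv, dtype=float)
    return arr.mean(axis=0)


def sis_select(panel: GenotypePanel, y: np.ndarray, k: int,
               min_maf: float = 0.05) -> np.ndarray:
    """Sure independence screening: MAF-filter, rank markers by absolute
    marginal Pearson correlation with the phenotype, return the top-k
    marker ids.  Rankings are nested: top-k' for k' < k is a subset."""
    filtered, _ = maf_filter(panel, min_maf)
    if k > filtered.n_markers:
        raise ValueError(f"k={k} exceeds {filtered.n_markers} markers after "
                         "MAF filtering")
    y = np.asarray(y, float)
    Xc = filtered.dosage - filtered.dosage.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = np.abs(Xc.T @ yc) / denom
    cors = np.nan_to_num(cors)
    order = np.argsort(-cors, kind="stable")[:k]
    return filtered.marker_ids[order]


@dataclass
class CVPlan:
    scheme: str
    folds: np.ndarray  # fold index per individual
    seed: int = 0
    n_folds: int = 10


def make_cv_plan(fam: FamilyMap, scheme: str, seed: int = 0,
                 n_folds: int = 10) -> CVPlan:
    """Partition individuals into folds.

    ``family_blocked`` keeps each full-sib family whole within one fold
    (with 450 families of 10 and 10 folds: 45 families per fold);
    ``within_family`` spreads each family's members over distinct folds
    (requires family sizes <= n_folds); ``random_individual`` ignores
    families.
    """
    if scheme not in CV_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n = fam.n
    folds = np.empty(n, dtype=int)
    if scheme == "family_blocked":
        fam_ids = rng.permutation(fam.n_families)
        assignment = {f: i % n_folds for i, f in enumerate(fam_ids)}
        folds = np.array([assignment[c] for c in fam.codes])
    elif scheme == "within_family":
        if fam.sizes.max() > n_folds:
            raise ValueError(f"family of size {fam.sizes.max()} cannot be "
                             f"spread over {n_folds} folds")
        for k in range(fam.n_families):
            members = np.flatnonzero(fam.codes == k)
            slots = rng.permutation(n_folds)[:members.size]
            folds[members] = slots
    else:
        folds = rng.permutation(n) % n_folds
    return CVPlan(scheme=scheme, folds=folds, seed=seed, n_folds=n_folds)


@dataclass
class PredictionReport:
    gebv: np.ndarray                   # combined GEBV (original y scale)
    per_spec_gebv: np.ndarray          # (n_specs, N)
    accuracy: float
    bias: float
    per_spec_accuracy: np.ndarray
    per_spec_bias: np.ndarray
    specs: list = field(default_factory=list)
    dropped_markers: dict = field(default_factory=dict)


def _fit_beta(panel_std, phen_std, spec, hyper, fitter, gibbs_cfg):
    if fitter == "gem":
        res = gem_fit(panel_std, phen_std, spec, hyper)
        return res.state.beta
    if fitter == "gibbs":
        chain = run_gibbs(panel_std, phen_std, spec, hyper, gibbs_cfg)
        return chain.beta.mean(axis=0)
    raise ValueError(f"unknown fitter {fitter!r}")


def run_cv(panel: GenotypePanel, phen: PhenotypeSet, specs: list[MUPriorSpec],
           plan: CVPlan, fitter: str = "gem", h2: float = 0.30,
           hyper: HyperConfig = None, gibbs_cfg: GibbsConfig = None,
           sis_k: int = None, sis_min_maf: float = 0.05,
           leaky_sis: bool = False) -> PredictionReport:
    """10-fold cross-validation of GEBV.

    For each fold the other folds form the training set; genotype
    columns and the phenotype are standardized on the training set only,
    effects are fitted per prior specification (given on the
    standardized scale), and held-out GEBV are computed with training
    scaling constants and translated back to the original phenotype
    scale.  Markers monomorphic within a training fold are dropped for
    that fold.  If ``sis_k`` is set, SIS pre-selection runs inside each
    training fold; ``leaky_sis=True`` reproduces the screening-on-all-
    individuals shortcut, which leaks validation information and tends
    to inflate accuracy.
    """
    hyper = hyper or HyperConfig()
    n = panel.n_individuals
    if plan.folds.shape[0] != n:
        raise ValueError("CV plan does not cover the panel")
    specs = list(specs)
    per_spec = np.zeros((len(specs), n))
    dropped = {}

    leaky_ids = None
    if sis_k is not None and leaky_sis:
        leaky_ids = set(sis_select(panel, phen.y, sis_k, sis_min_maf))

    for fold in range(plan.n_folds):
        val = plan.folds == fold
        train = ~val
        sub = replace(panel, dosage=panel.dosage[train])
        # drop markers with no variation in this training fold
        sds = sub.dosage.std(axis=0)
        keep = sds > 0
        if sis_k is not None:
            ids = leaky_ids if leaky_sis else set(
                sis_select(sub, phen.y[train], sis_k, sis_min_maf))
            keep &= np.isin(panel.marker_ids, list(ids))
        if not keep.all():
            dropped[fold] = panel.marker_ids[~keep & (sds <= 0)].tolist()
        sub = replace(sub, dosage=sub.dosage[:, keep],
                      marker_ids=panel.marker_ids[keep],
                      chrom=panel.chrom[keep], pos_cM=panel.pos_cM[keep])
        phen_train = PhenotypeSet(phen.y[train])
        sub_std, phen_std, scaling = standardize_fit(sub, phen_train)
        val_panel = replace(panel, dosage=panel.dosage[val][:, keep],
                            marker_ids=panel.marker_ids[keep],
                            chrom=panel.chrom[keep], pos_cM=panel.pos_cM[keep])
        val_std = scaling.transform_panel(val_panel)
        for si, spec in enumerate(specs):
            beta_hat = _fit_beta(sub_std, phen_std, spec, hyper, fitter, gibbs_cfg)
            g_std = gebv(beta_hat, val_std, fit_coding="standardized")
            per_spec[si, val] = g_std * scaling.y_sd  # back to trait units

    combined = average_gebv(per_spec)
    acc = np.array([accuracy_cv(per_spec[si], phen.y, h2)
                    for si in range(len(specs))])
    bs = np.array([bias(per_spec[si], phen.y) for si in range(len(specs))])
    return PredictionReport(
        gebv=combined, per_spec_gebv=per_spec,
        accuracy=accuracy_cv(combined, phen.y, h2),
        bias=bias(combined, phen.y),
        per_spec_accuracy=acc, per_spec_bias=bs,
        specs=specs, dropped_markers=dropped)
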