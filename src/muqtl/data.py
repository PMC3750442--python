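"""Core data containers: genotype panels, phenotypes, families, scaling.

Genotype dosages are held as a dense N x M float matrix in one of three
codings: ``raw`` counts of the reference allele (0/1/2, imputed values
anywhere in [0, 2]), ``centered`` (raw - 1, the -1/0/1 coding used for
additive effects), or ``standardized`` (each column scaled to sample
mean 0 and variance 1).  Standardization uses the population (1/N)
variance convention so "variance of 1" is exact on the training set.
Missing dosages are not supported; inputs are expected pre-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

CODINGS = ("raw", "centered", "standardized")


@dataclass
class GenotypePanel:
    """An N x M genotype dosage matrix with marker metadata."""

    dosage: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray = None
    pos_cM: np.ndarray = None
    coding: str = "raw"
    col_means: np.ndarray = None
    col_sds: np.ndarray = None
    source_coding: str = None  # coding before standardization

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2 or self.dosage.shape[0] < 1 or self.dosage.shape[1] < 1:
            raise ValueError("dosage must be a non-empty N x M matrix")
        if not np.all(np.isfinite(self.dosage)):
            raise ValueError("dosage contains non-finite values (missing genotypes "
                             "must be imputed before constructing a panel)")
        self.marker_ids = np.asarray(self.marker_ids)
        if self.marker_ids.shape[0] != self.dosage.shape[1]:
            raise ValueError("marker_ids length must equal number of markers")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.coding == "raw" and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise ValueError("raw dosages must lie in [0, 2]")
        if self.chrom is None:
            self.chrom = np.zeros(self.n_markers, dtype=int)
        else:
            self.chrom = np.asarray(self.chrom, dtype=int)
        if self.pos_cM is None:
            self.pos_cM = np.arange(self.n_markers, dtype=float)
        else:
            self.pos_cM = np.asarray(self.pos_cM, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]


@dataclass
class PhenotypeSet:
    """A single quantitative trait, optionally standardized."""

    y: np.ndarray
    standardized: bool = False
    y_mean: float = None
    y_sd: float = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotypes contain non-finite values")

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class FamilyMap:
    """Assignment of each individual to exactly one full-sib family."""

    family_of: np.ndarray

    def __post_init__(self):
        self.family_of = np.asarray(self.family_of, dtype=int).ravel()
        uniq = np.unique(self.family_of)
        self._index = {f: i for i, f in enumerate(uniq)}
        self.codes = np.array([self._index[f] for f in self.family_of])
        self.sizes = np.bincount(self.codes)

    @property
    def n_families(self) -> int:
        return self.sizes.shape[0]

    @property
    def n(self) -> int:
        return self.family_of.shape[0]


@dataclass
class ScalingRecord:
    """Training-set scaling constants, used to transform held-out data
    with training statistics and to translate predictions back to the
    original scale."""

    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    y_sd: float
    source_coding: str = "raw"

    def transform_panel(self, panel: GenotypePanel) -> GenotypePanel:
        if panel.coding != self.source_coding:
            panel = recode(panel, self.source_coding)
        z = (panel.dosage - self.x_means) / self.x_sds
        return replace(panel, dosage=z, coding="standardized",
                       col_means=self.x_means.copy(), col_sds=self.x_sds.copy())

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def inverse_transform_y(self, y_std: np.ndarray) -> np.ndarray:
        return np.asarray(y_std, dtype=float) * self.y_sd + self.y_mean


def recode(panel: GenotypePanel, target: str) -> GenotypePanel:
    """Convert a panel between codings (raw <-> centered is a shift by 1)."""
    if target not in CODINGS:
        raise ValueError(f"unknown coding {target!r}")
    if panel.coding == target:
        return panel
    if panel.coding == "raw" and target == "centered":
        return replace(panel, dosage=panel.dosage - 1.0, coding="centered")
    if panel.coding == "centered" and target == "raw":
        return replace(panel, dosage=panel.dosage + 1.0, coding="raw")
    if panel.coding == "standardized":
        if panel.col_means is None or panel.col_sds is None:
            raise ValueError("cannot undo standardization: column means/sds "
                             "were not recorded on this panel")
        back = panel.dosage * panel.col_sds + panel.col_means
        src = panel.source_coding or "raw"
        out = replace(panel, dosage=back, coding=src,
                      col_means=None, col_sds=None, source_coding=None)
        return recode(out, target) if out.coding != target else out
    raise ValueError(f"cannot recode {panel.coding} -> {target} directly; "
                     "standardize via standardize_fit")


def standardize_fit(panel: GenotypePanel, phen: PhenotypeSet):
    """Standardize genotype columns and the phenotype to mean 0, variance 1
    (population convention) on this panel, recording the constants.

    Returns ``(panel_std, phen_std, scaling)``.  Apply ``scaling`` to
    held-out data so that validation individuals are transformed with
    training statistics.
    """
    if panel.coding == "standardized":
        raise ValueError("panel is already standardized")
    means = panel.dosage.mean(axis=0)
    sds = panel.dosage.std(axis=0)  # 1/N convention
    if np.any(sds <= 0):
        bad = panel.marker_ids[sds <= 0]
        raise ValueError(f"monomorphic marker(s) with zero sd: {bad[:5]}... "
                         "remove them with maf_filter before standardizing")
    y_mean = float(phen.y.mean())
    y_sd = float(phen.y.std())
    if y_sd <= 0:
        raise ValueError("phenotype has zero variance")
    scaling = ScalingRecord(means, sds, y_mean, y_sd, source_coding=panel.coding)
    panel_std = replace(panel, dosage=(panel.dosage - means) / sds,
                        coding="standardized", col_means=means, col_sds=sds,
                        source_coding=panel.coding)
    phen_std = PhenotypeSet((phen.y - y_mean) / y_sd, standardized=True,
                            y_mean=y_mean, y_sd=y_sd)
    return panel_std, phen_std, scaling


def minor_allele_freq(panel: GenotypePanel) -> np.ndarray:
    """Per-marker minor allele frequency; non-integer imputed dosages
    contribute fractionally through the mean dosage."""
    if panel.coding == "raw":
        p = panel.dosage.mean(axis=0) / 2.0
    elif panel.coding == "centered":
        p = (panel.dosage.mean(axis=0) + 1.0) / 2.0
    else:
        raise ValueError("MAF requires raw or centered coding")
    return np.minimum(p, 1.0 - p)


def maf_filter(panel: GenotypePanel, min_maf: float):
    """Remove markers with MAF below ``min_maf``.

    Returns ``(filtered_panel, removed_ids)``.
    """
    maf = minor_allele_freq(panel)
    keep = maf >= min_maf
    removed = panel.marker_ids[~keep]
    out = replace(panel,
                  dosage=panel.dosage[:, keep],
                  marker_ids=panel.marker_ids[keep],
                  chrom=panel.chrom[keep],
                  pos_cM=panel.pos_cM[keep])
    return out, removed
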