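"""Pedigree-based synthetic data emulating the QTLMAS XII design.

A multi-generation sire x dam pedigree of full-sib families is gene-
dropped over a dense, equidistant bi-allelic SNP map.  Founder
haplotypes are drawn per marker at allele frequencies uniform over
``founder_maf_range`` (linkage equilibrium in founders); meioses follow
Haldane's no-interference model, with recombination fraction
r = (1 - exp(-2d))/2 between adjacent markers at map distance d Morgan,
so within-family linkage disequilibrium builds up through the pedigree.
A chosen number of markers act as additive QTL; true breeding values
are TBV_i = sum_q a_q x_iq on the centered (-1/0/1) coding, and the
residual variance is solved so that

    var(TBV) / (var(TBV) + family_env_var + sigma_e^2) = target_h2

on the realized training sample.  Phenotypes are mu + TBV +
family_env + N(0, sigma_e^2); validation generations carry genotypes
and TBV but their phenotypes are withheld.

The full-scale preset mirrors the published design (15 sires x 10 dams
x 10 offspring per generation, 3 training generations, 6 chromosomes x
1000 markers at 0.1 cM, h^2 = 0.30); the desk-scale preset shrinks this
to 15 sires x 6 dams x 6 offspring, one training and one validation
generation, 2 chromosomes x 250 markers, 10 QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FamilyMap, GenotypePanel, PhenotypeSet


@dataclass
class SimConfig:
    n_sires: int = 15
    n_dams_per_sire: int = 6
    n_offspring_per_mating: int = 6
    n_generations_train: int = 1
    n_generations_validate: int = 1
    n_chrom: int = 2
    markers_per_chrom: int = 250
    spacing_cM: float = 0.1
    n_qtl: int = 10
    qtl_effect_sd: float = 1.0
    qtl_effects: np.ndarray = None      # optional fixed effects
    target_h2: float = 0.30
    family_env_var: float = 0.0
    founder_maf_range: tuple = (0.05, 0.5)
    mu: float = 0.0
    seed: int = 0
    keep_haplotypes: bool = False  # store phased haplotypes in the truth

    def __post_init__(self):
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError("target_h2 must lie in [0, 1)")
        if self.spacing_cM <= 0:
            raise ValueError("spacing_cM must be positive")
        if self.n_qtl > self.n_chrom * self.markers_per_chrom:
            raise ValueError("more QTL than markers")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom

    @property
    def offspring_per_generation(self) -> int:
        return self.n_sires * self.n_dams_per_sire * self.n_offspring_per_mating


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray                  # training individuals
    realized_h2: float
    pedigree: np.ndarray             # (n, 2) parent row indices, -1 founders
    generation: np.ndarray           # per training individual
    sigma_e2: float = 0.0
    val_panel: GenotypePanel = None  # validation generations (phenotypes withheld)
    val_tbv: np.ndarray = None
    val_generation: np.ndarray = None
    haplotypes: np.ndarray = None    # (n_total, 2, M) phased alleles, optional
    train_rows: np.ndarray = None    # rows of `haplotypes` in the panel


def _meiosis(hap_a, hap_b, chrom_starts, r_adj, rng):
    """One gamete per parent: choose a starting haplotype per chromosome,
    then switch at Haldane crossover events between adjacent markers."""
    M = hap_a.shape[0]
    cross = rng.random(M) < r_adj           # r_adj[m]: interval (m-1, m)
    cross[chrom_starts] = False
    start = np.zeros(M, dtype=bool)
    start[chrom_starts] = rng.random(chrom_starts.size) < 0.5
    # cumulative XOR of crossovers within a chromosome gives the source
    out = np.empty(M, dtype=hap_a.dtype)
    for c0, c1 in zip(chrom_starts, np.append(chrom_starts[1:], M)):
        seg_cross = cross[c0:c1].copy()
        seg_cross[0] = False
        src = np.logical_xor.accumulate(seg_cross) ^ start[c0]
        out[c0:c1] = np.where(src, hap_b[c0:c1], hap_a[c0:c1])
    return out


def simulate_population(cfg: SimConfig):
    """Gene-drop a pedigree and return
    ``(GenotypePanel, PhenotypeSet, FamilyMap, SimTruth)`` for the
    training individuals; validation generations live inside the truth
    object.  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    M = cfg.n_markers
    chrom = np.repeat(np.arange(1, cfg.n_chrom + 1), cfg.markers_per_chrom)
    pos = np.tile(np.arange(cfg.markers_per_chrom) * cfg.spacing_cM, cfg.n_chrom)
    chrom_starts = np.arange(cfg.n_chrom) * cfg.markers_per_chrom
    d_morgan = np.empty(M)
    d_morgan[:] = cfg.spacing_cM / 100.0
    r_adj = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    r_adj[chrom_starts] = 0.5  # unlinked across chromosomes (unused: reset)

    lo, hi = cfg.founder_maf_range
    freqs = rng.uniform(lo, hi, M)

    n_dams = cfg.n_sires * cfg.n_dams_per_sire
    n_founders = cfg.n_sires + n_dams
    # haplotypes: (individual, 2, M) of 0/1 alleles
    founder_haps = (rng.random((n_founders, 2, M)) < freqs).astype(np.int8)

    haps = [founder_haps]
    parents = [np.full((n_founders, 2), -1, dtype=int)]
    gen_of = [np.zeros(n_founders, dtype=int)]
    fam_of = [np.full(n_founders, -1, dtype=int)]
    sex = [np.concatenate([np.zeros(cfg.n_sires, dtype=int),
                           np.ones(n_dams, dtype=int)])]  # 0 male, 1 female

    n_generations = cfg.n_generations_train + cfg.n_generations_validate
    offset = 0          # row offset of the previous generation
    fam_counter = 0
    for g in range(1, n_generations + 1):
        prev_haps = haps[-1]
        prev_sex = sex[-1]
        males = np.flatnonzero(prev_sex == 0)
        females = np.flatnonzero(prev_sex == 1)
        if males.size < cfg.n_sires or females.size < n_dams:
            raise ValueError("not enough parents of each sex in generation "
                             f"{g - 1}")
        sires = rng.choice(males, cfg.n_sires, replace=False)
        dams = rng.choice(females, n_dams, replace=False)
        n_off = cfg.offspring_per_generation
        off_haps = np.empty((n_off, 2, M), dtype=np.int8)
        off_parents = np.empty((n_off, 2), dtype=int)
        off_fam = np.empty(n_off, dtype=int)
        i = 0
        for si, s in enumerate(sires):
            for dj in range(cfg.n_dams_per_sire):
                d = dams[si * cfg.n_dams_per_sire + dj]
                for _ in range(cfg.n_offspring_per_mating):
                    off_haps[i, 0] = _meiosis(prev_haps[s, 0], prev_haps[s, 1],
                                              chrom_starts, r_adj, rng)
                    off_haps[i, 1] = _meiosis(prev_haps[d, 0], prev_haps[d, 1],
                                              chrom_starts, r_adj, rng)
                    off_parents[i] = (offset + s, offset + d)
                    off_fam[i] = fam_counter
                    i += 1
                fam_counter += 1
        haps.append(off_haps)
        parents.append(off_parents)
        gen_of.append(np.full(n_off, g, dtype=int))
        fam_of.append(off_fam)
        sex.append(rng.integers(0, 2, n_off))
        offset += prev_haps.shape[0]

    all_haps = np.concatenate(haps, axis=0)
    all_parents = np.concatenate(parents, axis=0)
    all_gen = np.concatenate(gen_of)
    all_fam = np.concatenate(fam_of)

    dosage_raw = all_haps.sum(axis=1).astype(float)       # 0/1/2
    centered = dosage_raw - 1.0

    # genetic architecture
    qtl_idx = np.sort(rng.choice(M, cfg.n_qtl, replace=False))
    if cfg.qtl_effects is not None:
        effects = np.asarray(cfg.qtl_effects, dtype=float)
        if effects.shape[0] != cfg.n_qtl:
            raise ValueError("qtl_effects length must equal n_qtl")
    else:
        effects = rng.normal(0.0, cfg.qtl_effect_sd, cfg.n_qtl)
    tbv_all = centered[:, qtl_idx] @ effects

    train_mask = (all_gen >= 1) & (all_gen <= cfg.n_generations_train)
    val_mask = all_gen > cfg.n_generations_train

    v_g = float(np.var(tbv_all[train_mask]))
    if cfg.target_h2 == 0.0 or v_g == 0.0:
        effects = np.zeros_like(effects)
        tbv_all = np.zeros_like(tbv_all)
        sigma_e2 = 1.0
    else:
        sigma_e2 = v_g * (1.0 - cfg.target_h2) / cfg.target_h2 - cfg.family_env_var
        if sigma_e2 <= 0:
            raise ValueError("family_env_var too large for the requested "
                             "heritability; no positive residual variance exists")

    fam_env = np.zeros(all_haps.shape[0])
    if cfg.family_env_var > 0:
        env_by_family = rng.normal(0.0, np.sqrt(cfg.family_env_var),
                                   int(all_fam.max()) + 1)
        has_fam = all_fam >= 0
        fam_env[has_fam] = env_by_family[all_fam[has_fam]]

    y_all = cfg.mu + tbv_all + fam_env + rng.normal(0.0, np.sqrt(sigma_e2),
                                                    all_haps.shape[0])

    marker_ids = np.array([f"c{c}m{i + 1}" for c, i in
                           zip(chrom, np.tile(np.arange(cfg.markers_per_chrom),
                                              cfg.n_chrom))])
    panel = GenotypePanel(dosage_raw[train_mask], marker_ids, chrom, pos,
                          coding="raw")
    phen = PhenotypeSet(y_all[train_mask])
    fam = FamilyMap(all_fam[train_mask])
    vy = float(np.var(y_all[train_mask]))
    truth = SimTruth(
        qtl_indices=qtl_idx, qtl_effects=effects,
        tbv=tbv_all[train_mask],
        realized_h2=float(np.var(tbv_all[train_mask]) / vy) if vy > 0 else 0.0,
        pedigree=all_parents, generation=all_gen[train_mask],
        sigma_e2=sigma_e2,
        val_panel=GenotypePanel(dosage_raw[val_mask], marker_ids, chrom, pos,
                                coding="raw") if val_mask.any() else None,
        val_tbv=tbv_all[val_mask] if val_mask.any() else None,
        val_generation=all_gen[val_mask] if val_mask.any() else None,
        haplotypes=all_haps if cfg.keep_haplotypes else None,
        train_rows=np.flatnonzero(train_mask) if cfg.keep_haplotypes else None,
    )
    return panel, phen, fam, truth


def desk_preset(seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale QTLMAS-like design: 540 training individuals in 90
    full-sib families, 500 markers on 2 chromosomes, 10 QTL, h^2 = 0.30."""
    kw = dict(n_sires=15, n_dams_per_sire=6, n_offspring_per_mating=6,
              n_generations_train=1, n_generations_validate=1,
              n_chrom=2, markers_per_chrom=250, spacing_cM=0.1,
              n_qtl=10, target_h2=0.30, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def qtlmas_like_preset(seed: int = 0, desk: bool = False, **overrides) -> SimConfig:
    """Full-scale preset mirroring the published design (6000 markers,
    1500 offspring per generation, h^2 = 0.30), or the desk-scale
    variant with ``desk=True``."""
    if desk:
        return desk_preset(seed=seed, **overrides)
    kw = dict(n_sires=15, n_dams_per_sire=10, n_offspring_per_mating=10,
              n_generations_train=3, n_generations_validate=3,
              n_chrom=6, markers_per_chrom=1000, spacing_cM=0.1,
              n_qtl=50, target_h2=0.30, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)
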