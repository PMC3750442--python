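"""File formats and run configuration.

Text formats only: TSV genotype matrices (one header row of marker ids,
one row per individual, first column ``id``), the PLINK RAW additive-
dosage dialect, two-column phenotype and family TSVs, an optional
marker map TSV, TSV result tables, and JSON run manifests.  Chain
output is stored as a compressed .npz container (one array per
parameter group) next to a TSV of per-marker posterior summaries.
Floats are serialized at full precision with '.' decimals so writer
output round-trips exactly through the readers.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import FamilyMap, GenotypePanel, PhenotypeSet
from .gibbs import ChainSamples, GibbsConfig
from .prior import HyperConfig, MUPriorSpec

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------- readers

def read_genotypes_tsv(path) -> GenotypePanel:
    """Delimited genotype matrix: header of marker ids, ``id`` first column."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0].lower() != "id":
        raise ValueError(f"{path}: first column must be 'id', got "
                         f"{df.columns[0]!r}")
    ids = df.columns[1:].to_numpy()
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    coding = "centered" if dosage.min() < 0 else "raw"
    panel = GenotypePanel(dosage, ids, coding=coding)
    panel.individual_ids = df.iloc[:, 0].astype(str).to_numpy()
    return panel


def read_plink_raw(path):
    """PLINK RAW additive dosages (header FID IID PAT MAT SEX PHENOTYPE
    snp1_A ...).  Returns (GenotypePanel, phenotype array or None);
    the _A allele suffix is stripped from marker names."""
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != expected:
        raise ValueError(f"{path}: not a PLINK RAW header (expected "
                         f"{expected}, got {list(df.columns[:6])})")
    snp_cols = df.columns[6:]
    ids = np.array([c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols])
    dosage = df[snp_cols].to_numpy(dtype=float)
    if np.isnan(dosage).any():
        raise ValueError(f"{path}: missing dosages present; impute first")
    panel = GenotypePanel(dosage, ids, coding="raw")
    panel.individual_ids = df["IID"].astype(str).to_numpy()
    phe = df["PHENOTYPE"].to_numpy(dtype=float)
    if np.all(phe == -9):
        phe = None
    return panel, phe


def read_phenotypes_tsv(path) -> PhenotypeSet:
    """Two-column TSV (id, value)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (id, value)")
    phen = PhenotypeSet(df.iloc[:, 1].to_numpy(dtype=float))
    phen.individual_ids = df.iloc[:, 0].astype(str).to_numpy()
    return phen


def read_families_tsv(path) -> FamilyMap:
    """Two-column TSV (id, family)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (id, family)")
    return FamilyMap(pd.factorize(df.iloc[:, 1])[0])


def read_marker_map_tsv(path) -> pd.DataFrame:
    """TSV (marker, chrom, pos_cM)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"marker", "chrom", "pos_cM"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: marker map needs columns {sorted(need)}")
    return df


# ---------------------------------------------------------------- writers

def write_genotypes_tsv(panel: GenotypePanel, path, individual_ids=None):
    ids = individual_ids if individual_ids is not None else \
        np.arange(1, panel.n_individuals + 1).astype(str)
    df = pd.DataFrame(panel.dosage, columns=panel.marker_ids)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_phenotypes_tsv(phen: PhenotypeSet, path, individual_ids=None):
    ids = individual_ids if individual_ids is not None else \
        np.arange(1, phen.n + 1).astype(str)
    pd.DataFrame({"id": ids, "value": phen.y}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_families_tsv(fam: FamilyMap, path, individual_ids=None):
    ids = individual_ids if individual_ids is not None else \
        np.arange(1, fam.n + 1).astype(str)
    pd.DataFrame({"id": ids, "family": fam.family_of}).to_csv(
        path, sep="\t", index=False)


def write_marker_map_tsv(panel: GenotypePanel, path):
    pd.DataFrame({"marker": panel.marker_ids, "chrom": panel.chrom,
                  "pos_cM": panel.pos_cM}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def save_chain(chain: ChainSamples, path):
    """Binary chain container: one array per parameter group."""
    np.savez_compressed(
        path, alpha=chain.alpha, beta=chain.beta, u=chain.u,
        sigma2=chain.sigma2, sigma2_u=chain.sigma2_u, S=chain.S,
        spec=np.array([chain.spec.p0, chain.spec.b, chain.spec.l]),
        meta=json.dumps(chain.meta))


def load_chain(path) -> ChainSamples:
    with np.load(path, allow_pickle=False) as z:
        spec = MUPriorSpec(*z["spec"].tolist())
        return ChainSamples(alpha=z["alpha"], beta=z["beta"], u=z["u"],
                            sigma2=z["sigma2"], sigma2_u=z["sigma2_u"],
                            S=z["S"], spec=spec,
                            meta=json.loads(str(z["meta"])))


def write_manifest(path, command: str, config: dict, seed, wall_time_s: float):
    from . import __version__
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "wall_time_s": wall_time_s,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Structured run configuration, readable from YAML."""

    genotypes: str = None
    phenotypes: str = None
    families: str = None
    marker_map: str = None
    out_dir: str = "muqtl_out"
    priors: list = field(default_factory=lambda: [[0.999, 0.01, 1.0]])
    hyper: dict = field(default_factory=dict)
    gibbs: dict = field(default_factory=dict)
    gem_tol_per_param: float = 1e-7
    gem_max_iter: int = 2000
    cv: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def prior_specs(self) -> list[MUPriorSpec]:
        return [MUPriorSpec(*map(float, p)) for p in self.priors]

    def hyper_config(self) -> HyperConfig:
        return HyperConfig(**self.hyper)

    def gibbs_config(self) -> GibbsConfig:
        kw = dict(self.gibbs)
        kw.setdefault("seed", self.seed)
        return GibbsConfig(**kw)

    def to_dict(self) -> dict:
        return asdict(self)
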