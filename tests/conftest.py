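import numpy as np
import pytest

from muqtl import (FamilyMap, GenotypePanel, PhenotypeSet, desk_preset,
                   maf_filter, simulate_population, standardize_fit)


@pytest.fixture(scope="session")
def desk_data():
    """One desk-scale QTLMAS-like simulation shared across tests."""
    panel, phen, fam, truth = simulate_population(desk_preset(seed=1))
    return panel, phen, fam, truth


@pytest.fixture(scope="session")
def desk_standardized(desk_data):
    panel, phen, fam, truth = desk_data
    panel_f, _ = maf_filter(panel, 0.01)
    panel_std, phen_std, scaling = standardize_fit(panel_f, phen)
    return panel_std, phen_std, fam, truth, panel_f, scaling


@pytest.fixture
def small_panel():
    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, (40, 12)).astype(float)
    return GenotypePanel(dosage, np.array([f"m{i}" for i in range(12)]),
                         coding="raw")


@pytest.fixture
def small_phen():
    rng = np.random.default_rng(8)
    return PhenotypeSet(rng.standard_normal(40))
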