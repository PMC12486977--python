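"""Shared fixtures: small simulated panels and milking data."""

import numpy as np
import pandas as pd
import pytest

from resilind.config import SimConfig
from resilind.plink import GenotypePanel
from resilind.simulate import simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_per_breed=(120, 120, 120), n_breeds=3, n_chrom=3, n_snp_per_chrom=300,
        n_farms=9, n_lactations_max=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config) -> GenotypePanel:
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_milkings(small_config, small_panel):
    milkings, calvings, truth = simulate_phenotypes(small_panel, small_config)
    return milkings, calvings, truth


@pytest.fixture(scope="session")
def one_breed_panel() -> GenotypePanel:
    cfg = SimConfig(n_per_breed=(500,), n_breeds=1, n_chrom=4, n_snp_per_chrom=250,
                    n_farms=4, fst=0.0, seed=17)
    return simulate_genotypes(cfg)


@pytest.fixture()
def hand_panel() -> GenotypePanel:
    """3 individuals x 4 SNPs with hand-written genotypes."""
    genotypes = np.array([
        [0, 1, 2, 1],
        [2, 1, 0, 0],
        [1, 0, 2, 2],
    ], dtype=np.int8)
    snp_map = pd.DataFrame({
        "chrom": ["1", "1", "1", "2"],
        "snp": ["s1", "s2", "s3", "s4"],
        "cm": 0.0,
        "pos": [100, 2000, 35000, 500],
        "a1": ["A", "A", "A", "A"],
        "a2": ["B", "B", "B", "B"],
    })
    samples = pd.DataFrame({"fid": ["F", "F", "F"], "iid": ["i1", "i2", "i3"]})
    return GenotypePanel(genotypes=genotypes, snp_map=snp_map, samples=samples)


def wood_yields(days: np.ndarray, scale: float = 14.0) -> np.ndarray:
    """Smooth Wood-curve daily yields used to build deterministic fixtures."""
    return scale * np.power(days, 0.25) * np.exp(-0.004 * days)


@pytest.fixture()
def smooth_lactation():
    days = np.arange(10, 306)
    return days, wood_yields(days.astype(float))
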