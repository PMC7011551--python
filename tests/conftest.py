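import numpy as np
import pandas as pd
import pytest

from rohscan.genotype_io import GenotypePanel
from rohscan.synthetic_data import SimConfig, simulate_panel


def make_panel(dosages, positions=None, chromosomes=None, populations=None):
    """Small hand-built panel; dosages is an (n_samples, n_snps) array."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100_000
    if chromosomes is None:
        chromosomes = ["1"] * m
    if populations is None:
        populations = ["P"] * n
    markers = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": chromosomes,
            "position_bp": np.asarray(positions, dtype=np.int64),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"x{i}" for i in range(n)], "population": populations}
    )
    return GenotypePanel(d, samples, markers)


@pytest.fixture(scope="session")
def sim_cohort():
    """A small two-population cohort with planted tracts and islands."""
    cfg = SimConfig(
        seed=42,
        n_samples=(40, 30),
        n_chromosomes=3,
        chromosome_length_bp=30_000_000,
        n_snps_per_chromosome=750,
        tracts_per_sample=(3.0, 4.0),
    )
    return (*simulate_panel(cfg), cfg)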