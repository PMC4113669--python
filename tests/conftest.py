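import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vigorclass import SimConfig, compute_grm, simulate_dataset
from vigorclass.genotype_io import GenotypePanel

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_panel(genotypes, scaffolds=None, lines=None, vigor=None):
    """Small literal panels for unit tests."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n, m = geno.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{j}" for j in range(m)],
            "chromosome": 1,
            "scaffold_id": scaffolds if scaffolds is not None else [f"sc{j}" for j in range(m)],
            "position_bp": np.arange(m) * 100,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "line_id": lines if lines is not None else ["L1"] * n,
            "vigor_class": np.asarray(vigor, dtype=np.int8)
            if vigor is not None
            else np.full(n, -1, dtype=np.int8),
        }
    )
    return GenotypePanel(geno, markers, samples)


@pytest.fixture(scope="session")
def beet_dataset():
    """124 plants, 18 lines (15 high / 3 low), 192 SNPs on 99 scaffolds."""
    return simulate_dataset(SimConfig(seed=11, target_h2=0.78))


@pytest.fixture(scope="session")
def beet_grm(beet_dataset):
    return compute_grm(beet_dataset.panel)


@pytest.fixture(scope="session")
def block_ld_dataset():
    """Fewer, denser scaffolds: strong exploitable within-scaffold LD."""
    return simulate_dataset(
        SimConfig(
            n_lines_high=10,
            n_lines_low=2,
            samples_per_line=12,
            n_scaffolds=10,
            n_snps=120,
            within_scaffold_rho=0.95,
            seed=3,
        )
    )
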