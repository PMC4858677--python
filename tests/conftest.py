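import numpy as np
import pytest

from popexpr.datatypes import GeneSNPTable
from popexpr.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared by read-only tests."""
    config = SimulationConfig(n_genes=120, seed=7)
    return simulate_dataset(config)


def make_snp_table(genotypes, gene_id="g1", gene_length=1000, quality=50.0,
                   positions=None, sample_ids=None):
    """Quick GeneSNPTable from a (sites x samples) genotype list."""
    geno = np.asarray(genotypes, dtype=int)
    if geno.ndim == 1:
        geno = geno[None, :]
    n_sites, n_samples = geno.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    qual = np.full(n_sites, quality, dtype=float) if np.isscalar(quality) else np.asarray(quality)
    return GeneSNPTable(
        gene_id=gene_id, gene_length=gene_length, positions=positions,
        quality=qual, genotypes=geno, sample_ids=sample_ids,
    )


def random_genotype_table(rng, n_samples=None, n_sites=None, gene_length=500,
                          missing_rate=0.15):
    """Random small genotype matrix with missing calls, for oracle checks."""
    n_samples = n_samples or int(rng.integers(2, 11))
    n_sites = n_sites or int(rng.integers(1, 6))
    geno = rng.integers(0, 3, size=(n_sites, n_samples))
    miss = rng.random((n_sites, n_samples)) < missing_rate
    geno = np.where(miss, -1, geno)
    return make_snp_table(geno, gene_length=gene_length)
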