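"""Shared fixtures: small simulated cohorts and handcrafted toy datasets.

All fixtures are deterministic (fixed seeds) and generated at test time;
nothing is read from disk.
"""

import numpy as np
import pandas as pd
import pytest

from paleostrat.data import GenotypeDataset
from paleostrat.simulate import (SimulationConfig, simulate_admixed_cohort,
                                 simulate_source_frequencies)

REFS = [f"Out{j + 1}" for j in range(5)]


def make_dataset(genotypes, chromosomes=None, genetic_pos=None, groups=None,
                 ploidy="diploid", cemetery=None):
    """Handcrafted dataset: genotypes is individuals x SNPs."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_snp = geno.shape
    if chromosomes is None:
        chromosomes = ["1"] * n_snp
    if genetic_pos is None:
        genetic_pos = np.arange(n_snp) * 0.01
    snps = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n_snp)],
        "chromosome": [str(c) for c in chromosomes],
        "genetic_pos": np.asarray(genetic_pos, dtype=float),
        "physical_pos": np.arange(1, n_snp + 1) * 1000,
        "ref": "A", "alt": "G",
    })
    if groups is None:
        groups = [f"ind{i}" for i in range(n_ind)]
    individuals = pd.DataFrame({
        "individual_id": [f"I{i}" for i in range(n_ind)],
        "sex": "unknown",
        "group": groups,
    })
    if cemetery is not None:
        individuals["cemetery"] = cemetery
    return GenotypeDataset(geno, snps, individuals, ploidy=ploidy)


def draw_population(rng, freqs, n_individuals, ploidy="pseudohaploid"):
    """Genotype rows for individuals drawn from per-SNP frequencies."""
    rows = []
    for _ in range(n_individuals):
        h1 = (rng.random(freqs.size) < freqs).astype(np.int8)
        h2 = (rng.random(freqs.size) < freqs).astype(np.int8)
        if ploidy == "pseudohaploid":
            pick = rng.random(freqs.size) < 0.5
            rows.append(np.where(pick, h1, h2) * 2)
        else:
            rows.append(h1 + h2)
    return np.vstack(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A moderate admixed cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_snps_per_chromosome=1500, n_chromosomes=14,
        n_target_individuals=30, cemetery_split=(15, 15),
        missing_rate=0.2, seed=42)
    dataset, truth = simulate_admixed_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def source_freqs():
    cfg = SimulationConfig(seed=7)
    return simulate_source_frequencies(cfg, n_snps=50000)
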