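"""Shared fixtures: small simulated populations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import binqtl as b

DESK_CHROMS = {"chr1": 150_000_000, "chr2": 150_000_000}


@pytest.fixture(scope="session")
def desk_snps() -> b.SNPSet:
    """Desk-scale panel: 2,000 SNPs over two 150-Mb chromosomes, 1 cM/Mb."""
    return b.simulate_parent_snps(2000, DESK_CHROMS, cm_per_mb=1.0, seed=42)


@pytest.fixture(scope="session")
def desk_population(desk_snps) -> b.TrueGenotypeSet:
    """200 F6:7 RILs on the desk-scale panel."""
    return b.simulate_ril_population(desk_snps, n_lines=200, n_selfing_generations=6, seed=42)


@pytest.fixture(scope="session")
def desk_phenotypes(desk_population):
    """Paper-like trait architecture on the desk population."""
    spec = b.paper_like_phenotype_spec()
    table, truth = b.simulate_phenotypes(desk_population, spec, seed=42)
    return spec, table, truth


@pytest.fixture(scope="session")
def desk_binmap(desk_population) -> b.BinMap:
    """Bin map built from noise-free truth genotypes, with a genetic map."""
    bm = b.build_bins(
        desk_population.genotypes, desk_population.snps, desk_population.line_ids
    )
    return b.estimate_genetic_map(bm)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
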