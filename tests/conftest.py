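import numpy as np
import pandas as pd
import pytest

import heteroscan as hs
from heteroscan.core import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale two-population design: 20 accessions, 120 SNPs, 4 reps."""
    return hs.SimConfig(n_accessions=20, n_snps=120, n_chromosomes=3, n_replicates=4, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    """(config, parents, pedigree, combined genotypes, trait table)."""
    cfg = small_config
    parents = hs.simulate_parental_genotypes(cfg)
    ped = hs.make_two_population_pedigree(cfg)
    hybrids = hs.derive_hybrid_genotypes(parents, ped)
    combined = GenotypeMatrix(
        calls=pd.concat([parents.calls, hybrids.calls]), snp_map=parents.snp_map
    )
    table = hs.simulate_traits(combined, ped, cfg)
    return cfg, parents, ped, combined, table


def one_population_config(seed, n_parents=100, n_snps=1000, qtls=(), residual_sd=None,
                          n_replicates=10):
    """Single-trait, single-population config for power/type-I studies."""
    return hs.SimConfig(
        n_accessions=n_parents,
        n_snps=n_snps,
        n_replicates=n_replicates,
        qtls=tuple(qtls),
        residual_sd=residual_sd,
        reference_ids=("REF1", "REF2"),
        seed=seed,
        trait_baselines={"FT": 29.0},
        genetic_sd={"FT": 4.8},
    )


def one_population_panel(cfg):
    """Simulate one common-reference population under ``cfg``.

    Returns (parents, pedigree, trait table, per-hybrid MPH_ABS series,
    dominant design, hybrid kinship).
    """
    parents = hs.simulate_parental_genotypes(cfg)
    ids = [a for a in parents.accessions if a not in cfg.reference_ids]
    ped = hs.make_pedigree(ids, cfg.reference_ids[0], "1")
    hybrids = hs.derive_hybrid_genotypes(parents, ped)
    combined = GenotypeMatrix(
        calls=pd.concat([parents.calls, hybrids.calls]), snp_map=parents.snp_map
    )
    table = hs.simulate_traits(combined, ped, cfg)
    het = hs.heterosis_table(table, ped)
    y = het[het["trait"] == "FT"].set_index("hybrid_id")["mph_abs"]
    design = hs.encode_dominant(parents, ped)
    k = hs.hybrid_kinship(hs.compute_kinship(parents), ped)
    return parents, ped, table, y, design, k
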