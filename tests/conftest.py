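"""Shared fixtures: one mid-size simulated population reused across modules."""

import numpy as np
import pandas as pd
import pytest

from pleiomap import (
    ModelSpec,
    SimConfig,
    adjust_phenotypes,
    estimate_variance_components,
    simulate_all,
)
from pleiomap.containers import GenotypeMatrix, Pedigree


SMALL_CFG = dict(
    n_sires=25,
    n_dams_per_sire=6,
    n_offspring_per_dam=4,
    n_chromosomes=2,
    chrom_length_bp=25_000_000,
    n_snps=1500,
    n_qtl=8,
    n_traits=4,
    h2_per_trait=[0.2, 0.4, 0.5, 0.6],
    qtl_var_frac=0.4,
    missing_rate_per_trait=0.05,
    seed=42,
)


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(**SMALL_CFG)
    ped, geno, pheno, truth = simulate_all(cfg)
    return {"cfg": cfg, "ped": ped, "geno": geno, "pheno": pheno, "truth": truth}


@pytest.fixture(scope="session")
def small_adjusted(small_sim):
    spec = ModelSpec()
    vc = {
        t: estimate_variance_components(
            small_sim["pheno"], small_sim["ped"], spec, t
        )
        for t in small_sim["cfg"].trait_names()
    }
    adj = adjust_phenotypes(small_sim["pheno"], small_sim["ped"], spec, vc)
    return {"spec": spec, "vc": vc, "adj": adj}


def toy_pedigree(n_off=8, seed=0):
    """Two founder couples, two sires/dams, a handful of offspring."""
    rng = np.random.default_rng(seed)
    rows = [
        (1, 0, 0, "M", 0, 0, 1.0, np.nan),
        (2, 0, 0, "F", 0, 0, 1.0, np.nan),
        (3, 0, 0, "M", 0, 0, 1.0, np.nan),
        (4, 0, 0, "F", 0, 0, 1.0, np.nan),
        (5, 1, 2, "M", 1, 0, 1.0, np.nan),
        (6, 3, 4, "F", 1, 0, 1.0, np.nan),
        (7, 1, 4, "F", 1, 0, 1.0, np.nan),
    ]
    aid = 8
    for _ in range(n_off):
        dam = int(rng.choice([6, 7]))
        rows.append((aid, 5, dam, "M" if rng.random() < 0.5 else "F", 2,
                     int(rng.integers(1, 3)), 1.0, 350.0))
        aid += 1
    return Pedigree(pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "sex", "generation", "flock", "Q", "age"]
    ))


def toy_genotypes(n_animals, n_snps=20, seed=0, animals=None):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, n_snps)
    dos = rng.binomial(2, p, size=(n_animals, n_snps)).astype(float)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n_snps)],
            "chrom": 1,
            "bp": np.arange(1, n_snps + 1) * 100_000,
        }
    )
    if animals is None:
        animals = np.arange(1, n_animals + 1)
    return GenotypeMatrix(dos, np.asarray(animals), snp_map)
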