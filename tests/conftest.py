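"""Shared fixtures: small simulated datasets and pedigree helpers."""
from __future__ import annotations

import numpy as np
import pytest

from wssgwas.pedigree import UNKNOWN, Pedigree
from wssgwas.simulate import SimConfig, simulate_dataset


def make_pedigree(records):
    """Pedigree from (id, sire, dam) name triples; None = unknown parent."""
    ids = [r[0] for r in records]
    lookup = {a: i for i, a in enumerate(ids)}

    def idx(x):
        return UNKNOWN if x is None else lookup[x]

    return Pedigree(
        np.array(ids, dtype=object),
        np.array([idx(r[1]) for r in records]),
        np.array([idx(r[2]) for r in records]),
    )


def random_pedigree(n, rng, founder_fraction=0.3):
    """Random valid pedigree: each non-founder picks two earlier parents."""
    n_f = max(2, int(n * founder_fraction))
    sire = np.full(n, UNKNOWN)
    dam = np.full(n, UNKNOWN)
    for i in range(n_f, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = s, d
    ids = np.array([f"P{i}" for i in range(n)], dtype=object)
    return Pedigree(ids, sire, dam)


@pytest.fixture(scope="session")
def small_dataset():
    """~280-animal dataset with QTLs, 50% genotyped; reused across tests."""
    cfg = SimConfig(
        n_founders=40,
        n_generations=2,
        offspring_per_mating=4,
        n_chromosomes=2,
        snps_per_chromosome=60,
        n_qtl=3,
        qtl_variance_fraction=0.5,
        heritability=0.42,
        genotyped_fraction=0.5,
        seed=11,
    )
    ped, geno_all, geno, phen, truth, meta = simulate_dataset(cfg)
    return {
        "config": cfg,
        "pedigree": ped,
        "genotypes_all": geno_all,
        "genotypes": geno,
        "phenotypes": phen,
        "truth": truth,
        "meta": meta,
    }
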