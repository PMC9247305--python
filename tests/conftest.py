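import numpy as np
import pandas as pd
import pytest

from caprilink.genotypes import GenotypeMatrix
from caprilink.simulate import PopulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full synthetic multi-country dataset under the default study design."""
    return simulate_dataset(PopulationSpec(seed=11))


@pytest.fixture(scope="session")
def validated_pedigrees(default_dataset):
    from caprilink.pedigree import validate_pedigree

    return {
        c: validate_pedigree(p)[0] for c, p in default_dataset.pedigrees.items()
    }


@pytest.fixture(scope="session")
def default_matches(validated_pedigrees):
    from caprilink.pedigree import link_pedigrees

    out = {}
    for s in validated_pedigrees:
        for t in validated_pedigrees:
            if s != t:
                out[(s, t)] = link_pedigrees(
                    validated_pedigrees[s], validated_pedigrees[t]
                )
    return out


def make_genotypes(calls, bp=None, chrom=None, phase=None, ids=None, country="FRA"):
    """Small hand-built GenotypeMatrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if bp is None:
        bp = (np.arange(m) + 1) * 1000
    if chrom is None:
        chrom = ["1"] * m
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "snp": [f"s{j}" for j in range(m)],
            "bp": bp,
            "a1": "A",
            "a2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"I{i:03d}" for i in range(n)],
            "breed": "ALP",
            "country": country,
            "birth_year": 2000,
        }
    )
    return GenotypeMatrix(calls=calls, variants=variants, samples=samples, phase=phase)


@pytest.fixture
def genotype_factory():
    return make_genotypes
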