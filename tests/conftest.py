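import numpy as np
import pandas as pd
import pytest

from twinqtl import (
    Pedigree,
    QtlSpec,
    SimulationConfig,
    VarianceComponents,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_founders=60,
        n_generations=2,
        n_herds=3,
        years=(2006, 2011),
        phenotype_mode="gaussian",
        variance_components=VarianceComponents(0.1, 0.15, 0.2, 0.05, 0.5),
    )


@pytest.fixture(scope="session")
def small_pedigree(small_config):
    return simulate_pedigree(small_config)


@pytest.fixture(scope="session")
def small_records(small_config, small_pedigree):
    return simulate_phenotypes(small_pedigree, None, small_config)


@pytest.fixture(scope="session")
def qtl_config():
    """Phased genotypes with a planted haplotype on a short chromosome."""
    return SimulationConfig(
        seed=11,
        n_founders=120,
        n_generations=2,
        n_herds=4,
        years=(2006, 2011),
        n_chromosomes=1,
        snps_per_chromosome=120,
        chromosome_length=10_000_000,
        qtl_spec=QtlSpec(
            chromosome=1,
            start_bp=4_000_000,
            end_bp=4_600_000,
            effect=-0.02,
            target_frequency=0.275,
        ),
    )


@pytest.fixture(scope="session")
def qtl_genotypes(qtl_config):
    ped = simulate_pedigree(qtl_config)
    geno = simulate_genotypes(ped, qtl_config)
    return ped, geno


def trio_pedigree():
    """Minimal sire/dam/offspring pedigree used by several oracles."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": [1, 2, 3],
                "sire": [-1, -1, 1],
                "dam": [-1, -1, 2],
                "sex": ["M", "F", "F"],
                "birth_year": [2000, 2000, 2005],
                "herd": [-1, 0, 0],
            }
        )
    )


@pytest.fixture
def trio():
    return trio_pedigree()


def random_pedigree(rng, n_founders=20, n_offspring=30):
    """Random multi-generation pedigree for property checks."""
    ids = list(range(1, n_founders + 1))
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    sex = ["M" if i % 2 == 0 else "F" for i in range(n_founders)]
    year = [2000] * n_founders
    for k in range(n_offspring):
        males = [ids[i] for i in range(len(ids)) if sex[i] == "M"]
        females = [ids[i] for i in range(len(ids)) if sex[i] == "F"]
        s = int(rng.choice(males))
        d = int(rng.choice(females))
        ids.append(n_founders + k + 1)
        sire.append(s)
        dam.append(d)
        sex.append("M" if rng.random() < 0.5 else "F")
        year.append(2001 + k // 5)
    return Pedigree(
        pd.DataFrame(
            {
                "id": ids,
                "sire": sire,
                "dam": dam,
                "sex": sex,
                "birth_year": year,
                "herd": 0,
            }
        )
    )
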