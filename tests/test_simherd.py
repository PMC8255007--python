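"""Synthetic-herd generator: determinism, Mendelian consistency, planted
structure."""

import numpy as np
import pandas as pd
import pytest

from twinqtl import (
    QtlSpec,
    SimulationConfig,
    VarianceComponents,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_seq_panel,
)
from twinqtl.config import ConfigError
from twinqtl.simherd import SimulationError, sample_breeding_values


def test_minimal_trio():
    cfg = SimulationConfig(seed=1, n_founders=2, n_generations=1, n_herds=1,
                           years=(2006, 2006))
    ped = simulate_pedigree(cfg)
    assert len(ped) == 3
    child = ped.table.iloc[2]
    assert child["sire"] == 1 and child["dam"] == 2


def test_pedigree_deterministic(small_config):
    a = simulate_pedigree(small_config).table
    b = simulate_pedigree(small_config).table
    pd.testing.assert_frame_equal(a, b)


def test_topological_audit():
    """Every non-founder's parents exist and precede it (exhaustive)."""
    cfg = SimulationConfig(seed=5, n_founders=40, n_generations=4,
                           years=(2006, 2013), n_herds=4)
    ped = simulate_pedigree(cfg)
    pos = {a: i for i, a in enumerate(ped.ids)}
    for row in ped.table.itertuples(index=False):
        for parent in (row.sire, row.dam):
            if parent != -1:
                assert parent in pos
                assert pos[parent] < pos[row.id]


def test_no_females_fails():
    cfg = SimulationConfig(seed=1, n_founders=4, founder_male_fraction=1.0,
                           n_generations=1)
    with pytest.raises(SimulationError):
        simulate_pedigree(cfg)


def test_gene_dropping_mendelian_consistency(qtl_config, qtl_genotypes):
    """Each child haplotype matches one of the corresponding parent's
    alleles at every marker when recombination only swaps between the two
    parental haplotypes."""
    ped, geno = qtl_genotypes
    H = geno.haplotypes
    s_idx, d_idx = ped._parent_indices()
    rng = np.random.default_rng(0)
    for i in rng.choice(len(ped), 40, replace=False):
        for h, par in ((0, s_idx[i]), (1, d_idx[i])):
            if par == -1:
                continue
            child = H[2 * i + h]
            ok = (child == H[2 * par]) | (child == H[2 * par + 1])
            assert ok.all()
    # dosage identity
    np.testing.assert_array_equal(geno.dosages, H[0::2] + H[1::2])


def test_no_recombination_copies_parent_haplotype(qtl_config):
    cfg = SimulationConfig(**{**qtl_config.__dict__, "recombination_rate": 0.0})
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    H = geno.haplotypes
    s_idx, _ = ped._parent_indices()
    children = np.nonzero(s_idx != -1)[0]
    for i in children[:30]:
        p = s_idx[i]
        child = H[2 * i]
        assert np.array_equal(child, H[2 * p]) or np.array_equal(child, H[2 * p + 1])


def test_monomorphic_founder_pool():
    cfg = SimulationConfig(seed=2, n_founders=30, n_generations=1,
                           snps_per_chromosome=50, founder_pool_size=1,
                           haplotypes_per_block=1)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    assert np.isin(geno.dosages, (0, 2)).all()


def test_planted_haplotype_frequency(qtl_genotypes):
    """Target frequency 0.275 realised within binomial sampling error."""
    _, geno = qtl_genotypes
    freq = geno.qtl_truth["carrier"].mean()
    assert abs(freq - 0.275) < 0.05


def test_phenotypes_deterministic(small_config, small_pedigree):
    a = simulate_phenotypes(small_pedigree, None, small_config)
    b = simulate_phenotypes(small_pedigree, None, small_config)
    pd.testing.assert_frame_equal(a, b)


def test_degenerate_all_zero_variance():
    cfg = SimulationConfig(
        seed=3, n_founders=30, n_generations=1, n_herds=1, years=(2006, 2006),
        phenotype_mode="gaussian",
        variance_components=VarianceComponents(0, 0, 0, 0, 0),
    )
    cfg.fixed_effect_values.age_slope = 0.0
    ped = simulate_pedigree(cfg)
    recs = simulate_phenotypes(ped, None, cfg)
    # single parity/season level cannot be forced, but with zero variance the
    # record value is exactly the fixed part: records sharing all levels match
    key = recs.groupby(["parity", "season", "sexed_semen"])["code"].nunique()
    assert (key == 1).all()


def test_herd_year_variance_recovered():
    """Sample variance of herd-year means consistent with sigma2_h."""
    vc = VarianceComponents(0.5, 1e-8, 1e-8, 0.0, 0.05)
    cfg = SimulationConfig(seed=9, n_founders=2050, founder_male_fraction=0.025,
                           n_generations=1, n_herds=40, years=(2006, 2010),
                           phenotype_mode="gaussian", variance_components=vc)
    ped = simulate_pedigree(cfg)
    recs = simulate_phenotypes(ped, None, cfg)
    assert len(recs) > 9000
    resid = recs["code"] - recs.groupby(["parity", "season", "sexed_semen"])[
        "code"
    ].transform("mean")
    hy_means = resid.groupby(
        [recs["herd"], recs["year"]]
    ).mean()
    assert np.var(hy_means, ddof=1) == pytest.approx(0.5, rel=0.25)


def test_binary_mode_prevalence():
    cfg = SimulationConfig(seed=13, n_founders=2050, founder_male_fraction=0.025,
                           n_generations=1, n_herds=20, years=(2006, 2015),
                           phenotype_mode="binary", target_prevalence=0.0356)
    ped = simulate_pedigree(cfg)
    recs = simulate_phenotypes(ped, None, cfg)
    rate = (recs["code"] == 2).mean()
    assert abs(rate - 0.0356) < 0.003


def test_breeding_value_covariance_structure(small_config, small_pedigree):
    """Sampled direct/maternal values reproduce G0 across replicates."""
    G0 = small_config.variance_components.genetic_covariance_matrix()
    founders = small_pedigree.table["sire"].to_numpy() == -1
    samples = []
    for rep in range(200):
        rng = np.random.default_rng(rep)
        u = sample_breeding_values(small_pedigree, small_config, rng)
        samples.append(u[founders])
    U = np.concatenate(samples, axis=0)
    emp = np.cov(U.T)
    np.testing.assert_allclose(emp, G0, rtol=0.1, atol=0.01)


def test_seq_panel_flip_zero_is_perfect_proxy(qtl_config, qtl_genotypes):
    ped, geno = qtl_genotypes
    cfg = SimulationConfig(**{**qtl_config.__dict__})
    cfg.seq_panel_spec.causal_proxy_flip = 0.0
    cfg.seq_panel_spec.missing_rate = 0.0
    panel = simulate_seq_panel(geno, cfg)
    proxy = panel.variants["is_causal_proxy"].to_numpy()
    j = int(np.nonzero(proxy)[0][0])
    np.testing.assert_array_equal(
        panel.genotypes[:, j], geno.carrier_dosage()
    )


def test_qtl_window_outside_map_rejected():
    cfg = SimulationConfig(
        seed=1, qtl_spec=QtlSpec(chromosome=2, start_bp=0, end_bp=100)
    )
    with pytest.raises(ConfigError):
        cfg.validate()


def test_seed_recorded_in_outputs(qtl_genotypes, small_records):
    _, geno = qtl_genotypes
    assert geno.seed == 11
    assert small_records.attrs["seed"] == 7
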