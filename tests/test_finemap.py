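"""Sequence-panel QC, Mendelian errors, LD screen, breed frequencies."""

import numpy as np
import pandas as pd
import pytest

from twinqtl.finemap import (
    FinemapError,
    QcThresholds,
    breed_frequencies,
    haplotype_variant_ld,
    mendelian_error_rate,
    vcf_qc,
)
from twinqtl.simherd import SeqPanel


def _panel(G, pos=None, breeds=None, families=None):
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    return SeqPanel(
        variants=pd.DataFrame(
            {
                "chrom": 1,
                "pos": pos if pos is not None else 1000 * (1 + np.arange(m)),
                "ref": "A",
                "alt": "C",
            }
        ),
        genotypes=G,
        sample_ids=np.arange(n) + 1,
        breeds=np.asarray(breeds) if breeds is not None
        else np.array(["Holstein"] * n),
        families=families if families is not None
        else pd.DataFrame(columns=["child", "parent1", "parent2"]),
    )


def test_variant_missingness_strict_boundary():
    """11% missing removed, exactly 10% retained."""
    n = 100
    G = np.ones((n, 2), dtype=np.int8)
    G[:50, :] = 0  # keep polymorphic
    G[:11, 0] = -1
    G[:10, 1] = -1
    panel = _panel(G)
    out, rep = vcf_qc(panel)
    assert rep.removed_variant_missing == 1
    assert out.genotypes.shape[1] == 1
    assert rep.variants_conserved and rep.samples_conserved


def test_qc_no_families_notes_zero():
    G = np.array([[0, 1], [1, 1], [2, 0], [1, 2]], dtype=np.int8)
    _, rep = vcf_qc(_panel(G))
    assert rep.n_families == 0
    assert rep.removed_sample_mendel == 0
    assert rep.removed_variant_mendel == 0


def test_qc_counts_match_brute_force():
    """Panel with planted violations of every rule against a brute-force
    sequential filter."""
    rng = np.random.default_rng(6)
    n, m = 120, 60
    G = rng.integers(0, 3, (n, m)).astype(np.int8)
    G[rng.random((n, m)) < 0.05] = -1
    G[:, 3] = np.where(np.arange(n) < 20, -1, 1)   # high missing variant
    G[:, 7] = np.where(G[:, 7] >= 0, 0, -1)        # rare/monomorphic
    G[5, :] = -1                                   # bad sample
    G[5, :10] = 1
    panel = _panel(G)
    thr = QcThresholds()
    out, rep = vcf_qc(panel, thr)

    # brute force, same order
    keepv = np.ones(m, bool)
    mv = (G < 0).mean(axis=0)
    keepv &= ~(mv > 0.1)
    Gm = np.ma.masked_less(G, 0)
    freq = Gm.mean(axis=0).filled(np.nan) / 2
    maf = np.minimum(freq, 1 - freq)
    drop = keepv & ((maf < 0.01) | np.isnan(maf))
    keepv &= ~drop
    ms = (G[:, keepv] < 0).mean(axis=1)
    keeps = ~(ms > 0.1)
    assert rep.n_variants_retained == keepv.sum()
    assert rep.n_samples_retained == keeps.sum()
    np.testing.assert_array_equal(out.sample_ids, panel.sample_ids[keeps])


def test_duo_error_definition():
    # parent 0/0, child 1/1 -> opposing homozygotes
    G = np.array([[0], [2]], dtype=np.int8)
    fam = pd.DataFrame({"child": [2], "parent1": [1], "parent2": [-1]})
    panel = _panel(G, families=fam)
    rs, rv, nfam = mendelian_error_rate(panel)
    assert nfam == 1
    assert rv[0] == 1.0
    assert rs[0] == 1.0 and rs[1] == 1.0


def test_trio_error_definition():
    # parents 0/0 x 1/1 -> child must be 0/1
    cases = [
        (0, 2, 1, 0.0),  # het child: fine
        (0, 2, 0, 1.0),  # hom child: impossible
        (0, 2, 2, 1.0),
    ]
    for g1, g2, gc, want in cases:
        G = np.array([[g1], [g2], [gc]], dtype=np.int8)
        fam = pd.DataFrame({"child": [3], "parent1": [1], "parent2": [2]})
        rs, rv, _ = mendelian_error_rate(_panel(G, families=fam))
        assert rv[0] == want


def test_mendel_rates_match_exhaustive_enumeration():
    """Random duos/trios against exhaustive inheritance-table checking."""
    rng = np.random.default_rng(11)
    n, m = 30, 40
    G = rng.integers(0, 3, (n, m)).astype(np.int8)
    G[rng.random((n, m)) < 0.1] = -1
    fams = pd.DataFrame(
        {
            "child": [3, 6, 9, 12],
            "parent1": [1, 4, 7, 10],
            "parent2": [2, -1, 8, -1],
        }
    )
    panel = _panel(G, families=fams)
    rs, rv, nfam = mendelian_error_rate(panel)
    assert nfam == 4

    def trio_ok(gc, g1, g2):
        poss1 = {0: {0}, 1: {0, 1}, 2: {1}}[g1]
        poss2 = {0: {0}, 1: {0, 1}, 2: {1}}[g2]
        return gc in {x + y for x in poss1 for y in poss2}

    err_v = np.zeros(m)
    tst_v = np.zeros(m)
    for child, p1, p2 in fams.itertuples(index=False):
        ci = child - 1
        for j in range(m):
            gc = G[ci, j]
            if p2 == -1:
                gp = G[p1 - 1, j]
                if gc < 0 or gp < 0:
                    continue
                tst_v[j] += 1
                if (gp == 0 and gc == 2) or (gp == 2 and gc == 0):
                    err_v[j] += 1
            else:
                g1, g2 = G[p1 - 1, j], G[p2 - 1, j]
                if gc < 0 or g1 < 0 or g2 < 0:
                    continue
                tst_v[j] += 1
                if not trio_ok(gc, g1, g2):
                    err_v[j] += 1
    with np.errstate(invalid="ignore"):
        want = np.where(tst_v > 0, err_v / np.maximum(tst_v, 1), 0.0)
    np.testing.assert_allclose(rv, want)


def test_ld_perfect_and_allele_swapped():
    rng = np.random.default_rng(2)
    d = rng.integers(0, 3, 200)
    G = np.column_stack([d, 2 - d, rng.integers(0, 3, 200)]).astype(np.int8)
    panel = _panel(G)
    dip = pd.DataFrame({"animal": panel.sample_ids, "dosage": d})
    ld = haplotype_variant_ld(dip, panel, r2_floor=0.0)
    by_pos = ld.set_index("pos")["r2"]
    assert by_pos[1000] == pytest.approx(1.0)
    assert by_pos[2000] == pytest.approx(1.0)  # allele swap is sign-free
    assert by_pos[3000] < 0.1


def test_ld_sorted_and_floored():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, 300)
    cols = []
    for flip in (0.0, 0.05, 0.2, 0.45):
        noise = rng.random(300) < flip
        g = np.where(noise, rng.integers(0, 3, 300), d)
        cols.append(g)
    panel = _panel(np.column_stack(cols).astype(np.int8))
    dip = pd.DataFrame({"animal": panel.sample_ids, "dosage": d})
    ld = haplotype_variant_ld(dip, panel, r2_floor=0.7)
    assert ld["r2"].is_monotonic_decreasing
    assert (ld["r2"] >= 0.7).all()
    assert ld.iloc[0]["pos"] == 1000


def test_ld_flip_ladder_ordering(qtl_config, qtl_genotypes):
    """Synthetic flip-rate ladder: r2 strictly ordered, causal proxy
    first; Spearman correlation between (1 - flip) and r2 is 1."""
    from dataclasses import replace
    from twinqtl import SeqPanelSpec, simulate_seq_panel
    from scipy import stats

    ped, geno = qtl_genotypes
    cfg = replace(
        qtl_config,
        seq_panel_spec=SeqPanelSpec(
            causal_proxy_flip=0.02, flip_min=0.1, flip_max=0.45,
            frac_independent=0.0, missing_rate=0.0, n_variants=40,
        ),
    )
    panel = simulate_seq_panel(geno, cfg)
    dip = pd.DataFrame(
        {"animal": geno.animal_ids, "dosage": geno.carrier_dosage()}
    )
    ld = haplotype_variant_ld(dip, panel, r2_floor=0.0)
    merged = ld.merge(panel.variants, on="pos")
    assert merged.iloc[0]["is_causal_proxy"]
    rho = stats.spearmanr(1 - merged["flip_rate"], merged["r2"]).statistic
    assert rho > 0.9


def test_breed_frequencies_threshold_inclusive():
    rng = np.random.default_rng(8)
    n = 149
    G = rng.integers(0, 3, (n, 1)).astype(np.int8)
    breeds = np.array(["A"] * 50 + ["B"] * 49 + ["C"] * 50)
    panel = _panel(G, breeds=breeds)
    out = breed_frequencies(panel, 1000, min_records=50)
    assert set(out["breed"]) == {"A", "C"}
    a = out.set_index("breed")
    hand = G[:50, 0].mean() / 2
    assert a.loc["A", "alt_frequency"] == pytest.approx(hand)


def test_breed_fixed_for_ref():
    G = np.zeros((60, 1), dtype=np.int8)
    panel = _panel(G, breeds=np.array(["A"] * 60))
    out = breed_frequencies(panel, 1000)
    assert out["alt_frequency"].iloc[0] == 0.0


def test_malformed_genotype_rejected():
    G = np.array([[0, 5], [1, 1]], dtype=np.int8)
    with pytest.raises(FinemapError, match="variant 1"):
        vcf_qc(_panel(G))
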