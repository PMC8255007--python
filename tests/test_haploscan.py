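"""Sliding-haplotype scan: enumeration, dosages, GLS consistency."""

import numpy as np
import pandas as pd
import pytest

from twinqtl.assoc import build_grm, fit_null_model, single_snp_scan
from twinqtl.haploscan import (
    HaploscanError,
    Segment,
    diplotype_dosage_table,
    diplotype_effect_on_trait,
    enumerate_windows,
    haplotype_dosages,
    haplotype_scan,
)
from twinqtl.simherd import PhasedGenotypes


def _map(m, chrom=1, spacing=10_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": spacing * (1 + np.arange(m)),
            "id": [f"s{i}" for i in range(m)],
            "ref": "A",
            "alt": "B",
        }
    )


def _phased(H, mm=None):
    H = np.asarray(H, dtype=np.int8)
    return PhasedGenotypes(
        marker_map=mm if mm is not None else _map(H.shape[1]),
        haplotypes=H,
        animal_ids=np.arange(H.shape[0] // 2) + 1,
    )


def test_enumerate_window_counts():
    mm = _map(12)
    seg = Segment(1, 0, 200_000)
    w9 = enumerate_windows(mm, seg, [9])
    assert len(w9) == 4
    w11 = enumerate_windows(mm, seg, [11])
    assert len(w11) == 2
    both = enumerate_windows(mm, seg, [9, 11])
    assert len(both) == 6
    # m=9 -> exactly one window of length 9
    w = enumerate_windows(_map(9), seg, [9])
    assert len(w) == 1


def test_even_length_rejected():
    with pytest.raises(HaploscanError):
        enumerate_windows(_map(12), Segment(1, 0, 1_000_000), [9, 10])


def test_segment_with_too_few_markers_is_empty():
    w = enumerate_windows(_map(5), Segment(1, 0, 1_000_000), [9])
    assert len(w) == 0


def test_haplotype_dosages_hand_constructed():
    """6-animal phase with known strings matches the hand tally."""
    H = np.array(
        [
            [0, 0, 1], [0, 0, 1],   # animal 1: hom for '001'
            [0, 0, 1], [1, 1, 0],   # animal 2: het
            [1, 1, 0], [1, 1, 0],   # animal 3: hom '110'
            [0, 0, 1], [0, 1, 1],   # animal 4
            [0, 1, 1], [0, 1, 1],   # animal 5
            [1, 1, 0], [0, 0, 1],   # animal 6
        ]
    )
    phased = _phased(H)
    out = haplotype_dosages(phased, 0, 2)
    by_str = {s: (f, d) for s, f, d in out}
    assert set(by_str) == {"001", "110", "011"}
    f001, d001 = by_str["001"]
    assert f001 == pytest.approx(5 / 12)
    np.testing.assert_array_equal(d001, [2, 1, 0, 1, 0, 1])
    assert sum(f for f, _ in by_str.values()) == pytest.approx(1.0)


def test_all_homozygous_single_string():
    H = np.tile(np.array([1, 0, 1], dtype=np.int8), (8, 1))
    out = haplotype_dosages(_phased(H), 0, 2)
    assert len(out) == 1
    s, f, d = out[0]
    assert f == 1.0
    np.testing.assert_array_equal(d, [2, 2, 2, 2])


@pytest.fixture(scope="module")
def scan_setup():
    rng = np.random.default_rng(31)
    n, m = 300, 40
    freq = rng.uniform(0.2, 0.8, m)
    H = (rng.random((2 * n, m)) < freq).astype(np.int8)
    phased = _phased(H, _map(m))
    D = phased.dosages.astype(float)
    grm = build_grm(D).matrix
    y = rng.normal(size=n) + 0.8 * D[:, 17]
    null = fit_null_model(y, grm)
    return phased, D, y, null


def test_identical_dosage_vectors_identical_statistics():
    """Windows whose focal-haplotype dosages coincide give identical
    effect/SE/p (the mechanism behind long runs of equal top rows)."""
    rng = np.random.default_rng(53)
    n, L = 200, 9
    block = (rng.random((2 * n, L)) < 0.5).astype(np.int8)
    H = np.concatenate([block, block], axis=1)  # markers 9..17 copy 0..8
    phased = _phased(H, _map(2 * L))
    y = rng.normal(size=n)
    grm = build_grm(phased.dosages.astype(float)).matrix
    null = fit_null_model(y, grm)
    res = haplotype_scan(y, phased, Segment(1, 0, 10_000_000), null,
                         min_freq=0.05, lengths=[L])
    first = res[res["start_bp"] == 10_000]
    second = res[res["start_bp"] == 100_000]
    a = first.set_index("haplotype")[["effect", "se", "p_value"]]
    b = second.set_index("haplotype")[["effect", "se", "p_value"]]
    pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


def test_most_frequent_haplotype_matches_single_snp_gls(scan_setup):
    """For a single-marker window the haplotype dosage of the alt allele
    equals the marker dosage, and the scan p equals single_snp_scan's."""
    phased, D, y, null = scan_setup
    res = haplotype_scan(y, phased, Segment(1, 0, 10_000_000), null,
                         min_freq=0.02, lengths=[1])
    snp = single_snp_scan(y, D, null)
    for j in (0, 5, 17):
        hap_rows = res[(res["start_bp"] == phased.marker_map["pos"].iloc[j])
                       & (res["n_snps"] == 1) & (res["haplotype"] == "1")]
        if len(hap_rows) == 0:
            continue
        assert hap_rows["p_value"].iloc[0] == pytest.approx(
            snp["p_value"].iloc[j], abs=1e-10
        )


def test_scan_deterministic_and_ranked(scan_setup):
    phased, D, y, null = scan_setup
    seg = Segment(1, 0, 10_000_000)
    a = haplotype_scan(y, phased, seg, null, min_freq=0.05, lengths=[9, 11, 13])
    b = haplotype_scan(y, phased, seg, null, min_freq=0.05, lengths=[13, 9, 11])
    pd.testing.assert_frame_equal(a, b)
    assert a["p_value"].is_monotonic_increasing


def test_no_haplotype_above_min_freq(scan_setup):
    phased, D, y, null = scan_setup
    res = haplotype_scan(y, phased, Segment(1, 0, 10_000_000), null,
                         min_freq=0.9999, lengths=[9])
    assert len(res) == 0


def test_diplotype_effect_recovery():
    """Trait built as 0.664 x dosage + noise recovers the effect within
    2 SE."""
    rng = np.random.default_rng(41)
    n = 400
    dosage = rng.integers(0, 3, n).astype(float)
    D = ((rng.random((n, 300)) < 0.5).astype(int)
         + (rng.random((n, 300)) < 0.5).astype(int)).astype(float)
    grm = build_grm(D).matrix
    trait = 0.664 * dosage + rng.normal(0, 1.0, n)
    eff, se, p = diplotype_effect_on_trait(dosage, trait, grm)
    assert abs(eff - 0.664) < 2 * se
    assert p < 0.01


def test_diplotype_effect_null_calibration():
    """Orthogonal dosage: p-values uniform over replicates (KS at 1%)."""
    from scipy import stats

    rng = np.random.default_rng(43)
    n = 120
    D = ((rng.random((n, 200)) < 0.5).astype(int)
         + (rng.random((n, 200)) < 0.5).astype(int)).astype(float)
    grm = build_grm(D).matrix
    ps = []
    for _ in range(300):
        dosage = rng.integers(0, 3, n).astype(float)
        trait = rng.normal(size=n)
        _, _, p = diplotype_effect_on_trait(dosage, trait, grm)
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_diplotype_effect_permutation_invariance():
    rng = np.random.default_rng(47)
    n = 100
    dosage = rng.integers(0, 3, n).astype(float)
    trait = rng.normal(size=n) + 0.5 * dosage
    D = ((rng.random((n, 150)) < 0.5).astype(int)
         + (rng.random((n, 150)) < 0.5).astype(int)).astype(float)
    grm = build_grm(D).matrix
    a = diplotype_effect_on_trait(dosage, trait, grm)
    perm = rng.permutation(n)
    b = diplotype_effect_on_trait(dosage[perm], trait[perm],
                                  grm[np.ix_(perm, perm)])
    np.testing.assert_allclose(a, b, rtol=1e-6)


def test_diplotype_effect_refuses_tiny_overlap():
    with pytest.raises(HaploscanError, match="29"):
        diplotype_effect_on_trait(
            np.zeros(29), np.zeros(29), np.eye(29)
        )


def test_diplotype_dosage_table(scan_setup):
    phased, _, _, _ = scan_setup
    tab = diplotype_dosage_table(phased, 0, 2, "111")
    H = phased.haplotypes[:, 0:3]
    match = (H == 1).all(axis=1).astype(int)
    np.testing.assert_array_equal(
        tab["dosage"].to_numpy(), match[0::2] + match[1::2]
    )
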