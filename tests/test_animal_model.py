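"""Animal-model REML/BLUP against dense oracles on toy data."""

import numpy as np
import pandas as pd
import pytest

from twinqtl import SimulationConfig, VarianceComponents, simulate_pedigree, simulate_phenotypes
from twinqtl.animal_model import (
    BaseGroupRule,
    ModelDesign,
    ModelError,
    blup_solve,
    build_a_inverse,
    genetic_trend,
    heritabilities,
    reliability,
    reml_log_likelihood,
    reml_variance_components,
    standardize_ebv,
)
from twinqtl.records import encode_model_frame


@pytest.fixture(scope="module")
def toy():
    cfg = SimulationConfig(
        seed=3, n_founders=40, n_generations=2, n_herds=3, years=(2006, 2011),
        phenotype_mode="gaussian",
        variance_components=VarianceComponents(0.1, 0.15, 0.2, 0.05, 0.5),
    )
    ped = simulate_pedigree(cfg)
    recs = simulate_phenotypes(ped, None, cfg)
    design = ModelDesign.from_frame(encode_model_frame(recs, ped), ped)
    return cfg, ped, recs, design


def _dense_v(design, ped, vc):
    A = ped.relationship_matrix()
    G0 = vc.genetic_covariance_matrix()
    X = design.X.toarray()
    W = design.W.toarray()
    Zd = design.Zd.toarray()
    Zm = design.Zm.toarray()
    n = design.n
    V = (
        W @ W.T * vc.herd_year
        + Zd @ A @ Zd.T * G0[0, 0]
        + Zm @ A @ Zm.T * G0[1, 1]
        + (Zd @ A @ Zm.T + Zm @ A @ Zd.T) * G0[0, 1]
        + np.eye(n) * vc.residual
    )
    return V, X


def dense_reml_ll(design, ped, vc):
    V, X = _dense_v(design, ped, vc)
    y = design.y
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    _, ld1 = np.linalg.slogdet(V)
    _, ld2 = np.linalg.slogdet(XVX)
    return -0.5 * (ld1 + ld2 + y @ P @ y)


def test_mme_likelihood_matches_dense(toy):
    """Sparse MME restricted likelihood equals the dense V-based formula."""
    _, ped, _, design = toy
    vc = VarianceComponents(0.12, 0.1, 0.25, 0.03, 0.45)
    assert reml_log_likelihood(design, vc) == pytest.approx(
        dense_reml_ll(design, ped, vc), abs=1e-6
    )


def test_reml_optimum_matches_dense_likelihood(toy):
    """At the REML optimum no parameter perturbation raises the dense
    likelihood (the dense-matrix surface confirms the sparse solver)."""
    _, ped, _, design = toy
    est = reml_variance_components(design, max_iter=200)
    ll0 = dense_reml_ll(design, ped, est)
    assert reml_log_likelihood(design, est) == pytest.approx(ll0, abs=1e-6)
    theta = np.array(est.as_tuple())
    for k in range(5):
        for eps in (-1e-4, 1e-4):
            t = theta.copy()
            t[k] *= 1 + eps
            t[k] += eps * 1e-6
            if t[3] ** 2 > t[1] * t[2]:
                continue
            assert dense_reml_ll(design, ped, VarianceComponents(*t)) <= ll0 + 1e-7


def test_reml_invariant_to_record_order(toy):
    cfg, ped, recs, design = toy
    est1 = reml_variance_components(design, max_iter=200)
    shuffled = recs.sample(frac=1.0, random_state=1)
    design2 = ModelDesign.from_frame(encode_model_frame(shuffled, ped), ped)
    est2 = reml_variance_components(design2, max_iter=200)
    np.testing.assert_allclose(est1.as_tuple(), est2.as_tuple(), rtol=1e-6)


def test_reml_zero_direct_variance_pins_at_boundary():
    cfg = SimulationConfig(
        seed=21, n_founders=220, founder_male_fraction=0.1, n_generations=1,
        n_herds=4, years=(2006, 2010), phenotype_mode="gaussian",
        variance_components=VarianceComponents(0.05, 0.0, 0.3, 0.0, 0.5),
    )
    ped = simulate_pedigree(cfg)
    recs = simulate_phenotypes(ped, None, cfg)
    design = ModelDesign.from_frame(encode_model_frame(recs, ped), ped)
    est = reml_variance_components(design, max_iter=300)
    assert est.direct < 0.1 * est.maternal


def test_blup_matches_dense_gls(toy):
    """MME solutions equal dense GLS/BLUP computed by brute inversion."""
    _, ped, _, design = toy
    vc = VarianceComponents(0.12, 0.1, 0.25, 0.03, 0.45)
    res = blup_solve(design, vc, compute_pev=True)
    assert res.residual_norm < 1e-8

    V, X = _dense_v(design, ped, vc)
    y = design.y
    Vi = np.linalg.inv(V)
    XVX_i = np.linalg.inv(X.T @ Vi @ X)
    beta = XVX_i @ X.T @ Vi @ y
    np.testing.assert_allclose(
        res.fixed_solutions["estimate"].to_numpy(), beta, atol=1e-8
    )
    # u_hat = G Z' P y  (dense BLUP of the maternal effects)
    A = ped.relationship_matrix()
    G0 = vc.genetic_covariance_matrix()
    P = Vi - Vi @ X @ XVX_i @ X.T @ Vi
    Zd = design.Zd.toarray()
    Zm = design.Zm.toarray()
    m_hat = (G0[0, 1] * A @ Zd.T + G0[1, 1] * A @ Zm.T) @ P @ y
    got = res.ebv[res.ebv["trait"] == "mbm"]["ebv_raw"].to_numpy()
    np.testing.assert_allclose(got, m_hat, atol=1e-8)


def test_unrecorded_unrelated_animal_has_zero_ebv(toy):
    """A founder with no records and no recorded descendants stays at the
    population mean (EBV 0)."""
    _, ped, recs, design = toy
    vc = VarianceComponents(0.12, 0.1, 0.25, 0.03, 0.45)
    res = blup_solve(design, vc, compute_pev=False)
    used = set(recs["calf"]) | set(recs["dam"]) | set(recs["sire"])
    lonely = [a for a in ped.ids if a not in used]
    if lonely:
        sub = res.ebv[res.ebv["animal"].isin(lonely)]
        np.testing.assert_allclose(sub["ebv_raw"].to_numpy(), 0.0, atol=1e-10)


def test_pev_matches_resampling(toy):
    """Exact PEV from the inverted coefficient matrix agrees with the
    Monte-Carlo PEV over fresh simulation replicates of the same design."""
    cfg, ped, recs, design = toy
    vc = cfg.variance_components
    res = blup_solve(design, vc, compute_pev=True)
    rng = np.random.default_rng(0)
    errs = []
    from twinqtl.simherd import sample_breeding_values
    from twinqtl.animal_model import _MmeWorkspace
    ws = _MmeWorkspace(design)
    _, lu = ws.factorize(vc)
    W = design.W
    for rep in range(400):
        u = sample_breeding_values(ped, cfg, np.random.default_rng(rep + 1))
        h = rng.normal(0, np.sqrt(vc.herd_year), design.q_h)
        e = rng.normal(0, np.sqrt(vc.residual), design.n)
        y = (
            np.asarray(design.Zd @ u[:, 0]).ravel()
            + np.asarray(design.Zm @ u[:, 1]).ravel()
            + np.asarray(W @ h).ravel()
            + e
        )
        rhs = np.asarray(ws.M.T @ y).ravel() / vc.residual
        sol = lu.solve(rhs)
        errs.append(
            np.column_stack([sol[ws.sl_a] - u[:, 0], sol[ws.sl_m] - u[:, 1]])
        )
    errs = np.stack(errs)  # (rep, N, 2)
    mc_pev_m = errs[:, :, 1].var(axis=0)
    exact = res.ebv[res.ebv["trait"] == "mbm"]["pev"].to_numpy()
    # Monte-Carlo error at 400 replicates: compare means over animals
    assert mc_pev_m.mean() == pytest.approx(exact.mean(), rel=0.1)


def test_heritabilities_conventions():
    assert heritabilities(VarianceComponents(0, 0, 0, 0, 1.0)) == (0.0, 0.0)
    h = heritabilities(VarianceComponents(0, 1.0, 1.0, 0, 1.0))
    assert h[0] == pytest.approx(1 / 3)
    assert h[1] == pytest.approx(1 / 3)
    with pytest.raises(ModelError):
        heritabilities(VarianceComponents(0, 0, 0, 0, 0))


def test_reliability_limits():
    np.testing.assert_allclose(reliability(np.array([0.2]), 0.2), [0.0])
    np.testing.assert_allclose(reliability(np.array([0.0]), 0.2), [1.0])
    with pytest.raises(ModelError):
        reliability(np.array([0.1]), 0.0)


def _fake_ebvs(ped, rng):
    return pd.DataFrame(
        {
            "animal": np.concatenate([ped.ids, ped.ids]),
            "trait": ["mbd"] * len(ped) + ["mbm"] * len(ped),
            "ebv_raw": rng.normal(0, 2, 2 * len(ped)),
        }
    )


def test_standardize_base_group_exact(small_pedigree):
    rng = np.random.default_rng(2)
    ebvs = _fake_ebvs(small_pedigree, rng)
    rule = BaseGroupRule(breed=None, age_range_years=(8, 10))
    out = standardize_ebv(ebvs, small_pedigree, rule)
    base = out[out["is_base"]]
    for _, grp in base.groupby("trait"):
        assert grp["ebv_std"].mean() == pytest.approx(100.0)
        assert grp["ebv_std"].std(ddof=1) == pytest.approx(12.0)


def test_standardize_affine_invariance(small_pedigree):
    rng = np.random.default_rng(5)
    ebvs = _fake_ebvs(small_pedigree, rng)
    rule = BaseGroupRule(breed=None)
    a = standardize_ebv(ebvs, small_pedigree, rule)
    doubled = ebvs.assign(ebv_raw=2.0 * ebvs["ebv_raw"])
    b = standardize_ebv(doubled, small_pedigree, rule)
    np.testing.assert_allclose(a["ebv_std"], b["ebv_std"], atol=1e-9)


def test_standardize_degenerate_base_fails(small_pedigree):
    ebvs = _fake_ebvs(small_pedigree, np.random.default_rng(0))
    ebvs["ebv_raw"] = 1.0
    with pytest.raises(ModelError):
        standardize_ebv(ebvs, small_pedigree, BaseGroupRule(breed=None))


def test_genetic_trend_flat_when_ebvs_equal(small_pedigree):
    ebvs = _fake_ebvs(small_pedigree, np.random.default_rng(0))
    ebvs["ebv_raw"] = 3.0
    trend = genetic_trend(ebvs, small_pedigree)
    ok = trend.dropna(subset=["mean"])
    np.testing.assert_allclose(ok["mean"], 3.0)


def test_genetic_trend_detects_selection(small_pedigree):
    """EBVs rising with birth year give a positive regression slope."""
    ped = small_pedigree
    years = ped.table.set_index("id")["birth_year"]
    rng = np.random.default_rng(1)
    ebvs = _fake_ebvs(ped, rng)
    ebvs["ebv_raw"] = (
        0.5 * years.loc[ebvs["animal"]].to_numpy()
        + rng.normal(0, 0.5, len(ebvs))
    )
    trend = genetic_trend(ebvs, ped)
    sub = trend.dropna(subset=["mean"])
    slope = np.polyfit(sub["year"], sub["mean"], 1)[0]
    assert slope > 0.3
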