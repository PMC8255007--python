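"""Direct-maternal animal model: REML, BLUP, reliabilities, trend.

The model for the 1/2-coded multiple-birth response is

    y = X b + W h + Z_d a + Z_m m + e,

with fixed effects b (parity, season, sexed semen, age-of-dam covariate),
random herd-year h ~ N(0, I sigma2_h), correlated direct and maternal
additive effects (a, m) ~ N(0, G0 x A) where G0 is the 2x2 genetic
(co)variance matrix and A the pedigree numerator relationship matrix, and
residual e ~ N(0, I sigma2_e).

Variance components are estimated by average-information REML on the
sparse mixed-model equations, with expectation-maximisation fallback steps
whenever an AI update leaves the parameter space.  First derivatives use
the standard mixed-model-equation trace identities; the traces are exact
(dense inverse) on small systems and Hutchinson-probe estimates with a
fixed internal seed on large ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

logger = logging.getLogger(__name__)

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import VarianceComponents, ConfigError
from .pedigree import Pedigree
from .records import ModelFrame

TRAITS = ("mbd", "mbm")


class ModelError(RuntimeError):
    pass


class RemlNonConvergence(ModelError):
    def __init__(self, msg, last: VarianceComponents, trajectory: list):
        super().__init__(msg)
        self.last = last
        self.trajectory = trajectory


def build_a_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse inverse numerator relationship matrix (Henderson's rules with
    Meuwissen-Luo inbreeding)."""
    return pedigree.a_inverse()


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class ModelDesign:
    """Assembled design matrices for one trait evaluation.

    Fixed effects use full-rank coding: intercept, then dummies for every
    observed non-reference level of parity/season/sexed semen, then the
    centred age-of-dam covariate.  Random design matrices map records to
    herd-year levels and to calf/dam rows of the pedigree.
    """

    y: np.ndarray
    X: sp.csr_matrix
    W: sp.csr_matrix
    Zd: sp.csr_matrix
    Zm: sp.csr_matrix
    fixed_names: List[str]
    herd_year_levels: List[str]
    pedigree: Pedigree

    @classmethod
    def from_frame(cls, frame: ModelFrame, pedigree: Pedigree) -> "ModelDesign":
        d = frame.data
        n = len(d)
        cols = [np.ones(n)]
        names = ["intercept"]
        for factor in ("parity", "season", "sexed_semen"):
            cat = d[factor]
            observed = [l for l in cat.cat.categories if (cat == l).any()]
            for lev in observed[1:]:
                cols.append((cat == lev).to_numpy(dtype=float))
                names.append(f"{factor}:{lev}")
        age = d["age_of_dam"].to_numpy(dtype=float)
        cols.append(age - age.mean())
        names.append("age_of_dam")
        X = np.column_stack(cols)
        # guard against confounded fixed-effect columns
        rank = np.linalg.matrix_rank(X.T @ X)
        if rank < X.shape[1]:
            raise ModelError(
                "singular fixed-effect block; check for confounded levels "
                f"among {names}"
            )

        hy = d["herd_year"].astype(str)
        levels = sorted(hy.unique())
        level_pos = {l: j for j, l in enumerate(levels)}
        W = sp.csr_matrix(
            (np.ones(n), (np.arange(n), hy.map(level_pos).to_numpy())),
            shape=(n, len(levels)),
        )
        N = len(pedigree)
        calf_idx = pedigree.index_of(d["calf"].to_numpy())
        dam_idx = pedigree.index_of(d["dam"].to_numpy())
        Zd = sp.csr_matrix((np.ones(n), (np.arange(n), calf_idx)), shape=(n, N))
        Zm = sp.csr_matrix((np.ones(n), (np.arange(n), dam_idx)), shape=(n, N))
        return cls(
            y=d["y"].to_numpy(dtype=float),
            X=sp.csr_matrix(X),
            W=W,
            Zd=Zd,
            Zm=Zm,
            fixed_names=names,
            herd_year_levels=levels,
            pedigree=pedigree,
        )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q_h(self) -> int:
        return self.W.shape[1]

    @property
    def n_animals(self) -> int:
        return self.Zd.shape[1]


# ---------------------------------------------------------------------------
# internal MME assembly
# ---------------------------------------------------------------------------

class _MmeWorkspace:
    """Caches the pieces of the mixed-model equations that do not change
    across REML iterations."""

    def __init__(self, design: ModelDesign):
        self.design = design
        self.M = sp.hstack(
            [design.X, design.W, design.Zd, design.Zm], format="csr"
        )
        self.MtM = (self.M.T @ self.M).tocsr()
        self.Mty = np.asarray(self.M.T @ design.y).ravel()
        self.yty = float(design.y @ design.y)
        self.Ainv = design.pedigree.a_inverse().tocsc()
        # A acts on vectors through A = T D T' (gene-flow decomposition):
        # two sparse triangular solves, no factorization of A or A^-1
        self._Tinv, self._dvec = design.pedigree.gene_flow_operator()
        self._Tinv_T = self._Tinv.T.tocsr()
        self.log_det_a = design.pedigree.log_det_a()
        p, qh, N = design.p, design.q_h, design.n_animals
        self.sl_f = slice(0, p)
        self.sl_h = slice(p, p + qh)
        self.sl_a = slice(p + qh, p + qh + N)
        self.sl_m = slice(p + qh + N, p + qh + 2 * N)
        self.dim = p + qh + 2 * N

    def coefficient_matrix(self, vc: VarianceComponents) -> sp.csc_matrix:
        d = self.design
        G0inv = np.linalg.inv(vc.genetic_covariance_matrix())
        Ginv = sp.block_diag(
            [
                sp.identity(d.q_h, format="csr") / vc.herd_year,
                sp.kron(G0inv, self.Ainv, format="csr"),
            ],
            format="csr",
        )
        pad = sp.block_diag([sp.csr_matrix((d.p, d.p)), Ginv], format="csr")
        return (self.MtM / vc.residual + pad).tocsc()

    def factorize(self, vc: VarianceComponents):
        # C is symmetric positive definite: symmetric-mode minimum-degree
        # ordering with (near-)diagonal pivoting keeps the factorization
        # sparse even when components sit on wildly different scales;
        # partial pivoting would wreck the ordering and explode the fill
        C = self.coefficient_matrix(vc)
        lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A",
                       options=dict(SymmetricMode=True,
                                    DiagPivotThresh=0.001))
        return C, lu

    def solve_mme(self, lu, vc: VarianceComponents) -> np.ndarray:
        return lu.solve(self.Mty / vc.residual)

    def apply_A(self, v: np.ndarray) -> np.ndarray:
        """A v via T (D (T' v)) with T = (I - P)^-1."""
        u = spla.spsolve_triangular(self._Tinv_T, v, lower=False,
                                    unit_diagonal=True)
        return spla.spsolve_triangular(self._Tinv, self._dvec * u, lower=True,
                                       unit_diagonal=True)

    def log_likelihood(self, lu, vc: VarianceComponents, sol: np.ndarray) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        d = self.design
        G0 = vc.genetic_covariance_matrix()
        sign, ld_g0 = np.linalg.slogdet(G0)
        if sign <= 0:
            return -np.inf
        log_det_c = float(np.log(np.abs(lu.U.diagonal())).sum())
        ypy = (self.yty - sol @ self.Mty) / vc.residual
        m2ll = (
            d.n * np.log(vc.residual)
            + d.q_h * np.log(vc.herd_year)
            + d.n_animals * ld_g0
            + 2.0 * self.log_det_a
            + log_det_c
            + ypy
        )
        return -0.5 * m2ll


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _traces(ws: _MmeWorkspace, lu, dense_threshold: int, n_probes: int,
            probe_rng: np.random.Generator) -> Tuple[float, np.ndarray]:
    """(tr C^hh, 2x2 matrix of tr(A^-1 C^{ij})) for i,j in {direct, maternal}.

    Exact by dense inversion when the system is small; otherwise Hutchinson
    Rademacher-probe estimates sharing one sparse factorization.
    """
    d = ws.design
    if ws.dim <= dense_threshold:
        eye = np.eye(ws.dim)
        Cinv = lu.solve(eye)
        Ad = ws.Ainv.toarray()
        # tr(A^-1 B) with B = blocks of C^-1
        Caa = Cinv[ws.sl_a, ws.sl_a]
        Cam = Cinv[ws.sl_a, ws.sl_m]
        Cmm = Cinv[ws.sl_m, ws.sl_m]
        T = np.array(
            [
                [np.sum(Ad * Caa.T), np.sum(Ad * Cam.T)],
                [np.sum(Ad * Cam.T), np.sum(Ad * Cmm.T)],
            ]
        )
        return float(np.trace(Cinv[ws.sl_h, ws.sl_h])), T

    qh, N = d.q_h, d.n_animals
    Zh = np.where(probe_rng.random((qh, n_probes)) < 0.5, -1.0, 1.0)
    Za = np.where(probe_rng.random((N, n_probes)) < 0.5, -1.0, 1.0)
    Zm_ = np.where(probe_rng.random((N, n_probes)) < 0.5, -1.0, 1.0)
    R = np.zeros((ws.dim, 3 * n_probes))
    R[ws.sl_h, :n_probes] = Zh
    R[ws.sl_a, n_probes:2 * n_probes] = Za
    R[ws.sl_m, 2 * n_probes:] = Zm_
    S = lu.solve(R)
    AinvZa = ws.Ainv @ Za
    AinvZm = ws.Ainv @ Zm_
    t_h = float(np.mean(np.sum(Zh * S[ws.sl_h, :n_probes], axis=0)))
    s_a = S[:, n_probes:2 * n_probes]
    s_m = S[:, 2 * n_probes:]
    T_aa = float(np.mean(np.sum(AinvZa * s_a[ws.sl_a], axis=0)))
    T_am1 = float(np.mean(np.sum(AinvZa * s_a[ws.sl_m], axis=0)))
    T_am2 = float(np.mean(np.sum(AinvZm * s_m[ws.sl_a], axis=0)))
    T_mm = float(np.mean(np.sum(AinvZm * s_m[ws.sl_m], axis=0)))
    T_am = 0.5 * (T_am1 + T_am2)
    return t_h, np.array([[T_aa, T_am], [T_am, T_mm]])


def _score_and_em(ws: _MmeWorkspace, lu, vc: VarianceComponents,
                  sol: np.ndarray, t_h: float, T: np.ndarray):
    """REML score vector and the EM update, from shared MME quantities.

    Parameter order: (sigma2_h, sigma2_a, sigma2_m, sigma_am, sigma2_e).
    """
    d = ws.design
    n, p, qh, N = d.n, d.p, d.q_h, d.n_animals
    h_hat = sol[ws.sl_h]
    U = np.column_stack([sol[ws.sl_a], sol[ws.sl_m]])
    UAU = U.T @ (ws.Ainv @ U)
    e_hat = d.y - ws.M @ sol

    G0 = vc.genetic_covariance_matrix()
    G0inv = np.linalg.inv(G0)

    g_h = -0.5 * (
        qh / vc.herd_year
        - t_h / vc.herd_year**2
        - (h_hat @ h_hat) / vc.herd_year**2
    )
    S_G = -0.5 * (N * G0inv - G0inv @ (UAU + T) @ G0inv)
    tr_ginv_cuu = (
        t_h / vc.herd_year
        + G0inv[0, 0] * T[0, 0]
        + 2.0 * G0inv[0, 1] * T[0, 1]
        + G0inv[1, 1] * T[1, 1]
    )
    tr_p = (n - p - qh - 2 * N + tr_ginv_cuu) / vc.residual
    g_e = -0.5 * (tr_p - (e_hat @ e_hat) / vc.residual**2)
    score = np.array([g_h, S_G[0, 0], S_G[1, 1], 2.0 * S_G[0, 1], g_e])

    em = VarianceComponents(
        herd_year=float((h_hat @ h_hat + t_h) / qh),
        direct=float((UAU[0, 0] + T[0, 0]) / N),
        maternal=float((UAU[1, 1] + T[1, 1]) / N),
        direct_maternal=float((UAU[0, 1] + T[0, 1]) / N),
        residual=float((d.y @ e_hat) / (n - p)),
    )
    return score, em, e_hat


def _ai_matrix(ws: _MmeWorkspace, lu, vc: VarianceComponents,
               e_hat: np.ndarray) -> np.ndarray:
    """Average-information matrix via working vectors f_i = dV/dtheta_i P y."""
    d = ws.design
    Py = e_hat / vc.residual
    t_a = np.asarray(d.Zd.T @ Py).ravel()
    t_m = np.asarray(d.Zm.T @ Py).ravel()
    x_a = ws.apply_A(t_a)
    x_m = ws.apply_A(t_m)
    F = np.column_stack(
        [
            np.asarray(d.W @ (d.W.T @ Py)).ravel(),
            np.asarray(d.Zd @ x_a).ravel(),
            np.asarray(d.Zm @ x_m).ravel(),
            np.asarray(d.Zd @ x_m + d.Zm @ x_a).ravel(),
            Py,
        ]
    )
    MtF = np.asarray(ws.M.T @ F)
    S = lu.solve(MtF / vc.residual)
    AI = 0.5 * (F.T @ F - MtF.T @ S) / vc.residual
    return 0.5 * (AI + AI.T)


_MAX_GENETIC_CORRELATION = 0.99


def _project(theta: np.ndarray, floor: float, vary: float) -> np.ndarray:
    """Project a candidate into a numerically safe region of the
    parameter space: variances boxed between the floor and 10x the
    response variance (the residual additionally bounded below by
    var(y)/1000, since a residual near zero makes the mixed-model
    equations numerically rank-deficient), and the direct-maternal
    correlation capped so the genetic covariance stays invertible."""
    out = theta.copy()
    cap = 10.0 * vary
    out[[0, 1, 2]] = np.clip(out[[0, 1, 2]], floor, cap)
    out[4] = np.clip(out[4], max(floor, 1e-3 * vary), cap)
    bound = np.sqrt(out[1] * out[2]) * _MAX_GENETIC_CORRELATION
    out[3] = np.clip(out[3], -bound, bound)
    return out


def _trust_clip(theta: np.ndarray, cand: np.ndarray, factor: float) -> np.ndarray:
    """Limit each variance to change by at most ``factor`` multiplicatively
    in one step.  A single wild update that crashes a variance to the
    floor would strand the iteration there (the floor is an absorbing
    state of the EM map); bounded steps can still reach a genuine zero,
    just geometrically."""
    out = cand.copy()
    for i in (0, 1, 2, 4):
        lo, hi = theta[i] / factor, theta[i] * factor
        out[i] = np.clip(out[i], lo, hi)
    return out


_PROBE_SEED = 20210703  # fixed: REML must be deterministic


def _moment_init(design: ModelDesign) -> VarianceComponents:
    """Method-of-moments starting values.

    Ordinary-least-squares residuals of the fixed part are decomposed via
    unbiased within-group pair covariances: records sharing a herd-year
    estimate sigma2_h, records of one dam estimate sigma2_m (plus small
    sib terms), and paternal half sibs estimate sigma2_a / 4.  Crude, but
    close enough that the AI iteration converges in a handful of steps.
    """
    X = design.X.toarray()
    y = design.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    vary = float(np.var(r))

    def pair_cov(groups: np.ndarray) -> float:
        df = pd.DataFrame({"g": groups, "r": r, "r2": r * r})
        agg = df.groupby("g").agg(s=("r", "sum"), q=("r2", "sum"),
                                  k=("r", "size"))
        pairs = agg["k"] * (agg["k"] - 1) / 2.0
        total = float(((agg["s"] ** 2 - agg["q"]) / 2.0).sum())
        n_pairs = float(pairs.sum())
        return total / n_pairs if n_pairs > 0 else 0.0

    hy = np.asarray(design.W.argmax(axis=1)).ravel()
    dam = np.asarray(design.Zm.argmax(axis=1)).ravel()
    lo = 1e-4 * vary
    s_h = float(np.clip(pair_cov(hy), lo, 0.3 * vary))
    # a dam calves once per year, so her records never share a herd-year
    s_m = float(np.clip(pair_cov(dam), lo, 0.3 * vary))
    s_a = max(0.1 * s_m, lo)
    s_e = max(vary - s_h - s_m - s_a, 0.3 * vary)
    return VarianceComponents(
        herd_year=s_h,
        direct=s_a,
        maternal=s_m,
        direct_maternal=0.0,
        residual=s_e,
    )


def reml_variance_components(
    design: ModelDesign,
    init: Optional[VarianceComponents] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    dense_threshold: int = 6000,
    n_probes: int = 32,
    boundary_floor: float = 1e-12,
) -> VarianceComponents:
    """Estimate (sigma2_h, sigma2_a, sigma2_m, sigma_am, sigma2_e) by REML.

    Average-information updates with step halving against likelihood
    decrease, EM fallback when an AI step leaves the parameter space, and
    boundary clamping at ``boundary_floor``.  Convergence is declared when
    the relative change in the restricted log-likelihood drops below
    ``tol``.  Raises :class:`RemlNonConvergence` with the last iterate and
    the trajectory otherwise.
    """
    ws = _MmeWorkspace(design)
    vary = float(np.var(design.y))
    if vary <= 0:
        raise ModelError("response has zero variance")
    # absolute floor scaled to the data so the clamped MME stays factorable
    boundary_floor = max(boundary_floor, 1e-8 * vary)
    if init is None:
        init = _moment_init(design)
    init.validate()
    probe_rng = np.random.default_rng(_PROBE_SEED)
    # one fixed probe set, reused every iteration: the iteration map stays
    # deterministic and smooth in theta
    probes_state = probe_rng.bit_generator.state

    vc = replace(init)
    trajectory = []
    C, lu = ws.factorize(vc)
    sol = ws.solve_mme(lu, vc)
    ll = ws.log_likelihood(lu, vc, sol)
    lam_carry = 1e-6
    ai_mode = True        # damped-AI steps until they stall, then EM mode
    prev_em_delta = None  # for Aitken extrapolation of EM crawls
    for it in range(max_iter):
        probe_rng.bit_generator.state = probes_state
        t_h, T = _traces(ws, lu, dense_threshold, n_probes, probe_rng)
        logger.debug("it=%d traces done", it)
        score, em, e_hat = _score_and_em(ws, lu, vc, sol, t_h, T)
        AI = _ai_matrix(ws, lu, vc, e_hat)
        logger.debug("it=%d AI done", it)
        theta = np.array(vc.as_tuple())

        # Levenberg-Marquardt damped AI step: the AI matrix can be nearly
        # singular when components sit on very different scales, so damp
        # progressively until a parameter-space, likelihood-increasing step
        # is found; otherwise fall back to one EM update.
        new_vc, new_ll, new_lu, new_sol = None, -np.inf, None, None
        em_used = True
        if ai_mode:
            lam = max(lam_carry, 1e-8)
            ai_diag = np.abs(np.diag(AI))
            for _ in range(14):
                try:
                    delta = np.linalg.solve(AI + lam * np.diag(ai_diag), score)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = _project(
                    _trust_clip(theta, theta + delta, 10.0),
                    boundary_floor, vary,
                )
                cvc = VarianceComponents(*cand)
                logger.debug("it=%d LM lam=%.1e cand=%s", it, lam,
                             np.array2string(cand, precision=3))
                try:
                    _, clu = ws.factorize(cvc)
                except RuntimeError:
                    lam *= 10.0
                    continue
                csol = ws.solve_mme(clu, cvc)
                cll = ws.log_likelihood(clu, cvc, csol)
                if np.isfinite(cll) and cll >= ll - 1e-10:
                    new_vc, new_ll, new_lu, new_sol = cvc, cll, clu, csol
                    em_used = False
                    # classic LM schedule: relax damping after success,
                    # tighten after failures
                    lam_carry = lam / 10.0
                    break
                lam *= 10.0
        if new_vc is None:
            if ai_mode:
                lam_carry = lam
            # EM step, projected into the parameter space
            cand = _project(np.array(em.as_tuple()), boundary_floor, vary)
            new_vc = VarianceComponents(*cand)
            try:
                _, new_lu = ws.factorize(new_vc)
            except RuntimeError:
                # numerically degenerate at the boundary: stop here
                vc.se = None
                return vc
            new_sol = ws.solve_mme(new_lu, new_vc)
            new_ll = ws.log_likelihood(new_lu, new_vc, new_sol)
        # Aitken-style acceleration: when successive steps (AI or EM)
        # shrink geometrically -- the signature of a ridge or boundary
        # crawl -- extrapolate along the step direction, trying the Aitken
        # multiplier first and shorter jumps after it
        delta = np.array(new_vc.as_tuple()) - theta
        if prev_em_delta is not None:
            num = float(np.linalg.norm(delta))
            den = float(np.linalg.norm(prev_em_delta))
            if 0 < num < den and num / den > 0.5:
                aitken = min(1.0 / (1.0 - num / den), 512.0)
                for mult in (aitken, 128.0, 32.0, 8.0):
                    if mult > aitken:
                        continue
                    acc = _project(theta + mult * delta, boundary_floor, vary)
                    avc = VarianceComponents(*acc)
                    try:
                        _, alu = ws.factorize(avc)
                        asol = ws.solve_mme(alu, avc)
                        all_ = ws.log_likelihood(alu, avc, asol)
                    except RuntimeError:
                        continue
                    if np.isfinite(all_) and all_ > new_ll:
                        new_vc, new_ll = avc, all_
                        new_lu, new_sol = alu, asol
                        delta = None
                        break
        prev_em_delta = delta
        trajectory.append((it, new_vc.as_tuple(), new_ll))
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "it=%d step=%s ll=%.6f theta=%s",
                it, "EM" if em_used else "AI", new_ll,
                np.array2string(np.array(new_vc.as_tuple()), precision=3),
            )
        if em_used and new_ll < ll - tol * (abs(ll) + 1.0):
            # with Monte-Carlo traces the EM map is slightly perturbed; a
            # likelihood-decreasing EM step means we are within the trace
            # precision of a stationary point -- keep the better iterate
            vc.se = None
            return vc
        thresh = tol * (abs(ll) + 1.0)
        dll = abs(new_ll - ll)
        vc, ll, lu, sol = new_vc, new_ll, new_lu, new_sol
        if em_used:
            if dll < thresh:
                # an EM step that cannot move the likelihood means we sit
                # at a stationary point; a stalled damped-AI step does not
                vc.se = None
                return vc
            # stay in EM mode while it crawls (lets Aitken extrapolate);
            # hand back to AI once EM moves the likelihood substantially
            ai_mode = dll > 1e3 * thresh
        elif dll < thresh:
            # apparent AI convergence must be confirmed by EM
            ai_mode = False
    raise RemlNonConvergence(
        f"REML did not converge in {max_iter} iterations", vc, trajectory
    )


def reml_log_likelihood(design: ModelDesign, vc: VarianceComponents) -> float:
    """Restricted log-likelihood at ``vc`` (same constant convention as the
    dense formula -0.5[log|V| + log|X'V^-1 X| + y'Py])."""
    ws = _MmeWorkspace(design)
    _, lu = ws.factorize(vc)
    sol = ws.solve_mme(lu, vc)
    return ws.log_likelihood(lu, vc, sol)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def heritabilities(vc: VarianceComponents) -> Tuple[float, float]:
    """(direct, maternal) heritability.

    The phenotypic variance sums all components with the direct-maternal
    covariance counted once: sigma2_p = sigma2_h + sigma2_a + sigma2_m +
    sigma_am + sigma2_e.
    """
    s2p = vc.phenotypic
    if s2p <= 0:
        raise ModelError("non-positive phenotypic variance")
    return vc.direct / s2p, vc.maternal / s2p


@dataclass
class BlupResult:
    fixed_solutions: pd.DataFrame      # name, estimate
    ebv: pd.DataFrame                  # animal, trait, ebv_raw, pev, reliability
    herd_year_solutions: pd.DataFrame  # level, estimate
    residual_norm: float               # ||C s - rhs||


def blup_solve(
    design: ModelDesign,
    vc: VarianceComponents,
    compute_pev: bool = True,
    pev_chunk: int = 256,
) -> BlupResult:
    """Solve Henderson's mixed-model equations at fixed variance components.

    Returns fixed-effect solutions, direct (mbd) and maternal (mbm) EBVs
    for every pedigree animal, and (optionally) exact prediction-error
    variances from the genetic diagonal blocks of the inverted coefficient
    matrix, with reliabilities r2 = 1 - PEV/sigma2_g clamped to [0, 1].
    """
    vc.validate()
    ws = _MmeWorkspace(design)
    C, lu = ws.factorize(vc)
    rhs = ws.Mty / vc.residual
    sol = lu.solve(rhs)
    res_norm = float(np.linalg.norm(C @ sol - rhs))

    fixed = pd.DataFrame(
        {"name": design.fixed_names, "estimate": sol[ws.sl_f]}
    )
    hy = pd.DataFrame(
        {"level": design.herd_year_levels, "estimate": sol[ws.sl_h]}
    )

    ids = design.pedigree.ids
    N = design.n_animals
    a_hat, m_hat = sol[ws.sl_a], sol[ws.sl_m]
    pev_a = np.full(N, np.nan)
    pev_m = np.full(N, np.nan)
    if compute_pev:
        offs_a = ws.sl_a.start
        offs_m = ws.sl_m.start
        for lo in range(0, N, pev_chunk):
            hi = min(lo + pev_chunk, N)
            k = hi - lo
            E = np.zeros((ws.dim, 2 * k))
            E[offs_a + lo:offs_a + hi, :k] = np.eye(k)
            E[offs_m + lo:offs_m + hi, k:] = np.eye(k)
            S = lu.solve(E)
            pev_a[lo:hi] = S[offs_a + lo:offs_a + hi, :k].diagonal()
            pev_m[lo:hi] = S[offs_m + lo:offs_m + hi, k:].diagonal()

    rel_a = reliability(pev_a, vc.direct) if compute_pev else np.full(N, np.nan)
    rel_m = reliability(pev_m, vc.maternal) if compute_pev else np.full(N, np.nan)
    ebv = pd.concat(
        [
            pd.DataFrame(
                {"animal": ids, "trait": "mbd", "ebv_raw": a_hat,
                 "pev": pev_a, "reliability": rel_a}
            ),
            pd.DataFrame(
                {"animal": ids, "trait": "mbm", "ebv_raw": m_hat,
                 "pev": pev_m, "reliability": rel_m}
            ),
        ],
        ignore_index=True,
    )
    return BlupResult(fixed, ebv, hy, res_norm)


def reliability(pev: np.ndarray, sigma2_g: float) -> np.ndarray:
    """r2 = 1 - PEV / sigma2_g, clamped to [0, 1]."""
    if sigma2_g <= 0:
        raise ModelError("genetic variance must be positive for reliability")
    pev = np.asarray(pev, dtype=float)
    if np.nanmin(pev) < -1e-12:
        raise ModelError("negative prediction-error variance")
    return np.clip(1.0 - pev / sigma2_g, 0.0, 1.0)


@dataclass
class BaseGroupRule:
    """Base-population definition for EBV standardization: sires of the
    main breed born 8-10 years before the evaluation year."""

    sex: str = "M"
    age_range_years: Tuple[int, int] = (8, 10)
    eval_year: Optional[int] = None  # default: max birth year in pedigree
    breed: Optional[str] = "Holstein"
    min_breed_fraction: float = 7.0 / 8.0
    target_mean: float = 100.0
    target_sd: float = 12.0


def standardize_ebv(
    ebvs: pd.DataFrame,
    pedigree: Pedigree,
    base_rule: Optional[BaseGroupRule] = None,
) -> pd.DataFrame:
    """Affine-transform raw EBVs so the base group has mean 100 and SD 12.

    The transform is computed per trait on the base group and applied to
    all animals; a base group smaller than two animals or with zero EBV
    spread is an error.
    """
    rule = base_rule or BaseGroupRule()
    t = pedigree.table
    eval_year = rule.eval_year
    if eval_year is None:
        eval_year = int(t["birth_year"].max())
    lo, hi = eval_year - rule.age_range_years[1], eval_year - rule.age_range_years[0]
    mask = (
        (t["sex"].to_numpy() == rule.sex)
        & (t["birth_year"].to_numpy() >= lo)
        & (t["birth_year"].to_numpy() <= hi)
    )
    if rule.breed is not None and pedigree.breed_columns:
        mask &= pedigree.breed_fraction(rule.breed) >= rule.min_breed_fraction
    base_ids = set(int(i) for i in t["id"].to_numpy()[mask])

    out = ebvs.copy()
    out["ebv_std"] = np.nan
    out["is_base"] = out["animal"].astype(int).isin(base_ids)
    for trait, grp in out.groupby("trait"):
        base = grp[grp["is_base"]]
        if len(base) < 2:
            raise ModelError(
                f"base group for trait {trait!r} has {len(base)} animals (< 2)"
            )
        mu = base["ebv_raw"].mean()
        sd = base["ebv_raw"].std(ddof=1)
        if sd <= 0:
            raise ModelError(f"base group for trait {trait!r} has zero EBV spread")
        out.loc[grp.index, "ebv_std"] = (
            rule.target_mean + rule.target_sd * (grp["ebv_raw"] - mu) / sd
        )
    return out


def genetic_trend(
    ebvs: pd.DataFrame,
    pedigree: Pedigree,
    year_range: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-birth-year mean standardized EBV, by trait: (trait, year, n,
    mean, sd).  Years without animals yield n=0 rows with missing mean."""
    col = "ebv_std" if "ebv_std" in ebvs.columns else "ebv_raw"
    t = pedigree.table[["id", "birth_year"]]
    merged = ebvs.merge(t, left_on="animal", right_on="id")
    if year_range is None:
        year_range = (int(t["birth_year"].min()), int(t["birth_year"].max()))
    rows = []
    for trait, grp in merged.groupby("trait"):
        for yr in range(year_range[0], year_range[1] + 1):
            sel = grp[grp["birth_year"] == yr][col]
            rows.append(
                (
                    trait,
                    yr,
                    len(sel),
                    float(sel.mean()) if len(sel) else np.nan,
                    float(sel.std(ddof=1)) if len(sel) > 1 else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=["trait", "year", "n", "mean", "sd"])
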