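"""Genomic relationship matrix and single-SNP mixed-model association.

The scan regresses de-regressed EBVs on one marker at a time while a
random polygenic effect a ~ N(0, G sigma2_a) absorbs population
stratification; G is the VanRaden method-1 genomic relationship matrix.
Variance components are estimated once under the marker-free null model
via the eigen-rotated profile REML, then every marker is tested by
generalized least squares with the rotation fixed (single-rotation
strategy; no per-marker REML).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree


class AssocError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class GrmResult:
    matrix: np.ndarray
    kept: np.ndarray          # boolean mask over input markers
    frequencies: np.ndarray   # alt-allele frequencies of kept markers
    n_excluded: int


def build_grm(dosages: np.ndarray, maf_floor: float = 0.01) -> GrmResult:
    """VanRaden method-1 GRM from 0/1/2 dosages (animals x markers).

    Dosages are centred at 2p and the cross-product scaled by
    2 * sum p(1-p); monomorphic and sub-MAF markers are excluded and
    counted.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim != 2 or D.shape[0] < 2:
        raise AssocError("need a 2-D dosage matrix with >= 2 animals")
    p = D.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    kept = (maf >= maf_floor) & (D.var(axis=0) > 0)
    if not kept.any():
        raise AssocError("all markers monomorphic or below the MAF floor")
    Z = D[:, kept] - 2.0 * p[kept]
    denom = 2.0 * np.sum(p[kept] * (1.0 - p[kept]))
    G = (Z @ Z.T) / denom
    return GrmResult(G, kept, p[kept], int((~kept).sum()))


def breed_proportion_filter(
    pedigree: Pedigree, min_fraction: float = 0.6, breed: str = "Holstein"
) -> pd.DataFrame:
    """Animals whose pedigree-based gene proportion of ``breed`` is
    strictly greater than ``min_fraction``."""
    frac = pedigree.breed_fraction(breed)
    keep = frac > min_fraction
    return pd.DataFrame(
        {"animal": pedigree.ids[keep], "fraction": frac[keep]}
    )


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

@dataclass
class NullModelFit:
    sigma2_a: float
    sigma2_e: float
    mu: float
    eigenvalues: np.ndarray
    rotation: np.ndarray      # eigenvectors of G, columns orthonormal
    log_likelihood: float

    @property
    def heritability(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0

    def weights(self) -> np.ndarray:
        return self.eigenvalues * self.sigma2_a + self.sigma2_e


def fit_null_model(
    response: np.ndarray,
    grm: np.ndarray,
    bend_tol: float = -1e-6,
) -> NullModelFit:
    """REML fit of y = mu + a + e with a ~ N(0, G sigma2_a).

    Profile restricted likelihood over the ratio delta = sigma2_e /
    sigma2_a in the eigenbasis of G (deterministic; golden-section over
    log delta followed by closed-form variance recovery).  Slightly
    negative eigenvalues within ``bend_tol`` are clamped to zero; anything
    below that is an error.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if grm.shape != (n, n):
        raise AssocError("response and GRM are not conformable")
    lam, U = np.linalg.eigh((grm + grm.T) / 2.0)
    if lam.min() < bend_tol * max(1.0, abs(lam.max())):
        raise AssocError("GRM is not positive semi-definite within tolerance")
    lam = np.clip(lam, 0.0, None)
    ystar = U.T @ y
    xstar = U.T @ np.ones(n)

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = lam + delta                      # Var/sigma2_a in eigenbasis
        xwx = np.sum(xstar**2 / w)
        beta = np.sum(xstar * ystar / w) / xwx
        r = ystar - xstar * beta
        rss = np.sum(r**2 / w)
        s2a = rss / (n - 1)
        return 0.5 * (
            (n - 1) * np.log(s2a) + np.sum(np.log(w)) + np.log(xwx) + (n - 1)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    w = lam + delta
    xwx = np.sum(xstar**2 / w)
    mu = float(np.sum(xstar * ystar / w) / xwx)
    r = ystar - xstar * mu
    s2a = float(np.sum(r**2 / w) / (n - 1))
    return NullModelFit(
        sigma2_a=s2a,
        sigma2_e=s2a * delta,
        mu=mu,
        eigenvalues=lam,
        rotation=U,
        log_likelihood=float(-res.fun),
    )


# ---------------------------------------------------------------------------
# single-SNP scan
# ---------------------------------------------------------------------------

def single_snp_scan(
    response: np.ndarray,
    dosages: np.ndarray,
    null: NullModelFit,
    marker_map: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-marker GLS with variance parameters fixed at the null fit.

    For each marker the allele-substitution effect beta, its standard
    error, a two-sided Wald p-value and the explained variance
    2 p (1-p) beta^2 are reported.  Markers monomorphic in the analysed
    subset are emitted with missing effect and ``flagged=True``.
    """
    y = np.asarray(response, dtype=float)
    D = np.asarray(dosages, dtype=float)
    n, m = D.shape
    if len(y) != n:
        raise AssocError("response and dosages are not conformable")
    U, lam = null.rotation, null.eigenvalues
    w = null.weights()
    ystar = U.T @ y
    onestar = U.T @ np.ones(n)
    Dstar = U.T @ D
    wi = 1.0 / w

    # weighted 2x2 normal equations per marker, vectorised
    a11 = np.sum(onestar**2 * wi)
    a12 = Dstar.T @ (onestar * wi)
    a22 = np.sum(Dstar**2 * wi[:, None], axis=0)
    b1 = np.sum(onestar * ystar * wi)
    b2 = Dstar.T @ (ystar * wi)
    det = a11 * a22 - a12**2
    p_freq = D.mean(axis=0) / 2.0
    mono = (p_freq <= 0.0) | (p_freq >= 1.0) | (det <= 1e-12 * a11 * np.maximum(a22, 1e-300))

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        se = np.sqrt(a11 / det)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan

    out = pd.DataFrame(
        {
            "frequency": p_freq,
            "beta": beta,
            "se": se,
            "variance_explained": 2.0 * p_freq * (1.0 - p_freq) * beta**2,
            "p_value": pval,
            "flagged": mono,
        }
    )
    if marker_map is not None:
        for col in ("chrom", "pos", "id", "ref", "alt"):
            if col in marker_map.columns:
                out.insert(0, col, marker_map[col].to_numpy())
    return out


def bonferroni_significant(
    results: pd.DataFrame, n_tests: int, alpha: float = 0.05
) -> Tuple[pd.DataFrame, float]:
    """Markers with p <= alpha / n_tests, plus the threshold used."""
    if not (0.0 < alpha < 1.0):
        raise AssocError("alpha must be in (0, 1)")
    n_considered = int(results["p_value"].notna().sum())
    if n_tests < n_considered:
        raise AssocError(
            f"n_tests={n_tests} smaller than the {n_considered} results considered"
        )
    threshold = alpha / n_tests
    keep = results["p_value"] <= threshold
    return results[keep.fillna(False)].copy(), threshold


def manhattan_frame(results: pd.DataFrame) -> pd.DataFrame:
    """(chromosome, position, -log10 p) table for plotting."""
    ok = results["p_value"].notna()
    return pd.DataFrame(
        {
            "chrom": results.loc[ok, "chrom"],
            "pos": results.loc[ok, "pos"],
            "neglog10p": -np.log10(results.loc[ok, "p_value"]),
        }
    )
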