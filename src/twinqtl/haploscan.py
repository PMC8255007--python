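"""Exhaustive odd-length sliding-haplotype association scan.

Within a target segment every window of L consecutive markers (L odd,
default 9..301), shifted SNP-wise, is enumerated; for each window every
distinct phased haplotype above a frequency floor becomes a 0/1/2 dosage
regressor tested by the same fixed-rotation GLS machinery as the
single-SNP scan.  Windows whose focal-haplotype dosage vectors coincide
necessarily yield identical statistics, which is what produces runs of
equal-effect rows among the top hits.  The top haplotype's diplotype
dosage feeds the LD fine-mapping stage and can be tested against other
de-regressed traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import NullModelFit, fit_null_model
from .simherd import PhasedGenotypes


class HaploscanError(RuntimeError):
    pass


DEFAULT_LENGTHS = tuple(range(9, 302, 2))


@dataclass(frozen=True)
class Segment:
    chromosome: int
    start_bp: int
    end_bp: int

    @classmethod
    def parse(cls, text: str) -> "Segment":
        chrom, span = text.split(":")
        lo, hi = span.replace(",", "").split("-")
        return cls(int(chrom), int(lo), int(hi))


def enumerate_windows(
    marker_map: pd.DataFrame,
    segment: Segment,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> pd.DataFrame:
    """All (length, start) windows fully inside the segment.

    Returns a frame with first/last marker index (into the map), bp bounds
    and n_snps; total count is sum over L of max(0, m - L + 1) for m
    segment markers.  Even lengths are rejected.
    """
    for L in lengths:
        if L % 2 == 0:
            raise HaploscanError(f"haplotype lengths must be odd, got {L}")
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy()
    inside = np.nonzero(
        (chrom == segment.chromosome)
        & (pos >= segment.start_bp)
        & (pos <= segment.end_bp)
    )[0]
    m = len(inside)
    rows = []
    for L in lengths:
        for k in range(m - L + 1):
            i0, i1 = int(inside[k]), int(inside[k + L - 1])
            rows.append((segment.chromosome, i0, i1, int(pos[i0]), int(pos[i1]), L))
    return pd.DataFrame(
        rows,
        columns=["chrom", "first_idx", "last_idx", "start_bp", "end_bp", "n_snps"],
    )


def haplotype_dosages(
    phased: PhasedGenotypes, first_idx: int, last_idx: int
) -> List[Tuple[str, float, np.ndarray]]:
    """Distinct haplotype strings in a window with frequency and dosage.

    Tallies the allele strings of all 2n chromosomes over the window
    markers; per animal the dosage is the number of its two haplotypes
    matching the focal string.  Frequencies over distinct strings sum
    to 1.
    """
    H = phased.haplotypes[:, first_idx:last_idx + 1]
    n2 = H.shape[0]
    keys = [h.tobytes() for h in np.ascontiguousarray(H)]
    uniq: Dict[bytes, int] = {}
    codes = np.empty(n2, dtype=np.int64)
    for i, k in enumerate(keys):
        codes[i] = uniq.setdefault(k, len(uniq))
    out = []
    for k, c in uniq.items():
        match = (codes == c).astype(np.int8)
        freq = match.mean()
        dos = match[0::2] + match[1::2]
        allele_str = "".join(str(b) for b in np.frombuffer(k, dtype=np.int8))
        out.append((allele_str, float(freq), dos))
    return out


def haplotype_scan(
    response: np.ndarray,
    phased: PhasedGenotypes,
    segment: Segment,
    null: NullModelFit,
    min_freq: float = 0.05,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    top_k: Optional[int] = None,
) -> pd.DataFrame:
    """GLS effect/SE/p for every focal haplotype of every window.

    Results are ranked by p ascending, ties broken by longer window first
    and then genomic position.  Dosage vectors recur massively across
    overlapping windows, so fits are cached by dosage pattern; identical
    regressors provably receive identical statistics.
    """
    windows = enumerate_windows(phased.marker_map, segment, lengths)
    if len(windows) == 0:
        return pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "n_snps", "haplotype",
                     "frequency", "effect", "se", "p_value"]
        )
    y = np.asarray(response, dtype=float)
    U, w = null.rotation, null.weights()
    wi = 1.0 / w
    ystar = U.T @ y
    onestar = U.T @ np.ones(len(y))
    a11 = np.sum(onestar**2 * wi)
    b1 = np.sum(onestar * ystar * wi)

    cache: Dict[bytes, Tuple[float, float, float]] = {}

    def gls(dos: np.ndarray) -> Tuple[float, float, float]:
        key = dos.tobytes()
        hit = cache.get(key)
        if hit is not None:
            return hit
        d = dos.astype(float)
        dstar = U.T @ d
        a12 = np.sum(dstar * onestar * wi)
        a22 = np.sum(dstar**2 * wi)
        b2 = np.sum(dstar * ystar * wi)
        det = a11 * a22 - a12**2
        if det <= 1e-12 * a11 * max(a22, 1e-300):
            res = (np.nan, np.nan, np.nan)
        else:
            beta = (a11 * b2 - a12 * b1) / det
            se = float(np.sqrt(a11 / det))
            p = float(2.0 * stats.norm.sf(abs(beta / se)))
            res = (float(beta), se, max(p, np.finfo(float).tiny))
        cache[key] = res
        return res

    rows = []
    for win in windows.itertuples(index=False):
        for allele_str, freq, dos in haplotype_dosages(
            phased, win.first_idx, win.last_idx
        ):
            if freq < min_freq or freq >= 1.0:
                continue
            beta, se, p = gls(dos)
            if np.isnan(p):
                continue
            rows.append(
                (win.chrom, win.start_bp, win.end_bp, win.n_snps,
                 allele_str, freq, beta, se, p)
            )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "end_bp", "n_snps", "haplotype",
                 "frequency", "effect", "se", "p_value"],
    )
    if len(out) == 0:
        return out
    out = out.sort_values(
        ["p_value", "n_snps", "start_bp"], ascending=[True, False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k)
    return out


def diplotype_dosage_table(
    phased: PhasedGenotypes, first_idx: int, last_idx: int, allele_str: str
) -> pd.DataFrame:
    """(animal, dosage) for one focal haplotype, for export to fine-mapping."""
    target = np.array([int(c) for c in allele_str], dtype=np.int8)
    H = phased.haplotypes[:, first_idx:last_idx + 1]
    match = (H == target[None, :]).all(axis=1).astype(np.int8)
    dos = match[0::2] + match[1::2]
    return pd.DataFrame({"animal": phased.animal_ids, "dosage": dos})


def diplotype_effect_on_trait(
    diplotype_dosage: np.ndarray,
    trait_response: np.ndarray,
    grm: np.ndarray,
    min_animals: int = 30,
) -> Tuple[float, float, float]:
    """Mixed-model effect of a diplotype dosage on another trait.

    Fits the polygenic null on the trait, then a single-regressor GLS of
    the dosage under that rotation; returns (effect, SE, p).  Refuses to
    fit with fewer than ``min_animals`` overlapping animals.
    """
    d = np.asarray(diplotype_dosage, dtype=float)
    y = np.asarray(trait_response, dtype=float)
    if len(d) != len(y):
        raise HaploscanError("dosage and trait cover different animal sets")
    if len(y) < min_animals:
        raise HaploscanError(
            f"only {len(y)} overlapping animals (< {min_animals}); "
            "inference would be meaningless"
        )
    null = fit_null_model(y, grm)
    U, w = null.rotation, null.weights()
    wi = 1.0 / w
    ystar = U.T @ y
    onestar = U.T @ np.ones(len(y))
    dstar = U.T @ d
    a11 = np.sum(onestar**2 * wi)
    a12 = np.sum(dstar * onestar * wi)
    a22 = np.sum(dstar**2 * wi)
    b1 = np.sum(onestar * ystar * wi)
    b2 = np.sum(dstar * ystar * wi)
    det = a11 * a22 - a12**2
    if det <= 0:
        raise HaploscanError("dosage is confounded with the mean")
    beta = (a11 * b2 - a12 * b1) / det
    se = float(np.sqrt(a11 / det))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return float(beta), se, p
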