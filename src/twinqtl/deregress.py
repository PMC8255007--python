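"""De-regression of EBVs into GWAS pseudo-phenotypes.

Shrunken breeding values cannot be used directly as association responses:
part of each EBV is the parent average, and the shrinkage toward it
differs between animals.  Following the classical parent-average /
individual two-equation approach, each animal's own effective information
content is solved from its reliability and its parent-average reliability;
the de-regressed value is the information-weighted own contribution with
the parent average removed, and a per-record weight

    w = (1 - h2) / ((c + (1 - r2_dereg) / r2_dereg) * h2)

accounts for the heterogeneous residual variance of the pseudo-phenotype
(``c`` is the fraction of genetic variance not captured by markers).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .pedigree import Pedigree, UNKNOWN


class DeregressError(ValueError):
    pass


def _lambda(h2: float) -> float:
    return (1.0 - h2) / h2


def _own_information(lam: float, r2_i: float, r2_pa: float) -> float:
    """Own information content d_i from the 2x2 parent-average/individual
    system with A-inverse block [[4, -2], [-2, 2]] * lambda."""
    d_pa = lam * r2_pa / (1.0 - r2_pa) if r2_pa > 0 else 0.0
    return lam / (1.0 - r2_i) - 2.0 * lam + 4.0 * lam**2 / (d_pa + 4.0 * lam)


def deregress_ebv(
    ebvs: pd.DataFrame,
    pedigree: Pedigree,
    h2: float,
    c: float = 0.5,
) -> pd.DataFrame:
    """De-regress one trait's EBVs against their parent averages.

    ``ebvs`` needs columns ``animal``, ``ebv_raw`` and ``reliability``
    (one trait at a time; filter the BLUP output first).  For an animal
    with both parents unknown the classical single-animal de-regression
    EBV / r2 applies.  Otherwise the parent-average EBV (mean of parental
    EBVs, absent parents contributing 0) and parent-average reliability
    (sum of parental reliabilities / 4) enter the 2x2 system, the own
    information content d_i is solved from PEV-consistency with the
    stated reliability, and the de-regressed value is the own right-hand
    side divided by d_i.  Records with d_i <= 0 carry no own information
    and are flagged ``excluded`` rather than silently kept.
    """
    if not (0.0 < h2 < 1.0):
        raise DeregressError("h2 must be in (0, 1)")
    if not (0.0 <= c < 1.0):
        raise DeregressError("c must be in [0, 1)")
    for col in ("animal", "ebv_raw", "reliability"):
        if col not in ebvs.columns:
            raise DeregressError(f"ebvs lack column {col!r}")
    r2_all = ebvs["reliability"].to_numpy(dtype=float)
    if ((r2_all <= 0) | (r2_all >= 1)).any():
        raise DeregressError("reliabilities must lie strictly in (0, 1)")

    lam = _lambda(h2)
    idx = pedigree.index_of(ebvs["animal"].to_numpy())
    s_idx, d_idx = pedigree._parent_indices()
    ebv_of = dict(zip(idx.tolist(), ebvs["ebv_raw"].to_numpy()))
    r2_of = dict(zip(idx.tolist(), r2_all))

    out = []
    for (animal, g_i, r2_i), row in zip(
        ebvs[["animal", "ebv_raw", "reliability"]].itertuples(index=False), idx
    ):
        parents = [p for p in (s_idx[row], d_idx[row]) if p != UNKNOWN]
        if not parents:
            d_i = lam * r2_i / (1.0 - r2_i)
            dereg = g_i / r2_i
            pa, r2_pa = 0.0, 0.0
        else:
            pa = sum(ebv_of.get(int(p), 0.0) for p in parents) / 2.0
            r2_pa = sum(r2_of.get(int(p), 0.0) for p in parents) / 4.0
            d_i = _own_information(lam, r2_i, r2_pa)
            if d_i <= 0:
                out.append(
                    (animal, g_i, r2_i, pa, r2_pa, np.nan, np.nan, np.nan, True)
                )
                continue
            dereg = (-2.0 * lam * pa + (d_i + 2.0 * lam) * g_i) / d_i
        r2_dereg = d_i / (d_i + lam)
        w = (1.0 - h2) / ((c + (1.0 - r2_dereg) / r2_dereg) * h2)
        out.append((animal, g_i, r2_i, pa, r2_pa, dereg, r2_dereg, w, False))

    return pd.DataFrame(
        out,
        columns=[
            "animal",
            "ebv_raw",
            "reliability",
            "parent_average",
            "pa_reliability",
            "deregressed",
            "r2_dereg",
            "weight",
            "excluded",
        ],
    )


def regress_back(dereg: pd.DataFrame, pedigree: Pedigree, h2: float) -> pd.DataFrame:
    """Inverse of :func:`deregress_ebv`: re-shrink de-regressed values into
    EBVs through the same 2x2 system (round-trip oracle)."""
    lam = _lambda(h2)
    idx = pedigree.index_of(dereg["animal"].to_numpy())
    s_idx, d_idx = pedigree._parent_indices()
    rows = []
    for rec, row in zip(dereg.itertuples(index=False), idx):
        if rec.excluded:
            continue
        founder = s_idx[row] == UNKNOWN and d_idx[row] == UNKNOWN
        if founder:
            ebv = rec.deregressed * rec.reliability
        else:
            d_i = _own_information(lam, rec.reliability, rec.pa_reliability)
            ystar_i = rec.deregressed * d_i
            ebv = (ystar_i + 2.0 * lam * rec.parent_average) / (d_i + 2.0 * lam)
        rows.append((rec.animal, ebv))
    return pd.DataFrame(rows, columns=["animal", "ebv_raw"])


def filter_reliability(
    dereg: pd.DataFrame, min_reliability: float = 0.35
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records whose source EBV reliability is >= the threshold
    (inclusive bound).  Returns (subset, per-trait count report)."""
    keep = dereg["reliability"].to_numpy(dtype=float) >= min_reliability
    if "excluded" in dereg.columns:
        keep &= ~dereg["excluded"].to_numpy(dtype=bool)
    subset = dereg[keep].copy()
    group = (
        dereg["trait"] if "trait" in dereg.columns
        else pd.Series(["all"] * len(dereg), index=dereg.index)
    )
    report = (
        pd.DataFrame({"trait": group, "kept": keep})
        .groupby("trait")
        .agg(n_input=("kept", "size"), n_retained=("kept", "sum"))
        .reset_index()
    )
    return subset, report


def summary_statistics(dereg: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean/SD/n of the de-regressed values (evaluation-log style)."""
    mask = (
        ~dereg["excluded"].to_numpy(dtype=bool)
        if "excluded" in dereg.columns
        else np.ones(len(dereg), dtype=bool)
    )
    vals = dereg.loc[mask, "deregressed"].dropna()
    return pd.DataFrame(
        {
            "min": [vals.min()],
            "max": [vals.max()],
            "mean": [vals.mean()],
            "sd": [vals.std(ddof=1)],
            "n": [len(vals)],
        }
    )
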