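"""Sequence-panel QC, haplotype-variant LD screen, breed frequencies.

The candidate-variant search correlates the diplotype dosage of the top
associated haplotype (0/1/2 copies per animal) with every sequence
variant in a window around it.  Before the screen the panel passes the
evaluation QC in a fixed, auditable order: variant missingness, MAF,
sample missingness, then Mendelian-error rates from duos and trios; each
rule's removals are counted on the set surviving the previous rules.
r-squared is genotypic (squared Pearson correlation of dosages over
pairwise-complete samples) and therefore invariant to allele relabeling
on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .simherd import SeqPanel

UNKNOWN = -1


class FinemapError(RuntimeError):
    pass


@dataclass
class QcThresholds:
    max_variant_missing: float = 0.1
    min_maf: float = 0.01
    max_sample_missing: float = 0.1
    max_mendel_rate: float = 0.02

    def validate(self) -> "QcThresholds":
        for nm in ("max_variant_missing", "min_maf", "max_sample_missing",
                   "max_mendel_rate"):
            if not (0.0 <= getattr(self, nm) <= 1.0):
                raise FinemapError(f"threshold {nm!r} outside [0, 1]")
        return self


@dataclass
class QcReport:
    n_variants_input: int
    n_samples_input: int
    removed_variant_missing: int = 0
    removed_maf: int = 0
    removed_sample_missing: int = 0
    removed_variant_mendel: int = 0
    removed_sample_mendel: int = 0
    n_families: int = 0
    n_variants_retained: int = 0
    n_samples_retained: int = 0

    @property
    def variants_conserved(self) -> bool:
        return (
            self.removed_variant_missing + self.removed_maf
            + self.removed_variant_mendel + self.n_variants_retained
            == self.n_variants_input
        )

    @property
    def samples_conserved(self) -> bool:
        return (
            self.removed_sample_missing + self.removed_sample_mendel
            + self.n_samples_retained == self.n_samples_input
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("variant_missing", self.removed_variant_missing),
            ("variant_maf", self.removed_maf),
            ("sample_missing", self.removed_sample_missing),
            ("sample_mendel", self.removed_sample_mendel),
            ("variant_mendel", self.removed_variant_mendel),
            ("variants_retained", self.n_variants_retained),
            ("samples_retained", self.n_samples_retained),
            ("families", self.n_families),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def _validate_genotypes(G: np.ndarray) -> None:
    ok = np.isin(G, (-1, 0, 1, 2))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FinemapError(
            f"malformed genotype value {G[i, j]} at sample {i}, variant {j}"
        )


def mendelian_error_rate(
    panel: SeqPanel, families: Optional[pd.DataFrame] = None
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Per-sample and per-variant Mendelian-error rates from duos/trios.

    Duo error: opposing homozygotes between parent and child.  Trio error:
    a child genotype impossible given both parents (opposing homozygote
    with either parent, or parents both homozygous with a child allele
    count outside their sum/2 expectation).  Rates divide by non-missing
    tested transmissions; families with members absent from the panel are
    skipped.  Errors attach to the child and to both tested parents.
    """
    fams = families if families is not None else panel.families
    G = panel.genotypes
    n, m = G.shape
    pos_of = {int(s): i for i, s in enumerate(panel.sample_ids)}
    err_s = np.zeros(n)
    tst_s = np.zeros(n)
    err_v = np.zeros(m)
    tst_v = np.zeros(m)
    n_used = 0
    for fam in fams.itertuples(index=False):
        child = pos_of.get(int(fam.child))
        p1 = pos_of.get(int(fam.parent1)) if int(fam.parent1) != UNKNOWN else None
        p2 = pos_of.get(int(fam.parent2)) if int(fam.parent2) != UNKNOWN else None
        if child is None or (p1 is None and p2 is None):
            continue
        n_used += 1
        gc = G[child]
        members = [child] + [p for p in (p1, p2) if p is not None]
        if p1 is not None and p2 is not None:
            g1, g2 = G[p1], G[p2]
            tested = (gc >= 0) & (g1 >= 0) & (g2 >= 0)
            # impossible offspring: opposing homozygote with either parent,
            # or both parents homozygous and the child not their mean
            opp = ((g1 == 0) & (gc == 2)) | ((g1 == 2) & (gc == 0)) | \
                  ((g2 == 0) & (gc == 2)) | ((g2 == 2) & (gc == 0))
            both_hom = ((g1 % 2) == 0) & ((g2 % 2) == 0)
            bad_mean = both_hom & (gc != (g1 + g2) // 2)
            err = tested & (opp | bad_mean)
        else:
            gp = G[p1 if p1 is not None else p2]
            tested = (gc >= 0) & (gp >= 0)
            err = tested & (((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0)))
        for s in members:
            err_s[s] += err.sum()
            tst_s[s] += tested.sum()
        err_v += err
        tst_v += tested
    with np.errstate(invalid="ignore"):
        rate_s = np.where(tst_s > 0, err_s / np.maximum(tst_s, 1), 0.0)
        rate_v = np.where(tst_v > 0, err_v / np.maximum(tst_v, 1), 0.0)
    return rate_s, rate_v, n_used


def vcf_qc(
    panel: SeqPanel,
    thresholds: Optional[QcThresholds] = None,
    families: Optional[pd.DataFrame] = None,
) -> Tuple[SeqPanel, QcReport]:
    """Apply the evaluation QC rules in their stated order.

    1. variants with missing call rate > 0.1 (strict) removed;
    2. variants with MAF < 0.01 removed;
    3. samples with missing call rate > 0.1 removed;
    4. samples, then variants, with Mendelian-error rate > 0.02 removed
       (no-op with a report note when no family links exist).
    """
    thresholds = (thresholds or QcThresholds()).validate()
    G = panel.genotypes.copy()
    _validate_genotypes(G)
    report = QcReport(n_variants_input=G.shape[1], n_samples_input=G.shape[0])
    vkeep = np.ones(G.shape[1], dtype=bool)
    skeep = np.ones(G.shape[0], dtype=bool)

    miss_v = (G < 0).mean(axis=0)
    drop = miss_v > thresholds.max_variant_missing
    report.removed_variant_missing = int(drop.sum())
    vkeep &= ~drop

    with np.errstate(invalid="ignore"):
        Gm = np.ma.masked_less(G, 0)
        freq = Gm.mean(axis=0).filled(np.nan) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    drop = vkeep & ((maf < thresholds.min_maf) | np.isnan(maf))
    report.removed_maf = int(drop.sum())
    vkeep &= ~drop

    miss_s = (G[:, vkeep] < 0).mean(axis=1) if vkeep.any() else np.zeros(G.shape[0])
    drop_s = miss_s > thresholds.max_sample_missing
    report.removed_sample_missing = int(drop_s.sum())
    skeep &= ~drop_s

    fams = families if families is not None else panel.families
    sub = _subset(panel, skeep, vkeep)
    rate_s, rate_v, n_fam = mendelian_error_rate(sub, fams)
    report.n_families = n_fam
    drop_s2 = rate_s > thresholds.max_mendel_rate
    report.removed_sample_mendel = int(drop_s2.sum())
    keep_idx = np.nonzero(skeep)[0][~drop_s2]
    skeep = np.zeros(G.shape[0], dtype=bool)
    skeep[keep_idx] = True

    sub = _subset(panel, skeep, vkeep)
    _, rate_v, _ = mendelian_error_rate(sub, fams)
    drop_v2 = rate_v > thresholds.max_mendel_rate
    report.removed_variant_mendel = int(drop_v2.sum())
    vidx = np.nonzero(vkeep)[0][~drop_v2]
    vkeep = np.zeros(G.shape[1], dtype=bool)
    vkeep[vidx] = True

    report.n_variants_retained = int(vkeep.sum())
    report.n_samples_retained = int(skeep.sum())
    return _subset(panel, skeep, vkeep), report


def _subset(panel: SeqPanel, skeep: np.ndarray, vkeep: np.ndarray) -> SeqPanel:
    return SeqPanel(
        variants=panel.variants.loc[vkeep].reset_index(drop=True),
        genotypes=panel.genotypes[np.ix_(skeep, vkeep)],
        sample_ids=panel.sample_ids[skeep],
        breeds=panel.breeds[skeep],
        families=panel.families,
        seed=panel.seed,
    )


def haplotype_variant_ld(
    diplotype: pd.DataFrame,
    panel: SeqPanel,
    window: Optional[Tuple[int, int]] = None,
    r2_floor: float = 0.7,
) -> pd.DataFrame:
    """Genotypic r2 between the haplotype diplotype and each panel variant.

    ``diplotype`` is an (animal, dosage) frame from the haplotype scan.
    r2 is the squared Pearson correlation over samples non-missing for
    both; variants below ``r2_floor`` are dropped and the result is sorted
    by r2 descending.  Zero-variance variants are skipped with a flag
    column in the returned attrs.
    """
    dos_of = dict(zip(diplotype["animal"].astype(int), diplotype["dosage"]))
    shared = np.array([int(s) in dos_of for s in panel.sample_ids])
    if not shared.any():
        raise FinemapError("no overlapping samples between diplotype and panel")
    d = np.array([dos_of[int(s)] for s in panel.sample_ids[shared]], dtype=float)
    G = panel.genotypes[shared].astype(float)
    pos = panel.variants["pos"].to_numpy()
    in_win = np.ones(len(pos), dtype=bool)
    if window is not None:
        lo, hi = window
        in_win = (pos >= lo) & (pos <= hi)

    rows, skipped = [], []
    for v in np.nonzero(in_win)[0]:
        g = G[:, v]
        ok = g >= 0
        if ok.sum() < 3:
            skipped.append(v)
            continue
        gv, dv = g[ok], d[ok]
        if gv.std() == 0 or dv.std() == 0:
            skipped.append(v)
            continue
        r = np.corrcoef(gv, dv)[0, 1]
        freq = gv.mean() / 2.0
        rows.append(
            (
                panel.variants.at[v, "chrom"],
                int(pos[v]),
                panel.variants.at[v, "ref"],
                panel.variants.at[v, "alt"],
                float(min(freq, 1.0 - freq)),
                float(r * r),
            )
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "maf", "r2"]
    )
    out = out[out["r2"] >= r2_floor].sort_values("r2", ascending=False)
    out = out.reset_index(drop=True)
    out.attrs["skipped_variants"] = skipped
    return out


def breed_frequencies(
    panel: SeqPanel, variant_pos: int, min_records: int = 50
) -> pd.DataFrame:
    """Per-breed alt-allele frequency of one variant.

    Only breeds with at least ``min_records`` genotyped (non-missing)
    samples at the variant are reported.
    """
    sel = np.nonzero(panel.variants["pos"].to_numpy() == variant_pos)[0]
    if len(sel) == 0:
        raise FinemapError(f"no panel variant at position {variant_pos}")
    g = panel.genotypes[:, sel[0]]
    rows = []
    for breed in np.unique(panel.breeds):
        mask = (panel.breeds == breed) & (g >= 0)
        if mask.sum() >= min_records:
            rows.append((breed, int(mask.sum()), float(g[mask].mean() / 2.0)))
    return pd.DataFrame(rows, columns=["breed", "n", "alt_frequency"])
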