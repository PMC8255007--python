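"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: pedigree and phenotype CSV, result TSVs,
phased genotypes as VCF (``0|1`` GT) with a PLINK-text mirror, the
sequence panel as VCF with ``./.`` for missing calls.  Every simulation
output directory receives a provenance JSON with the seed and the
configuration hash.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .pedigree import Pedigree, UNKNOWN
from .simherd import PhasedGenotypes, SeqPanel

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# pedigree / phenotypes
# ---------------------------------------------------------------------------

def write_pedigree_csv(pedigree: Pedigree, path: PathLike) -> None:
    pedigree.table.to_csv(path, index=False)


def read_pedigree_csv(path: PathLike) -> Pedigree:
    t = pd.read_csv(path)
    return Pedigree(t)


def write_phenotypes_csv(records: pd.DataFrame, path: PathLike) -> None:
    records.to_csv(path, index=False)


def read_phenotypes_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_provenance(out_dir: PathLike, config: SimulationConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"seed": config.seed, "config_hash": config.config_hash()}
    (out / "provenance.json").write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_phased_vcf(geno: PhasedGenotypes, path: PathLike) -> None:
    """Phased genotypes as a VCF with ``0|1``-style GT fields."""
    ids = [str(a) for a in geno.animal_ids]
    H = geno.haplotypes
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in pd.unique(geno.marker_map["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for j, row in enumerate(geno.marker_map.itertuples(index=False)):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(len(ids))
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path: PathLike) -> PhasedGenotypes:
    """Read a phased VCF (``|``-separated GT) into PhasedGenotypes.

    Uses :mod:`cyvcf2` when available, falling back to a plain-text parse
    of the simple VCFs this package writes.
    """
    try:
        return _read_phased_cyvcf2(path)
    except ImportError:
        return _read_phased_plain(path)


def _read_phased_cyvcf2(path: PathLike) -> PhasedGenotypes:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows, haps = [], []
    for i, var in enumerate(vcf):
        rows.append(
            (int(var.CHROM), var.POS, var.ID or f"v{i}", var.REF, var.ALT[0])
        )
        g = var.genotype.array()
        if not (g[:, 2] == 1).all():
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        haps.append(g[:, :2])
    mm = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    # haps: list over markers of (n, 2) -> (2n, m)
    arr = np.empty((2 * len(samples), len(rows)), dtype=np.int8)
    for j, g in enumerate(haps):
        arr[0::2, j] = g[:, 0]
        arr[1::2, j] = g[:, 1]
    return PhasedGenotypes(
        marker_map=mm,
        haplotypes=arr,
        animal_ids=np.array([int(s) for s in samples]),
    )


def _read_phased_plain(path: PathLike) -> PhasedGenotypes:
    rows, haps, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            rows.append((int(chrom), int(pos), vid, ref, alt))
            h = np.empty(2 * len(samples), dtype=np.int8)
            for i, gt in enumerate(parts[9:]):
                allele = gt.split(":")[0]
                if "|" not in allele:
                    raise ValueError(f"unphased genotype at {chrom}:{pos}")
                a, b = allele.split("|")
                h[2 * i], h[2 * i + 1] = int(a), int(b)
            haps.append(h)
    mm = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    H = np.stack(haps, axis=1) if haps else np.zeros((2 * len(samples), 0), np.int8)
    return PhasedGenotypes(
        marker_map=mm,
        haplotypes=H,
        animal_ids=np.array([int(s) for s in samples]),
    )


def write_seq_panel_vcf(panel: SeqPanel, path: PathLike) -> None:
    """Sequence panel as an unphased VCF, missing calls as ``./.``."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    ids = [str(s) for s in panel.sample_ids]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            gts = "\t".join(code[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_seq_panel_vcf(
    path: PathLike,
    breeds: Optional[pd.DataFrame] = None,
    families: Optional[pd.DataFrame] = None,
) -> SeqPanel:
    """Read an unphased VCF into a SeqPanel; breeds/families optional
    two-column tables (sample, breed) / (child, parent1, parent2)."""
    rows, genos, samples = [], [], None
    gt_code = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
               "1/1": 2, "1|1": 2, "./.": -1, ".|.": -1, ".": -1}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            rows.append((int(parts[0]), int(parts[1]), parts[3], parts[4]))
            genos.append(
                [gt_code[g.split(":")[0]] for g in parts[9:]]
            )
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    G = np.array(genos, dtype=np.int8).T if genos else np.zeros((len(samples), 0), np.int8)
    sample_ids = np.array([int(s) for s in samples])
    if breeds is not None:
        breed_of = dict(zip(breeds.iloc[:, 0].astype(int), breeds.iloc[:, 1]))
        blab = np.array([breed_of.get(int(s), "unknown") for s in sample_ids])
    else:
        blab = np.array(["unknown"] * len(sample_ids))
    fams = families if families is not None else pd.DataFrame(
        columns=["child", "parent1", "parent2"]
    )
    return SeqPanel(
        variants=variants,
        genotypes=G,
        sample_ids=sample_ids,
        breeds=blab,
        families=fams,
    )


def write_breed_tsv(panel: SeqPanel, path: PathLike) -> None:
    pd.DataFrame({"sample": panel.sample_ids, "breed": panel.breeds}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PLINK text mirror
# ---------------------------------------------------------------------------

def write_plink_text(geno: PhasedGenotypes, prefix: PathLike) -> None:
    """PED/MAP pair mirroring the phased VCF (alleles A/B coded 1/2)."""
    prefix = str(prefix)
    mm = geno.marker_map
    with open(prefix + ".map", "w") as fh:
        for row in mm.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\n")
    H = geno.haplotypes + 1  # 1=ref, 2=alt
    with open(prefix + ".ped", "w") as fh:
        for i, a in enumerate(geno.animal_ids):
            gts = " ".join(
                f"{H[2 * i, j]} {H[2 * i + 1, j]}" for j in range(len(mm))
            )
            fh.write(f"0 {a} 0 0 0 -9 {gts}\n")


def read_plink_text(prefix: PathLike) -> PhasedGenotypes:
    prefix = str(prefix)
    mm = pd.read_csv(
        prefix + ".map", sep="\t",
        names=["chrom", "id", "cm", "pos"],
    )
    mm["ref"], mm["alt"] = "A", "B"
    ids, haps = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(int(parts[1]))
            al = np.array(parts[6:], dtype=np.int8) - 1
            haps.append(al)
    H = np.empty((2 * len(ids), len(mm)), dtype=np.int8)
    for i, al in enumerate(haps):
        H[2 * i] = al[0::2]
        H[2 * i + 1] = al[1::2]
    return PhasedGenotypes(
        marker_map=mm[["chrom", "pos", "id", "ref", "alt"]],
        haplotypes=H,
        animal_ids=np.array(ids),
    )
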