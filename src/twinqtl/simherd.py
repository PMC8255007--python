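"""Synthetic herd generator: pedigree, phased genotypes, phenotypes, panel.

Gene-dropping simulation of a closed dairy population.  Founder haplotypes
come from a block-structured pool (every pool haplotype is a mosaic of a
few ancestral block variants, giving block LD); descendants receive
recombined parental gametes at a uniform per-bp rate.  A focal haplotype
with a configurable target frequency can be planted in a QTL window; it
acts additively on the dam's maternal genetic value.  Phenotypes follow
the direct-maternal animal model: fixed effects (parity, season, sexed
semen, age of dam), a random herd-year effect, correlated direct/maternal
breeding values sampled recursively down the pedigree, and residual noise.
A gaussian mode emits the latent value directly (for exact REML parameter
recovery); a binary mode thresholds it to the 1/2 multiple-birth coding at
a target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig, ConfigError
from .pedigree import Pedigree, UNKNOWN

_SEASONS = np.array(["winter", "winter", "spring", "spring", "spring",
                     "summer", "summer", "summer", "fall", "fall", "fall",
                     "winter"])  # month 1..12 -> season


class SimulationError(RuntimeError):
    pass


@dataclass
class PhasedGenotypes:
    """Marker map plus two haplotype allele vectors per animal.

    ``haplotypes`` has shape (2n, m), rows 2i and 2i+1 belonging to animal
    ``animal_ids[i]``; entries are 0 (ref) / 1 (alt).  ``qtl_truth`` records
    the planted focal haplotype: the window marker indices, its allele
    string and the per-haplotype carrier indicator.
    """

    marker_map: pd.DataFrame  # chrom, pos, id, ref, alt
    haplotypes: np.ndarray
    animal_ids: np.ndarray
    qtl_truth: Optional[dict] = None
    parents: Optional[np.ndarray] = None  # (n, 2) sire/dam ids, -1 unknown
    seed: Optional[int] = None

    def __post_init__(self):
        m = self.marker_map
        for chrom, grp in m.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"marker positions must be strictly increasing on {chrom}"
                )
        if self.haplotypes.shape != (2 * len(self.animal_ids), len(m)):
            raise ValueError("haplotype matrix shape does not match map/animals")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def dosages(self) -> np.ndarray:
        """Alt-allele counts 0/1/2, shape (n_animals, n_markers)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def carrier_dosage(self) -> np.ndarray:
        """Copies of the planted focal haplotype per animal (0/1/2)."""
        if self.qtl_truth is None:
            raise ValueError("no planted QTL in this simulation")
        ind = self.qtl_truth["carrier"].astype(np.int8)
        return ind[0::2] + ind[1::2]


@dataclass
class SeqPanel:
    """Dense variant panel with missingness, breed labels and family links."""

    variants: pd.DataFrame  # chrom, pos, ref, alt, flip_rate, is_causal_proxy
    genotypes: np.ndarray   # (n_samples, n_variants) int8, -1 = missing
    sample_ids: np.ndarray
    breeds: np.ndarray
    families: pd.DataFrame  # child, parent1, parent2 (-1 if absent)
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.variants["pos"].is_monotonic_increasing:
            raise ValueError("panel variant positions must be sorted")

    def missing_rate_per_variant(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=0)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a multi-generation pedigree with herd and year structure.

    Founders alternate male/female.  Calving years are laid out in
    consecutive blocks of ``years_per_generation`` years per generation;
    each dam of a generation calves once per year of her block, mated to a
    random male of her own generation's parent pool.  Daughters stay in
    their dam's herd.
    """
    config.validate()
    rng = _rng(config, 1)
    yr0, yr1 = config.years
    ypg = config.years_per_generation

    ids, sires, dams, sexes, byears, herds, gens = [], [], [], [], [], [], []
    next_id = 1

    def add(sire, dam, sex, byear, herd, gen):
        nonlocal next_id
        ids.append(next_id); sires.append(sire); dams.append(dam)
        sexes.append(sex); byears.append(byear); herds.append(herd)
        gens.append(gen)
        next_id += 1
        return next_id - 1

    founder_year = yr0 - 4
    males, females = [], []
    n_male = int(np.ceil(config.n_founders * config.founder_male_fraction))
    for i in range(config.n_founders):
        sex = "M" if i < n_male else "F"
        herd = int(rng.integers(config.n_herds)) if sex == "F" else UNKNOWN
        a = add(UNKNOWN, UNKNOWN, sex, founder_year, herd, 0)
        (males if sex == "M" else females).append((a, herd, founder_year))

    herd_of = {a: h for a, h, _ in females}
    for g in range(1, config.n_generations + 1):
        if not males:
            raise SimulationError(f"no males available to sire generation {g}")
        if not females:
            raise SimulationError(f"no dams available for generation {g}")
        block0 = yr0 + (g - 1) * ypg
        sire_pool = np.array([a for a, _, _ in males])
        if len(sire_pool) > config.n_active_sires:
            # AI breeding: a limited sire pool serves every herd
            sire_pool = rng.choice(sire_pool, config.n_active_sires,
                                   replace=False)
        next_males, next_females = [], []
        for dam_id, herd, _ in females:
            if herd == UNKNOWN:
                herd = int(rng.integers(config.n_herds))
            for k in range(ypg):
                year = block0 + k
                if year > yr1:
                    break
                sire = int(sire_pool[rng.integers(len(sire_pool))])
                sex = "M" if rng.random() < config.male_fraction else "F"
                a = add(sire, dam_id, sex, year, herd, g)
                if sex == "M":
                    next_males.append((a, UNKNOWN, year))
                else:
                    next_females.append((a, herd, year))
        if not next_males and not next_females:
            raise SimulationError(f"generation {g} produced no offspring")
        males, females = next_males, next_females

    n = len(ids)
    main = config.main_breed_fraction
    tbl = pd.DataFrame(
        {
            "id": ids,
            "sire": sires,
            "dam": dams,
            "sex": sexes,
            "birth_year": byears,
            "herd": herds,
            "generation": gens,
        }
    )
    # static breed fractions: founders drawn around the main-breed level,
    # offspring average their parents
    labels = config.breed_labels
    fr = np.zeros((n, len(labels)))
    founder_mask = tbl["sire"].to_numpy() == UNKNOWN
    if len(labels) == 1:
        fr[founder_mask, 0] = 1.0
    else:
        f_main = np.clip(rng.normal(main, 0.08, founder_mask.sum()), 0.0, 1.0)
        fr[founder_mask, 0] = f_main
        fr[founder_mask, 1:] = ((1 - f_main) / (len(labels) - 1))[:, None]
    pos = pd.Series(np.arange(n), index=tbl["id"])
    s_idx = np.where(founder_mask, -1, pos.reindex(tbl["sire"]).fillna(-1).to_numpy())
    d_idx = np.where(founder_mask, -1, pos.reindex(tbl["dam"]).fillna(-1).to_numpy())
    for i in np.nonzero(~founder_mask)[0]:
        fr[i] = 0.5 * (fr[int(s_idx[i])] + fr[int(d_idx[i])])
    for j, lab in enumerate(labels):
        tbl[f"breed:{lab}"] = fr[:, j]
    return Pedigree(tbl)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _founder_pool(config: SimulationConfig, marker_map: pd.DataFrame,
                  rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Block-LD founder haplotype pool and the planted carrier flags."""
    m = len(marker_map)
    K = config.founder_pool_size
    pool = np.zeros((K, m), dtype=np.int8)
    freqs = rng.uniform(0.1, 0.9, size=m)
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        blocks = pos // config.ld_block_bp
        for b in np.unique(blocks):
            cols = idx[blocks == b]
            variants = (
                rng.random((config.haplotypes_per_block, len(cols)))
                < freqs[cols][None, :]
            ).astype(np.int8)
            choice = rng.integers(config.haplotypes_per_block, size=K)
            pool[:, cols] = variants[choice]

    carrier = np.zeros(K, dtype=bool)
    qtl = config.qtl_spec
    if qtl is not None:
        chrom_mask = marker_map["chrom"].to_numpy() == qtl.chromosome
        win = np.nonzero(
            chrom_mask
            & (marker_map["pos"].to_numpy() >= qtl.start_bp)
            & (marker_map["pos"].to_numpy() <= qtl.end_bp)
        )[0]
        if len(win) == 0:
            raise SimulationError("QTL window contains no markers")
        n_car = max(1, int(round(qtl.target_frequency * K)))
        carrier[rng.permutation(K)[:n_car]] = True
        focal = (rng.random(len(win)) < 0.5).astype(np.int8)
        pool[np.ix_(carrier, win)] = focal
        # non-carriers must differ from the focal string somewhere
        for k in np.nonzero(~carrier)[0]:
            if np.array_equal(pool[k, win], focal):
                pool[k, win[rng.integers(len(win))]] ^= 1
    return pool, carrier


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> PhasedGenotypes:
    """Gene-drop phased genotypes down the pedigree.

    Founder haplotypes are drawn (with replacement) from the block-LD pool;
    every descendant haplotype is a recombined copy of the corresponding
    parent's two haplotypes (Poisson crossovers at the configured per-bp
    rate).  Children of unknown parents draw a fresh pool gamete.
    """
    config.validate()
    rng = _rng(config, 2)
    m_per = config.snps_per_chromosome
    if m_per <= 0:
        raise SimulationError("marker map is empty")
    maps = []
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chromosome_length, dtype=np.int64),
                size=m_per,
                replace=False,
            )
        )
        maps.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos": pos,
                    "id": [f"snp{c}_{i}" for i in range(m_per)],
                    "ref": "A",
                    "alt": "B",
                }
            )
        )
    marker_map = pd.concat(maps, ignore_index=True)

    pool, pool_carrier = _founder_pool(config, marker_map, rng)
    n = len(pedigree)
    m = len(marker_map)
    H = np.zeros((2 * n, m), dtype=np.int8)
    carrier = np.zeros(2 * n, dtype=bool)

    chrom_arr = marker_map["chrom"].to_numpy()
    pos_arr = marker_map["pos"].to_numpy()
    chrom_slices = {
        c: np.nonzero(chrom_arr == c)[0] for c in range(1, config.n_chromosomes + 1)
    }

    qtl = config.qtl_spec
    win = None
    focal = None
    if qtl is not None:
        win = np.nonzero(
            (chrom_arr == qtl.chromosome)
            & (pos_arr >= qtl.start_bp)
            & (pos_arr <= qtl.end_bp)
        )[0]
        focal = pool[np.argmax(pool_carrier)][win].copy()

    sire_idx, dam_idx = pedigree._parent_indices()

    def pool_gamete():
        k = rng.integers(len(pool))
        return pool[k].copy(), pool_carrier[k]

    def meiosis(h0, h1):
        """One recombined gamete from the parent's pair of haplotypes."""
        gam = np.empty(m, dtype=np.int8)
        for c, cols in chrom_slices.items():
            span = config.chromosome_length
            n_x = rng.poisson(config.recombination_rate * span)
            cur = int(rng.integers(2))
            if n_x == 0:
                gam[cols] = (h0 if cur == 0 else h1)[cols]
                continue
            cuts = np.sort(rng.integers(1, span, size=n_x))
            cp = pos_arr[cols]
            seg = np.searchsorted(cuts, cp)  # segment index per marker
            use = (seg + cur) % 2
            gam[cols] = np.where(use == 0, h0[cols], h1[cols])
        return gam

    for i in range(n):
        for h, par in ((0, sire_idx[i]), (1, dam_idx[i])):
            row = 2 * i + h
            if par == UNKNOWN:
                H[row], carrier[row] = pool_gamete()
            else:
                H[row] = meiosis(H[2 * par], H[2 * par + 1])
                if win is not None:
                    carrier[row] = np.array_equal(H[row, win], focal)
    # with recombination a founder-derived carrier flag can go stale;
    # recompute exactly from the window alleles
    if win is not None:
        carrier = (H[:, win] == focal[None, :]).all(axis=1)

    truth = None
    if qtl is not None:
        truth = {
            "window_indices": win,
            "focal_alleles": focal,
            "carrier": carrier,
            "effect": qtl.effect,
            "chromosome": qtl.chromosome,
            "start_bp": int(pos_arr[win[0]]),
            "end_bp": int(pos_arr[win[-1]]),
        }
    par_ids = np.stack(
        [
            np.where(sire_idx == UNKNOWN, UNKNOWN, pedigree.ids[sire_idx]),
            np.where(dam_idx == UNKNOWN, UNKNOWN, pedigree.ids[dam_idx]),
        ],
        axis=1,
    )
    return PhasedGenotypes(
        marker_map=marker_map,
        haplotypes=H,
        animal_ids=pedigree.ids.copy(),
        qtl_truth=truth,
        parents=par_ids,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def sample_breeding_values(pedigree: Pedigree, config: SimulationConfig,
                           rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Jointly sample correlated direct/maternal breeding values (n, 2).

    Recursive gene-flow sampling: founders ~ N(0, G0); offspring get the
    parent average plus Mendelian-sampling noise with variance d_i * G0,
    d_i from the inbreeding-corrected Meuwissen-Luo coefficients.
    """
    if rng is None:
        rng = _rng(config, 3)
    G0 = config.variance_components.genetic_covariance_matrix()
    # Cholesky-like square root that tolerates singular G0
    w, V = np.linalg.eigh(G0)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    n = len(pedigree)
    s, d = pedigree._parent_indices()
    dvec = pedigree.mendelian_variance_coefficients()
    u = np.zeros((n, 2))
    noise = rng.standard_normal((n, 2))
    for i in range(n):
        pa = np.zeros(2)
        if s[i] != UNKNOWN:
            pa += 0.5 * u[s[i]]
        if d[i] != UNKNOWN:
            pa += 0.5 * u[d[i]]
        u[i] = pa + np.sqrt(dvec[i]) * (L @ noise[i])
    return u


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: Optional[PhasedGenotypes],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate one birth record per non-founder calf.

    Latent value = fixed part + herd-year effect + direct value of the calf
    + maternal value of the dam (+ planted-haplotype effect x dam's carrier
    dosage) + residual.  ``phenotype_mode="gaussian"`` emits the latent
    value as the 1/2-coded response ``code``; ``"binary"`` thresholds it to
    code 2 above ``binary_threshold`` (calibrated to ``target_prevalence``
    when the threshold is unset).  Returns a birth-record table consumable
    by :mod:`twinqtl.records`.
    """
    config.validate()
    if config.qtl_spec is not None and genotypes is None:
        raise SimulationError("a planted QTL requires simulated genotypes")
    rng = _rng(config, 4)
    vc = config.variance_components
    fev = config.fixed_effect_values

    u = sample_breeding_values(pedigree, config, rng)
    tbl = pedigree.table
    s_idx, d_idx = pedigree._parent_indices()
    calves = np.nonzero(d_idx != UNKNOWN)[0]
    if len(calves) == 0:
        raise SimulationError("pedigree has no non-founder calves")

    herd = tbl["herd"].to_numpy()
    year = tbl["birth_year"].to_numpy()
    dam_birth_year = year[d_idx[calves]]

    # herd-year random effects
    hy_key = herd[calves].astype(np.int64) * 100_000 + year[calves]
    uniq, hy_code = np.unique(hy_key, return_inverse=True)
    hy_eff = rng.normal(0.0, np.sqrt(vc.herd_year), size=len(uniq))

    # fixed-effect covariates
    nrec = len(calves)
    month = rng.integers(1, 13, size=nrec)
    season = _SEASONS[month - 1]
    season_code = pd.Categorical(
        season, categories=["spring", "summer", "fall", "winter"]
    ).codes
    # parity: calving index of the dam in calf birth-year order
    order = np.lexsort((year[calves], d_idx[calves]))
    parity = np.empty(nrec, dtype=np.int64)
    prev_dam, k = -2, 0
    for j in order:
        dj = d_idx[calves[j]]
        k = k + 1 if dj == prev_dam else 1
        parity[j] = k
        prev_dam = dj
    parity_lvl = np.minimum(parity, 5)
    sexed = rng.random(nrec) < config.sexed_semen_rate
    et = rng.random(nrec) < config.embryo_transfer_rate
    age_months = (year[calves] - dam_birth_year) * 12 + month - 6
    age_months = np.maximum(age_months, 18)

    fixed = (
        fev.intercept
        + np.asarray(fev.parity)[parity_lvl - 1]
        + np.asarray(fev.sexed_semen)[sexed.astype(int)]
        + np.asarray(fev.season)[season_code]
        + fev.age_slope * (age_months - 60)
    )

    qtl_term = np.zeros(nrec)
    if config.qtl_spec is not None:
        if genotypes.qtl_truth is None:
            raise SimulationError("genotypes carry no planted QTL")
        cd = genotypes.carrier_dosage()
        gpos = pd.Series(np.arange(len(genotypes.animal_ids)),
                         index=genotypes.animal_ids)
        dam_rows = gpos.loc[tbl["id"].to_numpy()[d_idx[calves]]].to_numpy()
        qtl_term = config.qtl_spec.effect * cd[dam_rows]

    latent = (
        fixed
        + hy_eff[hy_code]
        + u[calves, 0]
        + u[d_idx[calves], 1]
        + qtl_term
        + rng.normal(0.0, np.sqrt(vc.residual), size=nrec)
    )

    if config.phenotype_mode == "gaussian":
        code = latent
    else:
        thr = config.binary_threshold
        if thr is None:
            thr = float(np.quantile(latent, 1.0 - config.target_prevalence))
        code = np.where(latent > thr, 2, 1)

    out = pd.DataFrame(
        {
            "calf": tbl["id"].to_numpy()[calves],
            "dam": tbl["id"].to_numpy()[d_idx[calves]],
            "sire": tbl["id"].to_numpy()[s_idx[calves]],
            "herd": herd[calves],
            "year": year[calves],
            "month": month,
            "season": season,
            "parity": parity_lvl,
            "sexed_semen": sexed,
            "age_of_dam": age_months,
            "embryo_transfer": et,
            "code": code,
        }
    )
    out.attrs["seed"] = config.seed
    out.attrs["true_breeding_values"] = u
    out.attrs["phenotype_mode"] = config.phenotype_mode
    return out


# ---------------------------------------------------------------------------
# sequence panel
# ---------------------------------------------------------------------------

def simulate_seq_panel(genotypes: PhasedGenotypes,
                       config: SimulationConfig) -> SeqPanel:
    """Dense "sequence" variants around the planted QTL for fine-mapping.

    Each variant copies the per-gamete carrier indicator of the planted
    haplotype with a per-variant allele-flip rate, so downstream genotypic
    r-squared against the haplotype dosage decays smoothly with the flip
    rate; a configurable fraction of variants is drawn independently of the
    haplotype.  The designated causal proxy gets the lowest flip rate.
    Missing genotypes and breed labels are injected per the panel spec.
    """
    config.validate()
    if genotypes.qtl_truth is None:
        raise SimulationError("sequence panel requires a planted QTL")
    spec = config.seq_panel_spec
    qtl = config.qtl_spec
    rng = _rng(config, 5)

    center = (qtl.start_bp + qtl.end_bp) // 2
    lo = max(1, center - spec.window_bp // 2)
    hi = min(config.chromosome_length, center + spec.window_bp // 2)
    if lo >= hi:
        raise SimulationError("sequence-panel window is outside the map")
    nv = spec.n_variants
    pos = np.sort(rng.choice(np.arange(lo, hi, dtype=np.int64), nv, replace=False))

    flips = rng.uniform(spec.flip_min, spec.flip_max, size=nv)
    independent = rng.random(nv) < spec.frac_independent
    proxy = int(rng.integers(nv))
    independent[proxy] = False
    flips[proxy] = spec.causal_proxy_flip

    carrier = genotypes.qtl_truth["carrier"].astype(np.int8)  # per gamete
    n = genotypes.n_animals
    alleles = np.empty((2 * n, nv), dtype=np.int8)
    for v in range(nv):
        if independent[v]:
            p = rng.uniform(0.1, 0.9)
            alleles[:, v] = (rng.random(2 * n) < p).astype(np.int8)
        else:
            flip = (rng.random(2 * n) < flips[v]).astype(np.int8)
            alleles[:, v] = carrier ^ flip
    G = (alleles[0::2] + alleles[1::2]).astype(np.int8)
    miss = rng.random(G.shape) < spec.missing_rate
    G[miss] = -1

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(4, size=nv)
    alt_i = (ref_i + rng.integers(1, 4, size=nv)) % 4
    ref, alt = bases[ref_i], bases[alt_i]

    probs = spec.breed_probs or tuple([1.0 / len(spec.breeds)] * len(spec.breeds))
    breeds = rng.choice(np.array(spec.breeds), size=n, p=np.asarray(probs))

    # family links among the panel samples (duos/trios from the pedigree)
    ids = genotypes.animal_ids
    idset = set(int(i) for i in ids)
    fam_rows = []
    if genotypes.parents is not None:
        for child, (p1, p2) in zip(ids, genotypes.parents):
            p1 = int(p1) if int(p1) in idset else UNKNOWN
            p2 = int(p2) if int(p2) in idset else UNKNOWN
            if p1 != UNKNOWN or p2 != UNKNOWN:
                fam_rows.append((int(child), p1, p2))
    variants = pd.DataFrame(
        {
            "chrom": qtl.chromosome,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "flip_rate": flips,
            "independent": independent,
            "is_causal_proxy": np.arange(nv) == proxy,
        }
    )
    return SeqPanel(
        variants=variants,
        genotypes=G,
        sample_ids=ids.copy(),
        breeds=breeds,
        families=pd.DataFrame(fam_rows, columns=["child", "parent1", "parent2"]),
        seed=config.seed,
    )
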