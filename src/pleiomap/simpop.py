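"""Synthetic multi-trait sheep population simulator.

Generates a three-generation half-sib pedigree (founders -> sires/dams ->
phenotyped offspring), genotypes by gene-dropping coalescent founder
haplotypes through the pedigree with recombination at 1 cM/Mb, and
multi-trait phenotypes built from the same model the analysis assumes:

    y = mean + fixed effects (flock, sex, age) + breed-proportion effect
        + QTL effects + polygenic effect (pedigree covariance)
        + sire-by-flock effect + residual

Phenotypic variance is 1 per trait, so effect sizes are in phenotypic SD
units: sigma2_a = h2, sigma2_sf = sire_flock_var_frac and
sigma2_e = 1 - h2 - sire_flock_var_frac (heritability here is the ratio
a / (a + s.f. + e), matching the estimator downstream).  A configured
fraction of genetic variance comes from mapped QTL, part of which are
pleiotropic (effect vectors drawn from MVN(0, genetic_corr)) and part
private to single traits, so multi-trait detection can be separated from
single-trait power.  All randomness flows from one seed through a
documented stream split (numpy SeedSequence spawn order: pedigree,
genotypes, traits).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd

from .containers import ConfigError, GenotypeMatrix, Pedigree

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_all",
    "truth_report",
]

RECOMB_RATE = 1e-8  # 1 cM/Mb, per bp per meiosis
_FOUNDER_NE = 1000  # coalescent population size behind founder haplotypes
_MUT_RATE = 1.2e-8


def _default_corr(k: int) -> np.ndarray:
    r = np.full((k, k), 0.4)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SimConfig:
    """Knobs of the synthetic population (desk-scale defaults).

    Defaults give 2,000 phenotyped offspring, 3 chromosomes x 50 Mb with
    6,000 SNPs, 20 QTL and 8 traits whose heritabilities span the range
    seen in wool traits; every stage of the pipeline runs in minutes.
    """

    n_sires: int = 50
    n_dams_per_sire: int = 10
    n_offspring_per_dam: int = 4
    n_chromosomes: int = 3
    chrom_length_bp: int = 50_000_000
    n_snps: int = 6000
    n_qtl: int = 20
    n_traits: int = 8
    h2_per_trait: np.ndarray = None
    sire_flock_var_frac: float = 0.05
    genetic_corr: np.ndarray = None
    qtl_var_frac: float = 0.5
    private_qtl_frac: float = 0.5
    crossbred_frac: float = 0.3
    missing_rate_per_trait: float = 0.0
    env_corr: float = 0.25
    n_flocks: int = 5
    fixed_effect_sd: float = 0.5
    breed_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.h2_per_trait is None:
            self.h2_per_trait = np.linspace(0.1, 0.8, self.n_traits)
        self.h2_per_trait = np.asarray(self.h2_per_trait, dtype=float)
        if len(self.h2_per_trait) != self.n_traits:
            raise ConfigError("h2_per_trait length must equal n_traits")
        if self.genetic_corr is None:
            self.genetic_corr = _default_corr(self.n_traits)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        r = self.genetic_corr
        if r.shape != (self.n_traits, self.n_traits) or not np.allclose(r, r.T):
            raise ConfigError("genetic_corr must be a symmetric trait x trait matrix")
        if not np.allclose(np.diag(r), 1.0):
            raise ConfigError("genetic_corr must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ConfigError("genetic_corr must be positive semi-definite")
        for name in (
            "sire_flock_var_frac",
            "qtl_var_frac",
            "private_qtl_frac",
            "crossbred_frac",
            "missing_rate_per_trait",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_qtl > self.n_snps:
            raise ConfigError("n_qtl cannot exceed n_snps")
        if np.any(self.h2_per_trait < 0) or np.any(self.h2_per_trait > 1):
            raise ConfigError("heritabilities must lie in [0, 1]")
        if np.any(self.h2_per_trait + self.sire_flock_var_frac > 1):
            raise ConfigError("h2 + sire_flock_var_frac must not exceed 1")

    def trait_names(self) -> list[str]:
        return [f"trait_{i + 1}" for i in range(self.n_traits)]

    def streams(self):
        """Fixed stream split: (pedigree, genotypes, traits)."""
        return np.random.SeedSequence(self.seed).spawn(3)


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    qtl_snp_ids: list
    qtl_effects: np.ndarray  # n_qtl x n_traits, phenotypic SD units
    qtl_traits: list  # per QTL: list of trait indices with nonzero effect
    true_breeding_values: pd.DataFrame  # animal x trait
    true_h2: np.ndarray
    qtl_chrom: np.ndarray = None
    qtl_bp: np.ndarray = None

    def pleiotropic(self, min_traits: int = 2) -> np.ndarray:
        """Indices of QTL with effects on at least ``min_traits`` traits."""
        return np.asarray([i for i, t in enumerate(self.qtl_traits) if len(t) >= min_traits])

    def to_json_dict(self) -> dict:
        return {
            "qtl_snp_ids": list(map(str, self.qtl_snp_ids)),
            "qtl_chrom": [int(c) for c in self.qtl_chrom],
            "qtl_bp": [int(b) for b in self.qtl_bp],
            "qtl_effects": self.qtl_effects.tolist(),
            "qtl_traits": [list(map(int, t)) for t in self.qtl_traits],
            "true_h2": self.true_h2.tolist(),
        }


# ---------------------------------------------------------------- pedigree


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Three-generation pedigree with half-sib families and breed structure.

    Generation 0 founders are unrelated; generation 1 holds the sires and
    dams (each the child of a random founder couple); generation 2 holds
    ``n_sires * n_dams_per_sire * n_offspring_per_dam`` phenotyped offspring.
    Crossbreeding is introduced through dams so that exactly
    ``crossbred_frac`` of offspring have breed proportion 0.25 < Q <= 0.90
    while the remainder have Q > 0.90; crossbred dams are clustered on a
    subset of sires, but with some straightbred paternal half-sibs so the
    "shares a sire with a crossbred" rule downstream is exercised.
    """
    if cfg.n_sires < 1 or cfg.n_dams_per_sire < 1 or cfg.n_offspring_per_dam < 1:
        raise ConfigError("n_sires, n_dams_per_sire and n_offspring_per_dam must be positive")
    rng = np.random.default_rng(cfg.streams()[0])

    n_dams = cfg.n_sires * cfg.n_dams_per_sire
    n_f0_m, n_f0_f = cfg.n_sires, n_dams
    rows = []
    aid = 1
    f0_m, f0_f = [], []
    for _ in range(n_f0_m):
        rows.append((aid, 0, 0, "M", 0, 0, 1.0, np.nan))
        f0_m.append(aid)
        aid += 1
    for _ in range(n_f0_f):
        rows.append((aid, 0, 0, "F", 0, 0, 1.0, np.nan))
        f0_f.append(aid)
        aid += 1

    sires, dams = [], []
    for _ in range(cfg.n_sires):
        rows.append((aid, rng.choice(f0_m), rng.choice(f0_f), "M", 1, 0, 1.0, np.nan))
        sires.append(aid)
        aid += 1
    for _ in range(n_dams):
        rows.append((aid, rng.choice(f0_m), rng.choice(f0_f), "F", 1, 0, 1.0, np.nan))
        dams.append(aid)
        aid += 1

    # dam -> sire assignment, n_dams_per_sire dams each
    dam_sire = np.repeat(sires, cfg.n_dams_per_sire)
    # crossbred dams clustered on the leading sires, ~75% of each family,
    # until the exact quota is reached
    n_cross = round(cfg.crossbred_frac * n_dams)
    cross_dam = np.zeros(n_dams, dtype=bool)
    order = rng.permutation(cfg.n_sires)
    quota = n_cross
    for s in order:
        if quota <= 0:
            break
        fam = np.where(dam_sire == sires[s])[0]
        take = fam[rng.random(len(fam)) < 0.75][: quota]
        if len(take) == 0 and quota > 0:
            take = fam[:1]
        cross_dam[take] = True
        quota -= len(take)
    dam_q = np.where(cross_dam, rng.uniform(0.0, 0.8, n_dams), rng.uniform(0.95, 1.0, n_dams))

    sire_q = rng.uniform(0.95, 1.0, cfg.n_sires)
    sire_q_of_dam = np.repeat(sire_q, cfg.n_dams_per_sire)
    for j, dam in enumerate(dams):
        flock = int(rng.integers(1, cfg.n_flocks + 1))
        q_off = 0.5 * (sire_q_of_dam[j] + dam_q[j])
        for _ in range(cfg.n_offspring_per_dam):
            sex = "M" if rng.random() < 0.5 else "F"
            age = float(rng.uniform(300, 420))
            rows.append((aid, dam_sire[j], dam, sex, 2, flock, q_off, age))
            aid += 1

    table = pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "sex", "generation", "flock", "Q", "age"]
    )
    return Pedigree(table)


# --------------------------------------------------------------- genotypes


def _founder_haplotypes(cfg: SimConfig, n_founders: int, seed_pair):
    """Coalescent founder haplotypes per chromosome, sites restricted to
    biallelic SNPs with allele frequency in [0.05, 0.5] (minor allele)."""
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    haps, positions = [], []
    for c in range(cfg.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=n_founders,
            ploidy=2,
            sequence_length=cfg.chrom_length_bp,
            recombination_rate=RECOMB_RATE,
            population_size=_FOUNDER_NE,
            random_seed=int(seed_pair[0]) + 7 * c + 1,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=_MUT_RATE,
            random_seed=int(seed_pair[1]) + 7 * c + 1,
            model=msprime.BinaryMutationModel(),
        )
        gm = mts.genotype_matrix().astype(np.uint8)  # sites x haplotypes
        pos = np.asarray([s.position for s in mts.sites()])
        freq = gm.mean(axis=1)
        maf = np.minimum(freq, 1 - freq)
        keep = np.where((maf >= 0.05) & (maf <= 0.5) & (gm.max(axis=1) == 1))[0]
        if len(keep) < per_chrom[c]:
            raise ConfigError(
                f"chromosome {c + 1}: only {len(keep)} usable founder SNPs "
                f"for {per_chrom[c]} requested; lengthen the chromosome"
            )
        sel = keep[np.linspace(0, len(keep) - 1, per_chrom[c]).round().astype(int)]
        sel = np.unique(sel)
        haps.append(gm[sel].T.copy())  # haplotypes x snps
        positions.append(pos[sel].astype(np.int64) + 1)  # 1-based bp
        if np.any(np.diff(positions[-1]) <= 0):
            raise ConfigError("duplicate SNP positions from founder simulation")
    return haps, positions, per_chrom


def _gamete(hap_pair, pos_morgans, rng):
    """Meiosis with Poisson crossovers (no interference)."""
    length = pos_morgans[-1] - pos_morgans[0]
    n_x = rng.poisson(length)
    start = rng.integers(2)
    if n_x == 0:
        return hap_pair[start]
    cuts = np.sort(rng.uniform(pos_morgans[0], pos_morgans[-1], n_x))
    seg = (np.searchsorted(cuts, pos_morgans, side="right") + start) % 2
    take0 = seg == 0
    out = np.where(take0, hap_pair[0], hap_pair[1])
    return out


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop founder haplotypes through the pedigree.

    Founders receive coalescent haplotypes (LD decaying with distance);
    every non-founder receives one recombinant gamete from each parent
    (Poisson crossovers at 1 cM/Mb).  Dosages count the alternate allele.
    """
    seeds = cfg.streams()[1].spawn(2)
    geno_rng = np.random.default_rng(seeds[1])
    table = ped.table
    founder_rows = np.where((table["sire"] == 0) & (table["dam"] == 0))[0]
    if len(founder_rows) == 0:
        raise ConfigError("pedigree has no founders")
    if cfg.chrom_length_bp < cfg.n_snps // cfg.n_chromosomes:
        raise ConfigError("chromosome shorter than average SNP spacing")
    fh, positions, per_chrom = _founder_haplotypes(
        cfg, len(founder_rows), seeds[0].generate_state(2)
    )

    n = len(table)
    sire_idx, dam_idx = ped.parents_idx()
    dosages = np.empty((n, cfg.n_snps), dtype=np.float64)
    col0 = 0
    for c in range(cfg.n_chromosomes):
        m = per_chrom[c]
        pos_m = positions[c] * RECOMB_RATE * 100 / 100.0  # bp -> Morgans
        haps = np.empty((n, 2, m), dtype=np.uint8)
        for k, r in enumerate(founder_rows):
            haps[r, 0] = fh[c][2 * k]
            haps[r, 1] = fh[c][2 * k + 1]
        for i in range(n):
            s, d = sire_idx[i], dam_idx[i]
            if s < 0 and d < 0:
                continue
            haps[i, 0] = _gamete(haps[s], pos_m, geno_rng)
            haps[i, 1] = _gamete(haps[d], pos_m, geno_rng)
        dosages[:, col0 : col0 + m] = haps.sum(axis=1)
        col0 += m

    snp_map = pd.DataFrame(
        {
            "snp_id": [
                f"snp{c + 1}_{p}"
                for c in range(cfg.n_chromosomes)
                for p in positions[c]
            ],
            "chrom": np.repeat(np.arange(1, cfg.n_chromosomes + 1), per_chrom),
            "bp": np.concatenate(positions),
        }
    )
    return GenotypeMatrix(dosages, table["animal"].to_numpy(), snp_map)


# ------------------------------------------------------------------ traits


def _pick_qtl(geno: GenotypeMatrix, cfg: SimConfig, rng) -> np.ndarray:
    """QTL SNP column indices: MAF >= 0.1, pairwise separation >= 2 Mb."""
    p = geno.allele_freq()
    maf = np.minimum(p, 1 - p)
    chrom = geno.snp_map["chrom"].to_numpy()
    bp = geno.snp_map["bp"].to_numpy()
    eligible = np.where(maf >= 0.10)[0]
    rng.shuffle(eligible)
    chosen = []
    for j in eligible:
        if all(chrom[j] != chrom[k] or abs(int(bp[j]) - int(bp[k])) >= 2_000_000 for k in chosen):
            chosen.append(j)
        if len(chosen) == cfg.n_qtl:
            break
    if len(chosen) < cfg.n_qtl:
        raise ConfigError("could not place n_qtl QTL with 2-Mb separation")
    return np.sort(np.asarray(chosen))


def _drop_polygenic(ped: Pedigree, cov: np.ndarray, rng) -> np.ndarray:
    """Polygenic values down the pedigree: founders ~ MVN(0, cov); children
    get the parent average plus Mendelian-sampling noise MVN(0, cov/2)."""
    n, k = len(ped), cov.shape[0]
    chol = np.linalg.cholesky(cov + 1e-8 * np.eye(k))
    a = np.empty((n, k))
    sire_idx, dam_idx = ped.parents_idx()
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s < 0 and d < 0:
            a[i] = chol @ z[i]
        else:
            mid = 0.5 * (a[s] + a[d])
            a[i] = mid + np.sqrt(0.5) * (chol @ z[i])
    return a


def simulate_traits(
    geno: GenotypeMatrix, ped: Pedigree, cfg: SimConfig
) -> tuple[pd.DataFrame, TruthSet]:
    """Phenotypes for the offspring generation plus the ground truth.

    Per trait (phenotypic variance 1): QTL variance = qtl_var_frac * h2
    exactly (enforced by scaling), polygenic = (1 - qtl_var_frac) * h2,
    sire-by-flock = sire_flock_var_frac, residual = the remainder.  Fixed
    flock/sex/age effects have magnitude ``fixed_effect_sd`` so skipping
    adjustment is detectable; a breed effect proportional to Q is added.
    """
    rng = np.random.default_rng(cfg.streams()[2])
    table = ped.table
    off = ped.offspring()
    n_off = len(off)
    if n_off == 0:
        raise ConfigError("pedigree has no offspring")
    k = cfg.n_traits
    h2 = cfg.h2_per_trait

    # --- QTL effects
    qtl_idx = _pick_qtl(geno, cfg, rng)
    p = geno.allele_freq()[qtl_idx]
    het = 2 * p * (1 - p)
    n_priv = round(cfg.private_qtl_frac * cfg.n_qtl)
    n_pleio = cfg.n_qtl - n_priv
    which_pleio = np.sort(rng.choice(cfg.n_qtl, n_pleio, replace=False))
    is_pleio = np.zeros(cfg.n_qtl, dtype=bool)
    is_pleio[which_pleio] = True

    beta = np.zeros((cfg.n_qtl, k))
    pleio_share = 0.7 if n_priv else 1.0
    if n_pleio:
        chol = np.linalg.cholesky(cfg.genetic_corr + 1e-10 * np.eye(k))
        raw = rng.standard_normal((n_pleio, k)) @ chol.T
        beta[is_pleio] = raw
        for t in range(k):
            v = np.sum(het[is_pleio] * beta[is_pleio, t] ** 2)
            target = pleio_share * cfg.qtl_var_frac * h2[t]
            beta[is_pleio, t] *= np.sqrt(target / v) if v > 0 else 0.0
    qtl_traits = [list(range(k)) if is_pleio[q] else [] for q in range(cfg.n_qtl)]
    if n_priv:
        priv = np.where(~is_pleio)[0]
        owner = np.resize(np.arange(k), n_priv)
        rng.shuffle(owner)
        per_trait_priv = np.bincount(owner, minlength=k)
        for q, t in zip(priv, owner):
            target = (1 - pleio_share) * cfg.qtl_var_frac * h2[t] / per_trait_priv[t]
            beta[q, t] = rng.choice([-1.0, 1.0]) * np.sqrt(target / het[q])
            qtl_traits[q] = [int(t)]

    z_qtl = geno.dosages[:, qtl_idx] - 2 * p  # centered, all animals
    # rescale against the realized offspring variance (LD between QTL and
    # drift make the 2p(1-p)-based scaling only approximate): per trait the
    # QTL part of the genetic variance becomes exactly qtl_var_frac * h2
    off_rows_v = ped.rows_of(ped.offspring()["animal"])
    g_off = z_qtl[off_rows_v] @ beta
    realized = g_off.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(
            realized > 0, np.sqrt(cfg.qtl_var_frac * h2 / np.where(realized > 0, realized, 1.0)), 0.0
        )
    beta *= scale
    g_qtl = z_qtl @ beta

    # --- polygenic component: its covariance compensates the realized QTL
    # covariance so the TOTAL genetic covariance matches genetic_corr (the
    # few mapped QTL realize their cross-trait covariance noisily, and
    # private QTL dilute it; the infinitesimal background absorbs both)
    sd_g = np.sqrt(h2)
    target_total = cfg.genetic_corr * np.outer(sd_g, sd_g)
    qtl_cov = np.cov(g_off.T * scale[:, None], ddof=1) if k > 1 else np.atleast_2d(
        np.var(g_off[:, 0] * scale[0], ddof=1)
    )
    cov = target_total - qtl_cov
    lam, vec = np.linalg.eigh(cov)
    cov = (vec * np.clip(lam, 1e-10, None)) @ vec.T
    # restore the exact per-trait polygenic variance after the PSD clip
    dtarget = np.clip((1 - cfg.qtl_var_frac) * h2, 1e-12, None)
    d = np.sqrt(dtarget / np.diag(cov))
    cov = cov * np.outer(d, d)
    a_poly = _drop_polygenic(ped, cov, rng)

    tbv = g_qtl + a_poly

    # --- non-genetic components for offspring
    off_rows = ped.rows_of(off["animal"])
    flock = off["flock"].to_numpy()
    sexm = (off["sex"] == "M").to_numpy().astype(float)
    age = off["age"].to_numpy()
    q_prop = off["Q"].to_numpy()
    sire = off["sire"].to_numpy()

    flock_eff = rng.normal(0, cfg.fixed_effect_sd, (cfg.n_flocks + 1, k))
    sex_eff = rng.normal(0, cfg.fixed_effect_sd, k)
    age_slope = rng.normal(0, cfg.fixed_effect_sd, k)
    breed_eff = rng.normal(0, cfg.breed_effect_sd, k)
    age_std = (age - age.mean()) / age.std()

    sf_index: dict = {}
    for key in zip(sire, flock):
        sf_index.setdefault(key, len(sf_index))
    sf_eff = rng.normal(0, np.sqrt(cfg.sire_flock_var_frac), (len(sf_index), k))
    sf_of = np.asarray([sf_index[key] for key in zip(sire, flock)])

    resid_var = 1.0 - h2 - cfg.sire_flock_var_frac
    r_e = np.full((k, k), cfg.env_corr)
    np.fill_diagonal(r_e, 1.0)
    sd_e = np.sqrt(resid_var)
    chol_e = np.linalg.cholesky(r_e * np.outer(sd_e, sd_e) + 1e-12 * np.eye(k))
    resid = rng.standard_normal((n_off, k)) @ chol_e.T

    y = (
        10.0
        + flock_eff[flock]
        + np.outer(sexm, sex_eff)
        + np.outer(age_std, age_slope)
        + np.outer(q_prop - q_prop.mean(), breed_eff)
        + tbv[off_rows]
        + sf_eff[sf_of]
        + resid
    )

    if cfg.missing_rate_per_trait > 0:
        mask = rng.random((n_off, k)) < cfg.missing_rate_per_trait
        # keep at least one measured trait per animal
        all_missing = mask.all(axis=1)
        mask[all_missing, rng.integers(0, k, all_missing.sum())] = False
        y = np.where(mask, np.nan, y)

    pheno = off[["animal", "sire", "dam", "flock", "sex", "age", "Q"]].reset_index(drop=True)
    for t, name in enumerate(cfg.trait_names()):
        pheno[name] = y[:, t]

    truth = TruthSet(
        qtl_snp_ids=geno.snp_map["snp_id"].to_numpy()[qtl_idx].tolist(),
        qtl_effects=beta,
        qtl_traits=qtl_traits,
        true_breeding_values=pd.DataFrame(
            tbv, index=table["animal"].to_numpy(), columns=cfg.trait_names()
        ),
        true_h2=h2.copy(),
        qtl_chrom=geno.snp_map["chrom"].to_numpy()[qtl_idx],
        qtl_bp=geno.snp_map["bp"].to_numpy()[qtl_idx],
    )
    return pheno, truth


def simulate_all(cfg: SimConfig):
    """Convenience wrapper: pedigree, genotypes, phenotypes, truth."""
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    pheno, truth = simulate_traits(geno, ped, cfg)
    return ped, geno, pheno, truth


# ----------------------------------------------------------- truth scoring


def truth_report(truth: TruthSet, calls, window_bp: int, qtl_subset=None) -> dict:
    """Score called SNPs against the planted QTL.

    ``calls`` is a mapping method -> QtlCallSet (or a single call set, scored
    under method name "calls").  A QTL counts as recovered when at least one
    called SNP lies within ``window_bp`` of it on the same chromosome; a call
    with no QTL within ``window_bp`` is a false call.
    """
    if truth is None or len(truth.qtl_snp_ids) == 0:
        raise ConfigError("empty truth set")
    if not isinstance(calls, dict):
        calls = {"calls": calls}
    qsel = np.arange(len(truth.qtl_snp_ids)) if qtl_subset is None else np.asarray(qtl_subset)
    qc = np.asarray(truth.qtl_chrom)[qsel]
    qb = np.asarray(truth.qtl_bp)[qsel]
    out = {}
    for method, cs in calls.items():
        tab = cs.table if hasattr(cs, "table") else cs
        cc = tab["chrom"].to_numpy()
        cb = tab["bp"].to_numpy()
        recovered = 0
        for c, b in zip(qc, qb):
            if np.any((cc == c) & (np.abs(cb - b) <= window_bp)):
                recovered += 1
        false_calls = 0
        for c, b in zip(cc, cb):
            if not np.any((qc == c) & (np.abs(qb - b) <= window_bp)):
                false_calls += 1
        out[method] = {
            "n_qtl": int(len(qsel)),
            "recovered": int(recovered),
            "sensitivity": recovered / len(qsel),
            "false_calls": int(false_calls),
            "n_calls": int(len(tab)),
        }
    return out
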