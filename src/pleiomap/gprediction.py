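"""Relationship matrices, GBLUP, sire-family cross-validation, GEBV accuracy.

The numerator relationship matrix A comes from the pedigree by the tabular
method (with inbreeding on the diagonal); the genomic relationship matrix G
is VanRaden method 1, ``G = ZZ' / (2 sum p_j (1 - p_j))`` over SNPs with
MAF above a threshold.  GBLUP solves the equivalent animal model with
validation phenotypes treated as unknown, and accuracy is the per-fold
correlation between GEBV and the adjusted phenotype divided by sqrt(h2),
averaged over folds with its empirical standard error.

Cross-validation folds respect paternal half-sib families: crossbred
animals (0.25 < Q <= 0.90) and straightbreds sharing a sire with a
crossbred are always in training, and the remaining straightbred sire
families are split into folds whole, so no validation animal has paternal
half-sibs in training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import ConfigError, GenotypeMatrix, Pedigree

log = logging.getLogger(__name__)

__all__ = [
    "Grm",
    "FoldAssignment",
    "GebvTable",
    "build_a_matrix",
    "build_grm",
    "make_cv_folds",
    "gblup_solve",
    "reml_gblup_variances",
    "gblup_fit",
    "gebv_accuracy",
]


def build_a_matrix(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Rows/columns follow pedigree row order; diagonal is 1 + F (inbreeding).
    """
    n = len(ped)
    sire, dam = ped.parents_idx()
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == i or d == i:
            raise ConfigError(f"animal at row {i} is its own parent")
        if s >= 0 and d >= 0:
            a[i, :i] = 0.5 * (a[s, :i] + a[d, :i])
            a[i, i] = 1.0 + 0.5 * a[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            a[i, :i] = 0.5 * a[p, :i]
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0
        a[:i, i] = a[i, :i]
    return a


@dataclass
class Grm:
    """Genomic relationship matrix (VanRaden method 1)."""

    matrix: np.ndarray
    animals: np.ndarray
    n_snps_used: int
    maf_min: float
    n_excluded: int
    _row: dict = field(default=None, repr=False)

    def __post_init__(self):
        self._row = {int(a): i for i, a in enumerate(self.animals)}

    def rows_of(self, animals) -> np.ndarray:
        return np.asarray([self._row[int(a)] for a in animals])


def build_grm(geno: GenotypeMatrix, maf_min: float = 0.005) -> Grm:
    """G = ZZ' / (2 sum p(1-p)), Z allele-frequency-centered dosages.

    SNPs with MAF <= ``maf_min`` are excluded (count logged).  Allele
    frequencies come from the full genotype set supplied.  Missing dosages
    contribute 0 after centering (mean imputation).
    """
    if geno.n_animals < 2:
        raise ConfigError("need at least 2 animals for a GRM")
    p = geno.allele_freq()
    maf = np.minimum(p, 1 - p)
    keep = maf > maf_min
    n_excl = int((~keep).sum())
    if not keep.any():
        raise ConfigError("all SNPs excluded by the MAF filter")
    if n_excl:
        log.info("GRM: excluded %d SNPs with MAF <= %g", n_excl, maf_min)
    z = geno.dosages[:, keep] - 2 * p[keep]
    z = np.nan_to_num(z, nan=0.0)
    denom = 2 * np.sum(p[keep] * (1 - p[keep]))
    g = (z @ z.T) / denom
    return Grm(g, np.asarray(geno.animals), int(keep.sum()), maf_min, n_excl)


@dataclass
class FoldAssignment:
    """animal -> fold index (1..n_folds) or 0 for always-training."""

    fold: pd.Series  # index animal id, values int
    n_folds: int

    def validation_animals(self, f: int) -> np.ndarray:
        return self.fold.index[self.fold == f].to_numpy()

    def training_animals(self, f: int) -> np.ndarray:
        return self.fold.index[(self.fold != f)].to_numpy()


def make_cv_folds(ped: Pedigree, seed: int, n_folds: int = 5) -> FoldAssignment:
    """Fivefold split of straightbred offspring by whole sire families.

    Crossbreds (0.25 < Q <= 0.90) and straightbreds sharing a sire with a
    crossbred are marked always-training (fold 0); the remaining
    straightbred sire families are shuffled and dealt whole into folds, so
    no validation animal has a paternal half-sib in training.
    """
    off = ped.offspring()
    if "Q" not in off.columns:
        raise ConfigError("pedigree lacks breed proportions Q")
    q = off["Q"].to_numpy()
    cross = (q > 0.25) & (q <= 0.90)
    straight = q > 0.90
    if not (cross | straight).all():
        raise ConfigError("offspring with Q <= 0.25 are not supported")
    cross_sires = set(off.loc[cross, "sire"])
    always_training = cross | off["sire"].isin(cross_sires).to_numpy()
    eligible = off[~always_training]
    families = eligible["sire"].unique()
    if len(families) < n_folds:
        raise ConfigError(
            f"only {len(families)} eligible sire families for {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    families = families[rng.permutation(len(families))]
    fold_of_family = {s: 1 + i % n_folds for i, s in enumerate(families)}
    fold = pd.Series(0, index=off["animal"].to_numpy(), dtype=int)
    fold.loc[eligible["animal"].to_numpy()] = [
        fold_of_family[s] for s in eligible["sire"]
    ]
    return FoldAssignment(fold, n_folds)


@dataclass
class GebvTable:
    """Long table: animal, trait, gebv, fold (fold in which it was predicted)."""

    table: pd.DataFrame
    method: str


def gblup_solve(
    g: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    sigma2_g: float,
    sigma2_e: float,
) -> np.ndarray:
    """GEBV for all animals with phenotypes known only on ``train`` rows.

    Solves g_hat = sigma2_g G[:, t] V^-1 (y_t - mu_hat) with
    V = sigma2_g G_tt + sigma2_e I and a GLS intercept.
    """
    if sigma2_g <= 0:
        return np.zeros(g.shape[0])
    gtt = g[np.ix_(train, train)]
    v = sigma2_g * gtt + sigma2_e * np.eye(len(train))
    try:
        vi = np.linalg.inv(v)
    except np.linalg.LinAlgError:
        log.warning("singular GBLUP coefficient matrix; adding 1e-8 ridge")
        vi = np.linalg.inv(v + 1e-8 * np.eye(len(train)))
    yt = y[train]
    one = np.ones(len(train))
    mu = (one @ vi @ yt) / (one @ vi @ one)
    return sigma2_g * g[:, train] @ (vi @ (yt - mu))


def reml_gblup_variances(g: np.ndarray, y: np.ndarray, train: np.ndarray):
    """REML (sigma2_g, sigma2_e) for y = mu + g + e, g ~ N(0, G sigma2_g).

    One variance ratio, profiled residual variance, solved in the eigenbasis
    of the training-block GRM.
    """
    gtt = g[np.ix_(train, train)]
    d, u = np.linalg.eigh(gtt)
    d = np.clip(d, 0, None)
    yt = u.T @ y[train]
    xt = u.T @ np.ones((len(train), 1))
    n, p = len(yt), 1

    def neg2(log_gamma):
        gam = np.exp(log_gamma)
        w = gam * d + 1.0
        xw = xt / w[:, None]
        xtx = xt.T @ xw
        xty = xw.T @ yt
        beta = np.linalg.solve(xtx, xty)
        ypy = yt @ (yt / w) - xty.T @ beta
        s2 = float(ypy) / (n - p)
        return (n - p) * np.log(s2) + np.sum(np.log(w)) + np.linalg.slogdet(xtx)[1]

    res = minimize_scalar(neg2, bounds=(-10, 6), method="bounded")
    gam = float(np.exp(res.x))
    w = gam * d + 1.0
    xw = xt / w[:, None]
    beta = np.linalg.solve(xt.T @ xw, xw.T @ yt)
    ypy = yt @ (yt / w) - (xw.T @ yt).T @ beta
    s2e = float(ypy) / (n - p)
    return gam * s2e, s2e


def gblup_fit(
    grm: Grm,
    adj,
    folds: FoldAssignment | None,
    trait: str,
    vc=None,
) -> GebvTable:
    """GBLUP GEBV per cross-validation fold (or one fit if folds is None).

    Variances are re-estimated by REML on each training fold unless ``vc``
    supplies (sigma2_g, sigma2_e).  Validation animals are in the GRM but
    their phenotypes are treated as unknown.
    """
    values = adj.values[trait]
    animals = values.index.to_numpy()
    rows = grm.rows_of(animals)
    y_full = np.full(grm.matrix.shape[0], np.nan)
    y_full[rows] = values.to_numpy()
    observed = ~np.isnan(y_full)

    records = []
    fold_ids = range(1, folds.n_folds + 1) if folds is not None else [0]
    for f in fold_ids:
        if folds is not None:
            train_animals = set(folds.training_animals(f))
            train = np.where(
                observed & np.isin(grm.animals, list(train_animals))
            )[0]
            target = folds.validation_animals(f)
        else:
            train = np.where(observed)[0]
            target = grm.animals
        if vc is None:
            s2g, s2e = reml_gblup_variances(grm.matrix, y_full, train)
        else:
            s2g, s2e = vc
        gebv = gblup_solve(grm.matrix, y_full, train, s2g, s2e)
        trows = grm.rows_of(target)
        for aid, v in zip(target, gebv[trows]):
            records.append((int(aid), trait, float(v), f))
    return GebvTable(
        pd.DataFrame(records, columns=["animal", "trait", "gebv", "fold"]),
        method="GBLUP",
    )


def gebv_accuracy(gebv: GebvTable, adj, folds: FoldAssignment, trait: str, h2: float):
    """Accuracy = cor(GEBV, adjusted phenotype) / sqrt(h2), per fold.

    Returns dict with per-fold accuracies, their mean and the standard
    error of the mean over folds; zero-variance folds are flagged and
    excluded from the mean.
    """
    if h2 <= 0:
        raise ConfigError("h2 must be positive for the accuracy scaling")
    values = adj.values[trait]
    accs, flagged = {}, []
    tab = gebv.table[gebv.table["trait"] == trait]
    for f in range(1, folds.n_folds + 1):
        sub = tab[tab["fold"] == f]
        merged = sub.join(values.rename("pheno"), on="animal").dropna()
        if len(merged) < 3 or merged["gebv"].std() == 0:
            flagged.append(f)
            log.warning("fold %d flagged (too few animals or zero-variance GEBV)", f)
            continue
        r = np.corrcoef(merged["gebv"], merged["pheno"])[0, 1]
        accs[f] = r / np.sqrt(h2)
    vals = np.asarray(list(accs.values()))
    return {
        "per_fold": accs,
        "mean": float(vals.mean()) if len(vals) else np.nan,
        "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
        "flagged_folds": flagged,
    }
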