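"""Three approximate multi-trait analyses for mapping pleiotropic QTL.

multi-GWAS: the chi-square statistic ``t_i' V^-1 t_i`` per SNP, where t_i
stacks the signed single-trait GWAS t-values and V is the trait x trait
correlation of t-values over all SNPs (df = number of traits); the most
significant SNP below a threshold per 1-Mb window is kept.

multi-PP: combines single-trait BayesR posterior probabilities,
``pp_effect!=0 = 1 - prod_traits(pp_effect=0)``; SNPs above 0.3 are kept,
with contributing traits defined as those with per-trait pp above 0.05.

multi-LGEBV: per 250-kb window, the trait x trait covariance of local GEBV
standardized by phenotypic SDs; its first eigenvalue (variance of the
leading linear combination, in phenotypic SD units) ranks windows; within
each of the top windows the pseudo-trait S_LC = y'x (standardized local
GEBV dotted with the PC1 eigenvector) is mapped against every SNP in the
window under a model with a pedigree ("animal") random effect, and the
SNP with the highest F value is the best SNP.

Also here: cross-method overlap (Venn cells), SNP-effect correlation across
traits, and candidate-gene lookup within a +/-50-kb flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, GenotypeMatrix, Pedigree, window_index
from .phenomodel import _a_eigen

log = logging.getLogger(__name__)

__all__ = [
    "QtlCallSet",
    "build_tmatrix_v",
    "multi_gwas_chi2",
    "top_snp_per_mb",
    "multi_pp",
    "window_cov_pca",
    "select_top_windows",
    "pseudo_trait_slc",
    "best_snp_in_window",
    "compare_methods",
    "snp_effect_correlation",
    "candidate_genes",
]


@dataclass
class QtlCallSet:
    """Selected SNPs of one multi-trait method, sorted by position."""

    method: str  # multi-GWAS | multi-PP | multi-LGEBV
    table: pd.DataFrame  # snp_id, chrom, bp, statistic, traits

    def __post_init__(self):
        self.table = (
            self.table.sort_values(["chrom", "bp"]).reset_index(drop=True)
        )

    def snp_ids(self) -> set:
        return set(self.table["snp_id"])


# ------------------------------------------------------------- multi-GWAS


def build_tmatrix_v(gwas_tables: dict) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """SNP x trait signed t-values and their trait x trait correlation V.

    V is computed over all SNPs (flagged SNPs dropped listwise).  If V's
    smallest eigenvalue is below 1e-6, it is shrunk toward the identity,
    ``V <- (1-eps) V + eps I``, with the smallest eps restoring the bound;
    the applied eps is returned in the info dict.
    """
    traits = list(gwas_tables.keys())
    first = gwas_tables[traits[0]]
    tmat = pd.DataFrame(index=first["snp_id"], columns=traits, dtype=float)
    for tr in traits:
        tab = gwas_tables[tr]
        if not (tab["snp_id"].to_numpy() == first["snp_id"].to_numpy()).all():
            raise ConfigError("GWAS tables must cover the same SNP set in order")
        tmat[tr] = tab["t"].to_numpy()
    complete = tmat.dropna()
    zero_var = complete.std(ddof=0) == 0
    if zero_var.any():
        raise ConfigError(
            f"zero t-value variance for traits: {list(complete.columns[zero_var])}"
        )
    v = np.corrcoef(complete.to_numpy().T)
    eps = 0.0
    lam_min = float(np.linalg.eigvalsh(v).min())
    if lam_min < 1e-6:
        # smallest eps with min eig of (1-eps)V + eps I == 1e-6
        eps = (1e-6 - lam_min) / (1.0 - lam_min)
        v = (1 - eps) * v + eps * np.eye(v.shape[0])
        log.info("V-matrix shrinkage applied: eps=%.3g", eps)
    info = {"eps": eps, "lambda_min_raw": lam_min, "n_snps_used": len(complete)}
    meta = first[["snp_id", "chrom", "bp"]].copy()
    return tmat, v, {"info": info, "meta": meta, "traits": traits}


def multi_gwas_chi2(tmat: pd.DataFrame, v: np.ndarray) -> pd.DataFrame:
    """chi2_i = t_i' V^-1 t_i with P from chi-square, df = trait count."""
    lam = np.linalg.eigvalsh(v)
    if lam.min() <= 0:
        raise ConfigError("V must be positive definite")
    tv = tmat.to_numpy()
    finite = np.isfinite(tv).all(axis=1)
    vi = np.linalg.inv(v)
    chi2 = np.full(len(tmat), np.nan)
    rows = tv[finite]
    chi2[finite] = np.einsum("ij,jk,ik->i", rows, vi, rows)
    df = tmat.shape[1]
    p = stats.chi2.sf(chi2, df)
    return pd.DataFrame(
        {"snp_id": tmat.index, "chi2": chi2, "p": p, "flag": np.where(finite, "", "nonfinite")}
    ).reset_index(drop=True)


def top_snp_per_mb(
    chi2_table: pd.DataFrame,
    snp_meta: pd.DataFrame,
    threshold: float = 5e-7,
    window_bp: int = 1_000_000,
) -> QtlCallSet:
    """Most significant SNP passing the threshold per half-open 1-Mb tile;
    ties broken by smaller bp."""
    tab = chi2_table.merge(snp_meta, on="snp_id")
    tab = tab[np.isfinite(tab["p"]) & (tab["p"] < threshold)].copy()
    if len(tab) == 0:
        return QtlCallSet(
            "multi-GWAS",
            pd.DataFrame(columns=["snp_id", "chrom", "bp", "statistic", "p", "traits"]),
        )
    tab["tile"] = window_index(tab["bp"].to_numpy(), window_bp)
    tab = tab.sort_values(["chrom", "tile", "p", "bp"])
    best = tab.groupby(["chrom", "tile"], as_index=False).first()
    out = best[["snp_id", "chrom", "bp", "chi2", "p"]].rename(columns={"chi2": "statistic"})
    out["traits"] = [()] * len(out)
    return QtlCallSet("multi-GWAS", out)


# --------------------------------------------------------------- multi-PP


def multi_pp(fits: dict, snp_meta: pd.DataFrame, threshold: float = 0.3,
             trait_pp_min: float = 0.05) -> QtlCallSet:
    """Combined posterior probability that a SNP affects at least one trait.

    pp_effect!=0 = 1 - prod over traits of the per-trait probability of the
    zero class; SNPs above ``threshold`` are called, with contributing
    traits = those with per-trait pp_nonzero > ``trait_pp_min``.
    """
    traits = list(fits.keys())
    first = fits[traits[0]]
    pp0 = np.ones(len(first.snp_ids))
    per_trait = {}
    for tr in traits:
        fit = fits[tr]
        if not np.array_equal(fit.snp_ids, first.snp_ids):
            raise ConfigError("BayesR fits must share the SNP map")
        pz = fit.class_probs[:, 0]
        if np.any((pz < 0) | (pz > 1)):
            raise ConfigError("posterior probabilities outside [0, 1]")
        pp0 *= pz
        per_trait[tr] = 1.0 - pz
    combined = 1.0 - pp0
    called = np.where(combined > threshold)[0]
    meta = snp_meta.set_index("snp_id")
    rows = []
    for j in called:
        sid = first.snp_ids[j]
        contrib = tuple(tr for tr in traits if per_trait[tr][j] > trait_pp_min)
        rows.append(
            {
                "snp_id": sid,
                "chrom": meta.loc[sid, "chrom"],
                "bp": meta.loc[sid, "bp"],
                "statistic": combined[j],
                "traits": contrib,
            }
        )
    return QtlCallSet(
        "multi-PP",
        pd.DataFrame(rows, columns=["snp_id", "chrom", "bp", "statistic", "traits"]),
    )


# ------------------------------------------------------------ multi-LGEBV


@dataclass
class WindowPca:
    """Eigen-analysis of the standardized local-GEBV covariance per window."""

    windows: pd.DataFrame  # chrom, start, end, window_id
    eigvals: np.ndarray  # n_windows x n_traits, descending per window
    pc1_vec: np.ndarray  # n_windows x n_traits
    pc1_prop: np.ndarray  # n_windows
    traits: list
    trace: np.ndarray = None  # n_windows, trace of each covariance matrix


def window_cov_pca(lgms: dict, pheno_sds: pd.Series) -> WindowPca:
    """Per-window trait x trait standardized covariance of local GEBV,
    t_(y,x) = cov(LGEBV_y, LGEBV_x) / (sd_y sd_x), with eigenvalues sorted
    descending; PC1 proportion = lambda_1 / sum(lambda) (0 for an all-zero
    window).
    """
    traits = list(lgms.keys())
    first = lgms[traits[0]]
    if first.values.shape[0] < 2:
        raise ConfigError("need at least 2 animals")
    n_w = first.values.shape[1]
    k = len(traits)
    std = np.stack(
        [lgms[tr].values / float(pheno_sds[tr]) for tr in traits], axis=2
    )  # animals x windows x traits
    eigvals = np.zeros((n_w, k))
    pc1 = np.zeros((n_w, k))
    prop = np.zeros(n_w)
    trace = np.zeros(n_w)
    for wdx in range(n_w):
        yw = std[:, wdx, :]
        if np.allclose(yw, yw[0]):
            continue
        c = np.atleast_2d(np.cov(yw.T, ddof=1))
        lam, vec = np.linalg.eigh(c)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        eigvals[wdx] = lam
        pc1[wdx] = vec[:, 0]
        trace[wdx] = float(np.trace(c))
        tot = lam.sum()
        prop[wdx] = lam[0] / tot if tot > 0 else 0.0
    return WindowPca(first.windows.copy(), eigvals, pc1, prop, traits, trace)


def select_top_windows(wp: WindowPca, k: int = 120) -> pd.DataFrame:
    """The k windows with the largest first eigenvalue (ties by chromosome
    then bp), with PC1 proportions alongside."""
    if k > len(wp.windows):
        raise ConfigError("k exceeds the number of windows")
    tab = wp.windows.copy()
    tab["lambda1"] = wp.eigvals[:, 0]
    tab["pc1_prop"] = wp.pc1_prop
    tab["window_index"] = np.arange(len(tab))
    tab = tab.sort_values(
        ["lambda1", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    return tab.head(k).reset_index(drop=True)


def pseudo_trait_slc(
    lgms: dict, wp: WindowPca, window_index_: int, adj=None
) -> np.ndarray:
    """S_LC = y' x: standardized local GEBV dotted with the PC1 eigenvector.

    Animals missing a trait's phenotype use the mean local GEBV of the
    measured animals for that trait (requires ``adj`` for the missing mask;
    without it all animals are treated as measured).
    """
    x = wp.pc1_vec[window_index_]
    if not np.any(x):
        raise ConfigError("PC1 eigenvector absent for this window")
    traits = wp.traits
    first = lgms[traits[0]]
    animals = first.animals
    y = np.stack(
        [lgms[tr].values[:, window_index_] / 1.0 for tr in traits], axis=1
    )
    # standardize by phenotypic SD: values stored raw, so divide here
    sds = np.asarray([float(first_sd) for first_sd in _sds_of(lgms, traits, adj)])
    y = y / sds
    if adj is not None:
        mask = adj.values.reindex(animals)[traits].isna().to_numpy()
        col_mean = np.where(
            (~mask).sum(axis=0) > 0,
            np.nanmean(np.where(mask, np.nan, y), axis=0),
            0.0,
        )
        y = np.where(mask, col_mean, y)
    return y @ x


def _sds_of(lgms, traits, adj):
    if adj is not None:
        return [adj.pheno_sd[tr] for tr in traits]
    return [1.0 for _ in traits]


def best_snp_in_window(
    slc: np.ndarray,
    animals: np.ndarray,
    geno: GenotypeMatrix,
    ped: Pedigree,
    chrom: int,
    start: int,
    end: int,
) -> dict | None:
    """Best SNP for the window pseudo-trait.

    Fits S_LC ~ mean + SNP + animal + error per SNP in the half-open window
    [start, end), the animal effect random with pedigree covariance (ratio
    from a one-time REML on S_LC), and returns the SNP with the highest
    F value (ties by smaller bp); None if the window has no polymorphic SNP.
    """
    m = geno.snp_map
    in_w = (m["chrom"].to_numpy() == chrom) & (m["bp"].to_numpy() - 1 >= start) & (
        m["bp"].to_numpy() - 1 < end
    )
    if not in_w.any():
        log.warning("window %s:%d-%d has no SNPs; skipped", chrom, start, end)
        return None
    gsub = geno.subset(animals).subset_snps(in_w)
    s = np.nan_to_num(gsub.dosages, nan=0.0)
    poly = (s.max(axis=0) - s.min(axis=0)) > 0
    if not poly.any():
        log.warning("window %s:%d-%d monomorphic; skipped", chrom, start, end)
        return None

    d, u = _a_eigen(ped, animals)
    gamma = _reml_ratio(slc, d, u)
    w = 1.0 / (gamma * d + 1.0)
    yr = u.T @ slc
    sr = u.T @ s
    oner = u.T @ np.ones(len(slc))

    o_w = oner * w
    one_w_one = float(oner @ o_w)
    y_w = yr * w
    one_wy = float(oner @ y_w)
    sw_one = sr.T @ o_w
    s_wy = sr.T @ y_w
    s_ws = np.einsum("ij,ij->j", sr, sr * w[:, None])
    denom = s_ws - sw_one**2 / one_w_one
    numer = s_wy - sw_one * one_wy / one_w_one
    ypy0 = float(yr @ y_w) - one_wy**2 / one_w_one
    nn = len(slc)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = numer / denom
        ssr = numer * alpha  # explained weighted SS per SNP
        fval = ssr / ((ypy0 - ssr) / (nn - 2))
    fval = np.where(poly & (denom > 1e-12), fval, -np.inf)
    best = int(np.lexsort((gsub.snp_map["bp"].to_numpy(), -fval))[0])
    return {
        "snp_id": gsub.snp_map["snp_id"].iloc[best],
        "chrom": int(gsub.snp_map["chrom"].iloc[best]),
        "bp": int(gsub.snp_map["bp"].iloc[best]),
        "f_value": float(fval[best]),
        "effect": float(alpha[best]),
    }


def _reml_ratio(y, d, u) -> float:
    """One-component REML variance ratio (animal/pedigree vs residual)."""
    from scipy.optimize import minimize_scalar

    yr = u.T @ y
    xr = u.T @ np.ones((len(y), 1))
    n, p = len(yr), 1

    def neg2(logg):
        g = np.exp(logg)
        w = g * d + 1.0
        xw = xr / w[:, None]
        xtx = xr.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ yr)
        ypy = yr @ (yr / w) - (xw.T @ yr).T @ beta
        if ypy <= 0:
            return np.inf
        return (n - p) * np.log(float(ypy) / (n - p)) + np.sum(np.log(w)) + np.linalg.slogdet(xtx)[1]

    res = minimize_scalar(neg2, bounds=(-12, 6), method="bounded")
    return float(np.exp(res.x))


def multi_lgebv_calls(
    lgms: dict,
    wp: WindowPca,
    adj,
    geno: GenotypeMatrix,
    ped: Pedigree,
    k: int = 120,
) -> QtlCallSet:
    """Full multi-LGEBV procedure: top-k windows, S_LC, best SNP each."""
    top = select_top_windows(wp, k)
    traits = wp.traits
    animals = lgms[traits[0]].animals
    rows = []
    for rec in top.itertuples(index=False):
        slc = pseudo_trait_slc(lgms, wp, int(rec.window_index), adj)
        best = best_snp_in_window(
            slc, animals, geno, ped, int(rec.chrom), int(rec.start), int(rec.end)
        )
        if best is None:
            continue
        best["statistic"] = rec.lambda1
        best["pc1_prop"] = rec.pc1_prop
        best["window_id"] = rec.window_id
        contrib = tuple(
            tr for tr, wgt in zip(traits, wp.pc1_vec[int(rec.window_index)])
            if abs(wgt) > 1.0 / np.sqrt(len(traits)) / 2
        )
        best["traits"] = contrib
        rows.append(best)
    cols = ["snp_id", "chrom", "bp", "statistic", "f_value", "pc1_prop", "window_id", "traits"]
    tab = pd.DataFrame(rows, columns=cols + ["effect"]) if rows else pd.DataFrame(columns=cols)
    return QtlCallSet("multi-LGEBV", tab)


# ----------------------------------------------------- comparison & lookup


def compare_methods(calls: list, proximity_bp: int = 0) -> dict:
    """Venn cells of the call sets (exact SNP identity by default).

    With ``proximity_bp`` > 0, calls within that distance on the same
    chromosome are merged into one region before counting membership.
    """
    names = [c.method for c in calls]
    if proximity_bp <= 0:
        sets = {c.method: c.snp_ids() for c in calls}
    else:
        merged = pd.concat(
            [c.table.assign(_m=c.method)[["snp_id", "chrom", "bp", "_m"]] for c in calls]
        ).sort_values(["chrom", "bp"])
        region = (
            (merged["chrom"].diff() != 0)
            | (merged["bp"].diff() > proximity_bp)
        ).cumsum()
        merged["_region"] = region
        sets = {
            nm: set(merged.loc[merged["_m"] == nm, "_region"]) for nm in names
        }
    universe = set().union(*sets.values())
    cells = {}
    for key in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if key >> i & 1]
        cell = set(universe)
        for nm in names:
            cell = cell & sets[nm] if nm in members else cell - sets[nm]
        cells["&".join(members)] = len(cell)
    return {"cells": cells, "union": len(universe), "per_method": {n: len(sets[n]) for n in names}}


def snp_effect_correlation(gwas_tables: dict, snp_ids: list) -> pd.DataFrame:
    """Pearson correlation of SNP effect vectors across traits."""
    traits = list(gwas_tables.keys())
    if len(traits) < 3:
        raise ConfigError("need at least 3 traits")
    eff = pd.DataFrame(
        {
            tr: gwas_tables[tr].set_index("snp_id").loc[snp_ids, "effect"]
            for tr in traits
        }
    )
    zero = eff.std(axis=1, ddof=0) == 0
    if zero.any():
        log.warning("zero-variance effect vectors flagged: %s", list(eff.index[zero]))
    corr = eff.T.corr()
    corr.index.name = corr.columns.name = "snp_id"
    return corr


def candidate_genes(
    calls: QtlCallSet, annotation: pd.DataFrame, flank_bp: int = 50_000
) -> pd.DataFrame:
    """Genes overlapping [snp - flank, snp + flank] per call (closed bounds,
    1-based inclusive gene spans); the nearest by edge distance is primary.
    """
    ann = annotation.copy()
    bad = ann["start"] > ann["end"]
    if bad.any():
        log.warning("rejecting %d malformed gene intervals", int(bad.sum()))
        ann = ann[~bad]
    rows = []
    for call in calls.table.itertuples(index=False):
        lo, hi = call.bp - flank_bp, call.bp + flank_bp
        hit = ann[
            (ann["chrom"] == call.chrom) & (ann["end"] >= lo) & (ann["start"] <= hi)
        ].copy()
        if len(hit) == 0:
            continue
        inside = (hit["start"] <= call.bp) & (call.bp <= hit["end"])
        dist = np.where(
            inside, 0, np.minimum(abs(hit["start"] - call.bp), abs(hit["end"] - call.bp))
        )
        hit["distance"] = dist
        hit = hit.sort_values(["distance", "start"])
        for r, rec in enumerate(hit.itertuples(index=False)):
            rows.append(
                {
                    "snp_id": call.snp_id,
                    "chrom": call.chrom,
                    "bp": call.bp,
                    "gene": rec.gene,
                    "gene_start": rec.start,
                    "gene_end": rec.end,
                    "distance": rec.distance,
                    "primary": r == 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "bp", "gene", "gene_start", "gene_end", "distance", "primary"],
    )
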