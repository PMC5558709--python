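"""Reproducible end-to-end experiments on the synthetic population.

Each function runs one self-contained study at desk scale and returns the
summary quantities; the acceptance script and the acceptance tests both
call these, so the numbers in results files always come from a fresh
computation.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from . import bayesr as br
from . import gprediction as gp
from . import indexval as iv
from . import multitrait as mt
from . import phenomodel as pm
from . import simpop as sp

__all__ = [
    "fdr_worked_examples",
    "oracle_suite",
    "null_calibration",
    "desk_recovery",
    "strong_qtl_detection",
]


def fdr_worked_examples() -> dict:
    """FDR estimates from printed significance counts.

    Inputs are the published worked examples: per-trait genome scans at
    P<1e-5 and P<5e-7 over 510,174 SNPs, the multi-trait genome scan, and
    the three validation rows (P<0.05 over the tested SNP lists).
    """
    t_genome = 510_174
    return {
        "fdr_single_trait_ygfw_1e5_pct": pm.fdr(1e-5, 69, t_genome),
        "fdr_single_trait_agfw_1e5_pct": pm.fdr(1e-5, 304, t_genome),
        "fdr_multi_gwas_1e5_pct": pm.fdr(1e-5, 563, t_genome),
        "fdr_multi_gwas_5e7_pct": pm.fdr(5e-7, 263, t_genome),
        "fdr_validation_multi_gwas_pct": pm.fdr(0.05, 16, 105),
        "fdr_validation_multi_pp_pct": pm.fdr(0.05, 19, 77),
        "fdr_validation_multi_lgebv_pct": pm.fdr(0.05, 15, 120),
    }


# ----------------------------------------------------------------- oracles


def oracle_suite(seed: int) -> dict:
    """Max absolute error of each core statistic against brute force on
    small fixtures (A-matrix, GRM, GBLUP vs SNP-BLUP, chi-square,
    window eigen-analysis, S_LC, linear index, missing-trait imputation)."""
    rng = np.random.default_rng(seed)
    out = {}

    # pedigree A vs the recursive definition
    cfg = sp.SimConfig(n_sires=3, n_dams_per_sire=2, n_offspring_per_dam=3,
                       seed=seed)
    ped = sp.simulate_pedigree(cfg)
    a = gp.build_a_matrix(ped)
    sire, dam = ped.parents_idx()

    def a_rec(i, j, memo={}):
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        if i == j:
            s, d = sire[i], dam[i]
            v = 1.0 + (0.5 * a_rec(s, d) if s >= 0 and d >= 0 else 0.0)
        else:
            s, d = sire[j], dam[j]
            v = (0.5 * a_rec(i, s) if s >= 0 else 0.0) + (
                0.5 * a_rec(i, d) if d >= 0 else 0.0
            )
        memo[(i, j)] = v
        return v

    n = len(ped)
    oracle = np.asarray([[a_rec(i, j) for j in range(n)] for i in range(n)])
    out["a_matrix_max_err"] = float(np.abs(a - oracle).max())

    # GRM vs the direct formula
    p = rng.uniform(0.1, 0.5, 60)
    dos = rng.binomial(2, p, size=(30, 60)).astype(float)
    geno = _geno(dos)
    grm = gp.build_grm(geno)
    pf = dos.mean(axis=0) / 2
    keep = np.minimum(pf, 1 - pf) > 0.005
    z = dos[:, keep] - 2 * pf[keep]
    out["grm_max_err"] = float(
        np.abs(grm.matrix - z @ z.T / (2 * (pf[keep] * (1 - pf[keep])).sum())).max()
    )

    # GBLUP vs SNP-BLUP
    y = z @ rng.standard_normal(keep.sum()) * 0.1 + rng.standard_normal(30)
    train = np.arange(20)
    s2g, s2e = 0.5, 0.5
    gebv = gp.gblup_solve(grm.matrix, y, train, s2g, s2e)
    c = 2 * (pf[keep] * (1 - pf[keep])).sum()
    lam = s2e / (s2g / c)
    zt = z[train]
    vi = np.linalg.inv(zt @ zt.T + lam * np.eye(len(train)))
    one = np.ones(len(train))
    mu = (one @ vi @ y[train]) / (one @ vi @ one)
    out["gblup_snp_blup_max_err"] = float(
        np.abs(gebv - z @ (zt.T @ vi @ (y[train] - mu))).max()
    )

    # multi-trait chi-square vs explicit quadratic form
    k = 5
    v = 0.5 * np.eye(k) + 0.5
    rows = rng.multivariate_normal(np.zeros(k), v, size=200)
    tmat = pd.DataFrame(rows, columns=[f"t{i}" for i in range(k)])
    chi = mt.multi_gwas_chi2(tmat, v)["chi2"].to_numpy()
    vi = np.linalg.inv(v)
    oracle = np.asarray([r @ vi @ r for r in rows])
    out["chi2_max_err"] = float(np.abs(chi - oracle).max())

    # window eigen-analysis vs dense eigendecomposition
    lgms = {
        f"t{j}": br.LocalGebvMatrix(
            f"t{j}", rng.standard_normal((40, 5)), np.arange(1, 41),
            pd.DataFrame({"chrom": 1, "start": np.arange(5) * 250_000,
                          "end": (np.arange(5) + 1) * 250_000,
                          "window_id": [str(i) for i in range(5)]}),
        )
        for j in range(4)
    }
    sds = pd.Series({f"t{j}": 1.0 for j in range(4)})
    wp = mt.window_cov_pca(lgms, sds)
    err = 0.0
    for w in range(5):
        yw = np.column_stack([lgms[f"t{j}"].values[:, w] for j in range(4)])
        lam_o = np.sort(np.linalg.eigvalsh(np.cov(yw.T, ddof=1)))[::-1]
        err = max(err, float(np.abs(wp.eigvals[w] - lam_o).max()))
    out["window_eigen_max_err"] = err

    # S_LC vs explicit dot product
    slc = mt.pseudo_trait_slc(lgms, wp, 2)
    yw = np.column_stack([lgms[f"t{j}"].values[:, 2] for j in range(4)])
    out["slc_max_err"] = float(np.abs(slc - yw @ wp.pc1_vec[2]).max())

    # linear index vs explicit matrix product
    amat = rng.standard_normal((4, 4))
    cc = iv.EffectCovariance(amat @ amat.T + np.eye(4), [f"t{j}" for j in range(4)], 0.0)
    b = rng.standard_normal(4)
    comp = pd.DataFrame(rng.standard_normal((25, 4)), columns=cc.traits)
    yi = iv.linear_index(b, cc, comp)
    out["linear_index_max_err"] = float(
        np.abs(yi.to_numpy() - comp.to_numpy() @ np.linalg.inv(cc.cov) @ b).max()
    )

    # imputation vs the bivariate conditional expectation
    rho, s1, s2 = 0.6, 1.0, 2.0
    cov = np.asarray([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    yv = rng.multivariate_normal([0, 0], cov, size=50)
    values = pd.DataFrame(yv, columns=["a", "b"])
    values.iloc[:20, 1] = np.nan
    u = iv.PhenoCovariance(cov, ["a", "b"], 0.0)
    adj = pm.AdjustedPhenotypes(values, values.std(),
                                {t: pm.VarComp(0.3, 0, 0, 0.7, 0.3) for t in "ab"})
    comp = iv.impute_missing_phenotypes(adj, u)
    out["imputation_max_err"] = float(
        np.abs(comp.iloc[:20, 1].to_numpy() - rho * (s2 / s1) * yv[:20, 0]).max()
    )
    return out


def _geno(dos):
    from .containers import GenotypeMatrix

    m = dos.shape[1]
    return GenotypeMatrix(
        dos, np.arange(1, dos.shape[0] + 1),
        pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)], "chrom": 1,
                      "bp": (np.arange(m) + 1) * 100_000}),
    )


# ------------------------------------------------------------------- nulls


def null_calibration(seed: int) -> dict:
    """Behavior with no QTL anywhere.

    multi-GWAS chi-square under MVN(0,V) draws (mean ~ df, uniform P), and
    the linear-index validation on a simulation whose traits are purely
    polygenic + noise: direction agreement ~50%, significant fraction ~5%.
    """
    rng = np.random.default_rng(seed)
    k, n_draws = 6, 10_000
    v = 0.4 * np.eye(k) + 0.6
    rows = rng.multivariate_normal(np.zeros(k), v, size=n_draws)
    tab = mt.multi_gwas_chi2(
        pd.DataFrame(rows, columns=[f"t{i}" for i in range(k)]), v
    )
    from scipy import stats

    out = {
        "null_chi2_mean": float(tab["chi2"].mean()),
        "null_chi2_df": k,
        "null_p_ks_pvalue": float(stats.kstest(tab["p"], "uniform").pvalue),
    }

    # no-QTL simulation: validate random SNPs through linear indices
    cfg = sp.SimConfig(
        n_sires=40, n_dams_per_sire=7, n_offspring_per_dam=4,
        n_chromosomes=2, chrom_length_bp=25_000_000, n_snps=2000,
        n_qtl=2, n_traits=4, h2_per_trait=[0.3, 0.4, 0.5, 0.6],
        qtl_var_frac=0.0, seed=seed + 1,
    )
    ped, geno, pheno, _ = sp.simulate_all(cfg)
    spec = pm.ModelSpec()
    vc = {t: pm.estimate_variance_components(pheno, ped, spec, t)
          for t in cfg.trait_names()}
    adj = pm.adjust_phenotypes(pheno, ped, spec, vc)
    folds = gp.make_cv_folds(ped, seed=seed)
    val_animals = folds.validation_animals(1)
    train_mask = ~adj.values.index.isin(val_animals)

    adj_train = copy.copy(adj)
    adj_train.values = adj.values[train_mask]
    gwas_train = {t: pm.single_trait_gwas(geno, adj_train, ped, t)
                  for t in cfg.trait_names()}
    c = iv.EffectCovariance.from_gwas(gwas_train)
    adj_val = copy.copy(adj)
    adj_val.values = adj.values[~train_mask]
    completed = iv.impute_missing_phenotypes(adj_val)

    # "top" SNPs are arbitrary under the null: an evenly spaced sample
    pick = geno.snp_map.iloc[:: max(1, len(geno.snp_map) // 150)].copy()
    pick["statistic"] = 1.0
    pick["traits"] = [()] * len(pick)
    res = iv.validate_index_snps(pick, gwas_train, c, completed, geno, ped)
    out["null_validation_pct_same_direction"] = res["summary"]["pct_same_direction_all"]
    out["null_validation_significant_fraction"] = (
        res["summary"]["n_significant"] / res["summary"]["n_tested"]
    )
    return out


# --------------------------------------------------------- desk-scale study


def strong_qtl_detection(seed: int, n_iter: int = 10_000) -> dict:
    """One QTL explaining ~30% of phenotypic variance (n=500, m=1000):
    maximum BayesR pp_nonzero within 50 kb of the QTL."""
    cfg = sp.SimConfig(
        n_sires=25, n_dams_per_sire=5, n_offspring_per_dam=4,
        n_chromosomes=1, chrom_length_bp=25_000_000, n_snps=1000,
        n_qtl=1, n_traits=1, h2_per_trait=[0.45],
        qtl_var_frac=0.67, private_qtl_frac=0.0, seed=seed,
    )
    ped, geno, pheno, truth = sp.simulate_all(cfg)
    spec = pm.ModelSpec()
    vc = {"trait_1": pm.estimate_variance_components(pheno, ped, spec, "trait_1")}
    adj = pm.adjust_phenotypes(pheno, ped, spec, vc)
    bcfg = br.BayesRConfig(n_iter=n_iter, burn_in=n_iter // 3, n_chains=2,
                           seed=seed)
    fit = br.bayesr_fit(geno, adj, ped, bcfg, "trait_1")
    near = (
        np.abs(geno.snp_map["bp"].to_numpy() - truth.qtl_bp[0]) <= 50_000
    )
    p = geno.allele_freq()
    j = list(geno.snp_map["snp_id"]).index(truth.qtl_snp_ids[0])
    return {
        "qtl_variance_fraction": float(
            2 * p[j] * (1 - p[j]) * truth.qtl_effects[0, 0] ** 2
        ),
        "max_pp_within_50kb": float(fit.pp_nonzero[near].max()),
    }


def desk_recovery(seed: int, bayesr_iters: int = 1500, top_k: int = 20) -> dict:
    """The default desk-scale study: 2,000 animals, 6,000 SNPs, 20 QTL,
    8 traits.  Measures h2 recovery, GEBV accuracy (estimated vs true),
    multi-LGEBV sensitivity for pleiotropic QTL, and the realized genetic
    correlations of the generator."""
    cfg = sp.SimConfig(seed=seed)
    ped, geno, pheno, truth = sp.simulate_all(cfg)
    traits = cfg.trait_names()
    spec = pm.ModelSpec()
    vc = {t: pm.estimate_variance_components(pheno, ped, spec, t) for t in traits}
    adj = pm.adjust_phenotypes(pheno, ped, spec, vc)

    out = {}
    h2_err = [abs(vc[t].h2 - cfg.h2_per_trait[i]) for i, t in enumerate(traits)]
    out["h2_mean_abs_error"] = float(np.mean(h2_err))

    off = ped.offspring()["animal"].to_numpy()
    tbv = truth.true_breeding_values.loc[off].to_numpy()
    corr = np.corrcoef(tbv.T)
    iu = np.triu_indices(cfg.n_traits, k=1)
    out["genetic_corr_mean_abs_dev"] = float(
        np.abs(corr[iu] - cfg.genetic_corr[iu]).mean()
    )

    # ---- GBLUP accuracy, estimated vs truth-based
    geno_off = geno.subset(off)
    grm = gp.build_grm(geno_off)
    folds = gp.make_cv_folds(ped, seed=seed)
    acc_est, acc_true = [], []
    for i, t in enumerate(traits):
        gt = gp.gblup_fit(grm, adj, folds, t)
        est = gp.gebv_accuracy(gt, adj, folds, t, vc[t].h2)["mean"]
        merged = gt.table.merge(
            truth.true_breeding_values[t].rename("tbv"),
            left_on="animal", right_index=True,
        )
        r_true = [
            np.corrcoef(sub["gebv"], sub["tbv"])[0, 1]
            for f, sub in merged.groupby("fold")
            if sub["gebv"].std() > 0
        ]
        acc_est.append(est)
        acc_true.append(float(np.mean(r_true)))
    out["gblup_accuracy_mean"] = float(np.mean(acc_est))
    out["gblup_accuracy_true_mean"] = float(np.mean(acc_true))
    out["gblup_accuracy_abs_gap"] = float(abs(np.mean(acc_est) - np.mean(acc_true)))

    # ---- BayesR per trait, local GEBV, multi-LGEBV sensitivity
    bcfg = br.BayesRConfig(
        n_iter=bayesr_iters, burn_in=bayesr_iters // 3, n_chains=1, seed=seed
    )
    fits = {t: br.bayesr_fit(geno_off, adj, ped, bcfg, t) for t in traits}
    lgms = {t: br.local_gebv(fits[t], geno_off) for t in traits}
    wp = mt.window_cov_pca(lgms, adj.pheno_sd)
    top = mt.select_top_windows(wp, k=top_k)
    pleio = truth.pleiotropic()
    hit = 0
    for q in pleio:
        qb = truth.qtl_bp[q] - 1
        near = (
            (top["chrom"] == truth.qtl_chrom[q])
            & (top["start"] - 250_000 <= qb)
            & (qb < top["end"] + 250_000)
        )
        hit += int(near.any())
    out["lgebv_top%d_pleiotropic_sensitivity" % top_k] = hit / len(pleio)
    out["n_pleiotropic_qtl"] = int(len(pleio))
    out["pc1_prop_median_top_windows"] = float(top["pc1_prop"].median())

    # ---- the three call sets and their overlap
    gwas = {t: pm.single_trait_gwas(geno_off, adj, ped, t) for t in traits}
    tmat, v, extra = mt.build_tmatrix_v(gwas)
    chi2 = mt.multi_gwas_chi2(tmat, v)
    calls_gwas = mt.top_snp_per_mb(chi2, extra["meta"], threshold=5e-7)
    calls_pp = mt.multi_pp(fits, extra["meta"])
    calls_lg = mt.multi_lgebv_calls(lgms, wp, adj, geno_off, ped, k=top_k)
    venn = mt.compare_methods([calls_gwas, calls_pp, calls_lg])
    out["n_multi_gwas_calls"] = len(calls_gwas.table)
    out["n_multi_pp_calls"] = len(calls_pp.table)
    out["n_multi_lgebv_calls"] = len(calls_lg.table)
    out["n_union_calls"] = venn["union"]

    rep = sp.truth_report(
        truth,
        {"multi-GWAS": calls_gwas, "multi-PP": calls_pp, "multi-LGEBV": calls_lg},
        window_bp=500_000,
    )
    for m, r in rep.items():
        out[f"sensitivity_{m}"] = r["sensitivity"]
    return out
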