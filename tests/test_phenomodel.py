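"""Variance components, adjustment, GWAS against a GLS oracle, and the FDR
estimator against the published worked examples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiomap import (
    ModelSpec,
    SimConfig,
    adjust_phenotypes,
    build_a_matrix,
    estimate_variance_components,
    fdr,
    simulate_all,
    single_trait_gwas,
)
from pleiomap.containers import ConfigError

from conftest import toy_genotypes, toy_pedigree


# ------------------------------------------------------------------- REML


def test_h2_recovery_mean_over_seeds():
    """REML h2 for a true-0.5 trait, averaged over seeds, lands in [0.4, 0.6]."""
    est = []
    for seed in (11, 12, 13):
        cfg = SimConfig(
            n_sires=30, n_dams_per_sire=8, n_offspring_per_dam=4,
            n_chromosomes=2, chrom_length_bp=20_000_000, n_snps=1000,
            n_qtl=6, n_traits=2, h2_per_trait=[0.5, 0.5], seed=seed,
        )
        ped, geno, pheno, _ = simulate_all(cfg)
        vc = estimate_variance_components(pheno, ped, ModelSpec(), "trait_1")
        est.append(vc.h2)
    assert 0.4 < np.mean(est) < 0.6


def test_pure_noise_trait_h2_near_zero(small_sim):
    pheno = small_sim["pheno"].copy()
    rng = np.random.default_rng(5)
    pheno["noise"] = rng.standard_normal(len(pheno))
    vc = estimate_variance_components(
        pheno, small_sim["ped"], ModelSpec(), "noise"
    )
    assert vc.h2 < 0.1


def test_h2_scale_invariance(small_sim, small_adjusted):
    pheno = small_sim["pheno"].copy()
    pheno["scaled"] = pheno["trait_3"] * 2.0
    v1 = small_adjusted["vc"]["trait_3"]
    v2 = estimate_variance_components(pheno, small_sim["ped"], ModelSpec(), "scaled")
    assert v2.h2 == pytest.approx(v1.h2, abs=1e-3)
    assert v2.sigma2_e == pytest.approx(4 * v1.sigma2_e, rel=0.01)


def test_varcomp_invariants(small_adjusted):
    for vc in small_adjusted["vc"].values():
        assert vc.sigma2_a >= 0 and vc.sigma2_sf >= 0 and vc.sigma2_e > 0
        assert 0 <= vc.h2 <= 1
        assert vc.h2 == pytest.approx(
            vc.sigma2_a / (vc.sigma2_a + vc.sigma2_sf + vc.sigma2_e)
        )


# -------------------------------------------------------------- adjustment


def test_adjusted_residuals_centered_and_missing_preserved(small_sim, small_adjusted):
    adj = small_adjusted["adj"]
    for t in adj.traits():
        col = adj.values[t]
        assert abs(col.mean()) < 1e-8 * col.std()
    raw = small_sim["pheno"].set_index("animal")[adj.traits()]
    assert (adj.values.isna() == raw.isna()).all().all()


def test_adjustment_removes_flock_effect(small_sim, small_adjusted):
    """Simulated ~0.5-SD flock effects leave no detectable group difference:
    every post-adjustment flock mean is within t-test noise of zero, while
    the raw phenotypes show clearly separated flocks."""
    adj = small_adjusted["adj"]
    pheno = small_sim["pheno"].set_index("animal")
    flock = pheno["flock"]
    raw_t_max, adj_t_max = 0.0, 0.0
    for t in adj.traits():
        for df, acc in ((pheno[t], "raw"), (adj.values[t], "adj")):
            g = df.groupby(flock)
            tstat = (
                (g.mean() - df.mean()).abs() / (g.std() / np.sqrt(g.count()))
            ).max()
            if acc == "raw":
                raw_t_max = max(raw_t_max, tstat)
            else:
                adj_t_max = max(adj_t_max, tstat)
    assert adj_t_max < 4.0
    assert raw_t_max > 2 * adj_t_max


def test_no_terms_spec_gives_centered_phenotypes(small_sim):
    spec = ModelSpec(fixed_terms=(), breed_random=False,
                     sire_flock_random=False, polygenic=False)
    pheno = small_sim["pheno"]
    vc = {"trait_1": estimate_variance_components(pheno, small_sim["ped"], spec, "trait_1")}
    adj = adjust_phenotypes(pheno, small_sim["ped"], spec, vc)
    raw = pheno.set_index("animal")["trait_1"].dropna()
    expected = raw - raw.mean()
    got = adj.values["trait_1"].dropna()
    assert np.allclose(got.to_numpy(), expected.to_numpy(), atol=1e-10)


def test_adjustment_near_idempotent(small_sim, small_adjusted):
    """Re-adjusting already-adjusted data moves residuals only marginally."""
    adj = small_adjusted["adj"]
    pheno2 = small_sim["pheno"][["animal", "sire", "dam", "flock", "sex", "age", "Q"]].copy()
    t = "trait_3"
    pheno2[t] = adj.values[t].reindex(pheno2["animal"]).to_numpy()
    spec = small_adjusted["spec"]
    vc2 = {t: estimate_variance_components(pheno2, small_sim["ped"], spec, t)}
    adj2 = adjust_phenotypes(pheno2, small_sim["ped"], spec, vc2)
    delta = (adj2.values[t] - adj.values[t]).dropna()
    assert delta.abs().max() < 0.05 * adj.pheno_sd[t]


# ------------------------------------------------------------------- GWAS


def _gls_oracle(y, s, a_sub, s2a, s2e):
    """Explicit generalized least squares per SNP on a small fixture."""
    n = len(y)
    v = s2a * a_sub + s2e * np.eye(n)
    vi = np.linalg.inv(v)
    out = []
    for j in range(s.shape[1]):
        x = np.column_stack([np.ones(n), s[:, j]])
        xtvx = x.T @ vi @ x
        beta = np.linalg.solve(xtvx, x.T @ vi @ y)
        se = np.sqrt(np.linalg.inv(xtvx)[1, 1])
        out.append((beta[1], se, beta[1] / se))
    return np.asarray(out)


def test_gwas_matches_gls_oracle():
    ped = toy_pedigree(n_off=23, seed=3)
    n = len(ped)
    geno = toy_genotypes(n, n_snps=15, seed=4, animals=ped.animals)
    rng = np.random.default_rng(8)
    a_full = build_a_matrix(ped)
    y = rng.multivariate_normal(np.zeros(n), 0.5 * a_full + 0.5 * np.eye(n))
    off = ped.offspring()["animal"].to_numpy()

    from pleiomap.phenomodel import AdjustedPhenotypes, VarComp

    values = pd.DataFrame({"t": pd.Series(y, index=ped.animals)}).loc[off]
    vc = VarComp(0.5, 0.0, 0.0, 0.5, 0.5)
    adj = AdjustedPhenotypes(values, pd.Series({"t": 1.0}), {"t": vc})
    tab = single_trait_gwas(geno, adj, ped, "t")

    rows = ped.rows_of(off)
    a_sub = a_full[np.ix_(rows, rows)]
    gsub = geno.subset(off)
    oracle = _gls_oracle(values["t"].to_numpy(), gsub.dosages, a_sub, 0.5, 0.5)
    ok = tab["flag"] == ""
    assert np.allclose(tab.loc[ok, "effect"], oracle[ok, 0], atol=1e-8)
    assert np.allclose(tab.loc[ok, "t"], oracle[ok, 2], atol=1e-8)


def test_gwas_null_type_one_error(small_sim, small_adjusted):
    """Permuted phenotype: P<0.01 fraction within its binomial band."""
    import copy

    adj = copy.copy(small_adjusted["adj"])
    vals = adj.values.copy()
    rng = np.random.default_rng(17)
    obs = vals["trait_2"].dropna()
    vals.loc[obs.index, "trait_2"] = rng.permutation(obs.to_numpy())
    adj.values = vals
    tab = single_trait_gwas(small_sim["geno"], adj, small_sim["ped"], "trait_2")
    frac = (tab["p"].dropna() < 0.01).mean()
    assert 0.003 < frac < 0.022


def test_gwas_top_hit_is_the_planted_qtl(small_sim, small_adjusted):
    """The strongest QTL of a trait attains the genome-wide minimum P."""
    cfg, truth = small_sim["cfg"], small_sim["truth"]
    geno = small_sim["geno"]
    het = 2 * geno.allele_freq() * (1 - geno.allele_freq())
    sid = list(geno.snp_map["snp_id"])
    t_idx = 3
    best_q, best_v = None, 0
    for i in range(cfg.n_qtl):
        v = het[sid.index(truth.qtl_snp_ids[i])] * truth.qtl_effects[i, t_idx] ** 2
        if v > best_v:
            best_q, best_v = i, v
    tab = single_trait_gwas(geno, small_adjusted["adj"], small_sim["ped"], "trait_4")
    top = tab.loc[tab["p"].idxmin()]
    qc, qb = truth.qtl_chrom[best_q], truth.qtl_bp[best_q]
    assert top["chrom"] == qc and abs(top["bp"] - qb) < 250_000


def test_gwas_monomorphic_flagged(small_sim, small_adjusted):
    geno = small_sim["geno"].subset_snps(np.arange(20))
    geno.dosages[:, 0] = 1.0  # force monomorphic
    tab = single_trait_gwas(geno, small_adjusted["adj"], small_sim["ped"], "trait_1")
    assert tab.loc[0, "flag"] == "monomorphic"
    assert np.isnan(tab.loc[0, "p"])


# -------------------------------------------------------------------- FDR

TABLE2_T = 510_174
# (threshold, n_significant, printed FDR%) from the single-trait results
TABLE2_CELLS = [
    (1e-5, 69, 7.4), (5e-7, 7, 3.6),      # YGFW
    (1e-5, 304, 1.7), (5e-7, 157, 0.2),   # AGFW
    (1e-5, 122, 4.2), (5e-7, 75, 0.3),    # YYLD
    (1e-5, 113, 4.5), (5e-7, 59, 0.4),    # AYLD
    (1e-5, 68, 7.5), (5e-7, 26, 1.0),     # YSL
    (1e-5, 39, 13.1), (5e-7, 3, 8.5),     # ASL
    (1e-5, 56, 9.1), (5e-7, 31, 0.8),     # YSS
    (5e-7, 15, 1.7),                      # ASS
    (1e-5, 202, 2.5), (5e-7, 36, 0.7),    # YFD
    (1e-5, 295, 1.7), (5e-7, 69, 0.4),    # AFD
    (1e-5, 97, 5.3), (5e-7, 31, 0.8),     # YFDCV
    (1e-5, 109, 4.7), (5e-7, 47, 0.5),    # AFDCV
    (1e-5, 105, 4.9), (5e-7, 22, 1.2),    # YCURV
    (1e-5, 103, 5.0), (5e-7, 8, 3.2),     # ACURV
    (1e-5, 50, 10.2), (5e-7, 23, 1.1),    # YBRWR
    (1e-5, 15, 34.0), (5e-7, 2, 12.8),    # ABRWR
    (5e-7, 2, 12.8),                      # YBCOV
    (1e-5, 6, 85.0), (5e-7, 1, 25.5),     # ABCOV
    (1e-5, 19, 26.9), (5e-7, 1, 25.5),    # YCCOV
    (1e-5, 45, 11.3), (5e-7, 19, 1.3),    # ACCOV
    (1e-5, 11, 46.4),                     # YDAG
    (1e-5, 41, 12.4), (5e-7, 2, 12.8),    # YSSTRC
    (1e-5, 8, 63.8), (5e-7, 2, 12.8),     # AWEATH
    (1e-5, 46, 11.1), (5e-7, 15, 1.7),    # YCHAR
    (1e-5, 28, 18.2), (5e-7, 5, 5.1),     # ACHAR
    (1e-5, 22, 23.2), (5e-7, 1, 25.5),    # YFLROT
    (1e-5, 75, 6.8), (5e-7, 12, 2.1),     # AFLROT
    (1e-5, 15, 34.0),                     # YDUST
    (1e-5, 10, 51.0), (5e-7, 1, 25.5),    # ADUST
    (1e-5, 25, 20.4), (5e-7, 2, 12.8),    # YGCOL
    (1e-5, 21, 24.3),                     # AGCOL
    (1e-5, 28, 18.2), (5e-7, 5, 5.1),     # YCOLZ
    (1e-5, 25, 20.4),                     # ACOLZ
    (1e-5, 7, 72.9), (5e-7, 1, 25.5),     # YCOLYZ
    (1e-5, 22, 23.2), (5e-7, 3, 8.5),     # YCOLY
    (1e-5, 20, 25.5),                     # ACOLY
    (1e-5, 24, 21.3), (5e-7, 4, 6.4),     # YCOLX
    (1e-5, 23, 22.2),                     # ACOLX
    (1e-5, 9, 56.7),                      # YSKINQ
    (1e-5, 7, 72.9),                      # ASKINQ
]


@pytest.mark.parametrize("thr,n_sig,expected", TABLE2_CELLS)
def test_fdr_reproduces_single_trait_table(thr, n_sig, expected):
    assert round(fdr(thr, n_sig, TABLE2_T), 1) == expected


@pytest.mark.parametrize(
    "thr,n_sig,n_tests,expected",
    [
        (0.05, 16, 105, 29.3),  # multi-GWAS validation row
        (0.05, 19, 77, 16.1),   # multi-PP validation row
        (0.05, 15, 120, 36.8),  # multi-LGEBV validation row
        (1e-5, 563, 510_174, 0.9),  # multi-GWAS genome scan
        (5e-7, 263, 510_174, 0.1),
    ],
)
def test_fdr_reproduces_validation_rows(thr, n_sig, n_tests, expected):
    assert round(fdr(thr, n_sig, n_tests), 1) == expected


def test_fdr_unavailable_cases():
    assert fdr(1e-5, 5, 510_174) is None  # > 100%
    assert fdr(0.05, 0, 1000) is None  # nothing significant
    # A/T exactly P gives 100%
    assert fdr(0.05, 50, 1000) == pytest.approx(100.0)


def test_fdr_input_validation():
    with pytest.raises(ConfigError):
        fdr(0.05, 10, 5)
    with pytest.raises(ConfigError):
        fdr(0.0, 1, 10)


@settings(max_examples=50, deadline=None)
@given(
    thr=st.floats(1e-8, 0.2),
    n_sig=st.integers(1, 1000),
    n_tests=st.integers(1000, 10**6),
)
def test_fdr_monotone_in_count(thr, n_sig, n_tests):
    """More significant SNPs at the same threshold can only lower the FDR."""
    lo = fdr(thr, n_sig, n_tests)
    hi = fdr(thr, min(n_sig + 10, n_tests), n_tests)
    if lo is not None and hi is not None:
        assert hi <= lo + 1e-12
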