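"""Multi-trait statistics: chi-square combination, window eigen-analysis,
pseudo-trait mapping, overlap algebra and candidate-gene lookup."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiomap.containers import ConfigError
from pleiomap.multitrait import (
    QtlCallSet,
    build_tmatrix_v,
    candidate_genes,
    compare_methods,
    multi_gwas_chi2,
    multi_pp,
    pseudo_trait_slc,
    select_top_windows,
    snp_effect_correlation,
    top_snp_per_mb,
    window_cov_pca,
)
from pleiomap.bayesr import LocalGebvMatrix


def _gwas_tables(tvals, snp_meta, effects=None):
    out = {}
    for k, tr in enumerate(tvals.columns):
        out[tr] = pd.DataFrame(
            {
                "snp_id": snp_meta["snp_id"],
                "chrom": snp_meta["chrom"],
                "bp": snp_meta["bp"],
                "t": tvals[tr].to_numpy(),
                "effect": (
                    effects[tr].to_numpy() if effects is not None
                    else tvals[tr].to_numpy() * 0.01
                ),
            }
        )
    return out


@pytest.fixture()
def meta100():
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(100)],
            "chrom": np.repeat([1, 2], 50),
            "bp": np.tile(np.arange(1, 51) * 400_000, 2),
        }
    )


def test_v_matrix_matches_brute_force(meta100):
    rng = np.random.default_rng(0)
    tvals = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
    _, v, extra = build_tmatrix_v(_gwas_tables(tvals, meta100))
    oracle = np.corrcoef(tvals.to_numpy().T)
    assert np.allclose(v, oracle, atol=1e-12)
    assert extra["info"]["eps"] == 0.0


def test_v_matrix_shrinks_duplicated_trait(meta100):
    rng = np.random.default_rng(1)
    tvals = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
    tvals["d"] = tvals["c"]  # perfectly collinear
    _, v, extra = build_tmatrix_v(_gwas_tables(tvals, meta100))
    assert extra["info"]["eps"] > 0
    assert np.linalg.eigvalsh(v).min() >= 1e-6 - 1e-12


def test_v_matrix_independent_traits_small_offdiag():
    rng = np.random.default_rng(2)
    n = 6000
    meta = pd.DataFrame(
        {"snp_id": [f"s{i}" for i in range(n)], "chrom": 1,
         "bp": np.arange(1, n + 1) * 1000}
    )
    tvals = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
    _, v, _ = build_tmatrix_v(_gwas_tables(tvals, meta))
    off = v[np.triu_indices(4, k=1)]
    assert np.abs(off).max() < 0.1


def test_chi2_known_values(meta100):
    tvals = pd.DataFrame({"a": np.full(100, 2.0)})
    tab = multi_gwas_chi2(tvals, np.eye(1))
    assert np.allclose(tab["chi2"], 4.0)
    t2 = pd.DataFrame({"a": [3.0], "b": [4.0]})
    tab2 = multi_gwas_chi2(t2, np.eye(2))
    assert tab2["chi2"][0] == pytest.approx(25.0)


def test_chi2_null_calibration():
    """MVN(0,V) t-rows give mean chi2 ~ df and uniform P."""
    rng = np.random.default_rng(3)
    k = 5
    v = 0.5 * np.eye(k) + 0.5
    rows = rng.multivariate_normal(np.zeros(k), v, size=10_000)
    tvals = pd.DataFrame(rows, columns=[f"t{i}" for i in range(k)])
    tab = multi_gwas_chi2(tvals, v)
    mean = tab["chi2"].mean()
    se = np.sqrt(2 * k / 10_000)
    assert abs(mean - k) < 3 * se
    ks_p = stats.kstest(tab["p"], "uniform").pvalue
    assert ks_p > 0.01


def test_chi2_requires_positive_definite_v():
    v = np.asarray([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ConfigError):
        multi_gwas_chi2(pd.DataFrame({"a": [1.0], "b": [1.0]}), v)


def test_top_snp_per_mb_rules(meta100):
    rng = np.random.default_rng(4)
    p = pd.Series(rng.uniform(1e-9, 1.0, 100))
    p.iloc[0], p.iloc[1] = 1e-9, 1e-12  # same 1-Mb tile (bp 400k, 800k)
    p.iloc[5] = 1e-10  # bp 2.4 Mb, another tile
    chi2 = pd.DataFrame({"snp_id": meta100["snp_id"],
                         "chi2": 1.0, "p": p.to_numpy(), "flag": ""})
    calls = top_snp_per_mb(chi2, meta100, threshold=5e-7)
    got = set(calls.table["snp_id"])
    assert "s1" in got and "s0" not in got  # lower P wins inside the tile
    assert "s5" in got  # adjacent tile retained
    # brute-force per-tile argmin oracle
    tab = chi2.merge(meta100, on="snp_id")
    tab = tab[tab["p"] < 5e-7]
    tile = (tab["bp"] - 1) // 1_000_000
    oracle = set(
        tab.loc[tab.groupby([tab["chrom"], tile])["p"].idxmin(), "snp_id"]
    )
    assert got == oracle


class _FakeFit:
    def __init__(self, snp_ids, pz):
        self.snp_ids = np.asarray(snp_ids)
        self.class_probs = np.column_stack([pz, 1 - pz, np.zeros_like(pz), np.zeros_like(pz)])


def test_multi_pp_combination_rules(meta100):
    ids = meta100["snp_id"].to_numpy()
    pz_a = np.ones(100)
    pz_b = np.ones(100)
    pz_a[0] = 0.8
    pz_b[0] = 0.8  # combined 1 - 0.64 = 0.36 >= 0.3 -> called
    pz_a[1] = 0.0  # combined 1.0 -> called
    fits = {"a": _FakeFit(ids, pz_a), "b": _FakeFit(ids, pz_b)}
    calls = multi_pp(fits, meta100, threshold=0.3)
    got = dict(zip(calls.table["snp_id"], calls.table["statistic"]))
    assert got["s0"] == pytest.approx(0.36)
    assert got["s1"] == pytest.approx(1.0)
    assert len(got) == 2  # all-zero rows are not called
    traits = dict(zip(calls.table["snp_id"], calls.table["traits"]))
    assert set(traits["s0"]) == {"a", "b"}
    assert set(traits["s1"]) == {"a"}


def _lgm(values, trait, animals=None):
    n, w = values.shape
    windows = pd.DataFrame(
        {"chrom": 1, "start": np.arange(w) * 250_000,
         "end": (np.arange(w) + 1) * 250_000,
         "window_id": [f"1:{i}" for i in range(w)]}
    )
    return LocalGebvMatrix(
        trait, values, animals if animals is not None else np.arange(1, n + 1), windows
    )


def test_window_pca_matches_dense_oracle():
    rng = np.random.default_rng(5)
    vals = {f"t{k}": _lgm(rng.standard_normal((40, 6)), f"t{k}") for k in range(5)}
    sds = pd.Series({f"t{k}": rng.uniform(0.5, 2.0) for k in range(5)})
    wp = window_cov_pca(vals, sds)
    for w in range(6):
        y = np.column_stack(
            [vals[f"t{k}"].values[:, w] / sds[f"t{k}"] for k in range(5)]
        )
        c = np.cov(y.T, ddof=1)
        lam = np.sort(np.linalg.eigvalsh(c))[::-1]
        assert np.allclose(wp.eigvals[w], lam, atol=1e-10)
        assert wp.eigvals[w, 0] >= np.diag(c).max() - 1e-10
        assert wp.eigvals[w].sum() == pytest.approx(np.trace(c), abs=1e-8)
        assert wp.pc1_prop[w] == pytest.approx(lam[0] / lam.sum(), abs=1e-10)


def test_window_pca_single_trait_and_zero_window():
    rng = np.random.default_rng(6)
    vals = rng.standard_normal((30, 3))
    vals[:, 2] = 0.0  # all-zero window
    wp = window_cov_pca({"t": _lgm(vals, "t")}, pd.Series({"t": 2.0}))
    assert wp.eigvals[0, 0] == pytest.approx(np.var(vals[:, 0] / 2.0, ddof=1))
    assert wp.pc1_prop[2] == 0.0
    assert np.allclose(wp.eigvals[2], 0.0)


def test_select_top_windows_ordering():
    rng = np.random.default_rng(7)
    vals = {f"t{k}": _lgm(rng.standard_normal((25, 10)), f"t{k}") for k in range(3)}
    sds = pd.Series({f"t{k}": 1.0 for k in range(3)})
    wp = window_cov_pca(vals, sds)
    top_all = select_top_windows(wp, k=10)
    assert list(top_all["lambda1"]) == sorted(wp.eigvals[:, 0], reverse=True)
    assert len(select_top_windows(wp, k=0)) == 0
    with pytest.raises(ConfigError):
        select_top_windows(wp, k=11)


def test_pseudo_trait_is_dot_product():
    rng = np.random.default_rng(8)
    vals = {f"t{k}": _lgm(rng.standard_normal((20, 4)), f"t{k}") for k in range(3)}
    sds = pd.Series({f"t{k}": 1.0 for k in range(3)})
    wp = window_cov_pca(vals, sds)
    slc = pseudo_trait_slc(vals, wp, 1)
    y = np.column_stack([vals[f"t{k}"].values[:, 1] for k in range(3)])
    assert np.allclose(slc, y @ wp.pc1_vec[1], atol=1e-12)


def test_pseudo_trait_single_trait_identity():
    rng = np.random.default_rng(9)
    vals = {"t": _lgm(rng.standard_normal((20, 2)), "t")}
    wp = window_cov_pca(vals, pd.Series({"t": 1.0}))
    slc = pseudo_trait_slc(vals, wp, 0)
    x = wp.pc1_vec[0, 0]  # +/-1
    assert np.allclose(slc, vals["t"].values[:, 0] * x, atol=1e-12)


def test_compare_methods_identical_and_disjoint():
    def cs(name, ids):
        return QtlCallSet(name, pd.DataFrame(
            {"snp_id": ids, "chrom": 1, "bp": np.arange(len(ids)) + 1,
             "statistic": 1.0, "traits": [()] * len(ids)}))

    same = [cs(n, ["a", "b", "c"]) for n in ("m1", "m2", "m3")]
    res = compare_methods(same)
    assert res["cells"]["m1&m2&m3"] == 3 and res["union"] == 3
    dis = [cs("m1", ["a", "b"]), cs("m2", ["c", "d", "e"]),
           cs("m3", ["f", "g", "h", "i"])]
    res2 = compare_methods(dis)
    assert res2["union"] == 9
    assert res2["cells"]["m1"] == 2
    assert res2["cells"]["m2"] == 3
    assert res2["cells"]["m3"] == 4
    assert res2["cells"]["m1&m2&m3"] == 0


def test_compare_methods_matches_set_algebra():
    rng = np.random.default_rng(10)
    pool = [f"s{i}" for i in range(30)]
    picks = [sorted(rng.choice(pool, rng.integers(5, 15), replace=False))
             for _ in range(3)]

    def cs(name, ids):
        return QtlCallSet(name, pd.DataFrame(
            {"snp_id": ids, "chrom": 1,
             "bp": [int(s[1:]) * 10 + 1 for s in ids],
             "statistic": 1.0, "traits": [()] * len(ids)}))

    res = compare_methods([cs("x", picks[0]), cs("y", picks[1]), cs("z", picks[2])])
    sx, sy, sz = map(set, picks)
    assert res["union"] == len(sx | sy | sz)
    assert res["cells"]["x&y&z"] == len(sx & sy & sz)
    assert res["cells"]["x"] == len(sx - sy - sz)
    assert res["cells"]["x&y"] == len((sx & sy) - sz)


def test_snp_effect_correlation_oracle(meta100):
    rng = np.random.default_rng(11)
    eff = pd.DataFrame(
        rng.standard_normal((100, 5)),
        columns=[f"t{k}" for k in range(5)],
    )
    eff.iloc[1] = -eff.iloc[0]  # negated pair
    tables = _gwas_tables(eff * 10, meta100, effects=eff)
    corr = snp_effect_correlation(tables, ["s0", "s1", "s2"])
    assert corr.loc["s0", "s0"] == pytest.approx(1.0)
    assert corr.loc["s0", "s1"] == pytest.approx(-1.0)
    oracle = np.corrcoef(eff.iloc[[0, 1, 2]].to_numpy())
    assert np.allclose(corr.to_numpy(), oracle, atol=1e-12)


def test_candidate_gene_lookup_paper_interval():
    """A gene ending ~28.6 kb upstream of the SNP falls inside the flank;
    genes beyond 50 kb do not."""
    ann = pd.DataFrame(
        {
            "chrom": [3, 3, 3],
            "start": [58_986_758, 58_900_000, 60_000_000],
            "end": [58_990_671, 58_905_000, 60_001_000],
            "gene": ["near_gene", "far_gene", "way_past"],
        }
    )
    calls = QtlCallSet("m", pd.DataFrame(
        {"snp_id": ["x"], "chrom": [3], "bp": [59_019_274],
         "statistic": [1.0], "traits": [()]}))
    hits = candidate_genes(calls, ann, flank_bp=50_000)
    assert list(hits["gene"]) == ["near_gene"]
    assert hits["primary"].iloc[0]
    assert hits["distance"].iloc[0] == 59_019_274 - 58_990_671


def test_candidate_gene_boundary_rule():
    ann = pd.DataFrame(
        {"chrom": [1, 1], "start": [100_000, 100_000],
         "end": [150_000, 140_000], "gene": ["at_bound", "too_far"]}
    )
    calls = QtlCallSet("m", pd.DataFrame(
        {"snp_id": ["x"], "chrom": [1], "bp": [200_000],
         "statistic": [1.0], "traits": [()]}))
    hits = candidate_genes(calls, ann, flank_bp=50_000)
    assert list(hits["gene"]) == ["at_bound"]  # edge exactly 50 kb: included


def test_candidate_gene_malformed_interval_rejected():
    ann = pd.DataFrame(
        {"chrom": [1], "start": [200], "end": [100], "gene": ["bad"]}
    )
    calls = QtlCallSet("m", pd.DataFrame(
        {"snp_id": ["x"], "chrom": [1], "bp": [150],
         "statistic": [1.0], "traits": [()]}))
    assert len(candidate_genes(calls, ann)) == 0
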