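"""Mixed-model phenotype analysis: variance components, adjustment, GWAS, FDR.

The working model per trait is

    y = mu + X b + Z1 a + Z1 Q q + Z2 s.f + e

with fixed effects b (flock, sex, age, ...), a polygenic effect a ~
N(0, A sigma2_a) under the pedigree relationship matrix A, a breed effect
proportional to the pedigree breed proportion Q (q ~ N(0, I sigma2_q)), a
sire-by-flock interaction s.f and a residual.  REML estimates use the
eigenbasis of A on the phenotyped animals, with the low-rank sire-by-flock
and breed terms handled by the Woodbury identity, so each likelihood
evaluation is O(n * L) for L interaction levels.

Phenotype adjustment removes the fitted fixed effects and the BLUPs of the
breed and sire-by-flock effects but NOT the polygenic effect, which is
re-fitted downstream (GWAS polygenic control, BayesR residual polygenic
term).  The single-SNP GWAS is a two-stage scheme: adjust once, then score
every SNP by exact generalized least squares in the rotated (polygenic-
whitened) basis, which matches the one-SNP-at-a-time mixed model when the
variance components are held at their REML estimates.

The FDR estimator for a significance threshold P with A of T tests
significant is

    FDR% = 100 * P (1 - A/T) / [ (A/T) (1 - P) ],

the expected false-positive fraction among declared positives; values
above 100% (or A = 0) are reported as unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .containers import ConfigError, GenotypeMatrix, Pedigree
from .gprediction import build_a_matrix

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VarComp",
    "AdjustedPhenotypes",
    "estimate_variance_components",
    "adjust_phenotypes",
    "single_trait_gwas",
    "fdr",
]


@dataclass
class ModelSpec:
    """Which model terms to fit.

    ``fixed_terms`` name phenotype-table columns; float columns enter as
    centered covariates, everything else as categorical factors.
    """

    fixed_terms: tuple = ("flock", "sex", "age")
    breed_random: bool = True  # Q column, q ~ N(0, I sigma2_q)
    sire_flock_random: bool = True  # interaction of sire and flock columns
    polygenic: bool = True

    def validate(self, pheno: pd.DataFrame):
        missing = [c for c in self.fixed_terms if c not in pheno.columns]
        if self.breed_random and "Q" not in pheno.columns:
            missing.append("Q")
        if self.sire_flock_random and not {"sire", "flock"} <= set(pheno.columns):
            missing.append("sire/flock")
        if missing:
            raise ConfigError(f"phenotype table lacks model columns: {missing}")


@dataclass
class VarComp:
    sigma2_a: float
    sigma2_sf: float
    sigma2_q: float
    sigma2_e: float
    h2: float
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


@dataclass
class AdjustedPhenotypes:
    """Animal x trait residuals after fixed/breed/sire-by-flock removal."""

    values: pd.DataFrame  # index animal, one column per trait, NaN = missing
    pheno_sd: pd.Series  # per-trait phenotypic SD (of the adjusted phenotype)
    vc: dict  # trait -> VarComp

    def traits(self) -> list[str]:
        return list(self.values.columns)


# ------------------------------------------------------------------ design


def _design(pheno: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for term in terms:
        col = pheno[term]
        if pd.api.types.is_float_dtype(col):
            v = col.to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(term)
        else:
            dummies = pd.get_dummies(col, prefix=term, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(str(c))
    x = np.column_stack(cols)
    # drop aliased columns (rank deficiency) via pivoted QR
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag[0] * 1e-10).sum())
    if rank < x.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [names[j] for j in piv[rank:]]
        log.warning("dropping aliased fixed-effect columns: %s", dropped)
        x = x[:, keep]
        names = [names[j] for j in keep]
    return x, names


def _sf_design(pheno: pd.DataFrame) -> np.ndarray:
    key = pd.Series(list(zip(pheno["sire"], pheno["flock"])))
    codes = key.astype("category").cat.codes.to_numpy()
    z = np.zeros((len(pheno), codes.max() + 1))
    z[np.arange(len(pheno)), codes] = 1.0
    return z


# --------------------------------------------------- REML via eigen+Woodbury


class _TraitModel:
    """Rotated per-trait data for the mixed model on observed animals."""

    def __init__(self, pheno: pd.DataFrame, ped: Pedigree, spec: ModelSpec, trait: str):
        spec.validate(pheno)
        obs = pheno[trait].notna().to_numpy()
        sub = pheno[obs].reset_index(drop=True)
        if len(sub) == 0:
            raise ConfigError(f"no observations for trait {trait}")
        self.animals = sub["animal"].to_numpy()
        self.y = sub[trait].to_numpy(dtype=float)
        self.x, self.x_names = _design(sub, spec.fixed_terms)
        self.spec = spec
        b_blocks, b_sizes = [], []
        if spec.sire_flock_random:
            self.z_sf = _sf_design(sub)
            b_blocks.append(self.z_sf)
            b_sizes.append(self.z_sf.shape[1])
        else:
            self.z_sf = None
        if spec.breed_random:
            self.q_col = sub["Q"].to_numpy(dtype=float)[:, None]
            b_blocks.append(self.q_col)
            b_sizes.append(1)
        else:
            self.q_col = None
        self.b = np.hstack(b_blocks) if b_blocks else np.zeros((len(sub), 0))
        self.b_sizes = b_sizes

        if spec.polygenic:
            d, u = _a_eigen(ped, self.animals)
            self.d = d
            self.u = u
            self.yr = u.T @ self.y
            self.xr = u.T @ self.x
            self.br = u.T @ self.b if self.b.shape[1] else self.b
        else:
            self.d = np.zeros(len(sub))
            self.u = None
            self.yr, self.xr, self.br = self.y, self.x, self.b

    def gamma_vec(self, g_sf, g_q):
        out = []
        if self.spec.sire_flock_random:
            out += [g_sf] * self.b_sizes[0]
        if self.spec.breed_random:
            out += [g_q]
        return np.asarray(out)

    def neg2_reml(self, g_a, g_sf, g_q):
        w = g_a * self.d + 1.0
        yr, xr, br = self.yr, self.xr, self.br
        n, p = len(yr), xr.shape[1]
        t = np.column_stack([xr, yr])
        tw = t / w[:, None]
        logdet = float(np.sum(np.log(w)))
        if br.shape[1]:
            gam = self.gamma_vec(g_sf, g_q)
            sb = br * np.sqrt(gam)[None, :]
            sbw = sb / w[:, None]
            m = np.eye(sb.shape[1]) + sb.T @ sbw
            cm = np.linalg.cholesky(m)
            logdet += 2 * float(np.sum(np.log(np.diag(cm))))
            k = np.linalg.solve(m, sbw.T @ t)
            tsit = t.T @ tw - (sbw.T @ t).T @ k
        else:
            tsit = t.T @ tw
        xtsix = tsit[:p, :p]
        xtsiy = tsit[:p, p]
        ytsiy = tsit[p, p]
        sign, ld_x = np.linalg.slogdet(xtsix)
        if sign <= 0:
            return np.inf, None
        beta = np.linalg.solve(xtsix, xtsiy)
        ypy = ytsiy - xtsiy @ beta
        if ypy <= 0:
            return np.inf, None
        s2e = float(ypy) / (n - p)
        val = (n - p) * np.log(s2e) + logdet + ld_x
        return val, (s2e, beta)


_A_CACHE: dict = {}


def _a_eigen(ped: Pedigree, animals) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the A submatrix for ``animals`` (cached)."""
    key = (id(ped), hash(tuple(int(a) for a in animals)))
    if key not in _A_CACHE:
        if len(_A_CACHE) > 6:
            _A_CACHE.clear()
        full_key = (id(ped), "full")
        if full_key not in _A_CACHE:
            _A_CACHE[full_key] = build_a_matrix(ped)
        a_full = _A_CACHE[full_key]
        rows = ped.rows_of(animals)
        a_sub = a_full[np.ix_(rows, rows)]
        d, u = np.linalg.eigh(a_sub)
        _A_CACHE[key] = (np.clip(d, 0, None), u)
    return _A_CACHE[key]


def estimate_variance_components(
    pheno: pd.DataFrame, ped: Pedigree, spec: ModelSpec, trait: str, max_iter: int = 400
) -> VarComp:
    """REML variance components for one trait.

    Optimizes the log variance ratios (polygenic, sire-by-flock, breed
    relative to residual) by Nelder-Mead on the profiled REML criterion;
    h2 = sigma2_a / (sigma2_a + sigma2_sf + sigma2_e).
    """
    if pheno[trait].notna().sum() < 50:
        raise ConfigError("need at least 50 records for REML")
    tm = _TraitModel(pheno, ped, spec, trait)

    active = []
    if spec.polygenic:
        active.append("a")
    if spec.sire_flock_random:
        active.append("sf")
    if spec.breed_random:
        active.append("q")

    def unpack(theta):
        g = {"a": 0.0, "sf": 0.0, "q": 0.0}
        for name, t in zip(active, theta):
            g[name] = float(np.exp(np.clip(t, -25, 8)))
        return g

    def objective(theta):
        g = unpack(theta)
        val, _ = tm.neg2_reml(g["a"], g["sf"], g["q"])
        return val

    x0 = np.asarray([np.log(0.4) if a == "a" else np.log(0.05) for a in active])
    converged = True
    if active:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-7},
        )
        converged = bool(res.success)
        if not converged:
            log.warning("REML did not converge for %s: %s", trait, res.message)
        g = unpack(res.x)
    else:
        g = {"a": 0.0, "sf": 0.0, "q": 0.0}
    val, aux = tm.neg2_reml(g["a"], g["sf"], g["q"])
    s2e = aux[0]
    s2a, s2sf, s2q = g["a"] * s2e, g["sf"] * s2e, g["q"] * s2e
    # variance ratios below ~1e-8 are boundary estimates; report exact zero
    s2a, s2sf, s2q = (v if v > 1e-8 * s2e else 0.0 for v in (s2a, s2sf, s2q))
    h2 = s2a / (s2a + s2sf + s2e)
    return VarComp(
        s2a, s2sf, s2q, s2e, h2, converged,
        diagnostics={"neg2_reml": float(val), "n": len(tm.y)},
    )


def adjust_phenotypes(
    pheno: pd.DataFrame, ped: Pedigree, spec: ModelSpec, vc: dict
) -> AdjustedPhenotypes:
    """Residuals after removing fixed effects and breed / sire-by-flock BLUPs.

    The polygenic effect is NOT removed; it is re-fitted by every downstream
    stage.  Missing phenotypes stay missing.  ``vc`` maps trait -> VarComp.
    """
    traits = list(vc.keys())
    out = {}
    sds = {}
    all_animals = pheno["animal"].to_numpy()
    vc_out = {}
    for trait in traits:
        v = vc[trait]
        tm = _TraitModel(pheno, ped, spec, trait)
        g_a = v.sigma2_a / v.sigma2_e if v.sigma2_e > 0 else 0.0
        g_sf = v.sigma2_sf / v.sigma2_e if v.sigma2_e > 0 else 0.0
        g_q = v.sigma2_q / v.sigma2_e if v.sigma2_e > 0 else 0.0
        _, aux = tm.neg2_reml(g_a, g_sf, g_q)
        if aux is None:
            raise ConfigError(f"degenerate model for trait {trait}")
        beta = aux[1]
        resid = tm.y - tm.x @ beta
        if tm.b.shape[1]:
            # BLUP of the low-rank random terms under V = s2e (g_a A + I + B Gam B')
            w = g_a * tm.d + 1.0
            gam = tm.gamma_vec(g_sf, g_q)
            rr = tm.u.T @ resid if tm.u is not None else resid
            sb = tm.br * np.sqrt(gam)[None, :]
            sbw = sb / w[:, None]
            m = np.eye(sb.shape[1]) + sb.T @ sbw
            vir = rr / w - sbw @ np.linalg.solve(m, sbw.T @ rr)
            u_hat = gam * (tm.br.T @ vir)  # scaled BLUP in gamma units
            resid = resid - tm.b @ u_hat
        resid = resid - resid.mean()
        s = pd.Series(np.nan, index=all_animals, dtype=float)
        s.loc[tm.animals] = resid
        out[trait] = s
        sds[trait] = float(np.nanstd(resid, ddof=1))
        vc_out[trait] = v
    values = pd.DataFrame(out)
    values.index.name = "animal"
    return AdjustedPhenotypes(values, pd.Series(sds), vc_out)


# -------------------------------------------------------------------- GWAS

_ROT_CACHE: dict = {}


def _rotated_dosages(geno, animals, s, u) -> np.ndarray:
    """U' S for the phenotyped-animal dosage block (single-entry cache: the
    rotation is the costly step of the GWAS and is shared across traits
    whenever the observed-animal set is the same)."""
    key = (id(geno), hash(tuple(int(a) for a in animals)))
    hit = _ROT_CACHE.get("entry")
    if hit is not None and hit[0] == key:
        return hit[1]
    filled = np.where(s < 0, np.nanmean(np.where(s < 0, np.nan, s), axis=0), s)
    sr = u.T @ filled
    _ROT_CACHE["entry"] = (key, sr)
    return sr


def single_trait_gwas(
    geno: GenotypeMatrix, adj: AdjustedPhenotypes, ped: Pedigree, trait: str
) -> pd.DataFrame:
    """Per-SNP effect, SE, signed t and P for one trait.

    Exact GLS per SNP under y = mu + s alpha + a + e with the polygenic
    variance ratio held at its REML estimate: the phenotype and dosages are
    rotated once into the eigenbasis of A and every SNP is scored by
    weighted regression with the intercept absorbed.  P-values use the
    normal reference.  SNPs with fewer than two genotype classes among the
    phenotyped animals are flagged with null statistics.
    """
    values = adj.values[trait].dropna()
    animals = values.index.to_numpy()
    common = [a for a in animals if int(a) in geno._row]
    if not common:
        raise ConfigError("no overlap between genotyped and phenotyped animals")
    y = values.loc[common].to_numpy(dtype=float)
    gsub = geno.subset(common)
    s = np.nan_to_num(gsub.dosages, nan=-1.0)

    v = adj.vc[trait]
    d, u = _a_eigen(ped, common)
    g_a = v.sigma2_a / v.sigma2_e if v.sigma2_e > 0 else 0.0
    w = 1.0 / (g_a * d + 1.0)  # weights up to sigma2_e scale

    yr = u.T @ y
    sr = _rotated_dosages(geno, common, s, u)
    oner = u.T @ np.ones(len(y))

    o_w = oner * w
    sw_one = sr.T @ o_w  # per SNP
    one_w_one = float(oner @ o_w)
    y_w = yr * w
    s_wy = sr.T @ y_w
    s_ws = np.einsum("ij,ij->j", sr, sr * w[:, None])
    one_wy = float(oner @ y_w)

    denom = s_ws - sw_one**2 / one_w_one
    numer = s_wy - sw_one * one_wy / one_w_one

    n_classes = sum((s == g).any(axis=0).astype(int) for g in (0, 1, 2))
    ok = (denom > 1e-12) & (n_classes >= 2)

    # residual variance per SNP from the null model (score-test style): use
    # the REML residual scale, consistent across SNPs
    s2e = v.sigma2_e
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(ok, numer / denom, np.nan)
        se = np.where(ok, np.sqrt(s2e / denom), np.nan)
        tval = alpha / se
    pval = 2 * stats.norm.sf(np.abs(tval))
    pval = np.where(ok, pval, np.nan)

    out = gsub.snp_map.copy()
    out["effect"] = alpha
    out["se"] = se
    out["t"] = tval
    out["p"] = pval
    out["n"] = (s >= 0).sum(axis=0)
    out["flag"] = np.where(ok, "", "monomorphic")
    out["trait"] = trait
    return out


# --------------------------------------------------------------------- FDR


def fdr(p_threshold: float, n_significant: int, n_tests: int):
    """False discovery rate (%) at a P-value threshold.

    Returns the percentage, or None when unavailable (no significant tests,
    or the estimate exceeds 100%).
    """
    if not 0 < p_threshold < 1:
        raise ConfigError("p_threshold must lie in (0, 1)")
    if n_significant < 0 or n_tests < n_significant:
        raise ConfigError("need 0 <= n_significant <= n_tests")
    if n_significant == 0:
        return None
    a_frac = n_significant / n_tests
    value = 100.0 * p_threshold * (1 - a_frac) / (a_frac * (1 - p_threshold))
    if value > 100.0:
        return None
    return value
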