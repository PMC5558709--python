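"""Missing-phenotype prediction, linear-index construction and validation.

Missing phenotypes are predicted by multiple regression from the measured
traits using the trait x trait phenotypic covariance of adjusted
phenotypes: with U the inverse of the full covariance partitioned into
missing (n) and measured (m) blocks, ``y_n_hat = -(U^nn)^-1 U^nm y_m``,
which is algebraically the conditional expectation
``Sigma_nm Sigma_mm^-1 y_m`` of a multivariate normal.

For each putative QTL a linear index ``y_I = b' C^-1 y`` collapses the
multi-trait phenotype into one composite trait, where b holds the SNP's
estimated effects on all traits (training population only) and C is the
covariance of estimated SNP effects over all SNPs in training.  Each
index is then mapped against its own SNP in the held-out validation
animals (mean + SNP + animal + error, pedigree animal effect), and the
direction of the validation effect is compared with training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, GenotypeMatrix, Pedigree
from .multitrait import _reml_ratio
from .phenomodel import AdjustedPhenotypes, _a_eigen, fdr

log = logging.getLogger(__name__)

__all__ = [
    "PhenoCovariance",
    "EffectCovariance",
    "impute_missing_phenotypes",
    "linear_index",
    "validate_index_snps",
]


def _nearest_pd(mat: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Eigenvalue-floor projection to positive definiteness."""
    lam, vec = np.linalg.eigh(mat)
    shift = 0.0
    if lam.min() < floor:
        shift = float(floor - lam.min())
        lam = np.clip(lam, floor, None)
    return (vec * lam) @ vec.T, shift


@dataclass
class PhenoCovariance:
    """Trait x trait phenotypic covariance of adjusted phenotypes."""

    cov: np.ndarray
    traits: list
    shrinkage: float  # eigenvalue shift applied to reach positive definiteness

    @classmethod
    def from_adjusted(cls, adj: AdjustedPhenotypes) -> "PhenoCovariance":
        cov = adj.values.cov(min_periods=2).to_numpy()  # pairwise-complete
        if np.isnan(cov).any():
            raise ConfigError("trait pairs with no joint observations")
        pd_cov, shift = _nearest_pd(cov)
        if shift:
            log.info("phenotypic covariance shifted by %.3g for PDness", shift)
        return cls(pd_cov, list(adj.values.columns), shift)


@dataclass
class EffectCovariance:
    """Trait x trait covariance of estimated SNP effects (training only)."""

    cov: np.ndarray
    traits: list
    shrinkage: float

    @classmethod
    def from_gwas(cls, gwas_tables: dict) -> "EffectCovariance":
        traits = list(gwas_tables.keys())
        eff = np.column_stack(
            [gwas_tables[tr]["effect"].to_numpy() for tr in traits]
        )
        eff = eff[np.isfinite(eff).all(axis=1)]
        cov = np.cov(eff.T, ddof=1)
        pd_cov, shift = _nearest_pd(cov, floor=1e-12 * np.trace(cov) / len(traits))
        return cls(pd_cov, traits, shift)


def impute_missing_phenotypes(
    adj: AdjustedPhenotypes, u: PhenoCovariance | None = None
) -> pd.DataFrame:
    """Complete the adjusted-phenotype table by multiple regression.

    Per animal, missing traits are predicted as -(U^nn)^-1 U^nm y_m from
    the blocks of the inverse phenotypic covariance; measured entries are
    untouched.  Animals sharing a missing pattern are solved together.
    """
    if u is None:
        u = PhenoCovariance.from_adjusted(adj)
    values = adj.values[u.traits]
    isna = values.isna().to_numpy()
    none_measured = isna.all(axis=1)
    if none_measured.any():
        raise ConfigError(
            f"animals with no measured trait: {list(values.index[none_measured])[:5]}"
        )
    uinv = np.linalg.inv(u.cov)
    out = values.to_numpy().copy()
    patterns = {}
    for i, row in enumerate(isna):
        patterns.setdefault(row.tobytes(), []).append(i)
    for key, rows in patterns.items():
        miss = np.frombuffer(key, dtype=bool)
        if not miss.any():
            continue
        meas = ~miss
        unn = uinv[np.ix_(miss, miss)]
        unm = uinv[np.ix_(miss, meas)]
        ym = out[np.ix_(rows, np.where(meas)[0])]
        pred = -np.linalg.solve(unn, unm @ ym.T).T
        out[np.ix_(rows, np.where(miss)[0])] = pred
    return pd.DataFrame(out, index=values.index, columns=u.traits)


def linear_index(
    effects_b: np.ndarray, c: EffectCovariance, completed: pd.DataFrame
) -> pd.Series:
    """y_I = b' C^-1 y per animal for one putative QTL."""
    b = np.asarray(effects_b, dtype=float)
    if b.shape != (len(c.traits),):
        raise ConfigError("effect vector length must match trait count")
    w = np.linalg.solve(c.cov, b)
    y = completed[c.traits].to_numpy()
    return pd.Series(y @ w, index=completed.index, name="y_I")


def validate_index_snps(
    calls_table: pd.DataFrame,
    training_gwas: dict,
    c: EffectCovariance,
    completed_validation: pd.DataFrame,
    geno: GenotypeMatrix,
    ped: Pedigree,
    p_threshold: float = 0.05,
) -> dict:
    """Validate selected SNPs through their linear indices.

    For every called SNP: build y_I from the training effects, regress it
    on the SNP's dosage in the validation animals (pedigree animal effect),
    and compare effect directions with training.  The training-direction
    reference is b' C^-1 b-weighted, i.e. the index's own expected effect
    sign, which is positive by construction; validation agreement is
    therefore the sign of the validation regression.  Monomorphic SNPs are
    flagged and excluded from denominators.  FDR uses T = SNPs tested.
    """
    animals = completed_validation.index.to_numpy()
    gsub = geno.subset(animals)
    d, u_rot = _a_eigen(ped, animals)
    sid_col = {s: j for j, s in enumerate(gsub.snp_map["snp_id"])}
    traits = c.traits

    rows = []
    for call in calls_table.itertuples(index=False):
        sid = call.snp_id
        if sid not in sid_col:
            continue
        b = np.asarray(
            [training_gwas[tr].set_index("snp_id").loc[sid, "effect"] for tr in traits]
        )
        if not np.isfinite(b).all():
            continue
        y_i = linear_index(b, c, completed_validation).to_numpy()
        s = gsub.dosages[:, sid_col[sid]]
        s = np.nan_to_num(s, nan=float(np.nanmean(s)))
        if s.max() == s.min():
            rows.append({"snp_id": sid, "flag": "monomorphic"})
            continue
        gamma = _reml_ratio(y_i, d, u_rot)
        w = 1.0 / (gamma * d + 1.0)
        yr, sr, oner = u_rot.T @ y_i, u_rot.T @ s, u_rot.T @ np.ones(len(y_i))
        ow = oner * w
        owo = float(oner @ ow)
        denom = float(sr @ (sr * w)) - float(sr @ ow) ** 2 / owo
        numer = float(sr @ (yr * w)) - float(sr @ ow) * float(oner @ (yr * w)) / owo
        alpha = numer / denom
        ypy0 = float(yr @ (yr * w)) - float(oner @ (yr * w)) ** 2 / owo
        nn = len(y_i)
        fval = (numer * alpha) / ((ypy0 - numer * alpha) / (nn - 2))
        pval = float(stats.f.sf(fval, 1, nn - 2))
        # training-side effect of the SNP on its own index
        train_eff = float(b @ np.linalg.solve(c.cov, b))  # > 0 by construction
        rows.append(
            {
                "snp_id": sid,
                "effect_train": train_eff,
                "effect_valid": alpha,
                "p_valid": pval,
                "same_direction": bool(np.sign(alpha) == np.sign(train_eff)),
                "flag": "",
            }
        )
    tab = pd.DataFrame(rows)
    tested = tab[tab.get("flag", "") == ""] if len(tab) else tab
    n_tested = len(tested)
    n_sig = int((tested["p_valid"] < p_threshold).sum()) if n_tested else 0
    sig = tested[tested["p_valid"] < p_threshold] if n_tested else tested
    summary = {
        "n_tested": n_tested,
        "n_significant": n_sig,
        "pct_same_direction_all": (
            100.0 * tested["same_direction"].mean() if n_tested else np.nan
        ),
        "pct_same_direction_significant": (
            100.0 * sig["same_direction"].mean() if n_sig else np.nan
        ),
        "fdr_pct": fdr(p_threshold, n_sig, n_tested) if n_tested else None,
    }
    return {"table": tab, "summary": summary}
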