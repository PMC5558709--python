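"""File formats, genotype QC, configuration and pipeline orchestration.

Formats: PLINK text .ped/.map, a one-line-per-animal dosage TSV dialect,
VCF (sites + GT only), TSV pedigree/phenotype tables with a header line,
BED4 / GFF3 gene annotation (converted internally to 1-based inclusive
spans), JSON manifests and a YAML run configuration.

QC applies the SNP filters first (call rate, MAF, Hardy-Weinberg) and
then the per-animal call-rate filter, reporting counts per filter in
application order, because the order changes the counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, GenotypeMatrix, Pedigree

log = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "qc_genotypes",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation",
    "run_pipeline",
]


# ---------------------------------------------------------------------- QC


@dataclass
class QcThresholds:
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    animal_call_rate_min: float = 0.90

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")


def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg test from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = np.asarray([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.asarray([n_aa, n_ab, n_bb], dtype=float)
    nonzero = exp > 0
    chi2 = float(((obs[nonzero] - exp[nonzero]) ** 2 / exp[nonzero]).sum())
    return float(stats.chi2.sf(chi2, 1))


def qc_genotypes(geno: GenotypeMatrix, thr: QcThresholds = QcThresholds()):
    """SNP filters (call rate, MAF, HWE) then animal call-rate filter.

    Returns (filtered GenotypeMatrix, report dict with per-filter counts
    in application order).
    """
    d = geno.dosages
    n, m = d.shape
    called = ~np.isnan(d)
    report = {"n_snps_in": m, "n_animals_in": n}

    snp_cr = called.mean(axis=0)
    fail_cr = snp_cr < thr.snp_call_rate_min
    report["snps_fail_call_rate"] = int(fail_cr.sum())

    p = np.nanmean(d, axis=0) / 2
    maf = np.minimum(p, 1 - p)
    fail_maf = ~fail_cr & (maf < thr.maf_min)
    report["snps_fail_maf"] = int(fail_maf.sum())

    fail_hwe = np.zeros(m, dtype=bool)
    for j in np.where(~fail_cr & ~fail_maf)[0]:
        col = d[:, j]
        col = col[~np.isnan(col)]
        pval = hwe_chi2_p(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        fail_hwe[j] = pval < thr.hwe_p_min
    report["snps_fail_hwe"] = int(fail_hwe.sum())

    keep_snp = ~(fail_cr | fail_maf | fail_hwe)
    if not keep_snp.any():
        raise ConfigError("all SNPs removed by QC")
    d2 = d[:, keep_snp]

    animal_cr = (~np.isnan(d2)).mean(axis=1)
    keep_animal = animal_cr >= thr.animal_call_rate_min
    report["animals_fail_call_rate"] = int((~keep_animal).sum())
    report["n_snps_out"] = int(keep_snp.sum())
    report["n_animals_out"] = int(keep_animal.sum())

    out = GenotypeMatrix(
        d2[keep_animal],
        np.asarray(geno.animals)[keep_animal],
        geno.snp_map.loc[keep_snp].reset_index(drop=True),
    )
    return out, report


# --------------------------------------------------------------------- I/O


def write_genotypes(geno: GenotypeMatrix, prefix: str | Path, fmt: str = "ped-map"):
    prefix = Path(prefix)
    if fmt == "ped-map":
        with open(prefix.with_suffix(".map"), "w") as fh:
            for r in geno.snp_map.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.bp}\n")
        alleles = {0: "A A", 1: "A B", 2: "B B"}
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, aid in enumerate(geno.animals):
                geno_str = " ".join(
                    alleles.get(int(v), "0 0") if np.isfinite(v) else "0 0"
                    for v in geno.dosages[i]
                )
                fh.write(f"0 {aid} 0 0 0 -9 {geno_str}\n")
    elif fmt == "dosage-tsv":
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            fh.write("animal\t" + "\t".join(geno.snp_map["snp_id"]) + "\n")
            for i, aid in enumerate(geno.animals):
                vals = "\t".join(
                    "NA" if not np.isfinite(v) else str(int(v)) for v in geno.dosages[i]
                )
                fh.write(f"{aid}\t{vals}\n")
        geno.snp_map.to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)
    elif fmt == "vcf":
        with open(prefix.with_suffix(".vcf"), "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in pd.unique(geno.snp_map["chrom"]):
                end = int(geno.snp_map.loc[geno.snp_map["chrom"] == c, "bp"].max())
                fh.write(f"##contig=<ID={c},length={end + 1}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(a) for a in geno.animals)
                + "\n"
            )
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, r in enumerate(geno.snp_map.itertuples(index=False)):
                col = geno.dosages[:, j]
                cells = "\t".join(
                    gt.get(int(v), "./.") if np.isfinite(v) else "./." for v in col
                )
                fh.write(f"{r.chrom}\t{r.bp}\t{r.snp_id}\tA\tB\t.\t.\t.\tGT\t{cells}\n")
    else:
        raise ConfigError(f"unknown genotype format {fmt!r}")


def read_genotypes(path: str | Path, fmt: str = "ped-map") -> GenotypeMatrix:
    """Read dosage genotypes; dosage counts the alternate (B/ALT) allele."""
    path = Path(path)
    if fmt == "ped-map":
        snp_map = pd.read_csv(
            path.with_suffix(".map"),
            sep=r"\s+",
            names=["chrom", "snp_id", "cm", "bp"],
        )[["snp_id", "chrom", "bp"]]
        animals, rows = [], []
        with open(path.with_suffix(".ped")) as fh:
            for line in fh:
                parts = line.split()
                animals.append(int(parts[1]))
                al = parts[6:]
                pairs = zip(al[0::2], al[1::2])
                rows.append(
                    [
                        np.nan if a == "0" else (a == "B") + (b == "B")
                        for a, b in pairs
                    ]
                )
        dosages = np.asarray(rows, dtype=float)
    elif fmt == "dosage-tsv":
        tab = pd.read_csv(path.with_suffix(".tsv"), sep="\t", na_values="NA")
        animals = tab["animal"].to_numpy()
        dosages = tab.drop(columns="animal").to_numpy(dtype=float)
        snp_map = pd.read_csv(path.with_suffix(".snps.tsv"), sep="\t")
    elif fmt == "vcf":
        import cyvcf2

        vcf = cyvcf2.VCF(str(path))
        animals = [int(a) for a in vcf.samples]
        snp_rows, cols = [], []
        for var in vcf:
            snp_rows.append((var.ID, _chrom_int(var.CHROM), var.POS))
            col = [
                np.nan if a0 < 0 else float(int(a0 > 0) + int(a1 > 0))
                for a0, a1, *_ in var.genotypes
            ]
            cols.append(col)
        snp_map = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "bp"])
        dosages = np.asarray(cols, dtype=float).T
    else:
        raise ConfigError(f"unknown genotype format {fmt!r}")

    if snp_map["snp_id"].duplicated().any():
        raise ConfigError("duplicate SNP ids")
    order = np.lexsort((snp_map["bp"], snp_map["chrom"]))
    if not np.array_equal(order, np.arange(len(snp_map))):
        log.warning("SNP map unsorted; sorting by chromosome and position")
        snp_map = snp_map.iloc[order].reset_index(drop=True)
        dosages = dosages[:, order]
    return GenotypeMatrix(dosages, np.asarray(animals), snp_map)


def write_pedigree(ped: Pedigree, path):
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t"))


def write_phenotypes(pheno: pd.DataFrame, path):
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED4 (0-based half-open) or GFF3 (1-based
    inclusive); returned as 1-based inclusive chrom/start/end/gene."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if f[2].lower() != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name", attrs.get("ID", "unknown"))
                rows.append((_chrom_int(f[0]), int(f[3]), int(f[4]), name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    tab = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["chrom", "start", "end", "gene"])
    tab["chrom"] = tab["chrom"].map(_chrom_int)
    tab["start"] = tab["start"] + 1  # BED 0-based half-open -> 1-based inclusive
    return tab


def _chrom_int(c):
    s = str(c)
    for prefix in ("chr", "OAR"):
        if s.startswith(prefix):
            s = s[len(prefix):]
    try:
        return int(s)
    except ValueError:
        return s


# ---------------------------------------------------------------- pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the requested stages, writing a manifest per stage.

    ``config`` keys: seed (int), stages (list from: simulate, qc, adjust,
    gwas, gblup, bayesr, multitrait, validate), sim (SimConfig overrides),
    bayesr (BayesRConfig overrides).  Stages assume their inputs were
    produced by earlier stages in the same run.
    """
    from . import bayesr as br
    from . import gprediction as gp
    from . import indexval as iv
    from . import multitrait as mt
    from . import phenomodel as pm
    from . import simpop as sp

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["simulate"])
    manifests = {}
    state: dict = {}

    def manifest(stage, params, outputs):
        man = {
            "stage": stage,
            "seed": seed,
            "parameters": params,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
        path = out_dir / f"manifest_{stage}.json"
        path.write_text(json.dumps(man, indent=2, sort_keys=True))
        manifests[stage] = man

    try:
        if "simulate" in stages:
            sim_kwargs = dict(config.get("sim", {}))
            cfg = sp.SimConfig(seed=seed, **sim_kwargs)
            ped, geno, pheno, truth = sp.simulate_all(cfg)
            state.update(cfg=cfg, ped=ped, geno=geno, pheno=pheno, truth=truth)
            write_pedigree(ped, out_dir / "pedigree.tsv")
            write_phenotypes(pheno, out_dir / "phenotypes.tsv")
            write_genotypes(geno, out_dir / "genotypes", fmt="dosage-tsv")
            (out_dir / "truth.json").write_text(json.dumps(truth.to_json_dict()))
            manifest(
                "simulate",
                {k: str(v) for k, v in sim_kwargs.items()},
                [out_dir / f for f in
                 ("pedigree.tsv", "phenotypes.tsv", "genotypes.tsv", "truth.json")],
            )
        if "qc" in stages:
            geno_qc, report = qc_genotypes(state["geno"], QcThresholds())
            state["geno"] = geno_qc
            (out_dir / "qc_report.json").write_text(json.dumps(report, indent=2))
            manifest("qc", asdict(QcThresholds()), [out_dir / "qc_report.json"])
        if "adjust" in stages:
            spec = pm.ModelSpec()
            traits = state["cfg"].trait_names()
            vc = {
                t: pm.estimate_variance_components(state["pheno"], state["ped"], spec, t)
                for t in traits
            }
            adj = pm.adjust_phenotypes(state["pheno"], state["ped"], spec, vc)
            state.update(spec=spec, vc=vc, adj=adj)
            adj.values.to_csv(out_dir / "adjusted.tsv", sep="\t", na_rep="NA")
            manifest("adjust", {"traits": traits}, [out_dir / "adjusted.tsv"])
        if "gwas" in stages:
            gwas = {
                t: pm.single_trait_gwas(state["geno"], state["adj"], state["ped"], t)
                for t in state["cfg"].trait_names()
            }
            state["gwas"] = gwas
            for t, tab in gwas.items():
                tab.to_csv(out_dir / f"gwas_{t}.tsv", sep="\t", index=False, na_rep="NA")
            manifest(
                "gwas", {}, [out_dir / f"gwas_{t}.tsv" for t in gwas]
            )
        if "gblup" in stages:
            grm = gp.build_grm(state["geno"])
            folds = gp.make_cv_folds(state["ped"], seed=seed)
            accs = {}
            for t in state["cfg"].trait_names():
                gt = gp.gblup_fit(grm, state["adj"], folds, t)
                accs[t] = gp.gebv_accuracy(
                    gt, state["adj"], folds, t, state["vc"][t].h2
                )["mean"]
            state.update(grm=grm, folds=folds)
            (out_dir / "gblup_accuracy.json").write_text(json.dumps(accs, indent=2))
            manifest("gblup", {"folds": 5}, [out_dir / "gblup_accuracy.json"])
        if "bayesr" in stages:
            bcfg = br.BayesRConfig(seed=seed, **config.get("bayesr", {}))
            fits = {
                t: br.bayesr_fit(state["geno"], state["adj"], state["ped"], bcfg, t)
                for t in state["cfg"].trait_names()
            }
            state["fits"] = fits
            for t, fit in fits.items():
                pd.DataFrame(
                    {
                        "snp_id": fit.snp_ids,
                        "mean_effect": fit.beta_mean,
                        **{f"p_class{k}": fit.class_probs[:, k] for k in range(4)},
                        "pp_nonzero": fit.pp_nonzero,
                    }
                ).to_csv(out_dir / f"bayesr_{t}.tsv", sep="\t", index=False)
            manifest("bayesr", {"n_iter": bcfg.n_iter}, [out_dir / f"bayesr_{t}.tsv" for t in fits])
        if "multitrait" in stages:
            tmat, v, extra = mt.build_tmatrix_v(state["gwas"])
            chi2 = mt.multi_gwas_chi2(tmat, v)
            calls_gwas = mt.top_snp_per_mb(chi2, extra["meta"])
            calls_pp = mt.multi_pp(state["fits"], extra["meta"])
            lgms = {
                t: br.local_gebv(state["fits"][t], state["geno"])
                for t in state["cfg"].trait_names()
            }
            wp = mt.window_cov_pca(lgms, state["adj"].pheno_sd)
            k = min(int(config.get("top_windows", 20)), len(wp.windows))
            calls_lg = mt.multi_lgebv_calls(
                lgms, wp, state["adj"], state["geno"], state["ped"], k=k
            )
            state.update(calls={"multi-GWAS": calls_gwas, "multi-PP": calls_pp,
                                "multi-LGEBV": calls_lg})
            venn = mt.compare_methods([calls_gwas, calls_pp, calls_lg])
            for cs in state["calls"].values():
                cs.table.to_csv(
                    out_dir / f"calls_{cs.method}.tsv", sep="\t", index=False
                )
            (out_dir / "venn.json").write_text(json.dumps(venn, indent=2))
            manifest("multitrait", {"top_windows": k},
                     [out_dir / "venn.json"]
                     + [out_dir / f"calls_{c.method}.tsv" for c in state["calls"].values()])
        if "validate" in stages:
            folds = state.get("folds") or gp.make_cv_folds(state["ped"], seed=seed)
            val_animals = folds.validation_animals(1)
            adj = state["adj"]
            train_mask = ~adj.values.index.isin(val_animals)
            # training GWAS on the training subset only
            import copy

            adj_train = copy.copy(adj)
            adj_train.values = adj.values[train_mask]
            gwas_train = {
                t: pm.single_trait_gwas(state["geno"], adj_train, state["ped"], t)
                for t in state["cfg"].trait_names()
            }
            c = iv.EffectCovariance.from_gwas(gwas_train)
            adj_val = copy.copy(adj)
            adj_val.values = adj.values[~train_mask]
            completed = iv.impute_missing_phenotypes(adj_val)
            results = {}
            for name, cs in state["calls"].items():
                res = iv.validate_index_snps(
                    cs.table, gwas_train, c, completed, state["geno"], state["ped"]
                )
                results[name] = res["summary"]
            (out_dir / "validation.json").write_text(
                json.dumps(results, indent=2, default=float)
            )
            manifest("validate", {}, [out_dir / "validation.json"])
    except Exception as exc:  # noqa: BLE001
        log.error("pipeline halted at stage boundary: %s", exc)
        (out_dir / "manifest_failure.json").write_text(
            json.dumps({"completed": list(manifests), "error": str(exc)})
        )
        raise
    return manifests
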