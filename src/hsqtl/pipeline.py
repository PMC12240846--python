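"""End-to-end orchestration: simulate/ingest -> QC -> prep -> h2 -> GWAS ->
threshold -> QTL -> colocation -> clustering -> contrast tests.

A single :class:`RunConfig` drives the run.  The global seed is fanned out to
per-stage seeds by hashing the stage name (CRC32 xor global seed, mod 2^31),
so each stochastic stage is independently reproducible.  Every artifact is
written under the output directory as TSV/JSON and listed in a manifest with
a content hash; per-stage filter counts are logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genoqc, netclust, phenoprep, scan as scanmod, simdata, varcomp

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (CRC32 of the stage name xor the seed)."""
    return (zlib.crc32(stage.encode()) ^ (global_seed & 0x7FFFFFFF)) % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full analysis run (defaults mirror the study rules)."""

    seed: int = 1
    out_dir: str = "hsqtl_run"
    # input: either a simulation config or paths to real data
    sim: simdata.SimConfig | None = None
    genotype_prefix: str | None = None
    genotype_format: str = "plink"
    pheno_path: str | None = None
    # phenotype preparation
    gwas_traits: list[str] | None = None  # None -> first trait
    candidate_covariates: list[str] = field(default_factory=lambda: ["sex"])
    covariate_r2_threshold: float = 0.02
    # QC
    max_missing: float = 0.10
    min_maf: float = 0.005
    min_hwe_p: float = 1e-10
    # GWAS / QTL rules
    alpha: float = 0.05
    alpha_suggestive: float = 0.10
    n_perm: int = 100
    support_window: int = 500_000
    support_delta: float = 2.0
    interval_r2: float = 0.6
    coloc_window: int = 3_000_000
    annotation_path: str | None = None
    # clustering
    cluster_traits: list[str] | None = None
    cluster_K: int = 3
    edge_quantile: float = 0.8
    sbm_sweeps: int = 300
    sbm_burn_in: int = 100

    def validate(self) -> None:
        if self.sim is None and (self.genotype_prefix is None or self.pheno_path is None):
            raise ValueError("provide either a simulation config or genotype + phenotype paths")
        for name, v, lo, hi in [("max_missing", self.max_missing, 0, 1),
                                ("min_maf", self.min_maf, 0, 0.5),
                                ("alpha", self.alpha, 0, 1),
                                ("edge_quantile", self.edge_quantile, 0, 1),
                                ("interval_r2", self.interval_r2, 0, 1)]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.data = {"seed": config.seed, "stages": {}, "artifacts": {}, "notes": []}

    def add(self, stage: str, name: str, path: Path):
        self.data["artifacts"][name] = {
            "stage": stage, "path": str(path.relative_to(self.out_dir)),
            "sha256": _sha256(path),
        }

    def note(self, text: str):
        self.data["notes"].append(text)

    def stage(self, name: str, **info):
        self.data["stages"][name] = info

    def write(self):
        p = self.out_dir / "manifest.json"
        p.write_text(json.dumps(self.data, indent=2, default=str))
        return p


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns the manifest dict.

    Stages run in dependency order; any stage error propagates with partial
    outputs preserved on disk.  With ``n_perm=0`` the scan still runs but
    thresholding and QTL calling are skipped (noted in the manifest).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = _Manifest(out, config)
    (out / "config.json").write_text(json.dumps(
        dataclasses.asdict(config), indent=2, default=str))
    man.add("config", "config", out / "config.json")

    # ---- stage: input ----------------------------------------------------
    if config.sim is not None:
        simcfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        G, pheno, truth = simdata.simulate_cohort(simcfg)
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        man.add("simulate", "ground_truth", out / "ground_truth.json")
        man.stage("simulate", n_individuals=G.n_individuals, n_snps=G.n_snps)
    else:
        G = genoqc.read_genotypes(config.genotype_prefix, config.genotype_format)
        pheno = pd.read_csv(config.pheno_path, sep="\t", dtype={"id": str})
        man.stage("ingest", n_individuals=G.n_individuals, n_snps=G.n_snps)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    man.add("input", "phenotypes", out / "phenotypes.tsv")

    # ---- stage: genotype QC ---------------------------------------------
    n_before = G.n_snps
    G = genoqc.snp_stats(G)
    G = genoqc.filter_snps(G, config.max_missing, config.min_maf, config.min_hwe_p)
    man.stage("qc", n_snps_before=n_before, n_snps_after=G.n_snps)
    G.snps.to_csv(out / "snps_qc.tsv", sep="\t", index=False)
    man.add("qc", "snps_qc", out / "snps_qc.tsv")

    # ---- stage: phenotype preparation -----------------------------------
    trait_cols = [c for c in pheno.columns if c not in ("id", "site", "sex")
                  and pd.api.types.is_numeric_dtype(pheno[c])]
    gwas_traits = config.gwas_traits or trait_cols[:1]
    prepared: dict[str, phenoprep.PreparedPhenotype] = {}
    for t in trait_cols:
        prepared[t] = phenoprep.prepare_trait(
            pheno, t, config.candidate_covariates, config.covariate_r2_threshold)
    prep_df = pd.DataFrame({t: p.values for t, p in prepared.items()})
    prep_df.insert(0, "id", prep_df.index)
    prep_df.to_csv(out / "prepared_traits.tsv", sep="\t", index=False)
    man.add("prep", "prepared_traits", out / "prepared_traits.tsv")
    man.stage("prep", traits=trait_cols)

    # ---- stage: heritability --------------------------------------------
    grm = varcomp.compute_grm(G)
    loco = varcomp.compute_loco_grms(G)
    h2_rows = []
    for t in trait_cols:
        fit = varcomp.fit_greml(prepared[t].values.reindex(G.ids), grm)
        h2_rows.append({"trait": t, "h2": fit.h2, "se_h2": fit.se_h2,
                        "lrt_p": fit.lrt_p, "converged": fit.converged})
    h2_table = pd.DataFrame(h2_rows)
    h2_table.to_csv(out / "heritability.tsv", sep="\t", index=False)
    man.add("h2", "heritability", out / "heritability.tsv")
    man.stage("h2", n_traits=len(h2_rows))

    # ---- stage: GWAS + threshold + QTL -----------------------------------
    ws = scanmod.LocoWorkspace(G, loco)
    scans: dict[str, scanmod.ScanResult] = {}
    qtl_rows = []
    threshold = None
    for t in gwas_traits:
        res = scanmod.assoc_scan(prepared[t].values.reindex(G.ids), G, loco,
                                 workspace=ws, trait=t)
        scans[t] = res
        res.records.to_csv(out / f"scan_{t}.tsv", sep="\t", index=False)
        man.add("gwas", f"scan_{t}", out / f"scan_{t}.tsv")
        if config.n_perm > 0:
            if threshold is None:
                threshold = scanmod.permutation_threshold(
                    prepared[t].values.reindex(G.ids), G, loco,
                    n_perm=config.n_perm, alpha=config.alpha,
                    seed=stage_seed(config.seed, "permutation"), workspace=ws)
                man.stage("threshold", alpha=config.alpha,
                          n_perm=config.n_perm, value=threshold.value)
            qtls = scanmod.iterative_conditional_mapping(
                prepared[t].values.reindex(G.ids), G, loco, res, threshold,
                support_window=config.support_window,
                support_delta=config.support_delta,
                r2_min=config.interval_r2, workspace=ws)
            for q in qtls:
                qtl_rows.append(dataclasses.asdict(q))
    if config.n_perm == 0:
        man.note("n_perm=0: permutation thresholding and QTL calling skipped")
    qtl_cols = [f.name for f in dataclasses.fields(scanmod.Qtl)]
    qtl_table = pd.DataFrame(qtl_rows, columns=qtl_cols)
    qtl_table.to_csv(out / "qtls.tsv", sep="\t", index=False)
    man.add("qtl", "qtls", out / "qtls.tsv")
    man.stage("qtl", n_qtls=len(qtl_rows))

    # ---- stage: colocation ------------------------------------------------
    if config.annotation_path and qtl_rows:
        ann = pd.read_csv(config.annotation_path, sep="\t",
                          dtype={"chrom": str, "snp_id": str})
        coloc_frames = []
        for q in qtl_rows:
            qtl = scanmod.Qtl(**q)
            cf = scanmod.colocate(qtl, ann, G, window=config.coloc_window)
            cf.insert(0, "peak_snp", qtl.peak_snp)
            coloc_frames.append(cf)
        coloc = pd.concat(coloc_frames, ignore_index=True)
        coloc.to_csv(out / "colocation.tsv", sep="\t", index=False)
        man.add("coloc", "colocation", out / "colocation.tsv")

    # ---- stage: clustering ------------------------------------------------
    cluster_traits = config.cluster_traits or trait_cols
    Z = netclust.standardize_within_group(pheno, cluster_traits)
    net = netclust.build_similarity_network(Z, ids=list(pheno["id"]),
                                            edge_quantile=config.edge_quantile)
    fit = netclust.fit_sbm(net, K=config.cluster_K, n_sweeps=config.sbm_sweeps,
                           burn_in=config.sbm_burn_in,
                           seed=stage_seed(config.seed, "sbm"))
    if config.cluster_K == 3:
        fit = netclust.label_clusters(fit, pheno, cluster_traits)
        contrasts = netclust.cluster_contrasts(fit)
        contrast_df = pd.DataFrame(contrasts)
        contrast_df.insert(0, "id", fit.ids)
        contrast_df.to_csv(out / "cluster_contrasts.tsv", sep="\t", index=False)
        man.add("cluster", "cluster_contrasts", out / "cluster_contrasts.tsv")
        labels = [fit.labels[int(b)] for b in fit.assignments]
    else:
        labels = [str(b) for b in fit.assignments]
    assign = pd.DataFrame({"id": fit.ids, "block": fit.assignments,
                           "label": labels,
                           "confidence": fit.posterior_confidence})
    assign.to_csv(out / "cluster_assignments.tsv", sep="\t", index=False)
    man.add("cluster", "cluster_assignments", out / "cluster_assignments.tsv")
    man.stage("cluster", K=config.cluster_K, n_edges=net.n_edges)

    # ---- stage: allele x cluster contrast at the top QTL ------------------
    if qtl_rows and config.cluster_K == 3:
        top = max(qtl_rows, key=lambda q: q["peak_neglog10_p"])
        gcol = G.dosages[:, G.snp_index(top["peak_snp"])]
        gser = pd.Series(gcol, index=G.ids)
        vuln = pd.Series(contrasts["vulnerable_vs_rest"]).reindex(G.ids)
        chi2, df, p, tab = netclust.allele_by_cluster_test(gser, vuln)
        (out / "allele_by_cluster.json").write_text(json.dumps({
            "peak_snp": top["peak_snp"], "chi2": chi2, "df": df, "p": p,
            "table": tab.to_dict(),
        }, indent=2, default=str))
        man.add("contrast", "allele_by_cluster", out / "allele_by_cluster.json")

    path = man.write()
    log.info("run complete; manifest at %s", path)
    return man.data
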