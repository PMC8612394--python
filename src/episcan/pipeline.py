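"""Pipeline driver: simulate -> qc -> trait -> scan -> clump -> siprs.

Every stage writes its outputs plus a metadata record (seed, package
version, input checksums); re-running with an identical config and seed
reproduces byte-identical result files.  A stage failure halts the run,
leaves partial outputs in place, and drops a FAILED marker naming the
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .clump import cluster_gene, select_representatives
from .plink import read_plink, write_plink
from .qc import QCThresholds, union_qc
from .scan import (
    ScanConfig,
    cross_gene_scan,
    fixed_snp_scan,
    results_to_frame,
    stratify_by_sex,
)
from .simulate import (
    PhenotypeRecord,
    SimulationConfig,
    default_config,
    simulate_covariates,
    simulate_genotypes,
    simulate_trait,
    write_truth_sidecar,
)
from .siprs import DEFAULT_GRID, sweep_to_frame, threshold_sweep
from .trait import SurvivalTraitConfig, build_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    geno_prefix: str | None = None  # used when simulation is None
    pheno_path: str | None = None
    covar_path: str | None = None
    qc_a: QCThresholds = field(default_factory=QCThresholds)
    qc_b: QCThresholds = field(default_factory=QCThresholds)
    trait_cfg: SurvivalTraitConfig = field(default_factory=SurvivalTraitConfig)
    scan_cfg: ScanConfig = field(default_factory=ScanConfig)
    gene_a: str = "GENEA"
    gene_b: str = "GENEB"
    r2_threshold: float = 0.1
    alpha: float = 0.05
    siprs_fixed_snp: str | None = None  # default: top representative pair's SNP1
    siprs_grid: Sequence[float] = DEFAULT_GRID
    siprs_weighting: str = "beta"
    sex_stratified: bool = False
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, n_individuals: int = 6142) -> "PipelineConfig":
        return cls(simulation=default_config(n_individuals=n_individuals, seed=seed), seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, na_rep="NA")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}
    stage = "init"

    def finish_stage(name: str, files: list[Path]) -> None:
        meta["stages"][name] = {str(f.name): _sha256(f) for f in files if f.exists()}

    try:
        # ---- simulate / load -------------------------------------------
        stage = "simulate"
        if cfg.simulation is not None:
            geno = simulate_genotypes(cfg.simulation)
            covars = simulate_covariates(cfg.simulation)
            records = simulate_trait(geno, covars, cfg.simulation)
            prefix = outdir / "genotypes"
            write_plink(prefix, geno)
            _write_tsv(covars, outdir / "covariates.tsv", index=True)
            pheno = pd.DataFrame(
                {
                    "individual_id": [r.individual_id for r in records],
                    "age": [r.lifespan_or_last_age for r in records],
                    "died": [int(r.died) for r in records],
                }
            )
            _write_tsv(pheno, outdir / "phenotypes.tsv")
            write_truth_sidecar(outdir / "truth.json", cfg.simulation, records)
            finish_stage(
                "simulate",
                [
                    prefix.with_suffix(".bed"),
                    prefix.with_suffix(".bim"),
                    prefix.with_suffix(".fam"),
                    outdir / "covariates.tsv",
                    outdir / "phenotypes.tsv",
                    outdir / "truth.json",
                ],
            )
        else:
            if cfg.geno_prefix is None:
                raise PipelineError("simulate", "no simulation config and no geno_prefix")
            geno = read_plink(cfg.geno_prefix)
            for name, p in (("phenotype", cfg.pheno_path), ("covariate", cfg.covar_path)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
            pheno = pd.read_csv(cfg.pheno_path, sep="\t", dtype={"individual_id": str})
            records = [
                PhenotypeRecord(r["individual_id"], float(r["age"]), bool(r["died"]))
                for _, r in pheno.iterrows()
            ]
            covars = pd.read_csv(
                cfg.covar_path, sep="\t", index_col="individual_id", dtype={"individual_id": str}
            )

        # ---- qc --------------------------------------------------------
        stage = "qc"
        geno_qc, report = union_qc(geno, covars, cfg.qc_a, cfg.qc_b)
        report.to_json(outdir / "qc_report.json")
        _write_tsv(report.snp_table, outdir / "qc_snp_stats.tsv")
        write_plink(outdir / "genotypes_qc", geno_qc)
        finish_stage("qc", [outdir / "qc_report.json", outdir / "qc_snp_stats.tsv"])

        # ---- trait -----------------------------------------------------
        stage = "trait"
        labels, summary = build_cohort(
            records, cfg.trait_cfg, geno_qc.individual_ids, covars
        )
        geno_cohort = geno_qc.subset_individuals(
            [i in set(labels.index) for i in geno_qc.individual_ids]
        )
        _write_tsv(labels.to_frame(), outdir / "labels.tsv", index=True)
        _write_tsv(summary, outdir / "cohort_summary.tsv")
        finish_stage("trait", [outdir / "labels.tsv", outdir / "cohort_summary.tsv"])

        # ---- scan ------------------------------------------------------
        stage = "scan"
        snps_a = geno_cohort.gene_snps(cfg.gene_a)
        snps_b = geno_cohort.gene_snps(cfg.gene_b)
        if not snps_a or not snps_b:
            raise PipelineError(
                "scan", f"genes {cfg.gene_a!r}/{cfg.gene_b!r} have no SNPs after QC"
            )
        results = cross_gene_scan(geno_cohort, snps_a, snps_b, covars, labels, cfg.scan_cfg)
        _write_tsv(results_to_frame(results), outdir / "scan_results.tsv")
        files = [outdir / "scan_results.tsv"]
        if cfg.sex_stratified:
            for female, tag in ((False, "male"), (True, "female")):
                cov_s, lab_s, cfg_s = stratify_by_sex(covars, labels, female, cfg.scan_cfg)
                res_s = cross_gene_scan(geno_cohort, snps_a, snps_b, cov_s, lab_s, cfg_s)
                _write_tsv(results_to_frame(res_s), outdir / f"scan_results_{tag}.tsv")
                files.append(outdir / f"scan_results_{tag}.tsv")
        finish_stage("scan", files)

        # ---- clump -----------------------------------------------------
        stage = "clump"
        clusters_a = cluster_gene(snps_a, geno_cohort, results, cfg.r2_threshold, cfg.gene_a)
        clusters_b = cluster_gene(snps_b, geno_cohort, results, cfg.r2_threshold, cfg.gene_b)
        pairset = select_representatives(clusters_a, clusters_b, results, cfg.alpha)
        cluster_rows = [
            {"gene": c.gene, "seed": c.seed, "member": m}
            for c in clusters_a + clusters_b
            for m in c.members
        ]
        _write_tsv(pd.DataFrame(cluster_rows), outdir / "clusters.tsv")
        rep_df = results_to_frame(pairset.representatives)
        rep_df.attrs["bonferroni_alpha"] = pairset.bonferroni_alpha
        _write_tsv(rep_df, outdir / "independent_pairs.tsv")
        with open(outdir / "clump_summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "n_clusters_gene_a": len(clusters_a),
                    "n_clusters_gene_b": len(clusters_b),
                    "n_independent_tests": pairset.n_independent_tests,
                    "bonferroni_alpha": pairset.bonferroni_alpha,
                    "n_significant": len(pairset.significant),
                    "n_candidate_pairs": len(results),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        finish_stage(
            "clump",
            [outdir / "clusters.tsv", outdir / "independent_pairs.tsv", outdir / "clump_summary.json"],
        )

        # ---- siprs -----------------------------------------------------
        stage = "siprs"
        fixed = cfg.siprs_fixed_snp
        if fixed is None and pairset.representatives:
            fixed = pairset.representatives[0].rsid1
        if fixed is not None:
            scan_fixed = fixed_snp_scan(geno_cohort, fixed, covars, labels, cfg.scan_cfg)
            _write_tsv(results_to_frame(scan_fixed), outdir / "fixed_snp_scan.tsv")
            evals = threshold_sweep(
                scan_fixed,
                fixed,
                geno_cohort,
                labels,
                covars,
                list(cfg.scan_cfg.covariates),
                grid=cfg.siprs_grid,
                weighting=cfg.siprs_weighting,
            )
            _write_tsv(sweep_to_frame(evals), outdir / "siprs_sweep.tsv")
            finish_stage(
                "siprs", [outdir / "fixed_snp_scan.tsv", outdir / "siprs_sweep.tsv"]
            )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
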