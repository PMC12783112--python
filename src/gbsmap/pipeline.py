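"""End-to-end pipeline: simulate (or ingest) -> genotype -> filter ->
phenotype -> associate -> report.

All randomness flows from the single pipeline seed. Every stage logs
record counts in and out; a manifest lists each output with its
SHA-256 checksum, so fixed-seed runs are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np

from gbsmap import io as gio
from gbsmap.config import PipelineConfig
from gbsmap.filtering import filter_matrix, impute_passthrough
from gbsmap.genotyping import call_matrix, filter_observations
from gbsmap.phenotype import aggregate_pll
from gbsmap.association import manhattan_plot, run_scan
from gbsmap import synthetic

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("simulate")
def _stage_simulate(cfg: PipelineConfig, outdir: Path):
    sim = dataclasses.replace(cfg.simulation, random_seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    marker_map = synthetic.build_marker_map(sim, rng)
    geno = synthetic.simulate_cross(marker_map, sim, rng)
    obs = synthetic.simulate_observations(geno, sim, rng)
    pheno = synthetic.simulate_phenotypes(geno, sim, rng)
    synthetic.write_fixtures(outdir / "simulated", marker_map, geno, obs, pheno)
    logger.info("simulated %d samples, %d markers, %d observations, %d shoots",
                len(geno.genotypes), len(marker_map.table), len(obs), len(pheno))
    return geno, obs, pheno


@_stage("ingest")
def _stage_ingest(cfg: PipelineConfig):
    if cfg.phenotypes_path is None:
        raise PipelineError("ingest", "real-data mode requires phenotypes_path")
    obs = gio.read_observations_tsv(cfg.observations_path)
    pheno = gio.read_phenotypes_csv(cfg.phenotypes_path)
    return obs, pheno


@_stage("genotype")
def _stage_genotype(cfg: PipelineConfig, obs, parent_ids, outdir: Path):
    counts = filter_observations(obs, cfg.observation_filter)
    samples = obs["sample_id"].unique()
    matrix = call_matrix(
        counts, cfg.caller, cfg.discovery, samples=samples,
        parent_ids=parent_ids,
        susceptible_parent_id=cfg.scan.susceptible_parent_id,
    )
    gio.write_vcf(outdir / "calls.vcf", matrix)
    logger.info("discovered %d polymorphic sites", len(matrix.sites))
    return matrix


@_stage("filter")
def _stage_filter(cfg: PipelineConfig, matrix, outdir: Path):
    filtered, report = filter_matrix(matrix, cfg.site_filter)
    filtered = impute_passthrough(filtered)
    report.to_csv(outdir / "filter_report.tsv", sep="\t")
    gio.write_vcf(outdir / "filtered.vcf", filtered)
    dropped = report.loc[~report["kept"], "reason"].value_counts().to_dict()
    logger.info("kept %d / %d sites after filtering (dropped: %s)",
                int(report["kept"].sum()), len(report), dropped)
    return filtered


@_stage("phenotype")
def _stage_phenotype(pheno, outdir: Path):
    pll = aggregate_pll(pheno)
    pll.to_csv(outdir / "pll.tsv", sep="\t")
    return pll


@_stage("associate")
def _stage_associate(cfg: PipelineConfig, matrix, pll, outdir: Path, plot: bool):
    result = run_scan(matrix, pll, cfg.scan)
    header = (f"# bonferroni_threshold={result.threshold:.6g}\t"
              f"n_snps_tested={result.n_tested}\n")
    with open(outdir / "association.tsv", "w") as fh:
        fh.write(header)
        result.table.to_csv(fh, sep="\t", index=False)
    if plot and result.n_tested:
        manhattan_plot(result, outdir / "manhattan.png")
    logger.info("tested %d SNPs (skipped: %s); threshold %.3f; %d significant",
                result.n_tested, result.skipped, result.threshold,
                int(result.table["significant"].sum()) if result.n_tested else 0)
    return result


def _write_manifest(outdir: Path) -> Path:
    rows = []
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.tsv":
            digest = hashlib.sha256(f.read_bytes()).hexdigest()
            rows.append(f"{f.relative_to(outdir)}\t{digest}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def run_pipeline(cfg: PipelineConfig, plot: bool = True) -> dict:
    """Run the full analysis; returns the in-memory stage artifacts.

    Outputs (VCFs, filter report, PLL table, association table,
    optional Manhattan plot, manifest with checksums) land in
    ``cfg.output_dir``.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.observations_path is not None:
        obs, pheno = _stage_ingest(cfg)
        parent_ids = (cfg.scan.susceptible_parent_id,)
        geno = None
    else:
        geno, obs, pheno = _stage_simulate(cfg, outdir)
        parent_ids = geno.parent_ids

    matrix = _stage_genotype(cfg, obs, parent_ids, outdir)
    filtered = _stage_filter(cfg, matrix, outdir)
    pll = _stage_phenotype(pheno, outdir)
    result = _stage_associate(cfg, filtered, pll, outdir, plot)
    manifest = _write_manifest(outdir)
    return {
        "genotypes": geno, "observations": obs, "phenotypes": pheno,
        "matrix": matrix, "filtered": filtered, "pll": pll,
        "scan": result, "manifest": manifest,
    }
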