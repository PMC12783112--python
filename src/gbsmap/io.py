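"""Shared format readers and writers.

VCF output is a minimal GT-only VCF v4.2 emitted as text so that
fixed-seed runs are byte-stable; reading goes through
:mod:`pysam`. GFF3 parsing uses :mod:`gffutils` with an in-memory
database after a light line-level coordinate check (so malformed
lines are reported with their line number). Tabular inputs are
schema-checked pandas reads.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from gbsmap.genotyping import GenotypeMatrix

OBSERVATION_COLUMNS = ["sample_id", "chrom", "pos", "allele",
                       "offset_start", "offset_end", "phred"]
PHENOTYPE_COLUMNS = ["genotype_id", "year", "replicate",
                     "shoot_length_mm", "necrosis_length_mm"]
MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cM", "parent1_gt", "parent2_gt"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_observations_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, OBSERVATION_COLUMNS, f"observation table {path}")
    return df


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PHENOTYPE_COLUMNS, f"phenotype table {path}")
    return df


def read_marker_map_tsv(path: str | Path):
    from gbsmap.synthetic import MarkerMap

    df = pd.read_csv(path, sep="\t")
    _check_columns(df, MARKER_COLUMNS, f"marker map {path}")
    return MarkerMap(df)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


# ---------------------------------------------------------------- VCF


def _gt_code(gt: object, ref: str, alts: list[str]) -> str:
    if not isinstance(gt, str) or gt == "":
        return "./."
    a, b = gt.split("/")
    alleles = [ref] + alts
    try:
        return f"{alleles.index(a)}/{alleles.index(b)}"
    except ValueError:
        return "./."


def write_vcf(path: str | Path, matrix: GenotypeMatrix,
              source: str = "gbsmap") -> None:
    """Write a GT-only VCF v4.2; sites ordered by (chrom, pos).

    Parent flags and the susceptible-parent id are preserved in header
    meta lines so a round-trip read restores them.
    """
    sites = matrix.sites.sort_values(["chrom", "pos"], kind="stable")
    samples = list(matrix.calls.index)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sites["chrom"].unique():
        max_pos = int(sites.loc[sites["chrom"] == chrom, "pos"].max())
        lines.append(f"##contig=<ID={chrom},length={max_pos + 1}>")
    if matrix.parent_ids:
        lines.append(f"##parents={','.join(matrix.parent_ids)}")
    if matrix.susceptible_parent_id:
        lines.append(f"##susceptible_parent={matrix.susceptible_parent_id}")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for sid, row in sites.iterrows():
        ref = row["ref"]
        alts = [] if row["alt"] == "." else row["alt"].split(",")
        gts = [_gt_code(matrix.calls.loc[s, sid], ref, alts) for s in samples]
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{sid}\t{ref}\t{row['alt']}"
            "\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only VCF back into a GenotypeMatrix (via pysam)."""
    import pysam

    parent_ids: tuple[str, ...] = ()
    susceptible = None
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf.header.records:
            text = str(rec).strip()
            if text.startswith("##parents="):
                parent_ids = tuple(text.split("=", 1)[1].split(","))
            elif text.startswith("##susceptible_parent="):
                susceptible = text.split("=", 1)[1]
        site_rows = []
        calls: dict[str, list] = {}
        for rec in vf:
            sid = rec.id or f"{rec.chrom}:{rec.pos}"
            alt = ",".join(rec.alts) if rec.alts else "."
            site_rows.append((sid, rec.chrom, rec.pos, rec.ref, alt))
            column = []
            for s in samples:
                alleles = rec.samples[s].alleles
                if alleles is None or any(a is None for a in alleles):
                    column.append(np.nan)
                else:
                    a, b = sorted(alleles)
                    column.append(f"{a}/{b}")
            calls[sid] = column
    sites = pd.DataFrame(site_rows, columns=["site_id", "chrom", "pos", "ref", "alt"]
                         ).set_index("site_id")
    sites.index.name = None
    call_df = pd.DataFrame(calls, index=samples)
    return GenotypeMatrix(calls=call_df, sites=sites, parent_ids=parent_ids,
                          susceptible_parent_id=susceptible)


def write_truth_vcf(path: str | Path, marker_map, geno) -> None:
    """Write simulated truth genotypes as a VCF (marker ids as IDs)."""
    from gbsmap.genotyping import matrix_from_truth

    matrix = matrix_from_truth(geno)
    # keep marker ids as VCF IDs
    id_map = dict(zip(
        [f"{c}:{p}" for c, p in zip(marker_map.table["chrom"], marker_map.table["pos_bp"])],
        marker_map.table["marker_id"],
    ))
    matrix.sites.index = [id_map[s] for s in matrix.sites.index]
    matrix.calls.columns = list(matrix.sites.index)
    write_vcf(path, matrix, source="gbsmap-truth")


# --------------------------------------------------------------- GFF3


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise SchemaError(f"{path}:{lineno}: GFF3 line has {len(fields)} fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise SchemaError(f"{path}:{lineno}: end {end} < start {start}")


def read_gff3(path: str | Path) -> list:
    """Parse single-transcript gene models from a GFF3 file."""
    import gffutils

    from gbsmap.annotation import GeneModel

    path = Path(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        models.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, start=gene.start, end=gene.end,
            strand=gene.strand, exons=tuple(exons), cds=tuple(cds),
        ))
    return models


def write_gff3(path: str | Path, models: Iterable) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        lines.append("\t".join([
            m.chrom, "gbsmap", "gene", str(m.start), str(m.end), ".",
            m.strand, ".", f"ID={m.gene_id}",
        ]))
        mrna = f"{m.gene_id}.t1"
        lines.append("\t".join([
            m.chrom, "gbsmap", "mRNA", str(m.start), str(m.end), ".",
            m.strand, ".", f"ID={mrna};Parent={m.gene_id}",
        ]))
        for i, (s, e) in enumerate(m.exons, start=1):
            lines.append("\t".join([
                m.chrom, "gbsmap", "exon", str(s), str(e), ".", m.strand, ".",
                f"ID={mrna}.exon{i};Parent={mrna}",
            ]))
        for i, (s, e) in enumerate(m.cds, start=1):
            lines.append("\t".join([
                m.chrom, "gbsmap", "CDS", str(s), str(e), ".", m.strand, "0",
                f"ID={mrna}.cds{i};Parent={mrna}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")
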