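"""Gene-annotation summary statistics, windowed density tracks, and
locus interval arithmetic.

Summaries follow single-transcript gene models: the intron count is
exactly the exon count minus the gene count, and total intron length
is total gene length minus total exon length when exons tile genes.
Feature densities are counted in fixed-size windows (50 kb by
default). ``interval_length`` uses the end-minus-start convention of
printed locus spans (not the 1-based inclusive GFF3 length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneModel:
    """One single-transcript gene: 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if len(self.exons) == 0:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene bounds")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e


@dataclass(frozen=True)
class AnnotationSummary:
    """Gene-model statistics (single-transcript assumption).

    Lengths are 1-based inclusive (end - start + 1); means are kept at
    full precision and rounded only on report.
    """

    n_genes: int
    total_gene_length: int
    n_exons: int
    total_exon_length: int
    total_cds_length: int
    n_introns: int
    total_intron_length: int

    @property
    def mean_gene_length(self) -> float:
        return self.total_gene_length / self.n_genes

    @property
    def mean_exons_per_gene(self) -> float:
        return self.n_exons / self.n_genes

    @property
    def mean_introns_per_gene(self) -> float:
        return self.n_introns / self.n_genes

    @classmethod
    def from_counts(cls, n_genes: int, n_exons: int,
                    total_gene_length: int = 0, total_exon_length: int = 0,
                    total_cds_length: int = 0) -> "AnnotationSummary":
        """Derive the summary identities from headline counts.

        For single-transcript models n_introns = n_exons - n_genes and
        total intron length = total gene length - total exon length.
        """
        if n_genes < 1 or n_exons < n_genes:
            raise ValueError("need n_genes >= 1 and n_exons >= n_genes")
        return cls(
            n_genes=n_genes, n_exons=n_exons,
            total_gene_length=total_gene_length,
            total_exon_length=total_exon_length,
            total_cds_length=total_cds_length,
            n_introns=n_exons - n_genes,
            total_intron_length=total_gene_length - total_exon_length,
        )

    def report(self) -> dict[str, float | int]:
        """Table-style report with means rounded to 2 decimals."""
        return {
            "n_genes": self.n_genes,
            "total_gene_length_bp": self.total_gene_length,
            "mean_gene_length": round(self.mean_gene_length, 2),
            "total_exon_length_bp": self.total_exon_length,
            "n_exons": self.n_exons,
            "mean_exons_per_gene": round(self.mean_exons_per_gene, 2),
            "total_cds_length_bp": self.total_cds_length,
            "total_intron_length_bp": self.total_intron_length,
            "n_introns": self.n_introns,
            "mean_introns_per_gene": round(self.mean_introns_per_gene, 2),
        }


def _span(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0] + 1


def summarize_annotation(models: Iterable[GeneModel]) -> AnnotationSummary:
    """Aggregate gene-model statistics over single-transcript models."""
    models = list(models)
    if not models:
        raise ValueError("no gene models")
    n_genes = len(models)
    total_gene = sum(_span((m.start, m.end)) for m in models)
    n_exons = sum(len(m.exons) for m in models)
    total_exon = sum(_span(e) for m in models for e in m.exons)
    total_cds = sum(_span(c) for m in models for c in m.cds)
    return AnnotationSummary(
        n_genes=n_genes,
        total_gene_length=total_gene,
        n_exons=n_exons,
        total_exon_length=total_exon,
        total_cds_length=total_cds,
        n_introns=n_exons - n_genes,
        total_intron_length=total_gene - total_exon,
    )


def windowed_density(features: pd.DataFrame, chrom_lengths: dict[str, int],
                     window_size: int = 50_000) -> pd.DataFrame:
    """Per-window feature counts along each chromosome.

    ``features`` needs ``chrom`` and ``pos`` (1-based start) columns.
    Windows are 0-based half-open tiles of ``window_size``; a feature
    at 1-based position p lands in window floor((p-1)/window_size),
    so position 50,000 is the last base of window 0 and 50,001 starts
    window 1. The trailing partial window is included.

    Returns a DataFrame with chrom, window_start, count covering every
    window of every chromosome (zeros included).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    for c in ("chrom", "pos"):
        if c not in features.columns:
            raise ValueError(f"feature table missing column {c!r}")
    rows = []
    feats = features.groupby("chrom")
    for chrom, length in chrom_lengths.items():
        n_windows = max(1, math.ceil(length / window_size))
        counts = np.zeros(n_windows, dtype=np.int64)
        if chrom in feats.groups:
            pos = feats.get_group(chrom)["pos"].to_numpy()
            if (pos < 1).any() or (pos > length).any():
                bad = pos[(pos < 1) | (pos > length)][0]
                raise ValueError(f"position {bad} outside {chrom} (length {length})")
            idx = (pos - 1) // window_size
            np.add.at(counts, idx, 1)
        for w in range(n_windows):
            rows.append((chrom, w * window_size, int(counts[w])))
    extra = set(features["chrom"]) - set(chrom_lengths)
    if extra:
        raise ValueError(f"features on chromosomes without lengths: {sorted(extra)}")
    return pd.DataFrame(rows, columns=["chrom", "window_start", "count"])


def interval_length(start_bp: int, end_bp: int) -> int:
    """Locus span in the printed end-minus-start convention.

    Deliberately excludes the start base (end - start, not the 1-based
    inclusive end - start + 1): printed spans of locus intervals use
    this convention.
    """
    if end_bp < start_bp:
        raise ValueError(f"end {end_bp} < start {start_bp}")
    return end_bp - start_bp
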