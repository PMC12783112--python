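"""Post-calling site filters and per-site summaries.

A site is kept iff, among called samples (parents excluded by
default): call rate >= 50%, exactly two alleles observed, at least two
distinct genotype classes, minor allele frequency >= 10%, and the
heterozygosity rate lies in [0, 2*p*q + 20%] — a Hardy-Weinberg
expectation plus slack. Allele frequencies come from called genotypes
(two allele draws per called sample), not read counts. Filters are
conjunctive; reason codes report the first failing check in a fixed
order (call_rate, allele_number, genotype_classes, maf, het_range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from gbsmap.config import FilterConfig
from gbsmap.genotyping import GenotypeMatrix

REASON_ORDER = ("call_rate", "allele_number", "genotype_classes", "maf", "het_range")


@dataclass(frozen=True)
class SiteSummary:
    """Per-site call and allele statistics, the filter substrate."""

    site_id: str
    n_samples: int
    n_called: int
    call_rate: float
    alleles: tuple[str, ...]
    p: float  # frequency of first (sorted) allele; NaN if degenerate
    q: float
    n_genotype_classes: int
    maf: float
    het_rate: float

    @property
    def degenerate(self) -> bool:
        return self.n_called == 0


def summarize_site(column: pd.Series, site_id: str = "",
                   exclude: tuple[str, ...] = ()) -> SiteSummary:
    """Summarize one genotype-matrix column of "X/Y" strings (NaN missing).

    ``exclude`` drops flagged samples (parents) from every statistic.
    """
    col = column.drop(index=[s for s in exclude if s in column.index])
    n_samples = len(col)
    called = col.dropna()
    n_called = len(called)
    if n_called == 0:
        return SiteSummary(site_id, n_samples, 0, 0.0, (), math.nan, math.nan, 0,
                           math.nan, math.nan)
    allele_counts: dict[str, int] = {}
    n_het = 0
    classes = set()
    for g in called:
        a, b = g.split("/")
        allele_counts[a] = allele_counts.get(a, 0) + 1
        allele_counts[b] = allele_counts.get(b, 0) + 1
        n_het += a != b
        classes.add(g)
    alleles = tuple(sorted(allele_counts))
    total = 2 * n_called
    p = allele_counts[alleles[0]] / total
    q = 1.0 - p if len(alleles) == 2 else allele_counts[alleles[-1]] / total
    if len(alleles) == 1:
        p, q = 1.0, 0.0
    maf = min(allele_counts[a] / total for a in alleles) if len(alleles) > 1 else 0.0
    return SiteSummary(
        site_id=site_id, n_samples=n_samples, n_called=n_called,
        call_rate=n_called / n_samples if n_samples else 0.0,
        alleles=alleles, p=p, q=q, n_genotype_classes=len(classes),
        maf=maf, het_rate=n_het / n_called,
    )


def het_upper_bound(p: float, q: float, slack: float = 0.20) -> float:
    """Upper bound on the site heterozygosity rate: 2*p*q + slack, capped at 1."""
    if abs(p + q - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1 (got {p} + {q})")
    if p < 0 or q < 0:
        raise ValueError("allele frequencies must be non-negative")
    return min(2.0 * p * q + slack, 1.0)


def summarize_matrix(matrix: GenotypeMatrix,
                     cfg: FilterConfig | None = None) -> list[SiteSummary]:
    cfg = cfg or FilterConfig()
    exclude = matrix.parent_ids if cfg.exclude_parents else ()
    return [summarize_site(matrix.calls[sid], sid, exclude=exclude)
            for sid in matrix.calls.columns]


def apply_site_filters(summaries: list[SiteSummary],
                       cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Evaluate the conjunctive site filters.

    Returns a per-site report DataFrame (index site_id) with columns
    kept, reason (empty when kept), call_rate, maf, het_rate,
    het_bound. Keep/drop is order-independent; only the reported
    reason follows the fixed evaluation order.
    """
    cfg = cfg or FilterConfig()
    rows = []
    for s in summaries:
        reason = ""
        het_bound = math.nan
        if s.call_rate < cfg.min_call_rate:
            reason = "call_rate"
        elif len(s.alleles) != cfg.required_allele_number:
            reason = "allele_number"
        elif s.n_genotype_classes < cfg.min_genotype_classes:
            reason = "genotype_classes"
        elif s.maf < cfg.min_maf:
            reason = "maf"
        else:
            het_bound = het_upper_bound(s.p, s.q, cfg.het_bound_slack)
            if not (0.0 <= s.het_rate <= het_bound):
                reason = "het_range"
        if not reason and len(s.alleles) == 2:
            het_bound = het_upper_bound(s.p, s.q, cfg.het_bound_slack)
        rows.append((s.site_id, reason == "", reason, s.call_rate, s.maf,
                     s.het_rate, het_bound))
    return pd.DataFrame(
        rows, columns=["site_id", "kept", "reason", "call_rate", "maf",
                       "het_rate", "het_bound"],
    ).set_index("site_id")


def filter_matrix(matrix: GenotypeMatrix,
                  cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the site filters to a genotype matrix; return (filtered, report)."""
    report = apply_site_filters(summarize_matrix(matrix, cfg), cfg)
    kept = report.index[report["kept"]]
    return matrix.subset_sites(kept), report


def impute_passthrough(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Imputation placeholder: preserves missing genotypes unchanged.

    The published workflow imputes low-depth genotypes with Beagle; an
    external imputer would slot in here. This stub keeps the pipeline
    shape without altering calls.
    """
    return matrix
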