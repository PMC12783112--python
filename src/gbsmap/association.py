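"""Per-SNP allele-group Wilcoxon rank-sum scan of mean PLL.

For each biallelic SNP with minor allele frequency >= 0.05 among the
tested progeny, the progeny are split into two groups by carrier
status of the allele not carried (homozygously) by the susceptible
reference parent. The two groups' mean-PLL values are compared with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test; the genome-wide
significance threshold is the Bonferroni level
-log10(alpha / number of SNPs tested).

The exact null distribution of the rank-sum statistic (tie-free case,
small groups) is computed by counting k-subsets of ranks by rank sum —
equivalent to enumerating all C(n1+n2, n1) equally likely rank
assignments. Larger or tied samples use the normal approximation with
tie-corrected variance and continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gbsmap.config import ScanConfig
from gbsmap.genotyping import GenotypeMatrix


def bonferroni_threshold(n_snps_tested: int, alpha: float = 0.01) -> float:
    """Genome-wide significance level: -log10(alpha / n tested)."""
    if n_snps_tested < 1:
        raise ValueError("threshold undefined for zero SNPs tested")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-math.log10(alpha / n_snps_tested))


def _rank_sum_counts(n1: int, n_total: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks {1..n_total} with sum s."""
    max_s = n1 * n_total
    ways = np.zeros((n1 + 1, max_s + 1))
    ways[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(n1, 0, -1):  # descending: each rank used once
            ways[k, r:] += ways[k - 1, : max_s + 1 - r]
    return ways[n1]


def exact_rank_sum_p(w: float, n1: int, n2: int) -> float:
    """Exact two-sided p for rank sum ``w`` of group 1 (no ties).

    The null puts equal probability on every C(n1+n2, n1) assignment
    of ranks to group 1; two-sided p = min(1, 2 * smaller tail).
    """
    counts = _rank_sum_counts(n1, n1 + n2)
    total = counts.sum()
    w_int = int(round(w))
    lower = counts[: w_int + 1].sum() / total
    upper = counts[w_int:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _normal_rank_sum_p(w: float, n1: int, n2: int, tie_counts: np.ndarray) -> float:
    """Normal-approximation two-sided p with tie correction and
    continuity correction."""
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    diff = w - mean
    # continuity correction shrinks |diff| by 0.5
    z = (abs(diff) - 0.5) / math.sqrt(var) if abs(diff) > 0.5 else 0.0
    one_sided = float(stats.norm.sf(z))
    return min(1.0, 2.0 * one_sided)


def wilcoxon_rank_sum(values1, values2,
                      cfg: ScanConfig | None = None) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the midrank sum of group 1. The exact null distribution is
    used when both groups have at most ``cfg.exact_max_n`` values and
    the pooled sample is tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    cfg = cfg or ScanConfig()
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    no_ties = bool((tie_counts == 1).all())
    if no_ties and len(x) <= cfg.exact_max_n and len(y) <= cfg.exact_max_n:
        p = exact_rank_sum_p(w, len(x), len(y))
    else:
        p = _normal_rank_sum_p(w, len(x), len(y), tie_counts)
    return w, p


@dataclass(frozen=True)
class AlleleGroups:
    """Progeny split by carrier status of the non-reference allele."""

    group1: tuple[str, ...] = ()  # carriers of the non-reference allele
    group2: tuple[str, ...] = ()
    non_reference_allele: str | None = None
    skip_reason: str | None = None


def group_by_allele(calls: pd.Series, susceptible_parent_call,
                    progeny_ids: list[str]) -> AlleleGroups:
    """Split called progeny into carrier / non-carrier groups.

    The non-reference allele is the allele not carried by the
    susceptible parent, which must be homozygous at the SNP; a
    heterozygous or missing parent call leaves the reference allele
    ambiguous and the SNP is skipped with a reason code.
    """
    pg = susceptible_parent_call
    if not isinstance(pg, str) or pg == "":
        return AlleleGroups(skip_reason="missing_reference")
    ref_a, ref_b = pg.split("/")
    if ref_a != ref_b:
        return AlleleGroups(skip_reason="ambiguous_reference")
    ref = ref_a
    called = calls.loc[[s for s in progeny_ids if s in calls.index]].dropna()
    observed = sorted({a for g in called for a in g.split("/")})
    non_ref = [a for a in observed if a != ref]
    if not non_ref:
        return AlleleGroups(skip_reason="monomorphic")
    if len(non_ref) > 1:
        return AlleleGroups(skip_reason="multiallelic")
    alt = non_ref[0]
    carriers = tuple(s for s, g in called.items() if alt in g.split("/"))
    others = tuple(s for s in called.index if s not in set(carriers))
    if not carriers or not others:
        return AlleleGroups(non_reference_allele=alt,
                            skip_reason="degenerate_groups")
    return AlleleGroups(group1=carriers, group2=others, non_reference_allele=alt)


@dataclass
class ScanResult:
    """Association-scan output: per-SNP table, threshold and bookkeeping."""

    table: pd.DataFrame
    threshold: float
    n_tested: int
    skipped: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_tested == 0


def _progeny_maf(calls: pd.Series) -> float:
    counts: dict[str, int] = {}
    for g in calls.dropna():
        for a in g.split("/"):
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0 or len(counts) < 2:
        return 0.0
    return min(counts.values()) / total


def run_scan(matrix: GenotypeMatrix, pll_means: pd.DataFrame | pd.Series,
             cfg: ScanConfig | None = None) -> ScanResult:
    """Run the per-SNP Wilcoxon scan of mean PLL.

    ``pll_means``: per-genotype mean PLL, a Series or a DataFrame with
    a ``pll_mean`` column (as produced by
    :func:`gbsmap.phenotype.aggregate_pll`). Only progeny present in
    both the matrix and the phenotype table are tested; SNPs with
    MAF < ``cfg.min_maf_scan`` among those progeny are excluded before
    testing, and the Bonferroni threshold uses the count of SNPs
    actually tested.
    """
    cfg = cfg or ScanConfig()
    if isinstance(pll_means, pd.DataFrame):
        if "pll_mean" not in pll_means.columns:
            raise ValueError("phenotype table lacks a pll_mean column")
        pll_means = pll_means["pll_mean"]
    tested_progeny = [s for s in matrix.progeny_ids if s in pll_means.index]
    if not tested_progeny:
        raise ValueError("no phenotyped progeny shared with the genotype matrix")
    pheno = pll_means.loc[tested_progeny]

    parent_id = cfg.susceptible_parent_id
    if parent_id not in matrix.calls.index:
        raise ValueError(f"susceptible parent {parent_id!r} not in genotype matrix")

    rows = []
    skipped: dict[str, int] = {}
    for sid in matrix.calls.columns:
        col = matrix.calls[sid]
        prog_col = col.loc[tested_progeny]
        if _progeny_maf(prog_col) < cfg.min_maf_scan:
            skipped["maf"] = skipped.get("maf", 0) + 1
            continue
        groups = group_by_allele(col, col.loc[parent_id], tested_progeny)
        if groups.skip_reason:
            skipped[groups.skip_reason] = skipped.get(groups.skip_reason, 0) + 1
            continue
        v1 = pheno.loc[list(groups.group1)].to_numpy()
        v2 = pheno.loc[list(groups.group2)].to_numpy()
        w, p = wilcoxon_rank_sum(v1, v2, cfg)
        site = matrix.sites.loc[sid]
        rows.append((sid, site["chrom"], int(site["pos"]), len(v1), len(v2), w, p,
                     float(-math.log10(p)) if p > 0 else math.inf))

    if not rows:
        return ScanResult(
            table=pd.DataFrame(
                columns=["snp_id", "chrom", "pos", "n_group1", "n_group2", "W",
                         "p_value", "neg_log10_p", "significant"]
            ),
            threshold=math.nan, n_tested=0, skipped=skipped,
        )
    table = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "n_group1", "n_group2", "W",
                       "p_value", "neg_log10_p"],
    )
    threshold = bonferroni_threshold(len(table), cfg.alpha)
    table["significant"] = table["neg_log10_p"] >= threshold
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return ScanResult(table=table, threshold=threshold, n_tested=len(table),
                      skipped=skipped)


def manhattan_plot(result: ScanResult, path) -> None:
    """Render the Manhattan plot (-log10 p vs position, threshold dashed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(10, 3.5))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(t.groupby("chrom", sort=True)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, grp["neg_log10_p"], s=8,
                   color="tab:blue" if i % 2 == 0 else "tab:cyan")
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max() + 1
    if not math.isnan(result.threshold):
        ax.axhline(result.threshold, linestyle="--", color="black", linewidth=1)
    ax.set_xticks(ticks, labels, rotation=60, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
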