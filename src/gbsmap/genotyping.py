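"""Two-step tGBS SNP identification and genotype classification.

Step 1 (discovery): per-sample provisional calls identify polymorphic
sites — homozygous needs the top allele supported by >=5 unique reads
and >=80% of aligned reads; heterozygous needs the top two alleles each
supported by >=5 reads and >=30%. A site is polymorphic when at least
two distinct alleles occur across provisional calls.

Step 2 (genotyping): a SNP is homozygous if >=5 reads support the
major allele covering >=90% of reads at the site, heterozygous if two
alleles each have >=2 reads, each is strictly >20% of reads, and
combined they are >=5 reads covering >=90%; anything else is missing.
The homozygous and heterozygous conditions are mutually exclusive
(a minor allele >20% forces the major below 80%), so evaluation order
is cosmetic; homozygous is checked first for determinism.

"Unique reads" is interpreted as distinct read records — there is no
alignment layer here to deduplicate by coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from gbsmap.config import CallerConfig, DiscoveryConfig, ObservationFilterConfig

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

HOM = "HOM"
HET = "HET"
MISSING = "MISSING"


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid call at one site: HOM (1 allele), HET (2), or MISSING."""

    state: str
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = {HOM: 1, HET: 2, MISSING: 0}[self.state]
        if len(self.alleles) != n:
            raise ValueError(f"{self.state} call must carry {n} allele(s)")
        if self.state == HET and self.alleles[0] == self.alleles[1]:
            raise ValueError("HET alleles must be distinct")

    def gt_string(self) -> str:
        if self.state == MISSING:
            return ""
        if self.state == HOM:
            return f"{self.alleles[0]}/{self.alleles[0]}"
        a, b = sorted(self.alleles)
        return f"{a}/{b}"


MISSING_CALL = GenotypeCall(MISSING)


@dataclass
class SiteCounts:
    """Filtered per-sample allele read counts at sites.

    ``counts``: DataFrame indexed by (sample_id, chrom, pos) with one
    integer column per base A/C/G/T. ``n_rejected`` counts observations
    dropped for a non-ACGT allele.
    """

    counts: pd.DataFrame
    n_rejected: int = 0


def filter_observations(obs: pd.DataFrame,
                        cfg: ObservationFilterConfig | None = None) -> SiteCounts:
    """Apply the edge mask and base-quality threshold, then tally alleles.

    Observations within ``edge_mask_bp`` of either read end
    (offset_start <= mask or offset_end <= mask) or with PHRED below
    ``min_phred`` are discarded. Records with a non-ACGT allele are
    rejected with a logged warning count.
    """
    cfg = cfg or ObservationFilterConfig()
    required = ["sample_id", "chrom", "pos", "allele", "offset_start", "offset_end", "phred"]
    missing = [c for c in required if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    if len(obs) == 0:
        index = pd.MultiIndex.from_arrays([[], [], []],
                                          names=["sample_id", "chrom", "pos"])
        return SiteCounts(counts=pd.DataFrame(columns=list(BASES), index=index),
                          n_rejected=0)

    valid_allele = obs["allele"].isin(BASES)
    n_rejected = int((~valid_allele).sum())
    if n_rejected:
        logger.warning("rejected %d observations with non-ACGT alleles", n_rejected)
    keep = (
        valid_allele
        & (obs["offset_start"] > cfg.edge_mask_bp)
        & (obs["offset_end"] > cfg.edge_mask_bp)
        & (obs["phred"] >= cfg.min_phred)
    )
    kept = obs.loc[keep]
    counts = (
        kept.groupby(["sample_id", "chrom", "pos", "allele"], sort=True)
        .size()
        .unstack("allele", fill_value=0)
        .reindex(columns=list(BASES), fill_value=0)
        .astype(np.int64)
    )
    counts.columns.name = None
    return SiteCounts(counts=counts, n_rejected=n_rejected)


def _count_array(counts: pd.DataFrame) -> np.ndarray:
    return counts[list(BASES)].to_numpy(dtype=np.int64)


def _provisional_alleles(arr: np.ndarray, cfg: DiscoveryConfig) -> np.ndarray:
    """Step-1 provisional call per row of a (n, 4) count array.

    Returns an (n, 4) boolean mask of alleles asserted by each
    provisional call (empty row = no call).
    """
    total = arr.sum(axis=1)
    order = np.argsort(arr, axis=1, kind="stable")  # ascending
    top, second = order[:, -1], order[:, -2]
    top_c = np.take_along_axis(arr, top[:, None], axis=1).ravel()
    sec_c = np.take_along_axis(arr, second[:, None], axis=1).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        hom = (top_c >= cfg.hom_min_reads) & (top_c >= cfg.hom_min_fraction * total)
        het = (
            (top_c >= cfg.het_min_reads_each)
            & (sec_c >= cfg.het_min_reads_each)
            & (top_c >= cfg.het_min_fraction_each * total)
            & (sec_c >= cfg.het_min_fraction_each * total)
        )
    het &= ~hom
    mask = np.zeros(arr.shape, dtype=bool)
    rows = np.arange(len(arr))
    mask[rows[hom], top[hom]] = True
    mask[rows[het], top[het]] = True
    mask[rows[het], second[het]] = True
    return mask


def discover_polymorphic_sites(site_counts: SiteCounts,
                               cfg: DiscoveryConfig | None = None) -> set[tuple[str, int]]:
    """Sites where provisional per-sample calls show >=2 distinct alleles."""
    cfg = cfg or DiscoveryConfig()
    counts = site_counts.counts
    if len(counts) == 0:
        return set()
    mask = _provisional_alleles(_count_array(counts), cfg)
    site_index = counts.index.droplevel("sample_id")
    present = pd.DataFrame(mask, columns=list(BASES))
    present["chrom"] = site_index.get_level_values("chrom")
    present["pos"] = site_index.get_level_values("pos")
    per_site = present.groupby(["chrom", "pos"], sort=True)[list(BASES)].any()
    poly = per_site.sum(axis=1) >= 2
    return {(c, int(p)) for (c, p) in per_site.index[poly]}


def call_genotype(counts: Mapping[str, int] | pd.Series,
                  cfg: CallerConfig | None = None) -> GenotypeCall:
    """Classify one sample x site from its filtered allele counts.

    HOM if the major allele has >= 5 reads and >= 90% of the total;
    else HET if the top two alleles each have >= 2 reads, each strictly
    > 20% of the total, and together >= 5 reads covering >= 90%;
    otherwise MISSING (including empty evidence).
    """
    cfg = cfg or CallerConfig()
    items = [(a, int(c)) for a, c in dict(counts).items() if int(c) > 0]
    if not items:
        return MISSING_CALL
    total = sum(c for _, c in items)
    # sort by count desc, allele asc: deterministic and, by the rule's
    # arithmetic, tie-break-invariant (see module docstring).
    items.sort(key=lambda ac: (-ac[1], ac[0]))
    major_a, major_c = items[0]
    if major_c >= cfg.hom_min_reads and major_c >= cfg.hom_min_fraction * total:
        return GenotypeCall(HOM, (major_a,))
    if len(items) >= 2:
        (a1, c1), (a2, c2) = items[0], items[1]
        if (
            c1 >= cfg.het_min_reads_each
            and c2 >= cfg.het_min_reads_each
            and c1 > cfg.het_min_fraction_each_exclusive * total
            and c2 > cfg.het_min_fraction_each_exclusive * total
            and c1 + c2 >= cfg.het_min_combined_reads
            and c1 + c2 >= cfg.het_min_combined_fraction * total
        ):
            return GenotypeCall(HET, (a1, a2))
    return MISSING_CALL


def _call_array(arr: np.ndarray, cfg: CallerConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized caller over an (n, 4) count array.

    Returns (state codes 0=MISSING/1=HOM/2=HET, major allele index,
    second allele index). Equivalent to :func:`call_genotype` row-wise.
    """
    total = arr.sum(axis=1)
    order = np.argsort(arr, axis=1, kind="stable")
    top, second = order[:, -1], order[:, -2]
    c1 = np.take_along_axis(arr, top[:, None], axis=1).ravel()
    c2 = np.take_along_axis(arr, second[:, None], axis=1).ravel()
    hom = (c1 >= cfg.hom_min_reads) & (c1 >= cfg.hom_min_fraction * total) & (total > 0)
    het = (
        ~hom
        & (c1 >= cfg.het_min_reads_each)
        & (c2 >= cfg.het_min_reads_each)
        & (c1 > cfg.het_min_fraction_each_exclusive * total)
        & (c2 > cfg.het_min_fraction_each_exclusive * total)
        & (c1 + c2 >= cfg.het_min_combined_reads)
        & (c1 + c2 >= cfg.het_min_combined_fraction * total)
    )
    state = np.zeros(len(arr), dtype=np.int8)
    state[hom] = 1
    state[het] = 2
    return state, top, second


@dataclass
class GenotypeMatrix:
    """Called genotypes over samples x polymorphic sites.

    ``calls``: DataFrame (index sample_id, columns site ids
    "chrom:pos") of sorted "X/Y" strings, NaN for missing. ``sites``:
    per-site DataFrame with chrom, pos, ref, alt. Parents are ordinary
    rows flagged via ``parent_ids``.
    """

    calls: pd.DataFrame
    sites: pd.DataFrame
    parent_ids: tuple[str, ...] = ()
    susceptible_parent_id: str | None = None

    @property
    def progeny_ids(self) -> list[str]:
        return [s for s in self.calls.index if s not in self.parent_ids]

    def subset_sites(self, site_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = [s for s in self.sites.index if s in set(site_ids)]
        return GenotypeMatrix(
            calls=self.calls[ids],
            sites=self.sites.loc[ids],
            parent_ids=self.parent_ids,
            susceptible_parent_id=self.susceptible_parent_id,
        )


def call_matrix(site_counts: SiteCounts,
                caller_cfg: CallerConfig | None = None,
                discovery_cfg: DiscoveryConfig | None = None,
                samples: Iterable[str] | None = None,
                parent_ids: tuple[str, ...] = (),
                susceptible_parent_id: str | None = None,
                restrict_to_discovered: bool = True) -> GenotypeMatrix:
    """Call genotypes for every sample at every (discovered) site.

    Sites are restricted to the step-1 polymorphic set unless
    ``restrict_to_discovered`` is False. Samples with no reads at a
    site are MISSING. The site table's ref allele follows the
    susceptible parent's homozygous call when available, else the
    lexicographically smallest called allele.
    """
    caller_cfg = caller_cfg or CallerConfig()
    counts = site_counts.counts
    if counts.index.duplicated().any():
        raise ValueError("duplicate (sample, site) count rows")

    if restrict_to_discovered:
        discovered = discover_polymorphic_sites(site_counts, discovery_cfg)
        site_key = list(zip(counts.index.get_level_values("chrom"),
                            counts.index.get_level_values("pos")))
        keep = np.array([k in discovered for k in site_key])
        counts = counts.loc[keep]

    extra = set() if samples is None else set(samples)
    all_samples = sorted(set(counts.index.get_level_values("sample_id")) | extra)
    site_pairs = sorted({(c, int(p)) for c, p in
                         zip(counts.index.get_level_values("chrom"),
                             counts.index.get_level_values("pos"))})
    site_ids = [f"{c}:{p}" for c, p in site_pairs]
    calls = pd.DataFrame(np.nan, index=all_samples, columns=site_ids, dtype=object)

    if len(counts):
        arr = _count_array(counts)
        state, top, second = _call_array(arr, caller_cfg)
        bases = np.array(BASES)
        b1, b2 = bases[top], bases[second]
        lo = np.where(b1 <= b2, b1, b2)
        hi = np.where(b1 <= b2, b2, b1)
        gt = np.where(
            state == 1,
            np.char.add(np.char.add(b1, "/"), b1),
            np.where(state == 2, np.char.add(np.char.add(lo, "/"), hi), ""),
        )
        idx = counts.index
        col = pd.Series(
            [f"{c}:{p}" for c, p in zip(idx.get_level_values("chrom"),
                                        idx.get_level_values("pos"))]
        )
        called = pd.DataFrame({
            "sample_id": idx.get_level_values("sample_id"),
            "site": col.to_numpy(),
            "gt": gt,
        })
        called = called[called["gt"] != ""]
        pivot = called.pivot(index="sample_id", columns="site", values="gt")
        calls.update(pivot)

    sites = pd.DataFrame(
        {"chrom": [c for c, _ in site_pairs], "pos": [p for _, p in site_pairs]},
        index=site_ids,
    )
    refs, alts = [], []
    for sid in site_ids:
        column = calls[sid].dropna()
        observed = sorted({a for g in column for a in g.split("/")})
        ref = None
        if susceptible_parent_id is not None and susceptible_parent_id in calls.index:
            pg = calls.loc[susceptible_parent_id, sid]
            if isinstance(pg, str) and pg[0] == pg[2]:
                ref = pg[0]
        if ref is None:
            ref = observed[0] if observed else "N"
        alt = ",".join(a for a in observed if a != ref) or "."
        refs.append(ref)
        alts.append(alt)
    sites["ref"] = refs
    sites["alt"] = alts
    logger.info("called %d samples x %d sites", len(all_samples), len(site_ids))
    return GenotypeMatrix(calls=calls, sites=sites, parent_ids=tuple(parent_ids),
                          susceptible_parent_id=susceptible_parent_id)


def matrix_from_truth(geno, susceptible_parent_id: str | None = None) -> GenotypeMatrix:
    """GenotypeMatrix view of simulated truth genotypes (perfect calls).

    Useful for analyses of the scan itself, bypassing the read layer.
    """
    t = geno.marker_map.table
    site_ids = [f"{c}:{p}" for c, p in zip(t["chrom"], t["pos_bp"])]
    calls = geno.genotypes.copy()
    calls.columns = site_ids
    sites = pd.DataFrame({"chrom": t["chrom"].to_numpy(), "pos": t["pos_bp"].to_numpy()},
                         index=site_ids)
    refs, alts = [], []
    for mid, sid in zip(t["marker_id"], site_ids):
        p1, p2 = geno.marker_map.parent_alleles(mid)
        observed = sorted(set(p1) | set(p2))
        ref = p1[0] if p1[0] == p1[1] else observed[0]
        refs.append(ref)
        alts.append(",".join(a for a in observed if a != ref) or ".")
    sites["ref"] = refs
    sites["alt"] = alts
    return GenotypeMatrix(calls=calls, sites=sites, parent_ids=geno.parent_ids,
                          susceptible_parent_id=susceptible_parent_id or geno.parent_ids[0])
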