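"""Configuration dataclasses for every pipeline stage.

Defaults encode the published tGBS calling/filtering thresholds and the
study's population structure (119 phenotyped progeny, 17 chromosomes,
two phenotyping years). All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ObservationFilterConfig:
    """Per-base evidence filters applied before allele counting.

    Polymorphisms in the first and last ``edge_mask_bp`` bases of a
    quality-trimmed read are ignored, and bases below PHRED
    ``min_phred`` are discarded.
    """

    edge_mask_bp: int = 3
    min_phred: int = 20

    def __post_init__(self) -> None:
        _check(self.edge_mask_bp >= 0, "edge_mask_bp must be >= 0")
        _check(self.min_phred >= 0, "min_phred must be >= 0")


@dataclass(frozen=True)
class DiscoveryConfig:
    """Step-1 polymorphic-site identification thresholds.

    A provisional homozygous call needs the top allele supported by at
    least ``hom_min_reads`` reads and ``hom_min_fraction`` of aligned
    reads; a provisional heterozygous call needs the top two alleles
    each supported by ``het_min_reads_each`` reads and
    ``het_min_fraction_each`` of aligned reads.
    """

    hom_min_reads: int = 5
    hom_min_fraction: float = 0.80
    het_min_reads_each: int = 5
    het_min_fraction_each: float = 0.30

    def __post_init__(self) -> None:
        for f in (self.hom_min_fraction, self.het_min_fraction_each):
            _check(0 < f <= 1, "fractions must be in (0, 1]")


@dataclass(frozen=True)
class CallerConfig:
    """Step-2 per-sample genotype classification thresholds.

    Homozygous: major allele supported by >= ``hom_min_reads`` reads and
    >= ``hom_min_fraction`` of all reads. Heterozygous: each of two
    alleles supported by >= ``het_min_reads_each`` reads, each strictly
    > ``het_min_fraction_each_exclusive`` of all reads, combined
    >= ``het_min_combined_reads`` reads covering
    >= ``het_min_combined_fraction`` of all reads. Otherwise missing.
    """

    hom_min_reads: int = 5
    hom_min_fraction: float = 0.90
    het_min_reads_each: int = 2
    het_min_fraction_each_exclusive: float = 0.20
    het_min_combined_reads: int = 5
    het_min_combined_fraction: float = 0.90

    def __post_init__(self) -> None:
        for f in (
            self.hom_min_fraction,
            self.het_min_fraction_each_exclusive,
            self.het_min_combined_fraction,
        ):
            _check(0 < f <= 1, "fractions must be in (0, 1]")


@dataclass(frozen=True)
class FilterConfig:
    """Post-calling site filters.

    Keep a site iff call rate >= ``min_call_rate``, exactly
    ``required_allele_number`` alleles among calls, at least
    ``min_genotype_classes`` distinct genotype classes, minor allele
    frequency >= ``min_maf``, and heterozygosity rate within
    [0, 2*p*q + ``het_bound_slack``].
    """

    min_call_rate: float = 0.50
    required_allele_number: int = 2
    min_genotype_classes: int = 2
    min_maf: float = 0.10
    het_bound_slack: float = 0.20
    exclude_parents: bool = True

    def __post_init__(self) -> None:
        for f in (self.min_call_rate, self.min_maf, self.het_bound_slack):
            _check(0 <= f <= 1, "rates must be in [0, 1]")
        _check(self.required_allele_number >= 1, "required_allele_number >= 1")


@dataclass(frozen=True)
class ScanConfig:
    """Association-scan configuration.

    Each SNP with MAF >= ``min_maf_scan`` among tested progeny is
    analysed; the genome-wide threshold is -log10(alpha / n tested).
    ``exact_max_n`` is the largest per-group size at which the exact
    (tie-free) Wilcoxon null distribution is used instead of the
    normal approximation.
    """

    min_maf_scan: float = 0.05
    alpha: float = 0.01
    susceptible_parent_id: str = "Idared"
    exact_max_n: int = 25
    random_seed: int = 0

    def __post_init__(self) -> None:
        _check(0 < self.alpha < 1, "alpha must be in (0, 1)")
        _check(0 <= self.min_maf_scan <= 0.5, "min_maf_scan in [0, 0.5]")


@dataclass(frozen=True)
class SimulationConfig:
    """Synthetic F1-cross generator settings.

    Population defaults mirror the study: 119 phenotyped progeny of a
    susceptible x resistant cross on 17 chromosomes, phenotyped in two
    years with up to five replicates per genotype. Carriers of the
    resistant-parent allele at the QTL have lower mean percent lesion
    length than non-carriers.
    """

    n_progeny: int = 119
    n_chromosomes: int = 17
    markers_per_chromosome: int = 60
    chromosome_length_bp: int = 30_000_000
    cm_per_mb: float = 4.0
    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    base_error_rate: float = 0.005
    read_length: int = 75
    low_phred_fraction: float = 0.05
    qtl_marker_id: str | None = "Chr03_M02"
    qtl_carrier_mean_pll: float = 25.0
    qtl_noncarrier_mean_pll: float = 60.0
    phenotype_sd: float = 15.0
    replicates_per_genotype: int = 5
    years: tuple[int, ...] = (2024, 2025)
    shoot_length_range_mm: tuple[float, float] = (300.0, 700.0)
    missing_shoot_rate: float = 0.05
    parent1_id: str = "Idared"
    parent2_id: str = "Jackii"
    random_seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_progeny >= 2, "n_progeny must be >= 2")
        for r in (self.base_error_rate, self.low_phred_fraction, self.missing_shoot_rate):
            _check(0 <= r <= 1, "rates must be in [0, 1]")
        _check(self.base_error_rate < 0.5, "base_error_rate must be < 0.5")
        for m in (self.qtl_carrier_mean_pll, self.qtl_noncarrier_mean_pll):
            _check(0 <= m <= 100, "PLL means must be in [0, 100]")
        _check(1 <= self.replicates_per_genotype <= 5, "replicates_per_genotype in 1..5")
        _check(self.mean_depth >= 0, "mean_depth must be >= 0")
        _check(self.read_length >= 1, "read_length must be >= 1")


_CONFIG_CLASSES: Mapping[str, type] = {
    "simulation": SimulationConfig,
    "observation_filter": ObservationFilterConfig,
    "discovery": DiscoveryConfig,
    "caller": CallerConfig,
    "site_filter": FilterConfig,
    "scan": ScanConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for the end-to-end pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    observation_filter: ObservationFilterConfig = field(default_factory=ObservationFilterConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    site_filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    seed: int = 0
    output_dir: str = "gbsmap_out"
    # real-data mode: paths to an observation TSV and phenotype CSV;
    # when unset, the pipeline simulates its inputs.
    observations_path: str | None = None
    phenotypes_path: str | None = None

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a nested mapping, rejecting unknown keys."""
        kwargs: dict[str, Any] = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in d.items():
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
            if key in _CONFIG_CLASSES:
                sub_cls = _CONFIG_CLASSES[key]
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                bad = set(value) - sub_known
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                value = dict(value)
                for k, v in value.items():
                    if isinstance(v, list):  # YAML lists -> tuples for frozen configs
                        value[k] = tuple(v)
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d
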