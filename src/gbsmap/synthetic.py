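"""Synthetic F1 biparental cross generator.

Emulates a tunable-GBS experiment on an F1 apple cross between a
susceptible and a resistant parent: biallelic markers segregating from
one or both parents, read-level base observations with sequencing
errors, read-position offsets and PHRED qualities, and a single-QTL
percent-lesion-length (PLL) phenotype with replicate/year structure.

Meiosis follows standard Mendelian segregation with Haldane
recombination (no interference): the recombination fraction between
adjacent markers at map distance d cM is r = (1 - exp(-2d/100)) / 2.
The genetic map is derived from physical positions at a fixed,
configurable cM/Mb rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gbsmap.config import SimulationConfig

BASES = np.array(["A", "C", "G", "T"])
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: Default mix of marker segregation types:
#: hetp1 = ab x aa (segregates from parent 1), hetp2 = aa x ab
#: (segregates from parent 2), both = ab x ab.
SEGREGATION_WEIGHTS = {"hetp1": 0.4, "hetp2": 0.4, "both": 0.2}


@dataclass(frozen=True)
class MarkerMap:
    """Ordered biallelic marker panel with parental genotypes.

    ``table`` columns: marker_id, chrom, pos_bp, pos_cM, parent1_gt,
    parent2_gt (genotypes as sorted "X/Y" strings). Positions are
    strictly increasing within a chromosome and genetic positions are
    non-decreasing with physical positions.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker_id", "chrom", "pos_bp", "pos_cM", "parent1_gt", "parent2_gt"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if t["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        for chrom, grp in t.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing or grp["pos_bp"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")
            if not grp["pos_cM"].is_monotonic_increasing:
                raise ValueError(f"genetic positions decrease on {chrom}")
        for _, row in t.iterrows():
            alleles = set(row.parent1_gt.split("/")) | set(row.parent2_gt.split("/"))
            if len(alleles) != 2:
                raise ValueError(
                    f"marker {row.marker_id} is not biallelic across parents: {sorted(alleles)}"
                )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    def parent_alleles(self, marker_id: str) -> tuple[tuple[str, str], tuple[str, str]]:
        row = self.table.set_index("marker_id").loc[marker_id]
        p1 = tuple(row.parent1_gt.split("/"))
        p2 = tuple(row.parent2_gt.split("/"))
        return p1, p2  # type: ignore[return-value]

    def resistance_allele(self, marker_id: str) -> str:
        """Allele tagging the resistant parent's contribution at a marker.

        The allele unique to parent 2 when exactly one exists, else the
        lexicographically larger parent-2 allele.
        """
        p1, p2 = self.parent_alleles(marker_id)
        unique = sorted(set(p2) - set(p1))
        if len(unique) == 1:
            return unique[0]
        return max(p2)


@dataclass
class F1Genotypes:
    """Truth genotypes of an F1 cross, parents included and flagged.

    ``genotypes``: DataFrame samples x markers of sorted "X/Y" strings
    (no missing values). ``from_parent1`` / ``from_parent2``: the allele
    each progeny inherited from each parent (progeny rows only).
    """

    genotypes: pd.DataFrame
    from_parent1: pd.DataFrame
    from_parent2: pd.DataFrame
    parent_ids: tuple[str, str]
    marker_map: MarkerMap = field(repr=False)

    @property
    def progeny_ids(self) -> list[str]:
        return [s for s in self.genotypes.index if s not in self.parent_ids]

    def carriers(self, qtl_marker_id: str) -> pd.Series:
        """Boolean per progeny: inherited the resistant-parent allele at the QTL."""
        allele = self.marker_map.resistance_allele(qtl_marker_id)
        return self.from_parent2[qtl_marker_id] == allele


def build_marker_map(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    segregation_weights: dict[str, float] | None = None,
) -> MarkerMap:
    """Evenly spaced marker panel with randomized parental genotypes.

    Markers are placed uniformly along each chromosome; genetic
    positions follow from physical positions at ``cfg.cm_per_mb``.
    Segregation types are drawn from ``segregation_weights``; the QTL
    marker (if configured) is forced to segregate from the resistant
    parent only (susceptible parent homozygous), so the resistant
    allele is identifiable in the association scan.
    """
    if cfg.markers_per_chromosome < 1:
        raise ValueError("need at least 1 marker per chromosome")
    rng = np.random.default_rng(cfg.random_seed) if rng is None else rng
    weights = SEGREGATION_WEIGHTS if segregation_weights is None else segregation_weights
    types = list(weights)
    probs = np.array([weights[t] for t in types], dtype=float)
    probs /= probs.sum()

    spacing = cfg.chromosome_length_bp // (cfg.markers_per_chromosome + 1)
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = f"Chr{c:02d}"
        for m in range(1, cfg.markers_per_chromosome + 1):
            pos = spacing * m
            ref, alt = rng.choice(4, size=2, replace=False)
            a, b = BASES[ref], BASES[alt]
            marker_id = f"{chrom}_M{m:02d}"
            seg = types[rng.choice(len(types), p=probs)]
            if cfg.qtl_marker_id is not None and marker_id == cfg.qtl_marker_id:
                seg = "hetp2"
            if seg == "hetp1":
                p1, p2 = f"{min(a,b)}/{max(a,b)}", f"{a}/{a}"
            elif seg == "hetp2":
                p1, p2 = f"{a}/{a}", f"{min(a,b)}/{max(a,b)}"
            else:
                p1 = p2 = f"{min(a,b)}/{max(a,b)}"
            rows.append((marker_id, chrom, pos, pos / 1e6 * cfg.cm_per_mb, p1, p2))
    table = pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos_bp", "pos_cM", "parent1_gt", "parent2_gt"]
    )
    if cfg.qtl_marker_id is not None and cfg.qtl_marker_id not in set(table["marker_id"]):
        raise ValueError(f"qtl_marker_id {cfg.qtl_marker_id!r} not in marker map")
    return MarkerMap(table)


def _gametes(
    alleles: np.ndarray,  # (n_markers, 2) allele strings for one parent
    marker_table: pd.DataFrame,
    n_progeny: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete per progeny per chromosome (Haldane model).

    Returns an (n_progeny, n_markers) array of transmitted alleles.
    """
    out = np.empty((n_progeny, len(marker_table)), dtype=alleles.dtype)
    for _, grp in marker_table.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        d = np.diff(grp["pos_cM"].to_numpy())
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        start = rng.integers(0, 2, size=n_progeny)
        if len(idx) > 1:
            switches = rng.random((n_progeny, len(idx) - 1)) < r
            hap = (start[:, None] + np.concatenate(
                [np.zeros((n_progeny, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
            )) % 2
        else:
            hap = start[:, None]
        out[:, idx] = alleles[idx][np.arange(len(idx)), hap]
    return out


def simulate_cross(marker_map: MarkerMap, cfg: SimulationConfig,
                   rng: np.random.Generator | None = None) -> F1Genotypes:
    """Simulate F1 progeny genotypes by Mendelian segregation.

    Each progeny receives one recombinant gamete per parent per
    chromosome; crossovers between adjacent markers occur with the
    Haldane probability r = (1 - exp(-2d/100))/2 for map distance d cM.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.random_seed) if rng is None else rng
    t = marker_map.table.reset_index(drop=True)
    counts = t.groupby("chrom", sort=False).size()
    if (counts < 1).any() or len(t) == 0:
        raise ValueError("marker map needs at least 1 marker per chromosome")

    p1 = np.array([g.split("/") for g in t["parent1_gt"]])
    p2 = np.array([g.split("/") for g in t["parent2_gt"]])
    g1 = _gametes(p1, t, cfg.n_progeny, rng)
    g2 = _gametes(p2, t, cfg.n_progeny, rng)

    progeny_ids = [f"F1_{i:03d}" for i in range(1, cfg.n_progeny + 1)]
    marker_ids = list(t["marker_id"])
    swap = g1 <= g2
    lo = np.where(swap, g1, g2)
    hi = np.where(swap, g2, g1)
    gt = pd.DataFrame(
        np.char.add(np.char.add(lo.astype(str), "/"), hi.astype(str)),
        index=progeny_ids, columns=marker_ids,
    )
    parent_rows = pd.DataFrame(
        [t["parent1_gt"].to_numpy(), t["parent2_gt"].to_numpy()],
        index=[cfg.parent1_id, cfg.parent2_id], columns=marker_ids,
    )
    genotypes = pd.concat([parent_rows, gt])
    return F1Genotypes(
        genotypes=genotypes,
        from_parent1=pd.DataFrame(g1, index=progeny_ids, columns=marker_ids),
        from_parent2=pd.DataFrame(g2, index=progeny_ids, columns=marker_ids),
        parent_ids=(cfg.parent1_id, cfg.parent2_id),
        marker_map=marker_map,
    )


def simulate_observations(geno: F1Genotypes, cfg: SimulationConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Read-level base observations for every sample x marker.

    Depth per sample x site is negative binomial with mean
    ``mean_depth`` and dispersion ``depth_dispersion`` (Poisson in the
    limit of large dispersion), capturing GBS depth overdispersion.
    Each read reports one of the two true alleles (uniformly), flipped
    to a uniformly chosen other base with probability
    ``base_error_rate``. Read offsets are uniform on [1, read_length];
    PHRED values fall below 20 with probability ``low_phred_fraction``.

    Returns a DataFrame with columns sample_id, chrom, pos, allele,
    offset_start, offset_end, phred, sorted by (sample, chrom, pos).
    """
    rng = np.random.default_rng(cfg.random_seed) if rng is None else rng
    t = geno.marker_map.table.reset_index(drop=True)
    samples = list(geno.genotypes.index)
    n_s, n_m = len(samples), len(t)

    if cfg.mean_depth <= 0:
        depths = np.zeros((n_s, n_m), dtype=np.int64)
    else:
        k = cfg.depth_dispersion
        p = k / (k + cfg.mean_depth)
        depths = rng.negative_binomial(k, p, size=(n_s, n_m))

    total = int(depths.sum())
    flat = depths.ravel()
    cell = np.repeat(np.arange(n_s * n_m), flat)
    s_idx, m_idx = cell // n_m, cell % n_m

    alleles = geno.genotypes.to_numpy()  # "X/Y" strings
    a1 = np.vectorize(lambda g: _BASE_CODE[g[0]])(alleles) if alleles.size else alleles
    a2 = np.vectorize(lambda g: _BASE_CODE[g[2]])(alleles) if alleles.size else alleles
    pick2 = rng.integers(0, 2, size=total).astype(bool)
    code = np.where(pick2, a2[s_idx, m_idx], a1[s_idx, m_idx]).astype(np.int64)
    if cfg.base_error_rate > 0:
        err = rng.random(total) < cfg.base_error_rate
        shift = rng.integers(1, 4, size=total)
        code = np.where(err, (code + shift) % 4, code)

    offset = rng.integers(1, cfg.read_length + 1, size=total)
    low = rng.random(total) < cfg.low_phred_fraction
    phred = np.where(low, rng.integers(2, 20, size=total), rng.integers(20, 41, size=total))

    obs = pd.DataFrame(
        {
            "sample_id": np.asarray(samples, dtype=object)[s_idx],
            "chrom": t["chrom"].to_numpy()[m_idx],
            "pos": t["pos_bp"].to_numpy()[m_idx],
            "allele": BASES[code],
            "offset_start": offset,
            "offset_end": cfg.read_length - offset + 1,
            "phred": phred,
        }
    )
    return obs.sort_values(["sample_id", "chrom", "pos"], kind="stable").reset_index(drop=True)


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator, lo: float = 0.0, hi: float = 100.0) -> np.ndarray:
    """Normal draws truncated to [lo, hi] by rejection (no point masses)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_phenotypes(geno: F1Genotypes, cfg: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Shoot-level fire-blight phenotypes under a single-QTL model.

    Per genotype x year x replicate: shoot length uniform on the
    configured range; PLL normal around the carrier or non-carrier mean
    (truncated to [0,100]); necrosis length = PLL/100 x shoot length.
    Carriers possess at least one allele inherited from the resistant
    parent at the QTL marker. With no QTL configured, every genotype
    uses the non-carrier mean (a null phenotype). Replicates drop out
    with probability ``missing_shoot_rate``.

    Columns: genotype_id, year, replicate, shoot_length_mm,
    necrosis_length_mm.
    """
    rng = np.random.default_rng(cfg.random_seed) if rng is None else rng
    progeny = geno.progeny_ids
    if cfg.qtl_marker_id is not None:
        if cfg.qtl_marker_id not in geno.genotypes.columns:
            raise ValueError(f"qtl_marker_id {cfg.qtl_marker_id!r} not simulated")
        carrier = geno.carriers(cfg.qtl_marker_id)
    else:
        carrier = pd.Series(False, index=progeny)
    # Parents: susceptible parent behaves as a non-carrier, resistant as carrier.
    sample_ids = list(geno.parent_ids) + progeny
    is_carrier = np.array(
        [False, True] + [bool(carrier[p]) for p in progeny]
    )

    n = len(sample_ids)
    reps = cfg.replicates_per_genotype
    rows = []
    for year in cfg.years:
        for rep in range(1, reps + 1):
            keep = rng.random(n) >= cfg.missing_shoot_rate
            shoot = rng.uniform(*cfg.shoot_length_range_mm, size=n)
            means = np.where(is_carrier, cfg.qtl_carrier_mean_pll, cfg.qtl_noncarrier_mean_pll)
            pll = np.empty(n)
            for grp_mean in np.unique(means):
                m = means == grp_mean
                pll[m] = _truncated_normal(float(grp_mean), cfg.phenotype_sd, int(m.sum()), rng)
            for i in np.flatnonzero(keep):
                rows.append(
                    (sample_ids[i], year, rep, round(shoot[i], 2),
                     round(pll[i] / 100.0 * shoot[i], 2))
                )
    return pd.DataFrame(
        rows, columns=["genotype_id", "year", "replicate", "shoot_length_mm", "necrosis_length_mm"]
    )


def simulate_gene_models(n_genes: int, chrom_lengths: dict[str, int],
                         rng: np.random.Generator,
                         mean_exons: float = 5.0) -> list:
    """Small random single-transcript gene models for annotation fixtures.

    Genes are placed uniformly; exon counts are 1 + Poisson(mean_exons - 1);
    exons tile alternating exon/intron blocks so intron identities hold
    exactly. Returns a list of :class:`gbsmap.annotation.GeneModel`.
    """
    from gbsmap.annotation import GeneModel

    chroms = list(chrom_lengths)
    models = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        n_ex = 1 + int(rng.poisson(max(mean_exons - 1.0, 0.0)))
        exon_lens = rng.integers(80, 400, size=n_ex)
        intron_lens = rng.integers(60, 800, size=max(n_ex - 1, 0))
        glen = int(exon_lens.sum() + intron_lens.sum())
        start = int(rng.integers(1, max(chrom_lengths[chrom] - glen, 2)))
        exons = []
        cursor = start
        for j in range(n_ex):
            exons.append((cursor, cursor + int(exon_lens[j]) - 1))
            cursor = exons[-1][1] + 1
            if j < n_ex - 1:
                cursor += int(intron_lens[j])
        models.append(
            GeneModel(
                gene_id=f"g{i + 1:05d}", chrom=chrom, start=start, end=exons[-1][1],
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons), cds=tuple(exons),
            )
        )
    return models


def write_fixtures(directory: str | Path, marker_map: MarkerMap, geno: F1Genotypes,
                   obs: pd.DataFrame, pheno: pd.DataFrame) -> dict[str, Path]:
    """Write the standard fixture files; byte-stable for a fixed seed.

    Emits markers.tsv, observations.tsv, truth.vcf, phenotypes.csv in
    ``directory`` and returns their paths.
    """
    from gbsmap import io as gio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": directory / "markers.tsv",
        "observations": directory / "observations.tsv",
        "truth_vcf": directory / "truth.vcf",
        "phenotypes": directory / "phenotypes.csv",
    }
    marker_map.table.to_csv(paths["markers"], sep="\t", index=False)
    obs.to_csv(paths["observations"], sep="\t", index=False)
    pheno.to_csv(paths["phenotypes"], index=False)
    gio.write_truth_vcf(paths["truth_vcf"], marker_map, geno)
    return paths
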