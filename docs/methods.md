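# Methods

This note documents the models, parameter choices and numerical
decisions behind `gbsmap`, and what the synthetic studies do and do
not demonstrate about real data.

## Genotype calling

Evidence is a table of per-base observations (sample, site, allele,
read offsets from both ends, PHRED quality). Before counting,
observations within `edge_mask_bp` (default 3) of either read end or
below PHRED `min_phred` (default 20) are discarded; non-ACGT records
are rejected with a logged count.

Calling is two-step. *Discovery* makes a provisional per-sample call
(homozygous: top allele ≥5 reads and ≥80% of aligned reads;
heterozygous: top two alleles each ≥5 reads and ≥30%) and keeps sites
where provisional calls disagree (≥2 distinct alleles across
samples). The thresholds are applied per sample; a pooled
interpretation would be an alternative reading and is left
configurable in spirit but not implemented. *Classification* then
calls each sample × site: homozygous if the major allele has ≥5 reads
covering ≥90% of the site's reads; else heterozygous if two alleles
have ≥2 reads each, each strictly >20%, combined ≥5 reads covering
≥90%; else missing.

Two remarks on the rule's arithmetic, both verified exhaustively in
the tests (all count vectors over 3 alleles up to depth 15):

- the homozygous and heterozygous branches are mutually exclusive — a
  minor allele above 20% forces the major below 80%, hence below 90% —
  so evaluation order is cosmetic (homozygous first, fixed for
  determinism);
- ties never make the outcome ambiguous. A tied top pair caps the
  major fraction at 50%, so homozygous cannot fire; a tie *for second
  place* that could affect the heterozygous branch is impossible,
  because coverage ≥90% with a duplicated second count forces the
  minor fraction below 20%. The caller still breaks ties
  deterministically (count desc, allele asc).

"Unique reads" is interpreted as distinct read records: there is no
alignment layer here to deduplicate by mapping coordinates. With real
duplicated libraries the effective thresholds would be slightly more
permissive than with true deduplication.

The VCF REF allele is the susceptible parent's homozygous allele when
available, else the lexicographically smallest observed allele.

## Site filters

Filters consume genotype-level allele frequencies (two draws per
called sample), not read counts, because the heterozygosity bound
2·p·q + slack is a Hardy–Weinberg expectation on genotype
frequencies. Keep iff: call rate ≥ 0.50, exactly 2 alleles among
calls, ≥2 distinct genotype classes, MAF ≥ 0.10, and het rate ≤
2pq + 0.20 (capped at 1). Filters are conjunctive and
order-independent; the reported reason code is the first failure in
the fixed order call_rate → allele_number → genotype_classes → maf →
het_range. Flagged parents are excluded from the statistics by
default. Imputation of low-depth genotypes (done with Beagle in the
workflow this mirrors) is a pass-through stub: missing calls stay
missing, and SNPs whose reference parent is uncalled are later
skipped rather than rescued.

## Phenotype

PLL = 100 × necrosis length / shoot length per shoot. Aggregation is
replicate mean within genotype × year, then the unweighted mean of
the available year means — so unequal replicate counts cannot bias
one year over another; a pooled-shoot mode exists behind a flag.
Genotypes measured in a single year use that year's mean. The
between-year correlation (Pearson by default, Spearman optional) uses
genotypes with both years and requires ≥3 pairs and non-constant
vectors.

## Association scan

SNPs with MAF < 0.05 among phenotyped progeny are excluded before
testing. Grouping uses the susceptible parent as the reference for
the susceptible allele: the non-reference allele is the one the
susceptible parent does not carry, which requires that parent to be
called homozygous; SNPs with a heterozygous or missing reference call
are skipped with a reason code (an optional resistant-parent-oriented
mode was considered and rejected to keep grouping unambiguous).
Group 1 is progeny carrying ≥1 non-reference allele; group 2 the
remaining called progeny; an empty group skips the SNP.

The Wilcoxon rank-sum statistic W is the midrank sum of group 1. When
both groups have ≤ `exact_max_n` (default 25) values and the pooled
sample is tie-free, the p-value comes from the exact null
distribution, computed by counting k-subsets of ranks by rank sum (a
dynamic program equivalent to enumerating all C(n1+n2, n1) equally
likely assignments); two-sided p = min(1, 2 × smaller tail).
Otherwise a normal approximation with tie-corrected variance

    var = n1·n2/12 · [(n+1) − Σ(t³−t)/(n(n−1))]

and a 0.5 continuity correction is used; tests verify exact and
approximate p agree within 0.01 for tie-free groups of 10–20 and that
the implementation matches an independent reference implementation
(scipy's Mann–Whitney U) exactly in both regimes.

The genome-wide threshold is −log₁₀(α/N) with α = 0.01 and N the
number of SNPs actually tested after MAF filtering and grouping —
not the panel size. With zero testable SNPs the scan returns an
explicitly empty result with an undefined threshold.

## Synthetic cross generator

The generator emulates the study design the analysis assumes: an F1
cross between a susceptible parent ('Idared'-like, parent 1) and a
resistant parent (*M. baccata*-like, parent 2), 119 progeny by
default, 17 chromosomes.

- **Marker panel.** 60 markers per 30-Mb chromosome, evenly spaced
  (~0.5 Mb). Segregation types are drawn 40% ab×aa (informative from
  parent 1), 40% aa×ab (from parent 2), 20% ab×ab. Only
  susceptible-parent-homozygous markers (aa×ab) can be oriented by
  the scan, so informative markers sit ~1.2 Mb apart on average —
  deliberately well below the ~2 Mb locality at which the scan is
  expected to localize a locus. (A real tGBS panel of hundreds of
  thousands of SNPs is effectively continuous at that scale; a
  sparser desk-scale panel would misrepresent the mapping resolution
  the method actually has.)
- **Genetic map.** Physical positions convert to genetic positions at
  a fixed 4 cM/Mb. Meiosis is Mendelian with Haldane recombination
  (no interference): r = (1 − e^(−2d/100))/2 between adjacent markers
  at distance d cM, one recombinant gamete per parent per chromosome.
- **Reads.** Depth per sample × site is negative binomial with mean
  20 and dispersion 5, matching the high per-site depths tGBS is
  designed for while keeping GBS-typical overdispersion; with the
  imputation stage stubbed out, depth is also what keeps parental
  reference calls available to the scan. Each read reports one of the
  two true alleles uniformly, flipped to another base with
  probability 0.005; offsets are uniform over the 75-bp read; 5% of
  bases fall below PHRED 20.
- **Phenotype.** Carriers of the resistant-parent allele at the QTL
  (top of chromosome 3 by default) draw PLL from N(25, 15²),
  non-carriers from N(60, 15²), truncated to [0,100] by rejection
  (resampling, so no point mass at the bounds to distort rank tests),
  with up to 5 replicates per genotype over years 2024–2025 and 5%
  missing shoots. Parents are phenotyped too (susceptible as
  non-carrier, resistant as carrier) but excluded from the scan.

What the simulations do **not** model: restriction-site distribution
(marker spacing is even, not fragment-driven), PCR duplicates,
alignment and mapping-quality artefacts, segregation distortion,
multi-locus or polygenic resistance, year × genotype interaction
beyond independent noise, and population structure. Passing the
simulation studies therefore shows the pipeline's statistics behave
correctly under the stated model, not that the thresholds are optimal
for any particular real library.

## Annotation statistics

Gene models are single-transcript with 1-based inclusive coordinates;
summaries report introns = exons − genes and intron length = gene −
exon length (exact identities under that model, asserted on random
synthetic annotations). Windowed density assigns a feature at 1-based
position p to window ⌊(p−1)/w⌋ (the trailing partial window
included), so position 50,000 is the last base of the first 50-kb
window. `interval_length` deliberately returns end − start — the
convention in which printed locus spans such as 598,337–602,501 =
4,164 bp are quoted — rather than the inclusive end − start + 1; the
1 bp discrepancy with GFF3-style lengths is intentional and
documented here.

## Problem sizes and determinism

Simulation-based checks use 20 replicates; null calibration uses a
~2,000-marker QTL-free panel with 119 progeny scanned on truth
genotypes (it probes the test's calibration, not the caller), while
QTL recovery runs the full read-level pipeline (~2.5 M observations
per replicate) at the default scenario. All randomness flows from a
single seed through `numpy.random.Generator`; fixed seeds give
byte-identical fixture files and manifest checksums.
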