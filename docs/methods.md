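# Methods

## The model

`hpscan` detects candidate selective sweeps with a pooled-heterozygosity
scan. At each bi-allelic SNP, a population's genotypes are pooled into a
major-allele count and a minor-allele count (major = the more frequent
allele within that population at that site). Sliding windows sum these
counts over their SNPs and score

    Hp = 2 ΣnMAJ ΣnMIN / (ΣnMAJ + ΣnMIN)²,

algebraically 2p(1−p) with p the pooled major fraction, hence bounded by
[0, 0.5] and invariant to rescaling all counts by a constant. Because
counts are pooled before the quadratic, Hp is close to twice the mean
pooled minor-allele fraction of the window's SNPs — it measures how far
the window's frequency spectrum has collapsed, not per-site heterozygosity
averaged. Hp values of analysed windows are standardised with the
genome-wide mean and standard deviation of one population's scan, giving
Z(Hp); strongly negative windows mark loci where variation has been swept
out.

The method assumes: bi-allelic SNPs from a single joint call per
population; a roughly homogeneous SNP density so the fixed min-SNP filter
is meaningful; and that the genome-wide Hp distribution is dominated by
neutral windows, so its moments are a valid null reference. No linkage or
demographic model enters the statistic.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| window size | 20,000 | bp | standard scale for sweep scans in livestock genomes; wide enough for ≥50 SNPs at ~10 SNPs/kb |
| step | 10,000 | bp | half-window overlap localises region edges to ±10 kb |
| min SNPs / window | 50 | count | windows with few SNPs have noisy Hp; bound inclusive (a 50-SNP window is analysed) |
| Z threshold | −4.0 | SD | fixed conventional cut-off, not an FDR-controlled one; inclusive (Z = −4.0 is significant) |
| max merge gap | 0 | bp | only overlapping/abutting significant windows merge; raising it bridges isolated failed windows for sensitivity analysis |

## Procedure and numerical choices

1. **Windows** start at position 1 and advance by the step; a truncated
   terminal window is emitted only when it is at least one step long and
   extends past the previous window's end, so every chromosome tail is
   covered exactly once and window lists contain no redundant tail windows
   whose span is already covered.
2. **Pooling**: missing alleles are excluded from both counts (the
   denominator reflects observed alleles only); a site with zero called
   alleles in a population is dropped and logged; ties between ref and alt
   counts label the reference allele major (Hp is symmetric, so this only
   fixes labels). Sites monomorphic within one population are retained by
   default — a site fixed in one population but segregating in the joint
   call is precisely the sweep signal — with a switch
   (`drop_monomorphic`) to exclude them.
3. **Filter, then transform**: the min-SNP exclusion is applied before the
   genome-wide mean and SD are computed, so sparse windows do not bias the
   null moments. `filter_before_transform=False` flips the order for
   sensitivity analysis. The SD uses the n−1 (sample) denominator; with
   thousands of windows the choice is numerically immaterial but it is
   fixed and tested (Z-scores re-standardise to mean 0, SD 1 within 1e−9).
   Z is always computed per population, never pooled across populations.
4. **Degenerate inputs** raise distinct errors: no window passing the
   filter, fewer than two passing windows, or zero Hp variance.
5. **Regions**: significant windows (Z ≤ threshold, inclusive) merge when
   the next window starts within `max_gap + 1` bp of the current region
   end. A run of k full windows spans w + (k−1)·s; merging is idempotent
   and conserves the significant-window count. Per-region SNP density
   divides the SNP count by the region's nominal length — the span rounded
   to the nearest 10 kb, in kb — and rounds half-up (`floor(x + 0.5)`),
   matching how such densities are conventionally reported; regions
   shorter than 5 kb (impossible with default windows) fall back to the
   exact span.
6. **Sharing across populations** is decided at window level: the genome
   is partitioned into maximal intervals with a constant set of covering
   populations (significant windows only), so shared coordinates are the
   intersection of the contributing windows, never the union of merged
   regions. With a designated wild population the classes are
   all-domestic+wild, all-domestic, domestic+wild, domestic-pair, unique;
   each interval lands in exactly one class and the table is invariant to
   population order. SNP sharing uses exact (chrom, pos, ref, alt) keys
   and exclusive Venn counts, so inclusion–exclusion identities hold by
   construction.

## The synthetic-data generator

The generator emulates the downstream statistical structure of a pooled
resequencing study, not its sequences: per-population SNP densities of
order 10–20 SNPs/kb, a folded neutral background with minor-allele
frequency uniform on [0.05, 0.5], a few percent missing genotypes, and
planted sweep intervals (tens to hundreds of kb) where minor-allele
frequencies are capped near 0. Defaults — two 5-Mb chromosomes, 10 diploid
samples, 14 SNPs/kb, three sweeps of 40–200 kb with MAF ceiling 0.02, 2 %
missing genotypes — are the fixed study conditions used throughout the
test suite and the acceptance script; 5-Mb chromosomes give ~1,000 windows
while keeping simulation under a few seconds. Each population draws from
its own RNG stream seeded by (master seed, CRC-32 of the label), so adding
a population never perturbs another's data, and populations are "called"
independently (separate site sets), mirroring per-population joint
genotyping. A sweep may be restricted to a subset of populations to
exercise sharing classification.

Deliberate non-realism: sites are i.i.d. (no linkage disequilibrium, no
coalescent genealogy, no recombination map), allele labels are uniform
over {A,C,G,T} with no transition bias, there is no demographic history,
and missingness is independent of genotype. Consequently, passing tests
show that the statistic, filters, merging and sharing logic are computed
correctly and that sweeps of the planted magnitude are recoverable; they
do not show robustness to LD-induced autocorrelation of neighbouring
windows, background selection, or call-rate artefacts in real data. Under
the defaults the genome-mean window Hp lands near 0.37 — inside the
0.25–0.40 band typical of pooled scans of diverse populations, though the
between-window SD is smaller than in real genomes because i.i.d. sites
remove most long-range heterogeneity. One consequence worth knowing: the
genome-wide SD is inflated by the planted sweep windows themselves, so on
very small simulated genomes (≲2 Mb with ≥5 % of the genome swept) sweep
windows may not reach Z ≤ −4; the default conditions keep the swept
fraction near 3 %, where recovery is exact.

## Design choices that were genuinely open

- **Window tail rule**: emitted-if-≥-one-step-and-covering-new-ground was
  chosen over always-emitting, because the latter duplicates coverage of
  chromosome ends with zero-information windows.
- **Moments before or after the SNP filter**: before-filter moments would
  let unanalysed windows shift the null; the default computes them after
  exclusion, with the alternative available as a flag.
- **Monomorphic sites count toward the window SNP filter** by default (see
  above), switchable.
- **Model/Results API**: the scan is exposed as `HpScan(...).fit() ->
  HpScanResults` so windows, moments, region calling, summaries and plots
  hang off one fitted object; module-level functions remain for each stage.

## Problem sizes

Tests run the generator at 2×2 Mb (most fixtures) and 2×5 Mb (recovery
check); the acceptance script uses 2×5 Mb for recovery plus a
four-population 2×2 Mb cohort for sharing — chosen to exercise ~1,000
windows per scan while completing in seconds.

## Known limitations

- The −4.0 cut-off is conventional, not calibrated; no FDR control.
- Hp uses pooled counts, so unequal sample sizes across sites (heavy
  missingness) weight sites unequally within a window.
- Sharing classes presume at most one wild/outgroup population.
- The VCF writer emits minimal GT-only records; it is meant for the
  simulator's output, not as a general-purpose VCF serialiser.
- Real-data concerns out of scope here: alignment, variant calling and
  quality filtering are assumed done upstream; sex chromosomes should be
  excluded via the chromosome whitelist.
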