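# Methods

## The mapping problem

Two pools ("bulks") of individuals are formed from the phenotypic extremes
of a segregating population and sequenced together.  At a marker unlinked
to the trait, both bulks are random draws from the same population, so
their alternate-allele read fractions differ only by sampling noise: the
composition of the finite pool, and binomial read sampling at finite
depth.  Near a trait-linked locus the extremes are enriched for opposite
alleles and the bulks' frequencies diverge.  `bsrmap` quantifies that
divergence per marker with three statistics, calibrates each against an
explicit null, and reports the genomic intersection of the three methods'
significant intervals as candidate regions.

## Sampling model (and the synthetic generator)

The generator implements exactly the null the thresholds assume, plus
planted deviations:

1. **Pool composition.**  Each bulk pools `n_per_bulk` individuals
   (default 42).  At a locus with expected alternate-allele frequency *p*,
   individual dosages are Binomial(2, *p*) for `F2` (1:2:1 at a null F2
   locus, *p* = 1/2) and `NATURAL` (Hardy–Weinberg at
   `background_alt_freq`), or 2·Bernoulli(*p*) for `RIL` (no
   heterozygotes).  The pooled frequency is the mean dosage / 2; summing
   i.i.d. individual dosages makes this a single Binomial(2n, *p*) (or
   Binomial(n, *p*)) draw.
2. **Read sampling.**  Per bulk, alternate depth ~ Binomial(depth, pooled
   frequency); depth is uniform on a configurable integer range (default
   20–100×, chosen so the 10–500× marker filter is normally passed, with
   optional contamination fractions at out-of-range depths to exercise
   it).
3. **Planted QTLs.**  A QTL shifts the two bulks' true frequencies to
   `p₀ ± delta_af/2` (clipped to [0, 1]), either constant across the
   region (`block`) or tapering linearly from the midpoint (`triangular`).
   `delta_af = 0.4` at 60× with 42 individuals per bulk is a strong but
   not dominant signal: the null 95% Δ band under those conditions is
   roughly ±0.24.
4. **Caller annotations.**  Passing sites get QD=20, FS=10, MQ=60, GQ=60;
   a configurable fraction receives failing values (one metric each) so
   the hard filters have work to do.  A small fraction of markers
   (default 5%) is emitted as 1-bp insertions to exercise per-class
   reporting.

All randomness derives from one seed through per-linkage-group
`SeedSequence` children, so identical seeds give byte-identical VCFs.

What the generator does **not** emulate: linkage/recombination structure
along chromosomes (marker frequencies are drawn independently given the
truth profile), alignment and calling artefacts (error reads, strand
bias, mapping ambiguity), or overdispersion beyond binomial sampling.
Passing recovery tests therefore demonstrate correctness of the
statistics and calibration under the stated sampling model, not
robustness to real-data artefacts.

## Filters

Order is fixed and each record is attributed to its first failing stage:
site metrics (`QD < 4`, `FS > 60`, `MQ < 40`; a missing metric passes,
since callers emit these only where computable), the cluster filter
(every variant in a run of ≥ 3 variants spanning ≤ 4 bp, the GATK
clustered-variant reading with both parameters exposed), missing
genotypes (a bulk with GQ < 20 or zero depth counts as missing), per-bulk
depth outside [10, 500] (inclusive), and the near-monomorphic rule.  The
monomorphic rule excludes markers where **both** bulks' SNP-index is
< 0.3 or both > 0.7: the both-bulk reading removes uninformative markers
while keeping exactly the divergent ones (e.g. indices 0.1 and 0.8) that
an either-bulk reading would discard.

Multiallelic sites are dropped by default (all statistics are biallelic);
a `split` policy that decomposes each ALT against REF is available.

## Statistics and thresholds

**Δ(SNP-index).**  SNP-index per bulk is the alternate read fraction;
Δ is high-bulk minus low-bulk.  Which pool is "high" is configuration
(the bulk-role mapping), not inference, so the sign of Δ is a labelling
convention.  The null band is simulated: 10,000 replicates per depth of
pool composition + read sampling, central type-1 quantile intervals at
95% and 99%.  Bands are simulated on a small depth grid (6 points
spanning the observed per-marker mean depths) and interpolated linearly
in depth, clamped at the grid ends; each marker is compared against the
band at its own mean bulk depth.

**G′.**  G is the 2×2 likelihood-ratio statistic on (ref, alt) × (bulk
high, bulk low) depths, with independence expectations; a zero row or
column total gives G = 0 (no information).  G is smoothed along each
linkage group with a tricube kernel, `w = (1 − (d/D)³)³` over
`|d| ≤ D` (default half-width D = 1 Mb — candidate regions of interest
are of Mb scale, and at 40–160 markers/Mb this averages enough neighbours
to stabilise the null while keeping 3-Mb signals sharp).  The null for
G′ is fitted from the data itself: ln G′ is trimmed by the Hampel rule
(median ± 3 × 1.4826 × MAD), a normal distribution is fitted to the
retained values (i.e. a log-normal null for G′, robust to the very
signal peaks being tested), and upper-tail p-values are BH-corrected;
q < 0.05 (95% level) or q < 0.01 (99%).  The upper tail is used because
divergence inflates G one-sidedly.  Markers with G′ = 0 are excluded
from the fit and assigned p = 1.

**ED⁵.**  ED is the Euclidean distance between the bulks' (alt, ref)
frequency vectors, which reduces to √2·|Δalt| and is therefore
depth-free; the fifth power suppresses background noise relative to
signal.  The threshold is the genome-wide empirical 95%/99% quantile of
the observed (smoothed) ED⁵ values.  A raw-depth ED variant
(`ed_mode="depth"`), which confounds coverage with divergence, exists
for strict replication of counts-based workflows but is never the
default.

Δ and ED⁵ are by default tricube-smoothed with the same kernel before
thresholding (configurable off): per-marker values at realistic depths
are too noisy to form contiguous intervals.  The Δ band is simulated for
raw per-marker nulls, so comparing smoothed Δ against it is conservative
for nulls while leaving block signals (whose smoothed value equals the
raw plateau) untouched.

**Both confidence levels are always computed.**  Published practice
mixes 95% and 99% lines per method; here all methods get both, and the
level used for the final intersection is a single parameter
(default 0.95, the level at which a three-way intersection is typically
non-empty).

## Regions

Significant markers ≤ `merge_gap` apart (default 500 kb, a compromise
between marker sparsity and region separation; recorded in outputs) form
one interval bounded by its first/last significant marker.  The final
regions are maximal intervals covered by ≥ `min_methods` (default 3) of
the three interval sets, computed by a boundary sweep; coordinates are
1-based inclusive and length in Mb is `(end − start + 1)/1e6` rounded to
two decimals.  Intersection is order-independent and idempotent, and its
coverage is contained in every supporting method's coverage.

## Annotation

Genes overlap a region if they share ≥ 1 bp.  Coding effects: the
substitution is located in the spliced CDS (reverse-complemented for
minus-strand genes; input alleles are on the forward genome strand as in
a VCF), the codon is rewritten and translated with the standard genetic
code only — appropriate for vertebrate nuclear genes.  Enrichment is the
upper-tail hypergeometric probability of observing ≥ k term carriers in
the candidate set, BH-corrected across terms; the background defaults to
all genes in the annotation.

## Numerical and design choices

- Quantiles are empirical inverse-CDF (type 1) everywhere, stated in
  output metadata, for cross-implementation reproducibility.
- The trimmed-null fit declares degeneracy (and raises) when the trimmed
  standard deviation is ≤ 1e-12 relative — all-equal inputs would
  otherwise produce p-values from float residue.
- The SNP-index band lookup uses the mean of the two bulks' depths; the
  delta-band width varies slowly enough in depth that the choice of mean
  versus min changes bands by less than Monte-Carlo error at the default
  grid.
- Boundary semantics: filter thresholds follow the filter expressions
  strictly (QD = 4.0 passes, depth 10 and 500 pass); ED⁵ exceedance and
  band exceedance are strict inequalities.
- Tie-breaks: the tricube weight at exactly d = D is 0, so window
  inclusion at the boundary is harmless; a marker always carries weight
  1 on itself, so smoothing is defined for isolated markers.

## Problem sizes in the test and acceptance studies

Null calibration uses 10,000 simulated replicates and 10,000 fresh null
markers at 60× / 42-per-bulk.  The parameter-recovery study uses 20
seeded genomes of 24 linkage groups × 2,000 markers (48,000 markers,
25 Mb per linkage group) with one planted 3-Mb, Δaf = 0.4 QTL, plus 20
matched null genomes checked for an empty 99%-level region table.  These
sizes give binomial standard errors comfortably inside the stated
tolerances while a full study completes in minutes on one core.

## Known limitations

- No linkage disequilibrium between markers in the generator: null
  calibration is exact for independent markers, slightly conservative
  for correlated ones after smoothing.
- The G′ null is fitted genome-wide, assuming the non-QTL fraction of
  the genome dominates; a genome that is mostly signal would inflate the
  fitted null.
- Two bulks only; multi-pool designs and haplotype-aware statistics are
  out of scope.
- Enrichment treats genes as exchangeable (no gene-length or expression
  bias correction).
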