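# Methods

`evoenrich` tests whether a set of evolutionary genomic annotations —
interval-based regions such as differentially methylated regions (DMRs)
between modern and archaic humans or human accelerated regions (HARs), and
marker-based lists such as Neanderthal selective-sweep (NSS) scores — is
enriched for association with a complex trait, using only GWAS summary
statistics and a pairwise-r² LD reference.  Two complementary readouts are
implemented: a genomic-control-corrected stratified QQ comparison at the SNP
level, and an interval-permutation gene-set test at the gene level.

## SNP-to-annotation assignment

GWAS positions are 1-based; all intervals are 0-based half-open (BED).  The
single conversion point is interval lookup: a SNP at position `pos` belongs
to `[start, end)` iff `start <= pos-1 < end`.

*Positional binning* assigns a SNP to every interval containing it.
*LD binning* additionally assigns any GWAS SNP with r² ≥ `r2_min` to a SNP
located inside the interval (for marker lists, to a seed marker).  This
recovers annotation signal when the interval's own SNPs were not genotyped
in a particular GWAS.  Because the r² relation contains implicit self-pairs,
LD assignment is always a superset of positional assignment, and lowering
`r2_min` can only grow it; both laws are enforced by tests.  The default
`r2_min = 0.8` is the conventional proxy-SNP cutoff; the threshold the
original LDsnpR-based analyses used is not published, so it is an explicit
parameter rather than a claim.

Standard GWAS hygiene filters are provided as explicit, commuting
operations: masking the extended MHC (chr6:25–35 Mb, long-range LD),
excluding SNPs with MAF < 0.05 (missing MAF conservatively fails the
filter), restricting to markers shared across studies, and keeping only
strictly negative NSS scores (the sign convention for positive selection in
modern humans; zero scores are excluded).

## Stratified QQ with genomic control

Genomic inflation is measured by λ_GC = median(χ²)/0.45494, the median
association χ² (1 df, from two-sided p) over the null median.  Correction
divides each SNP's χ² by the *global* λ estimated from all (masked,
filtered) GWAS SNPs and maps back through the χ²₁ upper tail; the same
global λ is applied to any SNP subset, so subset and full-GWAS curves are
directly comparable and the full-curve median is pinned to the null line.
λ is computed on the post-mask SNP set; the pre-mask value is also reported.

QQ curves plot sorted −log₁₀ corrected p against Hazen plotting positions
−log₁₀((i−0.5)/n).  Hazen positions are standard GWAS practice and
symmetric; the choice matters only at the extreme ranks.  Corrected
p-values are floored at 1e-300 before the log transform.  Two
machine-readable summaries replace the visual judgement of a plotted
deflection: (a) `crosses_gws` — whether any corrected subset p falls below
5×10⁻⁸ — and (b) the observed−expected gap evaluated at expected quantiles
1..5, reported as the curve's "deflection".  Both are this package's own
quantification of what is otherwise read off a figure.

## Interval-permutation gene-set test

The gene-level test re-implements the contract of interval enrichment
analysis (INRICH-style); it does not wrap or byte-match the original C++
tool.

1. **Interval derivation.**  Greedy p-ordered clumping: the unclaimed SNP
   with the smallest p ≤ threshold seeds an interval, claiming all
   same-chromosome SNPs with r² ≥ `r2_clump` (default 0.5); the interval
   spans the claimed SNPs (half-open, +1).  Ties in p break by (chrom, pos),
   making derivation deterministic.  The clumping parameters behind the
   original publication's figures are not printed there; its exact intervals
   are therefore not reconstructible and are not treated as reference
   values.
2. **Observed statistic.**  k = number of derived intervals overlapping at
   least one gene-set span (counted once however many genes are hit).
3. **Relocation null.**  Each replicate independently relocates every
   interval to a uniformly chosen placement spanning the same *number of
   consecutive GWAS SNPs* (SNP density preserved exactly, by construction).
   With gene-density matching on (default), placements whose total-gene
   count differs from the original interval's by more than ±1 are redrawn up
   to 100 times, then accepted — an explicit approximation to the original
   tool's stated matching contract, not a reproduction of its source.
   Empirical p = (1 + #{null k ≥ observed k})/(n_perm + 1): never zero, and
   ties favour the null.
4. **Bootstrap correction.**  Across the threshold grid (default 1e-8,
   1e-6, 1e-4, 1e-3, 0.01), each bootstrap replicate draws one null count
   per threshold, converts it to its empirical p, and records the minimum
   across thresholds; the corrected p of a threshold is the fraction of
   replicates whose minimum is ≤ its observed empirical p.  The corrected p
   is floored at the empirical p so correction never increases
   significance.  With a single threshold this is the identity up to Monte
   Carlo error; for two independent thresholds it converges to the Šidák
   limit 1−(1−α)², which is verified against the closed form.

Enrichment is declared when any threshold's corrected p < 0.05.  All
randomness flows from one seed through spawned generator streams, so a
fixed seed reproduces the report byte for byte.  Reference-scale runs use
n_perm = 10,000 and n_boot = 5,000; the calibration experiments in the test
suite and acceptance script use n_perm = 500 and n_boot = 200 over hundreds
of replicate datasets, which bounds the attainable empirical p at ~2×10⁻³ —
ample for a 0.05 decision — while keeping 500-dataset calibration runs to
about a minute.

## Enriched regions and gene lists

A region is "enriched" when ≥ 1 assigned SNP (LD-expanded membership when
available) has GC-corrected p ≤ the cutoff (default 5×10⁻⁸, boundary
inclusive; the cutoff behind published enriched-region counts is not
stated, so those counts are not comparison targets).  Regions map to genes
two ways, reported separately: *direct* genes whose span (± `flank_bp`,
default 0) overlaps an enriched region, and *LD-linked* genes containing a
SNP with r² ≥ `r2_min` to an enriched SNP — an r²-threshold approximation
to LD-block gene assignment.

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
consumes, not population-genetic realism:

- **Genome**: 4 chromosomes × 2,500 SNPs (10k SNPs) at ~1 kb spacing by
  default; positions strictly increasing.
- **LD**: idealized constant-r² blocks of 10 consecutive SNPs at r² = 0.9.
  The analysis consumes only an r² relation, and constant blocks make every
  LD oracle exact; no coalescent simulation is attempted.
- **Null association**: z ~ N(0,1)·√λ_true, p two-sided, so p-values are
  uniform at λ_true = 1 and λ_GC scales as designed.
- **Planted signal**: a fraction (default 10%) of the 20 target intervals
  receives z with mean δ, giving mean χ² = 1 + δ² in signal SNPs (checked
  against the noncentral-χ² moment).  A disjoint control annotation of equal
  size carries no signal.
- **Intervals** hold 16 SNPs each, placed without overlap uniformly over SNP
  index space so per-interval SNP counts are controlled (the permutation
  test's density matching needs this).  16 SNPs per region reflects the
  per-region SNP count of enriched methylation-difference regions in the
  motivating analysis (≈ 5,338 SNPs / 329 regions).
- **Genes**: one transcript containing each interval (± 2–5 kb) plus 30
  random background genes, so "genes containing the annotation" is always a
  well-defined gene set.
- `plant_missingness` removes a random fraction of target-interval SNPs
  from the GWAS (not the LD store), reproducing the situation LD binning
  exists for.

What passing tests on this generator do **not** show: behaviour under
realistic allele-frequency spectra, variable LD decay, population
stratification, or imputation noise.  The generator's λ is exact by
construction; real GWAS inflation mixes polygenicity with confounding that
genomic control cannot separate.

## Numerical and design choices

- p-values are validated into (0, 1]; p = 0 rows are rejected at parse time.
- χ² ↔ p conversions go through `scipy.stats.chi2` (`isf`/`sf`), which is
  stable to p = 1e-300; corrected p is floored there before logs.
- Chromosome names are normalised to `chr`-prefixed form at every reader.
- Duplicate LD pairs keep the larger r²; self-pairs are implicit (r² = 1).
- Overlapping annotation intervals list a SNP under each containing
  interval but count it once in the assigned set.
- Genic context precedence when transcripts disagree: 5'UTR > 3'UTR > exon
  > intron; UTRs are exonic sequence outside the CDS, oriented by strand;
  non-coding transcripts contribute "exon" calls for exonic positions.
- The pipeline writes no timestamps; every table carries the config hash
  and seed, so identical configs give identical checksums (re-running a
  stage is a checksum no-op).

## Known limitations

- The expected per-region detection probability at genome-wide stringency
  is 1−(1−q)^m for m SNPs per region, with q = Φ(δ−5.451)+Φ(−δ−5.451);
  at δ = 4 and m = 16 this is ≈ 0.70.  Region-level recall at 5×10⁻⁸ is
  therefore intrinsically limited by region SNP density, not by the
  implementation — denser regions or stronger signal are needed for
  near-complete recovery.
- Gene-density matching is approximate (±1 with capped retries); the exact
  matching scheme of the original interval-enrichment tool is unspecified.
- LD binning needs positions for LD-reference SNPs absent from the GWAS
  (`extra_positions`); without them such seeds are invisible.
- liftOver/genome-build conversion is out of scope: all inputs must share
  one build.  Pathway scoring over the produced gene lists is external.
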