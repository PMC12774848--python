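# Methods

## The mapping problem and the statistic

`cosegmap` localizes the locus of a monogenic recessive trait from four
whole-genome sequencing libraries of one family: a homozygous-mutant parent,
a heterozygous parent, a pool of homozygous-phenotype offspring, and a pool
of heterozygous (normal-phenotype) offspring.  Each library — including each
pool — is genotyped as a single diploid sample.

A biallelic variant is **informative** when it passes quality filters, lies
outside the repeat mask, and its parental genotypes already match the
pattern forced by the breeding design: homozygous in the homozygous parent
and heterozygous in the heterozygous parent.  An informative variant
**co-segregates** when the offspring pools show the same pattern —
homozygous call in the homozygous pool, heterozygous call in the
heterozygous pool.  Under the default orientation the reference genome is
wild-type, so "homozygous" means homozygous-ALT; an `AUTO` orientation
additionally accepts the mirrored pattern (homozygous-REF in the homozygous
libraries) for assemblies whose reference individual carries the mutant
allele, and the two orientations are tallied separately.

The scan statistic is the proportion of informative variants that
co-segregate, computed in sliding windows:

* genome-wide tier: 1 Mb windows advanced in 100 kb steps, SNP/MNP
  substitutions only, scaffolds longer than 1 Mb, windows anchored at
  position 0 with the final partial window kept and flagged truncated;
* fine tier: 200 kb windows, 50 kb steps over one region, with indels
  also counted.

Windows holding zero informative variants are *undefined* and never enter
peak calling: 0/0 is not evidence.  Missing pool genotypes keep a variant in
the denominator but never count as co-segregating (conservative
denominator); a missing parental genotype makes the site uninformative.

Only in the neighbourhood of the causal locus does phenotype sorting
guarantee transmission of the linked parental haplotype to the matching
pool, so the co-segregation proportion peaks there and decays with genetic
distance at the rate set by recombination.

## Peak calling and triage

Windows at or above a proportion cutoff are merged when they overlap or are
adjacent; each merged interval's co-segregating count is recounted over its
final span rather than summed over overlapping windows.  The default cutoff
is `max(0.5, 0.95 x p99)` where `p99` is the 99th percentile of defined
window proportions.  The percentile adapts the cutoff to the data's noise
level (observed interval minima in real crosses vary from ~69% to ~99.6%
with the peak height).  The 0.95 softening exists because window
proportions are discrete: with on the order of 10^2 informative markers per
window, a single miscalled pooled genotype moves a window by ~1%, and a
cutoff equal to the top percentile would carve a contiguous peak plateau
into fragments around individual miscalls.  Five percent of relative slack
covers several miscalls per window while still rejecting windows that have
genuinely decayed by recombination.

Merged intervals supported by fewer than `min_interval_coseg = 100`
co-segregating variants are reported but flagged *disregarded*: genuine
peaks at desk or genome scale carry hundreds to thousands of supporting
variants while spurious ones carry a handful, and 100 separates the two
regimes by roughly an order of magnitude on each side.  Surviving intervals
are ranked by maximum window proportion, then total co-segregating count,
then scaffold order (longest first) and start position.

Interval metrics follow reporting conventions: width in Mb rounded
half-up to 0.1 Mb, and density as co-segregating variants per Mb of covered
width rounded half-up to an integer.  Split intervals (two high blocks
flanking a low-co-segregation gap) are measured over the union of their
parts.

## Consequence annotation

A minimal codon-level annotator covers the variant classes the scan feeds
it: SNV and MNP substitutions against the canonical transcript (longest
total CDS; ties broken by the lexicographically smallest transcript ID) of
each overlapping gene.  The affected codon(s) are extracted strand-aware
from the spliced CDS, translated with the standard genetic code, and
classified as synonymous, missense, stop_gained, stop_lost, start_lost,
splice_site_proximal (within 2 bp of an exon boundary inside an intron, or
any substitution spanning an exon/intron boundary, which gets no codon
call), or non_coding.  MNPs are decomposed codon-wise and report the most
severe class, ties resolved toward the 5' codon.  Codon changes are
reported in the RNA alphabet ("UGG->UAG") as is conventional for nonsense
variants; protein position equals the 1-based codon index.  Indels
overlapping CDS are reported as `indel_in_CDS` with no protein-level
detail.  A REF allele that disagrees with the genome sequence is a hard
error, since it indicates a coordinate-system fault rather than a data
artifact.

Candidate triage ranks high-impact calls (premature stops, start/stop
losses, splice-proximal, CDS indels) ahead of missense, ahead of
synonymous/non-coding, with positional tie-breaks; an externally produced
differential-expression table can be joined per gene.  Alignment-column
conservation follows the Clustal convention: `*` when all non-gap residues
are identical, `:` when they all fall in one strong similarity group (STA,
NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW), blank otherwise; an all-gap
column is variable.

## The cross simulator

The simulator generates exactly the structure the scan assumes, nothing
more:

1. **Founders.**  Two parental lineages; the mutant-lineage haplotype
   carries the causal allele and, at a configurable fraction of markers
   (default 0.7), a linked alternate allele.  The remaining markers receive
   one of several uninformative parental patterns.  Marker positions are
   Poisson with density 200/Mb by default; the causal site is always a
   marker.
2. **Meiosis.**  Gametes receive a haplotype mosaic with Poisson
   (interference-free) crossovers at uniform positions, so recombinant
   fractions follow the Haldane map exactly and closed-form expectations
   are available for calibration tests.
3. **Phenotype sorting.**  Offspring are drawn until both pools hold
   `n_offspring` members (default 10): homozygous-causal offspring enter
   the homozygous pool, heterozygous the heterozygous pool; in the
   HETxHET design homozygous wild-type offspring are discarded, as they
   would be in a real recessive-phenotype cross.  An unfillable pool is an
   error after a generous draw cap.
4. **Pooled genotyping.**  Each pool is one diploid-like sample.  Per
   marker, depth is Poisson (mean 30), alternate reads are binomial around
   the true pooled allele fraction folded with a symmetric per-base error
   (default 0.005), and a threshold caller assigns HOM when the major read
   fraction is at least `f_hom = 0.9`, HET when the minor fraction is at
   least `f_het = 0.25`, MISSING otherwise (or at zero depth).  This
   threshold caller stands in for a variant caller's behaviour on pooled
   libraries.  An `analytic_calls` mode applies the thresholds to the exact
   pooled fraction (infinite-depth limit), making calls a deterministic
   function of recombinant counts — the basis of the closed-form
   co-segregation probability used in calibration tests.
5. **Parents** are genotyped error-free by default (configurable through
   the same read model).

A `ref_is_mutant_fraction` option flips REF/ALT labels at a random subset
of markers to emulate mapping against an assembly whose reference
individual carries the mutant haplotype; the `AUTO` scan orientation
recovers these sites.

**Genetic scale.**  The default desk genome is 3 scaffolds x 10 Mb at
10 cM/Mb.  Each scaffold stands in for a chromosome, and what meiosis
conserves is genetic length per chromosome (roughly 50–100 cM for typical
vertebrate chromosomes), not genetic length per Mb; scaling a ~100 Mb
chromosome down to 10 Mb therefore multiplies the per-Mb rate tenfold.  At
this scale linkage decays across a scaffold the way it decays across a real
chromosome, unlinked scaffolds behave as independent chromosomes, and one
simulated cross takes well under a second.

**Fixtures.**  `make_fixture_suite` writes a byte-reproducible FASTA + VCF +
BED + GFF3 + truth-JSON set.  The genome is random sequence whose base at
every marker equals the REF allele; three synthetic genes straddle the
causal locus.  The causal gene lies on the minus strand with a tryptophan
(TGG) codon whose middle base is the causal site, so the genomic C→T
substitution reads G→A on the coding strand and converts UGG to the UAG
stop — the geometry of a real nonsense variant reported as "C-to-T changing
UGG to UAG".  A plus-strand gene and a second minus-strand gene provide
strand coverage.  Random repeat-mask intervals cover ~5% of the genome but
never the fixture genes, since planted coding variants must remain
discoverable (as real causal coding variants, which sit outside repeat
annotations, do).

## What the simulator does and does not emulate

It reproduces the family structure, linked founder haplotypes, phenotype
sorting, finite pooled depth and per-base error — the features that drive
the statistic's signal and noise.  It does not model read-level artifacts
(mapping bias, duplicated repeats, indel realignment), variant-caller
idiosyncrasies beyond the threshold rule, crossover interference, or
segregation distortion.  Passing tests therefore demonstrate that the scan
recovers a causal interval when its statistical assumptions hold; they do
not certify behaviour under alignment artifacts that a repeat mask fails to
remove.

## Numerical and procedural choices

* Internal coordinates are 0-based half-open; all reported coordinates are
  1-based inclusive (VCF/GFF3 convention).
* Phased genotypes are treated as unphased; phase is irrelevant to the
  statistic.
* Records failing FILTER stay in the stream with `pass_filter=False`; the
  scan excludes them, keeping filtering auditable in one place.
  "Quality-filtered" is interpreted as FILTER = PASS or ".".
* Window counts use per-scaffold sorted position arrays and binary search;
  correctness is pinned by a brute-force recount oracle over a thousand
  random instances.
* Rounding of reported metrics is half-up (never banker's), at 0.1 Mb for
  widths and integers for densities.
* The threshold caller gives HOM precedence over HET if a configuration
  ever makes both predicates true (impossible at the defaults).
* Determinism: every stochastic component consumes a NumPy Generator seeded
  from the configuration; fixture files and pipeline outputs are
  byte-identical across reruns at fixed seed (timestamps are confined to
  logs).

## Test problem sizes

The test suite runs the recovery check at the default study conditions
(3 x 10 Mb, 200 markers/Mb, 10 offspring/pool, depth 30) over 100 seeded
replicates, the Haldane calibration at 1,000 replicates of a five-marker
scaffold in the infinite-depth mode, the unlinked-marker check at 2,000
simulator replicates against a 50,000-replicate first-principles Monte
Carlo, and scan exactness over 1,000 random small instances — a few minutes
in total on one CPU.

## Known limitations

* The co-segregation statistic is genotype-class based; allele-frequency
  BSA statistics (Δ SNP-index, G′) are out of scope.
* Consequence calls cover the canonical transcript only, and no
  UTR/regulatory or HGVS annotation is attempted; protein-domain impact is
  left to external tools via the report's free-text field.
* The HETxHET design exists for Mendelian calibration (both parents are
  heterozygous, so the genomic scan's expected-parental-genotype filter
  targets the HOMxHET design).
* With 10 offspring per pool, interval edges are set by a small number of
  recombination breakpoints; candidate intervals are accordingly wide
  (roughly the span until the first breakpoint on each side), exactly as in
  real crosses of this size.
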