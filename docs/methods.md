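# Methods

`ftindelscan` models the desk side of a promoter indel-marker study of
flowering-time (*FT*-family) genes: calling structural variants from gapped
alignments, predicting how PCR markers behave over those variants, screening
and associating marker genotypes with phenology traits, and scanning
transcription-factor binding motifs over the polymorphic regions.  This note
records the models, conventions and design decisions, and what the synthetic
data generator does and does not emulate.

## Coordinate frames

All marker and variant positions are ultimately expressed on a signed
integer axis relative to the transcription start site (TSS): 0 at the TSS,
negative upstream.  Position 0 occupies one base pair, so the inclusive
length of the interval between two endpoints is `|a − b| + 1`; an amplicon
running from −511 to +229 is 741 bp.  For genes annotated on the
reverse-complement strand, upstream corresponds to larger genomic
coordinates, and `tss_relative` is strand-antisymmetric by construction.

Internally, alignment columns and reference positions are 1-based inclusive.
`CoordMap` is a bijection between alignment columns and ungapped reference
positions (columns where the reference is gapped report the anchor position
of the preceding base).  Exports convert at the boundary: BED is 0-based
half-open, VCF uses left-anchored-base indel records.

## Variant calling from gapped alignments

Within each contig's aligned span:

* a maximal run of contig gaps over reference bases is a **deletion**;
* a maximal run of contig bases over reference gaps is an **insertion**,
  anchored at the preceding reference base;
* aligned mismatches (both bases in A/C/G/T) are **SNP loci**; `N` never
  produces a call, and ambiguity codes other than `N` are rejected at parse
  time.

Two contigs carry *the same* indel only when their gap runs occupy identical
alignment-column intervals; partially overlapping runs remain distinct
variants, which is what allows overlapping deletions of different lengths
(a common situation in promoter catalogues) to be counted separately.
Terminal gap runs — a contig that simply does not extend over part of the
reference — are unaligned ends, i.e. missing data, never deletion calls.

A bookkeeping invariant is enforced by property test: per contig, the summed
insertion length minus the summed deletion length equals the ungapped
contig-minus-reference length difference over the aligned span.  The caller
is additionally checked for exact agreement with an independent per-column
brute-force scanner on randomized alignments up to 500 columns.

## The in-silico PCR marker model

A marker is described by the two outer endpoints of its reference product on
the TSS axis plus the primer lengths (default 20 bp when true primer
sequences are not supplied; configurable per marker).  For one haplotype:

    product = reference span + inserted bp within span − deleted bp within span

and the product is absent (a presence/absence variant, PAV) whenever a
deletion covers ≥ 1 bp of either primer's binding window, the `primer_len`
bases inward from each endpoint.  Insertions inside the span lengthen the
product; an insertion falling between the bases of a primer window is
treated as length change only, since primer disruption by insertions is not
modelled.

Gel resolvability is a single relative threshold: two bands merge when
`|Δlen| / max(len)` falls below it.  The default 0.02 reproduces the two
canonical situations of standard agarose work — an 8-bp difference on a
~800-bp product is unresolvable, while a 7-bp difference on a ~230-bp
product separates on high-resolution agarose (a `HIGH_RES_RESOLVABILITY`
preset of 0.005 is provided).

Diploid scoring pools both haplotype observables in one lane: a match to the
score-0 allele pattern gives 0, to the score-2 pattern 2, a band mixture
drawing on both gives 1 (heterozygote), anything else is NA.  Allele
patterns may list several alternative observables (multi-allelic loci are
encoded as one-vs-rest binary markers, each with its own class-to-score
mapping), and "no product" is a genuine scored state, not missing data.
Note that for PAV markers the heterozygote is not callable on a gel — the
product allele masks the absent one — which is why such markers define no
score-1 pattern.

Minor allele frequency uses **allele counting**: heterozygotes contribute
one allele to each class, `MAF = (2·n_minor_hom + n_het) / (2·n_called)`,
reported in percent and always ≤ 50.  A genotype-count mode would be a
one-line change; allele counting is the population-genetics default and is
what the screening threshold is applied to.  Markers are retained when
`MAF ≥ 1.5 %` (boundary inclusive — the discard rule is "< 1.5") and not
monomorphic.

Discriminatory accuracy of a target-specific marker over a panel of N lines
is `(N − mismatches)/N × 100` to one decimal, a mismatch being a non-target
line carrying the target-specific allele (homozygous or heterozygous) or a
target line lacking it.

## Association statistics

Phenology traits (days from sowing to floral bud emergence, start of
flowering, end of flowering; two seasons; 3–10 replicates per line) are far
from normal in diversity panels — early landraces and late winter ecotypes
form separate modes — so the analysis is rank-based:

1. **Normality check.**  One-sample Kolmogorov–Smirnov against a normal with
   the sample mean and SD.  Estimating the parameters from the data makes
   the asymptotic p-value conservative (a Lilliefors correction would be
   sharper); with the gross bimodality involved this is immaterial, and the
   conservative direction is the safe one.
2. **Ranks.**  Per-line replicate means, then average ranks (ties get the
   mean of the spanned ranks, so the rank sum is always n(n+1)/2).  Line
   means are rounded to 1e-6 day — far below the 0.1-day recording
   precision — so that rank order does not depend on floating-point
   summation order.
3. **Correlation.**  Product–moment correlation of the phenotype *ranks*
   against the *raw* marker scores 0/1/2, pairwise-complete (the phenotype
   is re-ranked over the complete pairs).  This is deliberately not
   classical Spearman: the scores enter untransformed.  A both-ranked
   variant is available behind the `both_ranked` flag for comparison.
4. **Significance.**  Two-tailed t-test,
   `t = ρ·√((n−2)/(1−ρ²))` on n−2 df, then Bonferroni:
   `p_adj = min(1, m·p_raw)`.  The family size `m` defaults to all markers
   in the run; a per-gene family policy is available because the choice of
   family cannot be settled from published summary figures alone.  Reporting
   uses adjusted p ≤ 0.05.

Between-year trait repeatability is the Spearman correlation of per-line
trait means across the two seasons.

## TFBS scanning and the exclusivity filter

Motifs are either IUPAC consensus strings (exact degenerate matching, score
1) or position-frequency matrices.  Matrix similarity of a window is

    Σᵢ fᵢ(baseᵢ) / Σᵢ maxᵦ fᵢ(b)

— the matched-frequency sum over the maximal-frequency sum, 1.0 for the
consensus word — with sites called at similarity ≥ 0.85 by default.  This
formula is our documented interpretation of a "similarity" score; promoter
annotation services do not publish theirs, so absolute scores are not
comparable across tools (and no attempt is made to reproduce external
site tables row-for-row).  Windows containing `N` are skipped.  Both strands
are scanned; a window matching on both strands (palindromes such as the
AGL15 CArG box CARGNCAT) is reported once with strand "both".

Scanning runs on the ungapped sequence; positions are mapped back to
alignment columns so sites can be intersected with the variant catalogue.
A site is *in a polymorphic region* when ≥ 1 bp of its window overlaps the
union of indel column intervals and SNP columns (an all-or-nothing mode
exists behind a flag; a SNP's region is its single column).  Within a
promoter scope (the columns upstream of the TSS column), a TF is
**exclusive** when every one of its in-scope sites lies in polymorphic
regions — the candidates whose binding is created or destroyed by the indel
alleles.  Exclusivity is monotone in the region set: enlarging the
polymorphic set can never revoke it.  The per-indel report intersects
exclusive TFs with a user-supplied flowering-pathway annotation list; no
motif database is bundled (the shipped demo set is one literature consensus
plus synthetic matrices, labelled as such).

## The synthetic panel generator

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes, under one `numpy` Generator per
call (identical seeds give byte-identical files).

**Alignment.**  A random reference plus ≥ 2 contigs with planted deletions,
insertions, SNPs, optional terminal truncations, and — via explicit
plantings — overlapping deletions sharing breakpoints and deletions that
abolish primer sites.  The default variant-size spectrum (deletions 7–400
bp on a 5-kb reference) is the real promoter catalogue scaled down an order
of magnitude so that round-trip tests stay fast; nothing in the caller is
length-sensitive, so this loses no generality.  Per contig, planted events
may not overlap each other; across contigs they may.

**Genotypes.**  Markers are drawn independently per line — a deliberate
simplification justified by the very rapid LD decay reported for the
species, which per-marker (rather than haplotype) association leans on
anyway.  Genotype frequencies follow an inbreeding model with
`F = selfing_rate` (default 0.95): heterozygote frequency `2pq(1 − s)`,
matching the rarity of heterozygote gel calls in a predominantly selfing
crop.

**Phenotypes.**  Per line, a genetic value from a two-component
normal mixture (70 % early around 0 d, sd 6; 30 % late shifted +30 d, sd 8)
mirrors the bimodal early-landrace / late-winter-ecotype structure and
guarantees KS rejection; additive marker effects are added on top.  The
phase gaps BE→SF (uniform 4–12 d) and SF→EF (uniform 15–35 d) belong to the
line and are shared between years, so BE ≤ SF ≤ EF holds per line by
construction.  A per-year environmental noise term is added, and replicate
observations (3–10 per line-year, sd 2 d, recorded to 0.1 d) are drawn
around the line-year mean.  Default baseline 50 d puts the bulk of BE values
in the 36–112 d range typical of long-day greenhouse phenotyping.

**Calibration.**  The analysis reports rank statistics, for which the
bimodal mixture has no convenient closed form, so two quantities are
calibrated once by Monte-Carlo bisection on a 20 000-draw sample with a
fixed internal seed (independent of the run seed, cached per config):

* the environmental noise SD, so that the between-year *Spearman*
  correlation of line means matches the configured repeatability (default
  0.96);
* `effect_size_for_rho`, which converts a target rank-vs-score correlation
  (e.g. the |ρ| ≈ 0.3–0.4 regime of strongly associated promoter indels)
  into days-per-score-unit.

Sizing these against the raw-scale Pearson formulas instead would miss the
targets by ~0.1 on the correlation scale, because ranking compresses the
gap between the two phenology modes.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: linkage between markers and any population
structure or kinship (the association scan performs no such correction, by
design), genotyping error beyond simple missingness, shared greenhouse
micro-environment among replicates, year-specific genotype-by-environment
interaction beyond an additive noise term, and multi-allelic marker systems
(simulated markers are biallelic; multi-allelic encodings are exercised by
hand-built fixtures instead).

## Numerical and scale choices

* Sizes used by the default test and validation runs: oracle-equivalence
  checks use 100 seeded fixtures per operation (alignments up to 500
  columns, 200–300-bp motif scans); null calibration uses 200 panels of 100
  lines × 20 markers; effect recovery uses 50 panels of 626 lines; the
  repeatability check uses one 600-line panel.  The full suite runs in well
  under a minute of CPU.
* Type-I tolerance bands are binomial: ±3σ around 5 % for the pooled raw
  rate, +3σ one-sided for the familywise rate across panels.
* Ties in gel-class merging are resolved transitively over sorted band
  lengths; `no_product` is always its own class.
* Degenerate inputs raise typed errors: ragged alignments, single-sequence
  files, non-N ambiguity codes, all-missing genotype columns, zero-variance
  vectors, |ρ| = 1 (reported as the smallest positive normal float and
  flagged), empty scope intervals.

## Known limitations

* Two printed worked examples of product length in the source marker tables
  deviate by 1–4 bp from the inclusive-span convention that the other 18
  rows satisfy; they are treated as typesetting artefacts and excluded from
  validation.
* Absolute motif-similarity scores depend on the (unpublished) scoring
  formula and database version of external annotation tools; only the
  package's own formula is reproducible.
* The Bonferroni family the original analyses used (global vs per-gene)
  cannot be reverse-engineered from printed p-value ranges; both policies
  are implemented and neither is asserted as "the" one.
* VCF output is minimal (sites + INFO, no per-sample genotype columns);
  carriers are recorded in INFO tags.
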