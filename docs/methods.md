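# Methods

## Model and assumptions

The package implements variant-aware short-read mapping by reference
customization rather than by modifying the aligner. Two coupled
transformations define the method:

**Construction.** The personalized diploid reference is the universal
haploid genome with (i) hom-alt SNPs substituted in place and (ii) one
appended segment ("mini chromosome") per non-reference haplotype
combination of each cluster of het/indel variants. The construction
assumes genotypes are correct and unphased: across clusters separated
by at least k+m bases no read can observe phase, so enumerating all
within-cluster combinations is sufficient for mapping purposes even
though it over-represents haplotypes (2^h − 1 minis for h het sites
instead of at most 2 true haplotypes). Minis are appended to their
parent chromosome, keeping its name, so paired-end mapping still sees
mates on one reference sequence; the N×(m+1) separator guarantees any
window taking bases from both sides of a junction carries at least m+1
mismatches and is unmappable under an m-mismatch/indel budget.

**Conversion.** Alignments to the augmented genome are a superposition
of real placements and construction artifacts. The converter translates
mini placements through the per-mini alignment (match blocks plus the
combo's insertions/deletions), recomputes NM/MD against the *universal*
sequence — so alternative alleles deliberately reappear as mismatches,
which is what downstream callers must see — and collapses placements
sharing a translated (chrom, pos, strand). Reads straddling a separator
or mini boundary are emitted unmapped with a reason tag (`ZF`) rather
than clipped: the separators exist precisely to forbid those
placements.

## Mapping quality

The aligner's MAPQ on the augmented genome is misleading in both
directions: artifactually low for backbone+mini twins, and computed
against the wrong reference for alt reads. After collapse:

* placements collapsing to a single locus get
  `max(original, unique_mapq)` with `unique_mapq = 37` (the
  conventional unique-hit score of short-read aligners; the cap is 60).
  The promotion applies only when uniqueness was established by
  collapsing several candidate placements — a read that always had one
  placement keeps its aligner score, so conversion of a SAM that never
  touches minis is the identity apart from header lengths and NM/MD;
* genuinely multi-locus reads get the Phred-scaled posterior of the
  best locus: each locus's likelihood is the product of
  `max(10^(−q/10), min_base_error)` over its mismatch sites
  (`min_base_error = 1e-4` keeps a few high-quality mismatches from
  zeroing a likelihood), the posterior is normalized over loci, and
  MAPQ = `round(−10·log10(1 − posterior))`, floored/capped to [0, 60].
  Two loci with identical mismatch profiles give posterior 0.5 and
  MAPQ 3.

MAPQ is never lowered by conversion. Original MAPQ and mini origin are
preserved in `ZQ`/`ZR` tags when they change.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 36 bp | read length; sets window and cluster scales |
| m | 2 bp | max indel length tolerated in mapping (BWA default for 36-bp reads) |
| w | 2k−1+2m = 75 | mini width; any read overlapping the variant fits with m bases of slack per side; hard floor 2k−1 |
| d | < k+m | single-linkage clustering distance between variant start positions |
| max_cluster_hets | 8 | enumeration cap: a cluster needing more than 255 minis falls back to one mini per variant |
| unique_mapq / cap | 37 / 60 | conversion constants above |

The window around a cluster is `[first.pos − (w−1)/2,
last.pos_end + (w−1)/2)`, clipped at chromosome ends (not padded). For
a single unclipped SNP this reproduces width w with the alternative
allele at index (w−1)/2 exactly. For indels the window flanks the full
reference footprint of the cluster, so an anchored deletion's mini is
(footprint + 2·flank − deleted bases) long. Hom-alt indels are routed
to minis, not backbone edits: editing them in place would shift every
downstream coordinate and break the fixed liftback frame. Mini
sequences are cut from the hom-alt-edited backbone, so reads carrying
both a hom-alt allele and a nearby het allele map cleanly. Variants
overlapping undefined (N) reference sequence are dropped with a logged
count.

## Synthetic data

The generator emulates the statistical setting the method targets:
i.i.d. random genomes at configurable GC; diploid individuals with
Bernoulli SNP positions (default rate 0.01 — dense enough that ~30% of
adjacent variant pairs fall within k+m and exercise clustering), 1–3 bp
indels at 0.001, 60% het genotypes with random phase; Mendelian
children drawing one allele per parent per locus; uniform single-end
reads from both haplotypes with i.i.d. substitution errors (default
0.5%) at constant Q30, with truth coordinates maintained through
per-haplotype offset maps.

What it does **not** model, and hence what passing tests do not show:
real genomes' repeat structure (the dominant source of multi-mapping in
practice — random 36-mers are almost always unique, so the universal
strategy is handicapped far less here than on a human genome), quality
decay and indel sequencing errors, insert-size structure of read pairs,
linkage disequilibrium, and genotyping/imputation error in the input
VCF (the build takes the sample's true variants, i.e. a perfect-assay
scenario). Relative improvements measured here are therefore
conservative in some directions (repeats) and optimistic in others
(genotype quality); only their signs and ordering, not magnitudes,
should be compared with real-data studies.

The oracle mapper is exhaustive and ungapped: every position on both
strands of every chromosome is scored by Hamming distance (reference N
never matches), making "unique with ≤ t mismatches" a provable property
instead of an aligner heuristic. Indel-bearing alignments are exercised
through directly constructed SAM records. The pileup caller counts
bases with quality ≥ 13 from primary reads with MAPQ > 0 and calls, at
depth ≥ 2, alt/alt for alt fraction ≥ 0.8, het for [0.2, 0.8), else
ref/ref. It has no error model: at 4X a single Q30 error can produce a
false het, which inflates trio Mendelian inconsistency for both
strategies equally and is the main noise floor in calling comparisons.

## Evaluation conventions

* Unique-mapping rate: reads with exactly one placement (after
  conversion: one distinct translated locus) within the mismatch
  threshold, over all reads.
* Concordance is computed on gold non-ref/ref SNP loci that received
  some call; a completeness figure (fraction of such loci called) is
  reported alongside so silence cannot masquerade as accuracy. Het
  called as hom-alt (or vice versa) counts as discordant-but-called.
* Genotype-level metrics are restricted to SNP loci: the caller emits
  substitution genotypes, and production pipelines filter call sets to
  SNPs before this comparison.
* Mendelian inconsistency: biallelic loci called in all three trio
  members where not all three are homozygous; an error is a child
  genotype not composable from one allele of each parent. Note the
  all-homozygous exclusion removes even some true errors (e.g.
  alt/alt × ref/ref → alt/alt) by construction of the denominator.
* MAF bins: (0, 1%], (1%, 5%], (5%, 50%], right-inclusive.
* Gold no-call loci are excluded from every denominator.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; VCF/SAM are
  shifted at I/O boundaries. The auxiliary liftback map is a plain TSV
  (`EDIT` and `MINI` lines plus `#` headers carrying k, m, w and
  universal lengths) whose write→read round-trip is exact.
* Collapse tie-breaks are deterministic: within a locus, lowest
  NM-vs-universal, then backbone origin, then lexicographic origin id;
  across loci, lowest NM then leftmost coordinate. Identical inputs
  yield byte-identical FASTA, aux-map and SAM outputs.
* The all-reference haplotype combination is never built (it already
  exists on the backbone), and a 1/2 het site contributes one mini per
  alt allele, never the reference.
* Reads whose converted placement would start or end inside a combo
  insertion are soft-clipped at the insertion remainder; alignments
  cannot begin or end with an insertion op in SAM.
* Degenerate inputs: empty variant list → construction is the identity;
  all-failed translations → read emitted unmapped with its reason;
  empty clusters cannot occur by construction.

## Problem sizes

Test and acceptance workloads use 20–50-kb genomes, 2,000–10,000 reads
and three replicate seeds — large enough that binomial noise on the
reported rates is at the percent level, small enough that the
exhaustive oracle stays the mapper. Stochastic comparisons (calling
improvement at 4X, trio MI) are averaged or pooled over the three
replicates; single replicates at 4X sit inside the caller's noise
floor, as the demo output shows.

## Known limitations

* The constructor enumerates combinations per cluster independently;
  whether a wider w should widen flanks asymmetrically is unresolved
  (symmetric split is used).
* The converter assumes the aligner reports its multi-mapping evidence
  as primary/secondary records or `XA` hits; evidence the aligner
  discards cannot be collapsed.
* Mate repair recomputes RNEXT/PNEXT/TLEN but does not re-evaluate
  proper-pair flags against an insert-size model.
* The pileup caller is deliberately minimal test plumbing, not a
  production genotyper.
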