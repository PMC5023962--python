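# Methods

## The problem

DNA (class 2) transposons move by excision and reinsertion.  An
excision leaves a double-strand break whose repair — via resected
single-stranded intermediates and error-prone second-strand synthesis —
deposits substitutions and small InDels up to several kb into the
flanking sequence.  Between two closely related genomes this shows up
as local SNP accumulations centred on excision scars.  `tescar`
implements the comparative analysis end to end: classify TE
presence/absence loci, profile the flanking mutation gradient, date
LTR retroelements against their target-site duplications, measure the
knock-on effect on promoters and coding-sequence ends, predict
excision sites from SNP density, and discover small DNA transposons
de novo from their terminal inverted repeats.

Because the analysis needs two annotated genomes with known history,
the package ships a first-class simulator whose truth table makes
every analysis testable by parameter recovery.

## Simulator (`synthetic_genomes`)

An ancestral genome is drawn with uniform base composition and
`n_genes` intronless, forward-strand coding genes (ATG + non-stop
codons + TAA) separated by random intergenic gaps.  A TE library holds
two families per DNA-transposon superfamily (DTT, DTH, DTM, DTA, DTC)
with terminal inverted repeats of 15–25 bp.  Ancestral TE copies are
planted flanked by exact target-site duplications (TSDs) of the
superfamily-specific length (DTT 2, DTH 3, DTM 9, DTA 8, DTC 3,
retroelements 5 bp — standard superfamily conventions, configurable).
Placement is biased toward the 2 kb up/downstream of genes with odds
`near_gene_bias : 1` (default 10:1); the near/uniform decision is made
once per element so the bias governs where elements end up.

Two descendant genomes then evolve independently:

* **Background**: per-site substitutions at `background_sub_rate`
  (default 0.005 per lineage; halve it to emulate a pair of genomes
  that are ~99.5% identical *to each other*) and InDels at
  `background_indel_rate` (default 5e-4) with geometric(0.5) lengths
  capped at 50 bp.
* **Insertions**: new TE copies into one lineage, duplicating the
  current target site exactly (TSDs are perfect at insertion time).
* **Excisions**: an ancestral TE is removed from one lineage with a
  footprint drawn from `excision_type_mix` — *perfect* (both TSD units
  retained), *deletion* (TE plus 20–300 bp of flank on one side, the
  other breakpoint within 3 bp of a TE end), or *filler* (TE replaced
  by 10–300 bp of unrelated sequence, breakpoints within 3 bp of the
  TE ends).  The excised lineage's flanks mutate at
  `rate(d) = background * (1 + (A - 1) * exp(-d / L))`
  out to `gradient_extent` (defaults A=5, L=1000 bp, extent 3000 bp);
  the InDel rate is scaled by the same fold factor.  The exponential
  form is a modelling choice — the observation it encodes is only that
  mutation density decays smoothly over ~3 kb.
* **LTR retroelements** (lineage A): each element gets an age-like
  per-site rate r drawn uniform from `ltr_divergence_range`
  (0.002–0.02); both LTRs mutate independently at r, the two TSD
  copies at `tsd_rate_multiplier * r` (default 5).  Elements are kept
  ≥ 12 kb apart (`ltr_min_separation`): real full-length family
  members are almost never within the 14-kb pairing window, and the
  manual dot-plot screening that removed adjacent solo-LTR pairings in
  curated element sets is out of scope.

All randomness flows from one seed through named child streams;
identical configurations give byte-identical FASTA/GFF3/truth output.
The truth table records every event with anchors in both genomes and
satisfies an exact length-conservation identity used as a test.

What the simulator does *not* emulate: selection, nested/fragmented
TEs, methylation, non-uniform base composition, introns, segmental
duplication, and real repeat landscapes.  Passing recovery tests
therefore demonstrates correctness of the measurement machinery under
the stated mutational model, not performance on real assemblies.

## Alignment (`align_core`)

Pairs up to ~5 kb x 5 kb are aligned by exact affine-gap DP
(Needleman–Wunsch/Smith–Waterman via Biopython), scores +2/-3, gap
open -10, extend -0.5 (a gap of length L costs open + (L-1)·extend);
N is scored 0 against everything and never counts as a mismatch.
Longer loci use anchor-and-chain: unique shared 20-mers, longest
colinear chain, exact DP between anchors (recursing with smaller k,
then an edit-distance path as last resort for huge divergent
segments).  On the ≥99% identical sequences this package compares the
chained score equals full DP, verified on multi-kb test pairs.  Among
co-optimal tracebacks the engine's canonical first traceback is
reported; it is deterministic for fixed input.

Mutation events: one substitution per mismatching base–base column;
one InDel event per maximal gap run, whatever its length.

## Polymorphism classification (`polymorphisms`)

Optimal alignments place gaps ambiguously around direct repeats, so
the classifier works in sequence space.  It anchors on clean flank
alignment ≥ 40 bp outside the annotated TE, extracts the non-carrier
junction sequence, and compares it by edit distance against two
reconstructed patterns: *perfect excision* (TE removed, both TSD
units kept) and *insertion* (TE plus one TSD unit removed).  The
closer pattern within a tolerance of max(3, 12% of the pattern
length) wins; exact ties are broken by junction length (a partial
extra TSD remnant argues for an excision scar) and double ties are
honestly ambiguous — a TE inserted into a pre-existing direct repeat
cannot be distinguished from a perfect excision.  Loci matching
neither pattern are resolved by breakpoint geometry: mismatch-budgeted
prefix/suffix walks locate the removed block; one breakpoint within
~3 bp of a TE end with ≥ TSD+4 bp removed on the other side is an
excision-with-deletion, ≥ 10 bp of interstitial sequence < 70%
identical to the TE is a filler.  The insertion call additionally
requires the carrier's TSD copies to agree within 1 mismatch.

On 500 simulated mixed events the classifier is ~95–97% accurate with
the remainder almost entirely in the ambiguous bucket.

## Flank profiles and the gradient fit (`flank_profiles`)

Events of each classified locus are re-indexed by signed distance from
the anchor in the coordinates of the genome lacking the TE (there the
scar is a single point).  The disrupted junction zone contributes
neither events nor coverage, so the scar's own footprint cannot
masquerade as flanking mutations.  Counts are pooled over loci and
divided by pooled coverage in sliding windows (400/40 bp for
substitutions, 1000/100 bp for InDels); windows with per-locus
coverage below 25% of the locus count are masked.  Loci qualify when
>7000 of the 24-kb window could be aligned.

The gradient is summarized by least squares on
`density(d) = b (1 + (A_obs - 1) exp(-|d|/L))`, initialized from the
far-field median.  The pairwise baseline b contains the background of
*both* lineages while the excess arises in the excised lineage only,
so the fold-increase in that lineage is `2*A_obs - 1`
(`GradientFit.amplitude_excised_lineage`); with the default
conditions (200 excisions) both A and L recover within ±25%.

## Orthology (`orthology`), LTR/TSD dating (`ltr_tsd`)

Loci are verified orthologous by splitting them into 1-kb segments and
mapping each segment (16-mer diagonal voting, then local alignment;
hits must align ≥600 bp; dinucleotide entropy <1 bit is unmappable,
emulating word-seeded search filters).  A pass needs a majority (>50%
of mappable segments) landing in the partner locus in both directions
plus reciprocal best-locus identification.

LTR elements are found consensus-driven: hits of each family's LTR
consensus (extrapolated to full consensus extent so trimmed mutated
ends do not shift the TSD windows) are paired same-family/strand
<14 kb apart, overlaps resolved by summed score.  LTR–LTR mismatches
are counted over base–base columns of a local alignment (elements
with <50% of an LTR aligned are flagged unreliable); family outliers
>2 population-SD below the family's mean identity are dropped
(inter-element recombination).  TSDs are the gapless 5-bp flanks; the
pooled TSD vs LTR mismatch rates are compared by uncorrected 2x2
chi-square.  The ratio recovers a simulated 5x multiplier to ~±5%.

## Gene-region rates (`gene_region_rates`)

Promoters are the 2 kb upstream of the transcription start; intergenic
controls are equally long segments centred in gaps ≥10 kb, matched
across genomes by flanking gene IDs; alignments must cover >600 bp.
Chromosome arms (from the annotated centromere) are split into three
equal bins, bin 1 distal, compiled across arms; per-bin distributions
are compared by two-sided Mann–Whitney (tie-corrected normal
approximation with continuity, matching wilcox.test defaults).  The
headline contrast is
`(divergence_promoter / divergence_intergenic - 1) * 100`.

CDS pairs come from mutual best hits (k-mer vote prescreen, local
alignment only for contested ranks; exact ties excluded), aligned at
the protein level (BLOSUM62, local) and back-translated so codons
correspond.  Synonymous sites are restricted to third positions where
both codons share one of the eight 4-fold-degenerate prefixes
GC/GG/CT/CC/CG/TC/AC/GT — for the 6-fold amino acids only the
CT (Leu), TC (Ser) and CG (Arg) boxes, where any third-base change is
silent.  Aligned codon columns are cut into five equal bins (remainder
widening the first bins); the per-bin rate is substitutions per
eligible site scaled by 1000/3 ("per kb" of codon sequence at eligible
sites — denominator choice documented here because bin length would
also be defensible; ratios between bins are unaffected).  Pairs enter
only with >1500 aligned bases.

## Discovery (`discovery`)

High-SNP segments are 500-bp windows (step 250) whose substitution
density reaches ≥4x a supplied background — a deliberate formalization
of a selection the original analysis did by eye; both knobs are
exposed.  Enrichment of event categories in high-SNP vs control locus
sets uses the uncorrected 2x2 chi-square.  Note that for small tables
the continuity-corrected and uncorrected tests can disagree
noticeably; the package defaults to uncorrected with Yates available
by flag.

TIR scanning aligns 1-kb windows (500 bp overlap) locally against
their own reverse complement; stems ≥15 bp at ≥70% identity with
non-overlapping arms nominate an element from left-arm start to
right-arm end, deduplicated across windows.  Candidates are accepted
when the genome holds ≥3 further copies (≥50 bp at ≥80% identity,
self-locus excluded) — "multiple hits" interpreted as ≥3,
configurable.  On 50 planted MITEs in 300 kb this yields recall and
precision ≥0.9.

## Numerical and reproducibility notes

* Problem sizes in tests and the acceptance script: 200 excision loci
  for the gradient, 500 events for the classifier, 192 LTR elements,
  50 MITEs, 400 CDS pairs — matching the stated study conditions while
  completing in minutes on one CPU.
* All coordinates are 0-based half-open in memory; conversion happens
  only at the GFF3/BED boundary.
* Reports are plain TSV/JSON with fixed float formatting; rerunning
  the pipeline with the same seed reproduces every output byte for
  byte.
* Known limitations: no strand-resolved profiles; per-superfamily
  stratification exists only as a filter; nested or fragmented TEs are
  not modelled; the classifier's "ambiguous" bucket replaces the
  manual curation a human would apply to borderline scars.
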