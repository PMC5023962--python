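# tescar

Transposon excision scars and their mutational footprints in pairwise
genome comparisons.

DNA (class 2) transposons move by cut-and-paste.  Every excision
leaves a double-strand break, and the error-prone repair of that break
writes substitutions and small InDels into the surrounding sequence —
up to several kilobases from the excision point.  Between two closely
related genomes (think *Oryza sativa* vs *O. glaberrima*, ~99.5%
identical) this produces a characteristic signature: local SNP
accumulations that decay roughly exponentially away from excision
scars, elevated substitution burdens in the target-site duplications
(TSDs) of retroelement insertions, and — because small DNA transposons
prefer to insert next to genes — faster evolution of promoters and of
the 5′/3′ ends of coding sequences.

`tescar` implements this comparative analysis as a tested pipeline:

* **`synthetic_genomes`** — a two-genome evolution simulator with a
  machine-readable truth table: background substitutions/InDels, TE
  insertions with superfamily-specific TSDs, excisions with
  perfect/deletion/filler footprints plus a configurable flanking
  mutation gradient `rate(d) = μ·(1 + (A−1)·e^(−d/L))`, LTR
  retroelements with initially identical LTRs, genes and promoters.
* **`align_core`** — exact affine-gap global/local alignment (blastn-like
  scores) with anchor-and-chain for long loci; mutation-event
  extraction (an InDel run of any length counts once) and sliding-window
  densities.
* **`orthology`** — 1-kb segment mapping with reciprocal best-locus
  verification.
* **`polymorphisms`** — classification of TE presence/absence loci into
  insertions and excision subtypes from TSD and breakpoint rules.
* **`flank_profiles`** — pooled mutation profiles around anchors and the
  exponential gradient fit.
* **`ltr_tsd`** — consensus-driven full-length LTR element discovery,
  LTR–LTR divergence dating, TSD-vs-LTR substitution-rate comparison
  (χ²).
* **`gene_region_rates`** — TE coverage around genes, promoter vs
  intergenic conservation in chromosome-arm bins (Mann–Whitney), and
  synonymous substitution rates in five CDS bins restricted to
  4-fold-degenerate third positions.
* **`discovery`** — excision-site prediction from SNP accumulations,
  repeat-slippage detection, and de novo discovery of small DNA
  transposons from terminal inverted repeats.
* **`stats` / `pipeline` / `cli`** — uncorrected 2×2 χ², tie-corrected
  rank-sum test, running averages; stage orchestration; a thin
  `tescar` command line.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

Run the demo pipeline on a simulated 1.5-Mb genome pair (25 lineage
specific insertions, 15 excisions with the default gradient A=5,
L=1000 bp):

```bash
tescar run --out demo_out --seed 11
```

prints, after ~25 s on one CPU:

```json
{
  "outputs": [
    "calls.tsv", "cds_bins.tsv", "gradient_fit.tsv",
    "high_snp_segments.tsv", "ltr_elements.tsv", "profile_indels.tsv",
    "profile_substitutions.tsv", "promoter_bins.tsv",
    "promoter_loci.tsv", "tir_candidates.tsv"
  ],
  "gradient": {
    "amplitude_excised_lineage": 5.135,
    "scale_bp": 978.5
  }
}
```

`calls.tsv` holds one row per classified TE locus (class, anchor in
both genomes, deletion extent / filler length), and `gradient_fit.tsv`
the fitted mutation gradient:

```
amplitude_observed  amplitude_excised_lineage  scale_bp  baseline    rmsd
3.06765             5.13531                    978.499   0.00982658  0.0016011
```

Reading: the pairwise substitution density next to excision scars is
3.07× the far-field baseline (0.0098/bp, i.e. the summed background of
both lineages); because the repair excess arises in the excised
lineage only, that lineage experienced a 5.1-fold elevation at the
scar, decaying with a 980-bp scale — recovering the simulated A=5,
L=1000 from just 15 excision loci.  Rerunning with the same seed
reproduces every output byte for byte.

The same machinery works on real data: `tescar classify` takes two
genome FASTAs with TE-annotated GFF3s, `tescar ltr` a genome plus LTR
consensus FASTA, `tescar tir-scan` any genome FASTA.

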