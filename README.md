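# svase

**Sequence variants associated with splicing events, called directly from
RNA-seq split reads.**

A substantial share of disease-causing mutations, and many RNA-editing
events, act by disturbing pre-mRNA splicing — changing a splice site or a
splicing regulatory element.  RNA-seq observes both signals at once: a
spliced alignment carries the splicing junctions (reads with `N` CIGAR
gaps) and the variant alleles (mismatches in the aligned blocks).  `svase`
exploits this: it calls variants *de novo using only the reads that
support a given junction* and asks, for each variant, whether its
alternative allele is statistically confined to that junction's reads.
A hit — a SVASE, *sequence variant associated with a splicing event* — is
a substitution whose allele distribution is enriched in the reads
supporting one specific junction, for both known and novel splicing
events.  The package is aimed at transcriptomics researchers studying
splice-altering DNA mutations and RNA editing.

## Method

Inputs are a genome FASTA and a spliced alignment (SAM/BAM with split
reads); annotation (GTF/GFF/BED) and known DNA-mutation / RNA-editing
site lists (VCF or tabular) are optional.  The pipeline applies
multi-pass rule-based and statistical filters:

1. **Read QC.** Drop unmapped/secondary/supplementary records, PCR
   duplicates, QC failures, improperly paired reads, reads with indels or
   more than 3 mismatches, reads shorter than 30 bp and reads with mean
   base quality < Q30; bases below Q30 are additionally masked for
   pileups.
2. **Junction discovery.** Each `N` gap of a split read observes an
   intron `[s, e)`; observations need ≥ 8 bp aligned anchor on both
   sides.  Junctions with read depth < 3 are discarded, and each junction
   is tested against its *related* junctions (those sharing the intron
   start or end) for background expression: with total depth
   N over the group and b = ⌈0.01·N⌉, a one-sided Fisher exact test on
   [[depth, N−depth], [b, N−b]] must give p ≤ 0.05.
3. **Known/novel and shift events.** With annotation, junctions are
   classified by exact intron match (`-k no` restricts analysis to novel
   ones), and a novel junction is flagged a *shift* of a known one when a
   known intron of the same length sits k bp away (|k| ≤ 10) and the
   boundary sequence repeat makes the two alignments equivalent.
4. **Per-side variant calling.** Each junction is split at its 5′ss and
   3′ss into independent left/right parts; a pileup over the supporting
   reads' anchor blocks yields candidates filtered by depth ≥ 3, ALT
   reads ≥ 3, ALT fraction ≥ 0.1 and a one-sided Fisher test against the
   sequencing-error expectation (p ≤ 0.05).
5. **Consistency and association.** The ALT frequency in target-junction
   reads is compared (two-sided Fisher) with the frequency in
   related-junction reads.  If consistent, association contrasts target
   reads against all other covering reads; otherwise target ∪ related
   reads form the splicing-supporting row.  A one-sided Fisher p ≤ 0.05
   on (splicing-supporting × ALT/REF) validates the association; a
   variant with zero non-supporting coverage is junction-private and kept
   with p = 0 (flagged `NOCONTRAST`).
6. **Annotation.** Splice dinucleotide class (GT-AG, CT-AC, GC-AG,
   AT-AC) with strand inference; donor (9-mer) and acceptor (23-mer)
   position-weight-matrix scores for reference and variant alleles;
   source typing against known DNA-mutation/RNA-editing sites; distances
   to the junction breakpoint; flanking sequence export for ESE motif
   tools; VCF + TSV output and summary tables.

A deterministic synthetic-data generator (`svase.simdata`) produces a
genome, truthful spliced SAM and a truth table, so every stage is
testable without external downloads.

## Worked example

```bash
svase simulate -o demo --seed 5 --n-junctions 10 --chrom-len 80000 --n-variants 3
svase call -g demo/genome.fa -a demo/reads.sam -o demo_out
```

prints

```
wrote genome.fa, reads.sam (330 reads), truth.tsv (10 junctions, 3 plants,
3 expected associations) -> demo/
3 variant-junction associations across 10 junctions -> demo_out/
```

`demo_out/svase.tsv` then contains one row per association, e.g.

```
chrom  pos   ref alt junction        side depth alt_count alt_fraction p_variant  p_association ...
chr1   955   C   T   chr1:962-1320   left 30    27        0.9          4.6e-14    0.0
```

— at chr1:955 (1-based), 27 of the 30 reads supporting the junction with
intron 962–1320 carry C→T on the 5′ss side; p_variant is the Fisher test
against sequencing error, and p_association = 0 with the no-contrast
flag means no non-supporting read covers the site (the variant is fully
junction-private).  The same records appear as VCF in
`demo_out/svase.vcf`, flanking windows in `flanks.fa`, and descriptive
tables (motif classes, substitution spectrum, breakpoint distances)
under `demo_out/summary/`.

The `examples/` directory holds short narrative scripts, one per
capability (end-to-end calling, the four Fisher constructions, shift
detection, splice-signal scoring).

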