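# Methods

This note documents the model, the statistical constructions, the
conventions the implementation fixes where the problem statement leaves
them open, and what the synthetic benchmark does and does not show.

## Coordinates and junction identity

All internal coordinates are 0-based, half-open; conversion happens only
at format boundaries (BED is native; GTF/GFF and VCF are 1-based).  A
splicing junction is identified with its intron interval
`(chrom, intron_start, intron_end)`: `intron_start` is the first intronic
base, `intron_end` one past the last.  A junction's *left part* is the
exonic anchor region upstream of the intron (the 5′ss side on the plus
strand), its *right part* the region downstream.  *Related* junctions
share the intron start or the intron end.  For per-side analysis the
competition is cross-wise: the left part of a junction competes with
junctions sharing its intron **end** (alternative donors feeding one
acceptor have different left sequences), and symmetrically for the right
part; the union of both sets is used for the junction-level background
test.

## Read filters

Checks run in a fixed order (unmapped → secondary/supplementary →
multi-mapped → duplicate → QC-fail → unpaired → indel → mismatch excess →
length → base quality) so rejection tallies are reproducible.  Defaults:
mean base quality ≥ Q30, read length ≥ 30 bp, ≤ 3 mismatches (from the
`NM` tag, else recomputed against the genome), no indels, proper pairing
required for paired data.  "Multiple mapping" is operationalised as the
secondary/supplementary flags plus a MAPQ floor (default: reject
MAPQ < 1, the common multi-mapper sentinel).  Base quality has a dual
role: the whole-read mean gates the read, and individual bases below the
threshold are masked so pileups never count error-prone calls while the
read still supports its junction.  The mismatch rule is a cap, not a
ban — a ban would make variant detection impossible.

## Statistical gates

All four gates are Fisher exact tests (scipy) on 2×2 tables; only the
construction differs.  Thresholds are raw p ≤ 0.05 throughout; no
multiple-testing correction is applied by default, with Benjamini–
Hochberg available behind the `multiple_testing="BH"` flag for the
association p-values.  Gate comparisons use a 1e-9 relative tolerance so
tables sitting exactly on the threshold (e.g. p = 1/20 at α = 0.05) are
not lost to float round-off.

**Background expression.** For a junction of depth d among related
junctions with combined depth N, the junction's read share is tested
against a configurable background proportion (default 1%):
b = ⌈0.01·N⌉ and p = one-sided Fisher on [[d, N−d], [b, N−b]].  A
junction with no relatives faces no competition and is kept with p
recorded as 0.  The construction is isolated in one function so
alternatives can be swapped in.

**Variant significance.** A candidate with a ALT calls at depth n is
tested against the count an error-only process would produce,
e = round(error_rate·n) with error_rate defaulting to the Q30 error
probability 0.001: one-sided Fisher on [[a, n−a], [e, n−e]].  The p is
monotone in e, so lowering the assumed error rate never loses calls.

**Consistency.** ALT/REF counts in target-junction reads vs
related-junction reads (side-specific set, target reads excluded from
the related stratum), two-sided Fisher; frequencies are *consistent*
when p > 0.05 or the related stratum has no coverage.

**Association.** Over all QC-passing reads covering the site, row 1 is
the splicing-supporting set — the target junction's reads when
consistent, target ∪ related when not — and row 2 is every other
covering read; columns are ALT vs REF calls (other bases are ignored).
One-sided Fisher for ALT enrichment in row 1.  When row 2 has zero
coverage the variant is junction-private: it is kept with p set to 0 and
a no-contrast flag, since junction-private variants are the signal of
interest, not noise.  Note the deliberate asymmetry: under consistency
the related reads serve as part of the *contrast*, under inconsistency
they join the splicing-supporting row — this is the only reading that
keeps the table well-formed in both branches.

## Variant calling

Pileups are restricted to the anchor blocks adjacent to the intron (not
whole reads), keeping the two junction parts independent; masked bases
are skipped, positions with zero unmasked coverage omitted.  Candidates
are SNVs only (indel reads were filtered upstream); several ALT bases at
one column are independent candidates.  Count floors: depth ≥ 3, ALT
reads ≥ 3, ALT fraction ≥ 0.1.

## Junction shift detection

A novel junction `[s, e)` is a *shift* of a known intron `[s−k, e−k]`
(k ∈ ±1..max_shift, default 10) when the known intron exists in the
annotation and the genome permits the ambiguity: for k > 0 the k bases
after the known start equal the k bases after the known end (mirrored
for k < 0), which makes the two spliced alignments produce identical
transcripts.  The smallest |k| wins, positive offsets break ties.

## Splice-signal scoring

Junctions are classed by terminal intron dinucleotides — GT-AG (+),
CT-AC (its minus-strand mirror), GC-AG and AT-AC with their mirrors,
anything else "other" — which also fixes the transcribed strand.  Donor
windows cover 3 exonic + 6 intronic bases, acceptor windows 20 intronic
+ 3 exonic, on the transcribed strand (minus-strand windows are
reverse-complemented).  Scoring is a first-order position weight matrix:
per-position base frequencies with additive pseudocount (default 0.25)
over a training set of annotated junctions (or, absent annotation, the
discovered canonical junctions), expressed as log2 odds against a
uniform background; a window's score is the sum of its per-position
log-odds, so a single substitution shifts the score by exactly its
per-position difference.  The scorer is an interface — a maximum-entropy
model or an external-tool wrapper can be slotted in; windows follow the
convention such tools use.  "Other"-motif junctions are scored in both
orientations and reported at the better one, flagged low-confidence.
Signal scores are annotation only, never a filter.

## Source typing and distances

Known-site matching is position plus exact (ref, alt); a position-only
match is reported as the weaker `position-known` label because public
dumps vary in allele orientation.  Distances use 1-based adjacency: the
exonic base touching the intron boundary is at breakpoint distance 1.
Exon-side distances are measured to the two ends of the anchor-covered
exon segment — the only exon extent the caller knows without
annotation — and mapped to 5′/3′ via the junction strand; measuring to
annotated exon boundaries instead would require the annotation and is
left to downstream tools.

## Synthetic data and what the benchmark shows

The generator writes truthful spliced SAM directly (it emulates the
*output* of a spliced aligner, so the caller is tested, not an aligner):
uniform-random genome with GT-AG (or CT-AC) motifs written at planted
introns, junction-spanning reads with anchors drawn from 15–40 bp,
per-junction depth 30, uniform base errors at 0.001, 10% non-split decoy
reads, and plants that are junction-private, shared across related
junctions, or genome-wide (ALT in every covering read, with dedicated
covering decoys so the association test has contrast).  The default
configuration — one 1 Mb chromosome, 200 junctions, 50 junction-private
plants at ALT fraction 0.9 — is the standard benchmark; the acceptance
tests use it as-is, with smaller variants (20–40 junctions over
120–250 kb) where a property does not need scale.  Problem sizes were
chosen so each stage still sees realistic depths and read counts while a
full run takes about a second.

The truth table's expected flag is derived from the generated reads and
the documented default thresholds (including association contrast from
whatever decoys actually cover the site), independently of the pipeline's
pileup machinery; a plant that the thresholds themselves exclude (e.g. a
single REF-carrying decoy flipping the association arithmetic) is marked
not-expected rather than letting the benchmark overstate recall.

The generator does **not** model realistic expression levels, positional
error profiles, fragment-size distributions or alignment artifacts other
than boundary-repeat shifts.  Passing the benchmark therefore shows the
machinery is correct and specific under its stated assumptions — it does
not certify performance on real libraries, where alignment errors and
overdispersed coverage dominate.

## Numerical and design choices

- Fisher p-values come from scipy's exact implementation; the test suite
  checks them against an exhaustive rational-arithmetic enumeration for
  every 2×2 table with N ≤ 30 (agreement < 1e-9, observed ~3e-16).
- Junction depth counts distinct read IDs; mates of a pair spanning the
  same junction count as two reads (they are independent molecules only
  insofar as upstream deduplication is trusted).
- Determinism first: no sampling anywhere on the call path, all set
  iterations ordered; rerunning a configuration is byte-identical.  The
  `threads` config field is accepted for interface stability, but
  chromosomes are processed sequentially (they are already independent
  partitions, and outputs are order-normalised regardless).
- GTF exon grouping uses the conventional `transcript_id` attribute
  (GFF3: `Parent`); other dialects need a pre-pass.
- Degenerate inputs: empty record lists produce header-only VCFs and
  all-zero summary tables; flanking windows truncate at contig edges;
  signal windows that would leave a contig yield missing scores rather
  than errors.

## Known limitations

SNVs only (no indels/MNVs, by construction after read QC); no genotype
likelihoods or strand-bias tests; single-sample calling (replicate
consistency is an evaluation metric in `simdata.evaluate`, not a joint
caller); exact-interval matching against annotation (no fuzzy known
matching beyond shift detection); the PWM scorer is first-order and
trained on whatever junctions are available, so its absolute scores are
dataset-relative.
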