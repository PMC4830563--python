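# Methods

## Overview

`pseudoscan` decides, for each target genome, whether a reference
protein-coding gene is intact, disrupted, deleted outright, or
unresolvable from the available contigs, and expresses every lesion in a
compact per-exon code dialect (`sa`, `sd`, `ns`, `i#`, `d#`, `5d#`,
`3d#`, `ed`, `tl`, `gd`). Species-level results are then mapped onto a
phylogeny under a Dollo model of gene loss. This note records the model
conventions, the defaults and why they were chosen, what the synthetic
benchmark does and does not emulate, and the known limitations.

## Coordinates, strand, reference model

Internally all coordinates are 0-based half-open; GFF3 I/O and
human-readable reports are 1-based inclusive. Minus-strand reference
genes are reverse-complemented at load, so every downstream module is
strand-free. The reference must itself be intact — start codon, single
terminal stop, no internal stop, exon phases consistent — and violations
are hard errors naming the broken invariant: a disrupted reference would
silently corrupt every downstream call.

## Exon mapping

Each exon is searched on both strands of every contig. Candidate regions
are seeded with shared k-mers (default k = 11) and refined by local
affine-gap alignment under a fixed score contract: match +2, mismatch −3,
a gap of length *L* costs 5 + 2·*L*, and N matches nothing (codons
containing N are reported as ambiguous, never as nonsense — WGS contigs
contain gaps, and calling mutations through them would fabricate
evidence). The aligner is Biopython's `PairwiseAligner` configured to
this contract (`open_gap_score = −7`, `extend_gap_score = −2` in its
convention); the test suite checks score equality against an independent
brute-force Gotoh dynamic-programming oracle.

Hit thresholds default to identity ≥ 0.6 and reference coverage ≥ 0.3.
Coverage is deliberately low so that exons truncated at their 5′ or 3′
end (`5d#`/`3d#`) are still detected as present-but-damaged rather than
absent; both thresholds are configurable because no single pair suits
every divergence level. Best hits are chosen by score with deterministic
tie-breaking (contig id, then leftmost start). Target-side sequences of
the best hits, in exon order, form the virtual cDNA, translated in frame
0 to the first stop.

## Point-mutation codes

From each exon's best alignment: the 2-nt target context left/right of
the alignment is compared with the canonical acceptor AG / donor GT
(`sa`/`sd`; a GC donor counts as a mutation by default, with an opt-in
switch to tolerate it); alignment gaps become `i#`/`d#`; unaligned
reference overhangs at exon termini become `5d#`/`3d#` when target
sequence continues past the alignment edge. At a contig edge all of
these are suppressed and an "inconclusive flank" note is attached —
missing sequence beyond an edge is never evidence.

**Reading frame.** Nonsense codons are found by scanning the target-side
exon segment straight through in the exon's reference start phase. For
internal indels this is arithmetically identical to tracking the
cumulative frameshift through the exon; for 5′ truncations it reads the
spliced product as it would actually be translated. The frame resets to
the reference phase at each exon start, so per-exon codes never depend on
lesions in earlier exons — matching a table layout in which each cell
stands alone. A stop codon occupying the final three nucleotides of the
last exon is the gene's natural termination, not `ns`.

**Status.** `intact` requires every exon present with zero codes and a
full-length translation (start codon, terminal stop, length within one
codon of the reference). Any recorded code — including an in-frame indel,
which preserves the frame but still marks the gene as mutated — makes the
species `disrupted`. `gene_deleted` requires the whole-gene rule below.
`inconclusive` is reserved for genomes whose only anomalies sit at contig
edges or are unresolvable absences.

## Structural calls

*Exon deletion (`ed`).* For each maximal run of absent exons, the nearest
detected exon on each side is used as a flank anchor; where fragmentation
(or a gene-terminal run) removes those, 200-nt non-exonic anchor windows
from the reference — the intron sequence adjacent to the run, or the
flank beyond the terminal exon — are located by alignment instead. The
run is deleted iff two anchors co-locate on one contig, in consistent
order and orientation, with the target gap shorter than the reference
span by at least the summed missing exon lengths. Anything less degrades
to "absent-inconclusive", never to `ed`.

*Translocation (`tl`).* An exon is translocated iff its best hit lies on
a different contig than its co-located flanking anchors, whose gap shows
the exon's sequence missing from where it should sit (reference span
minus target gap ≥ half the exon length). The intron-window fallback is
attempted only when the exon is alone on its contig — the signature of a
real translocation — which keeps the expensive unseeded window search off
the common path.

*Whole-gene deletion (`gd`).* Called only when no exon yields any hit
anywhere **and** a supplied control locus (a paralog expected to be
present) is detected, arguing against a mere assembly gap. Without a
control, or with the control also absent, the verdict is
"no-sequence-found" (inconclusive). `gd` excludes all per-exon codes, and
`ed`/`tl` are mutually exclusive per exon by construction.

## Dotplot anchors

Maximal exact k-mer match runs (default k = 16) on both strands, with
co-linear runs separated by ≤ 20 nt on both axes merged. This replaces a
chained-local-alignment tool with a deterministic primitive that is
sufficient for same-gene comparisons at this scale; the anchor set is
symmetric under transposition of the two sequences, and per-exon
coverage flags agree with the structural caller on simulated genomes
(both properties are tested). Output is a coordinate TSV for any generic
plotter; rendering is deliberately not part of the tested surface.

## Loss inference

Gene loss is a Dollo character: lost on a branch, never regained. The
reconstruction assigns one loss event to each maximal clade whose
scorable leaves are all non-intact (`inconclusive` species are treated as
missing data). Event counts are verified against exhaustive enumeration
on trees of up to 12 leaves. A multi-leaf event is corroborated when the
clade shares at least one identical mutation — same exon, same code, and
same reference-aligned position when positions are available; rows parsed
from a mutation table carry no positions and fall back to coarser
(exon, code) keys, flagged as such. Clades with no shared mutation are
*not* resolved: a single ancestral loss followed by divergent decay and
independent losses per lineage are equally consistent, so the event is
flagged `no_shared_support` and the alternative reading is reported
alongside. A loss on a terminal branch is classed independent.

## The synthetic benchmark

`make_reference` builds a random intact gene — by default 13 exons of
lengths (190, 140, 148, 155, 132, 120, 145, 122, 131, 126, 144, 136,
126), summing to a 1815-nt CDS (604-aa protein), 700-nt introns with
canonical GT/AG boundaries, and 600-nt intergenic flanks. These are
desk-scale stand-ins for a mid-sized vertebrate monooxygenase-family
locus; all randomness flows from explicit integer seeds.

`apply_mutation_plan` realizes splice substitutions (one nt of the
dinucleotide), nonsense codons (a single substitution creating a stop in
the tracked frame — never via indel, so `ns` and frameshift truths stay
independent), insertions/deletions, terminal truncations (intron left
intact), single- and multi-exon deletions (retaining ≥ 200 nt of intron
on each side so the flank-co-location rule is exercisable; terminal
deletions extend 100 nt into the flank), translocations (exon excised
with ±50 nt context onto its own contig), and whole-gene deletion.
`fragment_to_contigs` splits the locus at intron/intergenic positions at
least 300 nt from every surviving exon, so fragmentation can sever
structural evidence but never truncates an exon or strips its splice
context.

**Unambiguous placement.** When the generator chooses event positions it
rejects placements whose optimal-alignment representation differs from
the plan: indels keep a gap-cost margin of matching sequence on both
sides, terminal truncations must not be partially re-alignable across the
boundary (the analogue of indel normalization in variant calling, where
an ambiguous event has no canonical length), and frameshifted stretches
are resampled until they contain no incidental stop codon. Plans that
cannot be realized unambiguously on a given reference are redrawn in the
randomized suite. Events pinned to explicit positions are realized
verbatim, with truth codes derived from the realized sequence.

**What this does and does not show.** Passing the benchmark shows the
pipeline recovers exactly the lesions it is pointed at, under clean
sequence (no sequencing error, no polymorphism), moderate divergence
(target exons differ from the reference only by the planted events), and
unambiguous event representations. Real cross-species data add neutral
divergence between reference and target, ambiguous indel placements,
assembly errors, and repeats — so real-data recovery will be lower than
the benchmark's, and the thresholds above exist precisely to be tuned per
dataset. The mixture of loss modes in the randomized suite (≈ 22% intact,
30% point-mutation sets, 25% deletion runs, 11% translocations, 12%
whole-gene deletions) mirrors the proportions reported in published bird
surveys of this gene family.

## Problem sizes

The packaged survey table covers 57 species × 13 exons. The acceptance
script and the recovery test each run 200 simulated genomes per condition
(unfragmented and fragmented, up to 3 breaks), ~12-kb loci; oracle
equivalence checks run on ≤ 60-nt exons (alignment), ≤ 5-kb sequences
(dotplot), and ≤ 12-leaf trees (Dollo), sizes at which the brute-force
oracles are exact and fast.

## Known limitations

* Exon hits shorter than the seed k-mer (after heavy truncation) or with
  identity below threshold are invisible; there is no spliced-alignment
  rescue or read-level re-assembly.
* Terminal-truncation lengths are alignment-derived; under real neutral
  divergence the boundary can shift by a few nt when the deleted segment
  resembles the retained intron.
* The deletion/translocation rules need anchors: when fragmentation
  splits both exon neighbours and the intron windows, evidence is
  genuinely gone and the exon stays "absent-inconclusive".
* Breakpoints are not resolved to base pair, and inversions are visible
  only in the dotplot, not called.
* Mutation identity across species uses exact keys; convergent identical
  indels at homoplastic sites would be read as shared ancestry.
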