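# pseudoscan

Exon-aware pseudogene detection on fragmented genome assemblies, with
phylogenetic gene-loss mapping.

## The problem

When a protein-coding gene decays into a pseudogene, the wreckage is
scattered across three levels of evidence: ORF-disrupting point mutations
(splice-site substitutions, frameshifting indels, nonsense codons) inside
surviving exons; genomic rearrangements that delete or translocate whole
exons; and, at the extreme, deletion of the entire locus. Screening dozens
of whole-genome-shotgun (WGS) assemblies for such decay — as comparative
studies of sensory-gene loss do for genes like *MOXD2*, a monooxygenase
DBH-like gene implicated in olfaction and repeatedly lost across bird
lineages — means locating each reference exon in unordered contig sets,
classifying every lesion, and then asking on a phylogeny which losses are
shared (one ancestral event) and which are independent.

`pseudoscan` implements that pipeline end to end:

* **gene_model** — reference gene (FASTA + GFF3 exons) and target contig
  sets; minus-strand genes are normalized to plus orientation at load.
* **exon_mapper** — k-mer-seeded local alignment of each exon against both
  strands of every contig (match +2, mismatch −3, gap of length *L* costs
  5 + 2*L*; N matches nothing), and assembly of the "virtual cDNA" from
  best hits.
* **mutation_caller** — per-exon codes in a compact dialect: `sa`/`sd`
  (splice acceptor/donor), `ns` (nonsense codon), `i#`/`d#`
  (insertion/deletion of # nt), `5d#`/`3d#` (terminal truncations), plus
  gene status (intact / disrupted / gene_deleted / inconclusive).
* **structural_caller** — `ed` (exon deletion: absent exon whose flanking
  regions co-locate on one contig with a correspondingly shortened gap),
  `tl` (translocation: exon on a different contig than its co-located
  flanks), `gd` (whole-gene deletion: no trace of any exon, with a control
  paralog detected to rule out an assembly gap).
* **dotplot** — exact k-mer anchor chains between reference and target for
  visual verification of deletions/translocations.
* **loss_inference** — Dollo parsimony (loss is irreversible): one loss
  event per maximal all-lost clade, corroborated by mutations shared
  identically across the clade; clades with no shared mutation are flagged
  with both readings (ancestral loss vs. independent losses).
* **synthetic_data** — a generator of intact reference genes and mutated,
  contig-fragmented target genomes with machine-readable truth tables,
  used to validate the whole pipeline.
* **reporting** — the mutation-table dialect (parse/emit) and its summary
  statistics; a transcription of a published 57-species bird *MOXD2*
  survey is packaged as `data/bird_moxd2_mutations.tsv`.

## Worked example

```python
import pseudoscan as ps
from pseudoscan.synthetic_data import Event, MutationPlan

model = ps.make_reference(seed=1)          # 13 exons, 1815-nt CDS, 604-aa protein
plan = MutationPlan(events=(Event("del", 1, 17), Event("sd", 1)), seed=7)
genome, truth = ps.simulate_species(model, plan, species_id="manakin-like")

report = ps.analyze_species(model, genome)
print(report.cell_text(1), "|", report.status)
```

prints

```
d17, sd | disrupted
```

— exon 1 carries a 17-nt deletion (`d17`, a frameshift) and a splice-donor
mutation (`sd`: the intron no longer begins with GT), so the gene is
classified disrupted; the remaining exons are clean. The same cell string
appears in row "Golden-collared manakin" of the packaged survey table.

Summary statistics over a mutation table:

```python
counts = ps.summarize(ps.load_bird_survey())
# {'intact': 19, 'mutated': 32, 'both_point_and_ed': 21, 'point_only': 10,
#  'ed_only': 1, 'gd': 6, 'ed_species': 22, 'tl_species': 8,
#  'point_species': 31, 'any_loss': 38}
```

A thin CLI mirrors the library: `pseudoscan map`, `pseudoscan call`,
`pseudoscan dotplot`, `pseudoscan report`, `pseudoscan simulate`.

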