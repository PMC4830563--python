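"""Reference gene model and target genome containers with FASTA/GFF3 I/O.

The reference gene is held as a plus-strand genomic segment with an ordered
list of exon intervals. Minus-strand genes are reverse-complemented at load
time so that every downstream module is strand-free. Coordinates are 0-based
half-open internally; GFF3 I/O and human-readable reports are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = set("ACGTN")
STOP_CODONS = {"TAA", "TAG", "TGA"}


class GeneModelError(ValueError):
    """Raised when a gene model violates a structural invariant."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string in frame 0 (codons with N become X)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


@dataclass(frozen=True)
class GeneModel:
    """An intact reference gene on a plus-strand genomic segment.

    Parameters
    ----------
    gene_id:
        Identifier used in GFF3 output and reports.
    chrom_seq:
        Uppercase genomic sequence (A/C/G/T/N) containing the gene and its
        flanking context.
    exons:
        Ordered, non-overlapping ``(start, end)`` intervals (0-based,
        half-open) on ``chrom_seq``. Their concatenation is the CDS,
        start codon through stop codon.
    """

    gene_id: str
    chrom_seq: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    chrom_id: str = "ref"

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, exon_index: int) -> int:
        s, e = self.exons[exon_index - 1]
        return e - s

    def exon_seq(self, exon_index: int) -> str:
        s, e = self.exons[exon_index - 1]
        return self.chrom_seq[s:e]

    @property
    def cds_phase_per_exon(self) -> tuple[int, ...]:
        """Codon offset of each exon's first base (0 = starts a codon)."""
        phases = []
        total = 0
        for s, e in self.exons:
            phases.append(total % 3)
            total += e - s
        return tuple(phases)

    def cds(self) -> str:
        return "".join(self.chrom_seq[s:e] for s, e in self.exons)

    def protein(self) -> str:
        """Translation of the CDS, without the terminal stop."""
        aa = translate(self.cds())
        return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class ExonContext:
    """An exon sequence with its 2-nt intronic flanks (None at gene ends)."""

    exon_index: int
    seq: str
    left_flank: Optional[str]
    right_flank: Optional[str]


@dataclass
class TargetGenome:
    """A set of assembly contigs for one species."""

    species_id: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for cid, seq in self.contigs.items():
            if cid in norm:
                raise GeneModelError(f"duplicate contig id {cid!r}")
            s = seq.upper()
            if not s:
                raise GeneModelError(f"empty contig {cid!r}")
            if set(s) - VALID_ALPHABET:
                bad = sorted(set(s) - VALID_ALPHABET)
                raise GeneModelError(
                    f"contig {cid!r} contains invalid characters {bad}"
                )
            norm[cid] = s
        self.contigs = norm

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self.contigs.items())


def validate_gene_model(model: GeneModel) -> None:
    """Check every GeneModel invariant; raise GeneModelError naming the first
    violated one."""
    if not model.exons:
        raise GeneModelError("gene model has no exons")
    if set(model.chrom_seq) - VALID_ALPHABET:
        raise GeneModelError("chrom_seq contains characters outside A/C/G/T/N")
    prev_end = None
    for i, (s, e) in enumerate(model.exons, start=1):
        if not (0 <= s < e <= len(model.chrom_seq)):
            raise GeneModelError(f"exon {i} interval ({s}, {e}) out of bounds")
        if prev_end is not None:
            if s < prev_end:
                raise GeneModelError("overlapping exons")
            if s - prev_end < 2:
                raise GeneModelError(
                    f"exon {i} boundary lacks 2 nt of intron context"
                )
        prev_end = e
    if model.exons[0][0] < 0 or len(model.chrom_seq) - model.exons[-1][1] < 0:
        raise GeneModelError("exons extend past chrom_seq")
    cds = model.cds()
    if len(cds) % 3 != 0:
        raise GeneModelError("CDS length is not a multiple of 3")
    if not cds.startswith("ATG"):
        raise GeneModelError("CDS does not start with ATG")
    aa = translate(cds)
    if not aa.endswith("*"):
        raise GeneModelError("CDS does not end with a stop codon")
    if "*" in aa[:-1]:
        raise GeneModelError("reference ORF contains an internal stop codon")


def exon_sequence(model: GeneModel, exon_index: int) -> ExonContext:
    """Exon sequence plus left/right 2-nt intronic context.

    The first exon has no acceptor (left) context and the last exon no donor
    (right) context, mirroring gene boundaries.
    """
    if not 1 <= exon_index <= model.n_exons:
        raise IndexError(
            f"exon_index {exon_index} out of range 1..{model.n_exons}"
        )
    s, e = model.exons[exon_index - 1]
    left = model.chrom_seq[s - 2 : s].lower() if exon_index > 1 else None
    right = (
        model.chrom_seq[e : e + 2].lower()
        if exon_index < model.n_exons
        else None
    )
    return ExonContext(exon_index, model.chrom_seq[s:e], left, right)


# ---------------------------------------------------------------------------
# I/O


def write_gene_model(model: GeneModel, fasta_path, gff3_path) -> None:
    """Write the genomic segment as FASTA and the exon structure as GFF3
    (1-based inclusive coordinates, plus strand)."""
    rec = SeqRecord(
        Seq(model.chrom_seq), id=model.chrom_id, description=model.gene_id
    )
    SeqIO.write([rec], str(fasta_path), "fasta")
    lines = ["##gff-version 3"]
    gstart = model.exons[0][0] + 1
    gend = model.exons[-1][1]
    lines.append(
        "\t".join(
            [
                model.chrom_id,
                "pseudoscan",
                "gene",
                str(gstart),
                str(gend),
                ".",
                "+",
                ".",
                f"ID={model.gene_id}",
            ]
        )
    )
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(
            "\t".join(
                [
                    model.chrom_id,
                    "pseudoscan",
                    "exon",
                    str(s + 1),
                    str(e),
                    ".",
                    "+",
                    ".",
                    f"ID={model.gene_id}.exon{i};Parent={model.gene_id}",
                ]
            )
        )
    Path(gff3_path).write_text("\n".join(lines) + "\n")


def _exon_features_for_gene(db: "gffutils.FeatureDB", gene_id: str):
    feats = []
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent", [])
        ids = feat.attributes.get("ID", [])
        genes = feat.attributes.get("gene_id", [])
        if (
            gene_id in parents
            or gene_id in genes
            or any(i.startswith(gene_id) for i in ids)
        ):
            feats.append(feat)
    return feats


def read_gene_model(fasta_path, gff3_path, gene_id: str) -> GeneModel:
    """Load a reference gene from FASTA + GFF3 and normalize it to plus
    orientation.

    Raises GeneModelError if the gene is absent or any invariant is violated
    (including a reference ORF that is itself disrupted).
    """
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats = _exon_features_for_gene(db, gene_id)
    if not feats:
        raise GeneModelError(f"gene {gene_id!r} not found in {gff3_path}")
    chrom_ids = {f.seqid for f in feats}
    if len(chrom_ids) != 1:
        raise GeneModelError(f"gene {gene_id!r} spans multiple sequences")
    chrom_id = chrom_ids.pop()
    if chrom_id not in seqs:
        raise GeneModelError(f"sequence {chrom_id!r} missing from FASTA")
    strands = {f.strand for f in feats}
    if len(strands) != 1:
        raise GeneModelError(f"gene {gene_id!r} has mixed strands")
    strand = strands.pop()
    chrom_seq = seqs[chrom_id]
    exons = sorted((f.start - 1, f.end) for f in feats)  # to 0-based half-open
    if strand == "-":
        n = len(chrom_seq)
        chrom_seq = reverse_complement(chrom_seq)
        exons = sorted((n - e, n - s) for s, e in exons)
    model = GeneModel(
        gene_id=gene_id,
        chrom_seq=chrom_seq,
        exons=tuple(exons),
        strand="+",
        chrom_id=chrom_id,
    )
    validate_gene_model(model)
    return model


def read_target_genome(fasta_path, species_id: Optional[str] = None) -> TargetGenome:
    """Load a multi-FASTA contig set; sequences are uppercased on read."""
    if species_id is None:
        species_id = Path(fasta_path).stem
    contigs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not contigs:
        raise GeneModelError(f"no contigs found in {fasta_path}")
    return TargetGenome(species_id=species_id, contigs=contigs)


def write_target_genome(genome: TargetGenome, fasta_path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.contigs.items()
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
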