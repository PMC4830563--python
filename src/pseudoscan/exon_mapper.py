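"""Locate reference exons in target contigs and assemble the virtual cDNA.

Each exon is searched on both strands of every contig with a k-mer-seeded
local alignment under a fixed score contract: match +2, mismatch -3, and an
affine gap of length L costing 5 + 2L (N matches nothing). The best hits
per exon, in exon order, are concatenated into a "virtual cDNA" and
virtually translated; this is the substrate for ORF-disruption calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices
from .gene_model import GeneModel, TargetGenome, reverse_complement, translate

AT_EDGE = "at-contig-edge"


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


def make_aligner(scoring: Scoring = Scoring()) -> Align.PairwiseAligner:
    """Local affine-gap aligner implementing the score contract.

    A gap of length L costs ``|gap_open| + |gap_extend| * L``; codons with N
    never score as matches.
    """
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                mat[a, b] = scoring.match
            else:
                mat[a, b] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


@dataclass(frozen=True)
class ExonHit:
    """One local alignment of a reference exon to a target contig.

    Coordinates are 0-based half-open. ``strand`` gives the contig strand
    the exon matched; all sequence fields (``target_seq``, flanks, aligned
    blocks) are reported in the plus orientation of the exon. Target
    coordinates of the blocks refer to the oriented contig (the reverse
    complement for minus-strand hits); ``t_start``/``t_end`` are original
    contig coordinates.
    """

    exon_index: int
    contig_id: str
    strand: str
    t_start: int
    t_end: int
    r_start: int
    r_end: int
    score: float
    identity: float
    ref_coverage: float
    target_seq: str
    left_flank: str  # 2-nt intron context, or AT_EDGE
    right_flank: str
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    ot_start: int = 0  # oriented-frame target start
    ot_end: int = 0


@dataclass
class VirtualCdna:
    """Concatenated best exon hits in exon order, with per-exon status."""

    status: list[str]  # hit | partial | absent
    seq: str
    translation: str


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _seed_windows(
    exon: str, contig_index: dict[str, list[int]], k: int, pad: int
) -> list[tuple[int, int]]:
    """Cluster seed positions into candidate alignment windows."""
    positions: list[int] = []
    for i in range(len(exon) - k + 1):
        positions.extend(contig_index.get(exon[i : i + k], ()))
    if not positions:
        return []
    positions.sort()
    windows = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev > 2 * len(exon):
            windows.append((max(0, start - pad), prev + k + pad))
            start = p
        prev = p
    windows.append((max(0, start - pad), prev + k + pad))
    return windows


def _align_in_window(
    aligner,
    exon: str,
    oriented: str,
    w_start: int,
    w_end: int,
    min_identity: float,
    min_coverage: float,
    out: list,
) -> None:
    window = oriented[w_start:w_end]
    if not window:
        return
    alignments = aligner.align(window, exon)
    if alignments.score <= 0:
        return
    aln = alignments[0]
    t_blocks, r_blocks = aln.aligned
    ts, te = int(t_blocks[0][0]), int(t_blocks[-1][1])
    rs, re = int(r_blocks[0][0]), int(r_blocks[-1][1])
    matches = aligned_cols = 0
    for (tb0, tb1), (rb0, rb1) in zip(t_blocks, r_blocks):
        for dt in range(tb1 - tb0):
            aligned_cols += 1
            if window[tb0 + dt] == exon[rb0 + dt]:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = (re - rs) / len(exon)
    if identity >= min_identity and coverage >= min_coverage:
        blocks = tuple(
            ((int(r0), int(r1)), (w_start + int(t0), w_start + int(t1)))
            for (t0, t1), (r0, r1) in zip(t_blocks, r_blocks)
        )
        out.append(
            (
                float(alignments.score),
                w_start + ts,
                w_start + te,
                rs,
                re,
                identity,
                coverage,
                blocks,
            )
        )
    # look for further non-overlapping hits on either side
    if te - ts < w_end - w_start:
        left_end = w_start + ts
        right_start = w_start + te
        if left_end - w_start >= len(exon) * min_coverage:
            _align_in_window(
                aligner, exon, oriented, w_start, left_end, min_identity, min_coverage, out
            )
        if w_end - right_start >= len(exon) * min_coverage:
            _align_in_window(
                aligner, exon, oriented, right_start, w_end, min_identity, min_coverage, out
            )


def find_exon_hits(
    model: GeneModel,
    genome: TargetGenome,
    min_identity: float = 0.6,
    min_coverage: float = 0.3,
    seed_k: int = 11,
    scoring: Scoring = Scoring(),
) -> dict[int, list[ExonHit]]:
    """All local alignments of each exon to the contigs, per exon, sorted by
    score (ties: contig id, then leftmost start).

    Empty hit lists are valid results — an exon with no alignment meeting
    the identity/coverage thresholds is simply absent from the assembly.
    """
    aligner = make_aligner(scoring)
    oriented_contigs: dict[tuple[str, str], str] = {}
    indexes: dict[tuple[str, str], dict[str, list[int]]] = {}
    for cid, seq in genome.contigs.items():
        oriented_contigs[(cid, "+")] = seq
        oriented_contigs[(cid, "-")] = reverse_complement(seq)
    hits: dict[int, list[ExonHit]] = {}
    for exon_index in range(1, model.n_exons + 1):
        exon = model.exon_seq(exon_index)
        pad = len(exon) + 60
        found: list[ExonHit] = []
        for (cid, strand), oriented in oriented_contigs.items():
            if len(oriented) < seed_k or len(exon) < seed_k:
                continue
            key = (cid, strand)
            if key not in indexes:
                indexes[key] = _kmer_index(oriented, seed_k)
            windows = _seed_windows(exon, indexes[key], seed_k, pad)
            raw: list = []
            for w_start, w_end in windows:
                _align_in_window(
                    aligner, exon, oriented, w_start, w_end,
                    min_identity, min_coverage, raw,
                )
            n = len(oriented)
            for score, ots, ote, rs, re, identity, coverage, blocks in raw:
                left = oriented[ots - 2 : ots] if ots >= 2 else AT_EDGE
                right = oriented[ote : ote + 2] if n - ote >= 2 else AT_EDGE
                if strand == "+":
                    t_start, t_end = ots, ote
                else:
                    t_start, t_end = n - ote, n - ots
                found.append(
                    ExonHit(
                        exon_index=exon_index,
                        contig_id=cid,
                        strand=strand,
                        t_start=t_start,
                        t_end=t_end,
                        r_start=rs,
                        r_end=re,
                        score=score,
                        identity=identity,
                        ref_coverage=coverage,
                        target_seq=oriented[ots:ote],
                        left_flank=left,
                        right_flank=right,
                        blocks=blocks,
                        ot_start=ots,
                        ot_end=ote,
                    )
                )
        # drop strand-duplicate hits over the same contig interval
        found.sort(key=lambda h: (-h.score, h.contig_id, h.t_start))
        dedup: list[ExonHit] = []
        for h in found:
            if any(
                h.contig_id == g.contig_id
                and h.t_start < g.t_end
                and g.t_start < h.t_end
                for g in dedup
            ):
                continue
            dedup.append(h)
        hits[exon_index] = dedup
    return hits


def best_hits(hits: dict[int, list[ExonHit]]) -> dict[int, Optional[ExonHit]]:
    """Deterministic best hit per exon (highest score; ties broken by contig
    id then leftmost target start)."""
    return {e: (hs[0] if hs else None) for e, hs in hits.items()}


def assemble_virtual_cdna(
    model: GeneModel, best: dict[int, Optional[ExonHit]]
) -> VirtualCdna:
    """Exon-ordered concatenation of the target side of each best hit.

    Absent exons contribute nothing but are recorded; the concatenation is
    translated in frame 0 from its start, stopping at the first stop codon.
    """
    status = []
    parts = []
    for e in range(1, model.n_exons + 1):
        hit = best.get(e)
        if hit is None:
            status.append("absent")
            continue
        status.append("hit" if hit.ref_coverage >= 0.999 else "partial")
        parts.append(hit.target_seq)
    seq = "".join(parts)
    aa = translate(seq)
    if "*" in aa:
        aa = aa[: aa.index("*") + 1]
    return VirtualCdna(status=status, seq=seq, translation=aa)
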