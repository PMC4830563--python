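"""Call exon deletions (ed), translocations (tl) and whole-gene deletion (gd)
from contig context.

The rules operationalize flanking-region evidence on fragmented assemblies:

* an absent exon (or maximal run of absent exons) is *deleted* when the
  nearest detected exons — or, at the gene termini, 200-nt anchor windows
  from the reference flanks — co-locate on one contig in consistent order
  and orientation, with the gap between them shorter than the reference
  span by at least the missing exon lengths;
* an exon is *translocated* when its best hit sits on a different contig
  than its co-located neighbours, whose gap shows the exon's sequence
  missing from where it should sit;
* the whole gene is *deleted* only when no exon hits at all are found and
  a supplied control paralog is detected (arguing against an assembly
  gap); without a control the verdict stays "no-sequence-found".

Anything not meeting a rule degrades to "absent-inconclusive" — missing
sequence beyond a contig edge is never evidence of deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .exon_mapper import ExonHit, Scoring, make_aligner
from .gene_model import GeneModel, TargetGenome, reverse_complement

ANCHOR_WINDOW = 200


@dataclass(frozen=True)
class StructuralCall:
    kind: str  # ed | tl | gd | no-sequence-found
    exon_index: Optional[int]  # None for gene-level calls
    evidence: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class _Anchor:
    """A located reference landmark: an exon hit or a flank anchor window."""

    contig_id: str
    strand: str
    ot_start: int  # oriented-frame coordinates
    ot_end: int
    ref_start: int  # reference chrom_seq coordinates
    ref_end: int


def _anchor_from_hit(model: GeneModel, hit: ExonHit) -> _Anchor:
    s, _ = model.exons[hit.exon_index - 1]
    return _Anchor(
        contig_id=hit.contig_id,
        strand=hit.strand,
        ot_start=hit.ot_start,
        ot_end=hit.ot_end,
        ref_start=s + hit.r_start,
        ref_end=s + hit.r_end,
    )


def _locate_window(
    model: GeneModel,
    genome: TargetGenome,
    ref_start: int,
    ref_end: int,
    min_identity: float = 0.8,
    scoring: Scoring = Scoring(),
) -> Optional[_Anchor]:
    """Best local-alignment placement of a reference anchor window."""
    if ref_start < 0 or ref_end > len(model.chrom_seq) or ref_end - ref_start < 30:
        return None
    window = model.chrom_seq[ref_start:ref_end]
    aligner = make_aligner(scoring)
    best = None
    for cid in sorted(genome.contigs):
        seq = genome.contigs[cid]
        for strand in "+-":
            oriented = seq if strand == "+" else reverse_complement(seq)
            alignments = aligner.align(oriented, window)
            if alignments.score <= 0:
                continue
            aln = alignments[0]
            t_blocks, r_blocks = aln.aligned
            ts, te = int(t_blocks[0][0]), int(t_blocks[-1][1])
            rs, re = int(r_blocks[0][0]), int(r_blocks[-1][1])
            matches = cols = 0
            for (t0, t1), (r0, r1) in zip(t_blocks, r_blocks):
                for dt in range(t1 - t0):
                    cols += 1
                    if oriented[t0 + dt] == window[r0 + dt]:
                        matches += 1
            if not cols or matches / cols < min_identity:
                continue
            if (re - rs) / len(window) < 0.5:
                continue
            score = float(alignments.score)
            if best is None or score > best[0]:
                best = (
                    score,
                    _Anchor(cid, strand, ts, te, ref_start + rs, ref_start + re),
                )
    return best[1] if best else None


def _co_located(left: _Anchor, right: _Anchor) -> bool:
    return (
        left.contig_id == right.contig_id
        and left.strand == right.strand
        and left.ot_end <= right.ot_start
    )


def call_exon_deletions(
    model: GeneModel,
    best: dict[int, Optional[ExonHit]],
    genome: TargetGenome,
    anchor_window: int = ANCHOR_WINDOW,
) -> tuple[list[StructuralCall], dict[int, str]]:
    """ed calls for maximal runs of absent exons with co-located flanks.

    Returns the calls and a resolution map for absent exons:
    "absent_deleted" or "absent_inconclusive".
    """
    n = model.n_exons
    calls: list[StructuralCall] = []
    resolution: dict[int, str] = {}
    absent = [e for e in range(1, n + 1) if best.get(e) is None]
    if not absent or len(absent) == n:
        return calls, {e: "absent_inconclusive" for e in absent}

    runs: list[tuple[int, int]] = []
    start = prev = absent[0]
    for e in absent[1:]:
        if e == prev + 1:
            prev = e
        else:
            runs.append((start, prev))
            start = prev = e
    runs.append((start, prev))

    for j, k in runs:
        left_candidates: list[_Anchor] = []
        for e in range(j - 1, 0, -1):
            if best.get(e) is not None:
                left_candidates.append(_anchor_from_hit(model, best[e]))
                break
        right_candidates: list[_Anchor] = []
        for e in range(k + 1, n + 1):
            if best.get(e) is not None:
                right_candidates.append(_anchor_from_hit(model, best[e]))
                break
        # non-exonic anchor windows adjacent to the run: the start of the
        # intron after the previous exon / the end of the intron before the
        # next exon (reference flank windows at the gene termini)
        if j > 1:
            lo = model.exons[j - 2][1]
            win = _locate_window(model, genome, lo, lo + anchor_window)
        else:
            g0 = model.exons[0][0]
            win = _locate_window(
                model, genome, g0 - 2 * anchor_window, g0 - anchor_window
            )
        if win is not None:
            left_candidates.append(win)
        if k < n:
            hi = model.exons[k][0]
            win = _locate_window(model, genome, hi - anchor_window, hi)
        else:
            gn = model.exons[-1][1]
            win = _locate_window(
                model, genome, gn + anchor_window, gn + 2 * anchor_window
            )
        if win is not None:
            right_candidates.append(win)

        deleted = False
        missing = sum(model.exon_length(e) for e in range(j, k + 1))
        left = right = None
        for left in left_candidates:
            for right in right_candidates:
                if not _co_located(left, right):
                    continue
                tgt_gap = right.ot_start - left.ot_end
                ref_span = right.ref_start - left.ref_end
                if ref_span - tgt_gap >= missing:
                    deleted = True
                    break
            if deleted:
                break
        if deleted:
            tgt_gap = right.ot_start - left.ot_end
            ref_span = right.ref_start - left.ref_end
            for e in range(j, k + 1):
                calls.append(
                    StructuralCall(
                        "ed",
                        e,
                        evidence={
                            "contig": left.contig_id,
                            "run": (j, k),
                            "ref_span": ref_span,
                            "target_gap": tgt_gap,
                        },
                    )
                )
        for e in range(j, k + 1):
            resolution[e] = "absent_deleted" if deleted else "absent_inconclusive"
    return calls, resolution


def call_translocations(
    model: GeneModel,
    best: dict[int, Optional[ExonHit]],
    genome: TargetGenome,
    anchor_window: int = ANCHOR_WINDOW,
    anchor_offset: int = 50,
) -> list[StructuralCall]:
    """tl calls: the exon's best hit on one contig while its flanking
    regions co-locate on another with the exon's sequence missing from
    between them.

    Flanking regions are the nearest detected exons; when those are split
    across contigs (fragmentation), 200-nt reference intron windows
    adjacent to the exon's slot (offset by ``anchor_offset`` to skip
    sequence that may travel with the exon) serve as anchors instead.
    """
    n = model.n_exons
    calls: list[StructuralCall] = []
    for e in range(1, n + 1):
        hit = best.get(e)
        if hit is None:
            continue
        left_candidates: list[_Anchor] = []
        right_candidates: list[_Anchor] = []
        for i in range(e - 1, 0, -1):
            if best.get(i) is not None:
                left_candidates.append(_anchor_from_hit(model, best[i]))
                break
        for i in range(e + 1, n + 1):
            if best.get(i) is not None:
                right_candidates.append(_anchor_from_hit(model, best[i]))
                break
        exon_pair = bool(left_candidates) and bool(right_candidates) and _co_located(
            left_candidates[0], right_candidates[0]
        )
        alone_on_contig = not any(
            h is not None and h.contig_id == hit.contig_id
            for i, h in best.items()
            if i != e
        )
        if not exon_pair and alone_on_contig:
            # fall back to intron anchor windows beside the exon's slot
            s, t = model.exons[e - 1]
            win = _locate_window(
                model, genome, s - anchor_offset - anchor_window, s - anchor_offset
            )
            if win is not None:
                left_candidates.append(win)
            win = _locate_window(
                model, genome, t + anchor_offset, t + anchor_offset + anchor_window
            )
            if win is not None:
                right_candidates.append(win)
        found = None
        for left in left_candidates:
            for right in right_candidates:
                if not _co_located(left, right):
                    continue
                if hit.contig_id == left.contig_id:
                    continue
                tgt_gap = right.ot_start - left.ot_end
                ref_span = right.ref_start - left.ref_end
                if ref_span - tgt_gap >= 0.5 * model.exon_length(e):
                    found = (left, right, ref_span, tgt_gap)
                    break
            if found:
                break
        if found:
            left, right, ref_span, tgt_gap = found
            calls.append(
                StructuralCall(
                    "tl",
                    e,
                    evidence={
                        "exon_contig": hit.contig_id,
                        "flank_contig": left.contig_id,
                        "ref_span": ref_span,
                        "target_gap": tgt_gap,
                    },
                )
            )
    return calls


def call_gene_deletion(
    best: dict[int, Optional[ExonHit]],
    control_best: Optional[dict[int, Optional[ExonHit]]] = None,
) -> Optional[StructuralCall]:
    """gd when no exon of the target gene is found anywhere and the control
    paralog is detected; inconclusive otherwise."""
    if any(h is not None for h in best.values()):
        return None
    if control_best is None:
        return StructuralCall(
            "no-sequence-found", None, evidence={"control": "not supplied"}
        )
    control_found = any(h is not None for h in control_best.values())
    if control_found:
        return StructuralCall("gd", None, evidence={"control": "detected"})
    return StructuralCall(
        "no-sequence-found", None, evidence={"control": "also absent"}
    )
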