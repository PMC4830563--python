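"""Classify ORF-disrupting point mutations per exon.

Calls are rendered in a compact code dialect: ``sa``/``sd`` for splice
acceptor/donor mutations, ``ns`` for a nonsense (stop) codon, ``i#``/``d#``
for an insertion/deletion of # nt, ``5d#``/``3d#`` for #-nt truncations of
the exon's 5'/3' end, plus the structural codes ``ed`` (exon deletion),
``tl`` (translocation) and ``gd`` (gene deletion) emitted elsewhere.

Reading-frame convention: stop codons are scanned straight through the
target-side exon segment in the exon's reference start phase. For internal
indels this equals tracking the cumulative frameshift through the exon; the
frame resets to the reference phase at each exon start, so per-exon codes
never depend on mutations in earlier exons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .exon_mapper import AT_EDGE, ExonHit
from .gene_model import GeneModel

STOP_CODONS = {"TAA", "TAG", "TGA"}

POINT_CODE_KINDS = ("sa", "sd", "ns", "i", "d", "5d", "3d")
_CODE_RE = re.compile(r"^(?:(sa|sd|ns|ed|tl|gd)|(i|d|5d|3d)([1-9]\d*))$")


def render_code(kind: str, length: int = 0) -> str:
    """Render a (kind, length) pair as a table code, e.g. ('d', 17) → 'd17'."""
    if kind in ("sa", "sd", "ns", "ed", "tl", "gd"):
        return kind
    if kind in ("i", "d", "5d", "3d"):
        if length < 1:
            raise ValueError(f"{kind} code requires a positive length")
        return f"{kind}{length}"
    raise ValueError(f"unknown mutation kind {kind!r}")


def parse_code(code: str) -> tuple[str, int]:
    """Inverse of render_code; raises ValueError on unknown tokens."""
    m = _CODE_RE.match(code.strip())
    if not m:
        raise ValueError(f"unknown mutation code {code!r}")
    if m.group(1):
        return m.group(1), 0
    return m.group(2), int(m.group(3))


def stop_scan(seq: str, phase: int, skip_terminal_stop: bool = False) -> list[int]:
    """1-based start positions of stop codons when ``seq`` is read in a
    frame where its first base sits at codon offset ``phase``. Codons
    containing N are skipped (ambiguous, never called). With
    ``skip_terminal_stop`` a stop occupying the final 3 nt is ignored —
    the natural termination codon of a gene's last exon."""
    skip = (3 - phase) % 3
    out = []
    for i in range(skip, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            if skip_terminal_stop and i + 3 == len(seq):
                continue
            out.append(i + 1)
    return out


@dataclass(frozen=True)
class MutationCall:
    exon_index: int
    kind: str
    length: int
    position: int  # 1-based offset; see module docstring for ns convention
    code: str
    note: str = ""

    @classmethod
    def make(cls, exon_index, kind, length, position, note=""):
        return cls(exon_index, kind, length, position, render_code(kind, length), note)


def _sort_key(call: MutationCall, exon_len: int) -> float:
    if call.kind == "sa":
        return -2.0
    if call.kind == "5d":
        return -1.0
    if call.kind == "3d":
        return exon_len + 1.0
    if call.kind == "sd":
        return exon_len + 2.0
    return float(call.position)


def call_point_mutations(
    model: GeneModel,
    hit: ExonHit,
    allow_gc_donor: bool = False,
) -> list[MutationCall]:
    """Derive per-exon mutation codes from one exon alignment.

    From the alignment: (a) ``sa`` when the 2 nt left of the alignment are
    not AG (internal exons, flank present); (b) ``sd`` when the 2 nt right
    are not GT (GC optionally tolerated); (c) each alignment gap becomes
    ``i#``/``d#``, and unaligned reference overhangs at the exon termini
    become ``5d#``/``3d#`` when target sequence continues past the
    alignment edge; (d) ``ns`` for each stop codon in the target segment
    read in the exon's start phase. At a contig edge, splice and terminal
    calls are suppressed and an "inconclusive flank" note attached.
    """
    e = hit.exon_index
    exon_len = model.exon_length(e)
    phase = model.cds_phase_per_exon[e - 1]
    calls: list[MutationCall] = []

    left_at_edge = hit.left_flank == AT_EDGE
    right_at_edge = hit.right_flank == AT_EDGE

    # splice sites
    if e > 1:
        if left_at_edge:
            calls.append(MutationCall(e, "note", 0, 0, "", "inconclusive flank (5' at contig edge)"))
        elif hit.left_flank != "AG":
            calls.append(MutationCall.make(e, "sa", 0, 0))
    if e < model.n_exons:
        if right_at_edge:
            calls.append(MutationCall(e, "note", 0, exon_len + 1, "", "inconclusive flank (3' at contig edge)"))
        else:
            donor_ok = hit.right_flank == "GT" or (allow_gc_donor and hit.right_flank == "GC")
            if not donor_ok:
                calls.append(MutationCall.make(e, "sd", 0, exon_len + 1))

    # terminal truncations
    if hit.r_start > 0:
        if left_at_edge:
            calls.append(MutationCall(e, "note", 0, 1, "", "inconclusive 5' truncation (contig edge)"))
        else:
            calls.append(MutationCall.make(e, "5d", hit.r_start, 1))
    if hit.r_end < exon_len:
        if right_at_edge:
            calls.append(MutationCall(e, "note", 0, exon_len, "", "inconclusive 3' truncation (contig edge)"))
        else:
            calls.append(MutationCall.make(e, "3d", exon_len - hit.r_end, hit.r_end + 1))

    # alignment gaps, 5' → 3'
    blocks = hit.blocks
    for (r_prev, t_prev), (r_next, t_next) in zip(blocks, blocks[1:]):
        ref_jump = r_next[0] - r_prev[1]
        tgt_jump = t_next[0] - t_prev[1]
        if ref_jump > 0:
            calls.append(MutationCall.make(e, "d", ref_jump, r_prev[1] + 1))
        if tgt_jump > 0:
            calls.append(MutationCall.make(e, "i", tgt_jump, r_prev[1] + 1))

    # nonsense codons in the realized (target-side) exon segment
    is_last = e == model.n_exons
    for pos in stop_scan(hit.target_seq, phase, skip_terminal_stop=is_last):
        calls.append(MutationCall.make(e, "ns", 0, pos))

    notes = [c for c in calls if c.kind == "note"]
    real = [c for c in calls if c.kind != "note"]
    real.sort(key=lambda c: _sort_key(c, exon_len))
    return real + notes


def classify_gene_status(
    calls_by_exon: dict[int, list[MutationCall]],
    presence_by_exon: dict[int, str],
    structural_codes_by_exon: dict[int, list[str]],
    translation: str,
    reference_protein_length: int,
) -> str:
    """Overall gene status from per-exon evidence.

    intact: every exon present with zero calls and the virtual cDNA
    translates to a full-length protein (within one codon of the
    reference). gene_deleted: whole-gene deletion called. inconclusive:
    the only anomalies are at contig edges or unresolvable absences.
    disrupted: anything else.
    """
    if any("gd" in codes for codes in structural_codes_by_exon.values()):
        return "gene_deleted"
    has_calls = any(
        c.kind != "note" for calls in calls_by_exon.values() for c in calls
    )
    has_structural = any(
        c in ("ed", "tl") for codes in structural_codes_by_exon.values() for c in codes
    )
    has_notes = any(
        c.kind == "note" for calls in calls_by_exon.values() for c in calls
    )
    statuses = set(presence_by_exon.values())
    all_present = statuses <= {"hit", "partial"}
    if has_calls or has_structural:
        return "disrupted"
    if all_present:
        aa = translation
        full = aa.endswith("*") and aa.startswith("M") and (
            abs((len(aa) - 1) - reference_protein_length) <= 1
        )
        if full and not has_notes:
            return "intact"
        return "inconclusive" if has_notes else "disrupted"
    # some exons missing but nothing callable: edge/ambiguous evidence only
    if "absent_inconclusive" in statuses or has_notes:
        return "inconclusive"
    return "disrupted"
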