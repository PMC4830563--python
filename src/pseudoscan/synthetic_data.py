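"""Synthetic reference genes and mutated, contig-fragmented target genomes.

The generator emulates the situation faced when screening fragmented
whole-genome-shotgun assemblies for a pseudogenized gene: an intact
multi-exon reference, and per-species genomes carrying known
ORF-disrupting events — splice-site substitutions, small insertions and
deletions, nonsense codons, terminal (5'/3') exon truncations, single- and
multi-exon genomic deletions, exon translocations onto separate contigs,
and whole-gene deletion. Every genome ships with a machine-readable
TruthRecord holding the per-exon mutation codes the detection pipeline is
expected to recover.

Events are *placed* (when no explicit position is given) so that their
representation under the pipeline's alignment scoring is unambiguous:

* indels keep enough perfectly matching sequence on both sides that the
  optimal alignment cannot trade the gap against terminal trimming;
* terminal truncations are rejected when the removed segment could be
  partially re-aligned against the retained intron (which would shorten
  the apparent truncation), analogous to indel normalization in variant
  calling where an ambiguous event has no single canonical length;
* frameshifted stretches are resampled until they contain no incidental
  stop codon, so a planned insertion yields exactly ``i1`` and not
  ``i1, ns``.

When a caller pins an explicit position, the event is realized verbatim and
the truth codes are derived from the realized sequence (incidental stops
included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .gene_model import (
    GeneModel,
    GeneModelError,
    TargetGenome,
    validate_gene_model,
)
from .mutation_caller import STOP_CODONS, render_code, stop_scan

POINT_KINDS = ("sa", "sd", "ns", "ins", "del", "del5", "del3")
STRUCTURAL_KINDS = ("exon_del", "segment_del", "translocation", "gene_del")

DEFAULT_EXON_LENGTHS = (190, 140, 148, 155, 132, 120, 145, 122, 131, 126, 144, 136, 126)
DEFAULT_INTRON_LENGTH = 700
DEFAULT_FLANK_LENGTH = 600

#: nt of intron retained on each side of a genomic (exon/segment) deletion
DELETION_FLANK_KEEP = 200
#: nt of flanking context removed beyond the outermost exon of a terminal deletion
TERMINAL_TRIM = 100
#: nt of intron carried along with a translocated exon
TRANSLOCATION_CONTEXT = 50

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Raised when a plan cannot be realized (conflicts, unsatisfiable layout)."""


@dataclass(frozen=True)
class Event:
    """One planned mutation.

    kind: one of sa, sd, ns, ins, del, del5, del3, exon_del, segment_del,
    translocation, gene_del. ``exon`` is a 1-based exon id, or an inclusive
    ``(first, last)`` pair for segment_del, or None for gene_del.
    ``position`` is a 0-based offset within the (realized) exon for
    ins/del/ns; None means the generator chooses an unambiguous site.
    """

    kind: str
    exon: Union[int, tuple[int, int], None] = None
    length: int = 0
    position: Optional[int] = None


@dataclass(frozen=True)
class MutationPlan:
    events: tuple[Event, ...]
    seed: int = 0


@dataclass(frozen=True)
class TruthRecord:
    """Expected per-exon mutation codes and gene status for one genome."""

    species_id: str
    cells: tuple[tuple[str, ...], ...]
    status: str  # intact | disrupted | gene_deleted
    ns_positions: tuple[tuple[int, ...], ...] = ()

    def cell_text(self, exon_index: int) -> str:
        return ", ".join(self.cells[exon_index - 1])


@dataclass
class MutatedLocus:
    """The realized locus: main genomic sequence plus satellite contigs."""

    main_seq: str
    exon_regions: list[Optional[tuple[int, int]]]
    extra_contigs: list[str] = field(default_factory=list)
    realized_events: list[Event] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reference construction


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_reference(
    seed: int,
    n_exons: int = 13,
    exon_lengths: Optional[Sequence[int]] = None,
    intron_lengths: Optional[Sequence[int]] = None,
    flank_length: int = DEFAULT_FLANK_LENGTH,
    gene_id: str = "refgene",
) -> GeneModel:
    """Build a random but valid intact gene model, deterministic per seed.

    The CDS starts with ATG, ends with a single stop codon, contains no
    internal stop, and every intron begins with GT and ends with AG.
    """
    if exon_lengths is None:
        if n_exons == len(DEFAULT_EXON_LENGTHS):
            exon_lengths = DEFAULT_EXON_LENGTHS
        else:
            base = [120] * n_exons
            base[0] += (3 - sum(base) % 3) % 3
            exon_lengths = base
    exon_lengths = list(exon_lengths)
    if len(exon_lengths) != n_exons:
        raise GeneModelError("exon_lengths does not match n_exons")
    if n_exons < 2:
        raise GeneModelError("need at least 2 exons")
    if any(l <= 0 for l in exon_lengths):
        raise GeneModelError("exon lengths must be positive")
    total = sum(exon_lengths)
    if total % 3 != 0:
        raise GeneModelError("total CDS length must be a multiple of 3")
    if intron_lengths is None:
        intron_lengths = [DEFAULT_INTRON_LENGTH] * (n_exons - 1)
    intron_lengths = list(intron_lengths)
    if len(intron_lengths) != n_exons - 1:
        raise GeneModelError("need n_exons - 1 intron lengths")
    if any(l < 20 for l in intron_lengths):
        raise GeneModelError("intron lengths must be >= 20")

    rng = np.random.default_rng(seed)
    n_codons = total // 3
    cds = "ATG" + _random_codons(rng, n_codons - 2)
    cds += ["TAA", "TAG", "TGA"][int(rng.integers(3))]

    # split CDS into exons
    exon_seqs = []
    pos = 0
    for l in exon_lengths:
        exon_seqs.append(cds[pos : pos + l])
        pos += l

    introns = [
        "GT" + _random_seq(rng, l - 4) + "AG" for l in intron_lengths
    ]
    flank5 = _random_seq(rng, flank_length)
    flank3 = _random_seq(rng, flank_length)

    parts = [flank5]
    exons = []
    cursor = len(flank5)
    for i, es in enumerate(exon_seqs):
        exons.append((cursor, cursor + len(es)))
        parts.append(es)
        cursor += len(es)
        if i < n_exons - 1:
            parts.append(introns[i])
            cursor += len(introns[i])
    parts.append(flank3)

    model = GeneModel(
        gene_id=gene_id,
        chrom_seq="".join(parts),
        exons=tuple(exons),
        strand="+",
        chrom_id=f"{gene_id}_chrom",
    )
    validate_gene_model(model)
    return model


# ---------------------------------------------------------------------------
# Alignment-ambiguity guards

_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 2, -3, -5, -2


def _anchored_extension_score(a: str, b: str) -> int:
    """Best score of an alignment extension anchored at position 0 of both
    strings (Gotoh affine; gap of length L costs 5 + 2L). Positive means the
    removed segment could be partially re-aligned across the boundary."""
    la, lb = len(a), len(b)
    neg = -(10 ** 6)
    best = 0
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a
    M[0][0] = 0
    for i in range(la + 1):
        for j in range(lb + 1):
            if i > 0:
                X[i][j] = max(
                    M[i - 1][j] + _GAP_OPEN + _GAP_EXTEND,
                    X[i - 1][j] + _GAP_EXTEND,
                )
            if j > 0:
                Y[i][j] = max(
                    M[i][j - 1] + _GAP_OPEN + _GAP_EXTEND,
                    Y[i][j - 1] + _GAP_EXTEND,
                )
            if i > 0 and j > 0:
                s = _MATCH if a[i - 1] == b[j - 1] else _MISMATCH
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            best = max(best, M[i][j])
    return best


def _indel_margin(length: int) -> int:
    """Matching nt required on both sides of an indel so the optimal
    alignment cannot trade the gap against terminal trimming."""
    return (5 + 2 * length + 1) // 2 + 3


# ---------------------------------------------------------------------------
# Plan application


def _validate_plan(model: GeneModel, plan: MutationPlan) -> None:
    n = model.n_exons
    deleted: set[int] = set()
    translocated: set[int] = set()
    gene_del = False
    point_exons: dict[int, list[Event]] = {}
    for ev in plan.events:
        if ev.kind == "gene_del":
            gene_del = True
            continue
        if ev.kind in ("exon_del", "segment_del"):
            if ev.kind == "exon_del":
                j = k = int(ev.exon)
            else:
                j, k = ev.exon  # type: ignore[misc]
            if not (1 <= j <= k <= n):
                raise SimulationError(f"deletion run {j}..{k} outside exons")
            deleted.update(range(j, k + 1))
            continue
        if ev.kind == "translocation":
            e = int(ev.exon)
            if not 1 <= e <= n:
                raise SimulationError(f"translocation exon {e} out of range")
            translocated.add(e)
            continue
        if ev.kind not in POINT_KINDS:
            raise SimulationError(f"unknown event kind {ev.kind!r}")
        e = int(ev.exon)
        if not 1 <= e <= n:
            raise SimulationError(f"event exon {e} out of range")
        if ev.kind == "sa" and e == 1:
            raise SimulationError("sa impossible on first exon (no acceptor)")
        if ev.kind == "sd" and e == n:
            raise SimulationError("sd impossible on last exon (no donor)")
        if ev.kind in ("ins", "del", "del5", "del3") and ev.length < 1:
            raise SimulationError(f"{ev.kind} length must be >= 1")
        point_exons.setdefault(e, []).append(ev)
    if gene_del and (deleted or translocated or point_exons):
        raise SimulationError("gene_del excludes all other events")
    if deleted & translocated:
        raise SimulationError(
            "translocation and deletion are mutually exclusive per exon"
        )
    if set(point_exons) & deleted:
        raise SimulationError("point events on a deleted exon")
    for t in translocated:
        if any(abs(t - d) == 1 for d in deleted):
            raise SimulationError(
                "translocated exon adjacent to a deleted exon (shared intron)"
            )
    if deleted and len(deleted) == n:
        raise SimulationError("deleting every exon: use gene_del")


class _Applier:
    def __init__(self, model: GeneModel, plan: MutationPlan):
        _validate_plan(model, plan)
        self.model = model
        self.plan = plan
        self.rng = np.random.default_rng(plan.seed)
        n = model.n_exons
        g0 = model.exons[0][0]
        gn = model.exons[-1][1]
        self.flank5 = model.chrom_seq[:g0]
        self.flank3 = model.chrom_seq[gn:]
        self.exon_seqs = [model.exon_seq(i) for i in range(1, n + 1)]
        self.introns = [
            model.chrom_seq[model.exons[i][1] : model.exons[i + 1][0]]
            for i in range(n - 1)
        ]
        self.codes: list[list[tuple[float, str]]] = [[] for _ in range(n)]
        self.ns_pos: list[list[int]] = [[] for _ in range(n)]
        self.deleted: set[int] = set()
        self.translocated: dict[int, str] = {}
        self.gene_del = False
        self.realized: list[Event] = []

    # -- splice-site substitutions -------------------------------------
    def _mutate_dinuc(self, dinuc: str, canonical: str) -> str:
        while True:
            pos = int(self.rng.integers(2))
            new = str(self.rng.choice(_BASES))
            cand = dinuc[:pos] + new + dinuc[pos + 1 :]
            if cand != dinuc and cand != canonical:
                return cand

    def _apply_splice(self, ev: Event) -> None:
        e = int(ev.exon)
        exon_len = len(self.exon_seqs[e - 1])
        if ev.kind == "sa":
            intron = self.introns[e - 2]
            self.introns[e - 2] = intron[:-2] + self._mutate_dinuc(intron[-2:], "AG")
            self.codes[e - 1].append((-2.0, "sa"))
        else:
            intron = self.introns[e - 1]
            self.introns[e - 1] = self._mutate_dinuc(intron[:2], "GT") + intron[2:]
            self.codes[e - 1].append((exon_len + 2.0, "sd"))
        self.realized.append(ev)

    # -- point events within one exon ----------------------------------
    def _left_context(self, e: int) -> str:
        return self.introns[e - 2] if e > 1 else self.flank5

    def _right_context(self, e: int) -> str:
        return self.introns[e - 1] if e <= len(self.introns) else self.flank3

    def _apply_exon_events(self, e: int, events: list[Event], max_tries: int = 300) -> None:
        """Realize del5/del3/ins/del/ns on exon ``e`` with unambiguous
        placement, retrying stochastic choices until the realized sequence
        scans clean (planned stop codons and nothing else)."""
        phase = self.model.cds_phase_per_exon[e - 1]
        ref = self.exon_seqs[e - 1]
        pinned = all(ev.position is not None for ev in events if ev.kind != "del5" and ev.kind != "del3")
        last_err = "placement failed"
        for _ in range(max_tries):
            ok, result = self._try_realize(e, ref, phase, events)
            if ok:
                seq, codes, ns_positions, realized = result
                self.exon_seqs[e - 1] = seq
                self.codes[e - 1].extend(codes)
                self.ns_pos[e - 1].extend(ns_positions)
                self.realized.extend(realized)
                return
            last_err = result
            if pinned:
                break
        if pinned:
            # verbatim realization with truth derived from the sequence
            seq, codes, ns_positions, realized = self._realize_verbatim(e, ref, phase, events)
            self.exon_seqs[e - 1] = seq
            self.codes[e - 1].extend(codes)
            self.ns_pos[e - 1].extend(ns_positions)
            self.realized.extend(realized)
            return
        raise SimulationError(
            f"could not realize events on exon {e} after {max_tries} attempts: {last_err}"
        )

    def _try_realize(self, e, ref, phase, events):
        rng = self.rng
        is_last = e == self.model.n_exons
        seq = ref
        codes: list[tuple[float, str]] = []
        realized: list[Event] = []
        used: list[tuple[int, int]] = []  # occupied (start, end) in current seq
        del5 = next((ev for ev in events if ev.kind == "del5"), None)
        del3 = next((ev for ev in events if ev.kind == "del3"), None)
        internal = [ev for ev in events if ev.kind in ("ins", "del")]
        ns_events = [ev for ev in events if ev.kind == "ns"]

        offset5 = 0
        if del5 is not None:
            L = del5.length
            if L > len(ref) // 2:
                return False, "del5 longer than half the exon"
            context = self._left_context(e)
            if _anchored_extension_score(ref[:L][::-1], context[-30:][::-1]) > 0:
                return False, "ambiguous del5 boundary"
            seq = seq[L:]
            offset5 = L
            codes.append((-1.0, render_code("5d", L)))
            realized.append(replace(del5, position=0))
        if del3 is not None:
            L = del3.length
            if L > len(seq) // 2:
                return False, "del3 longer than half the exon"
            context = self._right_context(e)
            if _anchored_extension_score(ref[len(ref) - L :], context[:30]) > 0:
                return False, "ambiguous del3 boundary"
            seq = seq[:-L]
            codes.append((len(ref) + 1.0, render_code("3d", L)))
            realized.append(replace(del3, position=len(ref) - L))

        # internal indels, applied right-to-left so positions stay valid
        placed: list[tuple[int, Event]] = []
        for ev in internal:
            L = ev.length
            m = _indel_margin(L)
            span = L if ev.kind == "del" else 0
            lo, hi = m, len(seq) - m - span
            if hi < lo:
                return False, f"exon too short for {ev.kind}{L}"
            if ev.position is not None:
                p = ev.position
                if not (0 <= p <= len(seq) - span):
                    raise SimulationError("event outside exon bounds")
            else:
                p = int(rng.integers(lo, hi + 1))
                if any(p - 12 < u_end and u_start < p + span + 12 for u_start, u_end in used):
                    return False, "events too close"
            used.append((p, p + span))
            placed.append((p, ev))
        for p, ev in sorted(placed, key=lambda t: -t[0]):
            if ev.kind == "del":
                if seq[p : p + ev.length] == "":
                    return False, "deletion outside sequence"
                seq = seq[:p] + seq[p + ev.length :]
                codes.append((offset5 + p + 1.0, render_code("d", ev.length)))
            else:
                ins = _random_seq(rng, ev.length)
                seq = seq[:p] + ins + seq[p:]
                codes.append((offset5 + p + 1.0, render_code("i", ev.length)))
            realized.append(replace(ev, position=p))

        incidental = stop_scan(seq, phase, skip_terminal_stop=is_last)
        if incidental:
            return False, "incidental stop codon in realized frame"

        # nonsense codons: single-nt substitutions creating a stop in the
        # exon's start phase, scanned straight through the realized sequence
        skip = (3 - phase) % 3
        ns_positions: list[int] = []
        for ev in ns_events:
            if ev.position is not None:
                c = ev.position
            else:
                starts = [
                    i
                    for i in range(skip, len(seq) - 2, 3)
                    if i >= 3
                    and i + 3 <= len(seq) - 3
                    and not any(i - 6 < u_end and u_start < i + 9 for u_start, u_end in used)
                    and self._stop_one_sub(seq[i : i + 3]) is not None
                ]
                if not starts:
                    return False, "no codon available for ns"
                c = int(rng.choice(starts))
            stop = self._stop_one_sub(seq[c : c + 3])
            if stop is None:
                return False, "codon cannot become a stop by one substitution"
            seq = seq[:c] + stop + seq[c + 3 :]
            used.append((c, c + 3))
            ns_positions.append(c + 1)
            codes.append((c + 1.0, "ns"))
            realized.append(replace(ev, position=c))

        found = stop_scan(seq, phase, skip_terminal_stop=is_last)
        if sorted(found) != sorted(ns_positions):
            return False, "stop-codon scan does not match plan"
        return True, (seq, codes, ns_positions, realized)

    def _realize_verbatim(self, e, ref, phase, events):
        ok, result = self._try_realize(e, ref, phase, events)
        if ok:
            return result
        # realize at pinned positions, deriving truth from the sequence
        seq = ref
        codes: list[tuple[float, str]] = []
        realized: list[Event] = []
        for ev in sorted(
            [ev for ev in events if ev.kind in ("ins", "del")],
            key=lambda ev: -(ev.position or 0),
        ):
            p = ev.position or 0
            if ev.kind == "del":
                seq = seq[:p] + seq[p + ev.length :]
                codes.append((p + 1.0, render_code("d", ev.length)))
            else:
                seq = seq[:p] + _random_seq(self.rng, ev.length) + seq[p:]
                codes.append((p + 1.0, render_code("i", ev.length)))
            realized.append(ev)
        ns_positions = stop_scan(seq, phase, skip_terminal_stop=(e == self.model.n_exons))
        for pos in ns_positions:
            codes.append((float(pos), "ns"))
        return seq, codes, ns_positions, realized

    @staticmethod
    def _stop_one_sub(codon: str) -> Optional[str]:
        if len(codon) != 3 or codon in STOP_CODONS:
            return None
        for stop in ("TAA", "TAG", "TGA"):
            if sum(a != b for a, b in zip(codon, stop)) == 1:
                return stop
        return None

    # -- structural events ---------------------------------------------
    def _apply_deletion_run(self, j: int, k: int) -> None:
        n = self.model.n_exons
        keep = DELETION_FLANK_KEEP
        if j > 1:
            if len(self.introns[j - 2]) < keep + 10:
                raise SimulationError("intron too short to retain deletion flank")
            self.introns[j - 2] = self.introns[j - 2][:keep]
        else:
            self.flank5 = self.flank5[:-TERMINAL_TRIM]
        if k < n:
            if len(self.introns[k - 1]) < keep + 10:
                raise SimulationError("intron too short to retain deletion flank")
            self.introns[k - 1] = self.introns[k - 1][-keep:]
        else:
            self.flank3 = self.flank3[TERMINAL_TRIM:]
        for e in range(j, k + 1):
            self.deleted.add(e)
            self.codes[e - 1] = [(-10.0, "ed")]
        for idx in range(j - 1, k - 1):  # introns fully inside the run
            self.introns[idx] = ""

    def _apply_translocation(self, e: int) -> None:
        ctx = TRANSLOCATION_CONTEXT
        if e > 1:
            left = self.introns[e - 2][-ctx:]
            self.introns[e - 2] = self.introns[e - 2][:-ctx]
        else:
            left = self.flank5[-ctx:]
            self.flank5 = self.flank5[:-ctx]
        if e <= len(self.introns):
            right = self.introns[e - 1][:ctx]
            self.introns[e - 1] = self.introns[e - 1][ctx:]
        else:
            right = self.flank3[:ctx]
            self.flank3 = self.flank3[ctx:]
        self.translocated[e] = left + self.exon_seqs[e - 1] + right
        self.codes[e - 1].append((-10.0, "tl"))

    # -- main ------------------------------------------------------------
    def run(self) -> tuple[MutatedLocus, list[list[tuple[float, str]]]]:
        events = self.plan.events
        if any(ev.kind == "gene_del" for ev in events):
            self.gene_del = True
            trim = TERMINAL_TRIM
            main = self.flank5[:-trim] + self.flank3[trim:]
            locus = MutatedLocus(
                main_seq=main,
                exon_regions=[None] * self.model.n_exons,
                realized_events=[Event("gene_del")],
            )
            for i in range(self.model.n_exons):
                self.codes[i] = [(-10.0, "gd")]
            return locus, self.codes

        for ev in events:
            if ev.kind in ("sa", "sd"):
                self._apply_splice(ev)
        by_exon: dict[int, list[Event]] = {}
        for ev in events:
            if ev.kind in ("ns", "ins", "del", "del5", "del3"):
                by_exon.setdefault(int(ev.exon), []).append(ev)
        for e, evs in sorted(by_exon.items()):
            self._apply_exon_events(e, evs)
        for ev in events:
            if ev.kind == "exon_del":
                self._apply_deletion_run(int(ev.exon), int(ev.exon))
                self.realized.append(ev)
            elif ev.kind == "segment_del":
                j, k = ev.exon  # type: ignore[misc]
                self._apply_deletion_run(j, k)
                self.realized.append(ev)
        for ev in events:
            if ev.kind == "translocation":
                self._apply_translocation(int(ev.exon))
                self.realized.append(ev)

        parts = [self.flank5]
        cursor = len(self.flank5)
        regions: list[Optional[tuple[int, int]]] = []
        n = self.model.n_exons
        for i in range(1, n + 1):
            if i in self.deleted or i in self.translocated:
                regions.append(None)
            else:
                es = self.exon_seqs[i - 1]
                regions.append((cursor, cursor + len(es)))
                parts.append(es)
                cursor += len(es)
            if i <= len(self.introns):
                parts.append(self.introns[i - 1])
                cursor += len(self.introns[i - 1])
        parts.append(self.flank3)
        locus = MutatedLocus(
            main_seq="".join(parts),
            exon_regions=regions,
            extra_contigs=[self.translocated[e] for e in sorted(self.translocated)],
            realized_events=self.realized,
        )
        return locus, self.codes


def apply_mutation_plan(
    model: GeneModel, plan: MutationPlan, species_id: str = "sim"
) -> tuple[MutatedLocus, TruthRecord]:
    """Realize a mutation plan on the reference locus.

    Returns the mutated locus (main genomic sequence, satellite contigs for
    translocated exons, updated exon coordinates) and the TruthRecord of
    expected per-exon codes in canonical order (tl/ed first, then 5'→3').
    """
    applier = _Applier(model, plan)
    locus, keyed = applier.run()
    cells = tuple(
        tuple(code for _, code in sorted(c, key=lambda t: t[0])) for c in keyed
    )
    if applier.gene_del:
        status = "gene_deleted"
    elif any(cells[i] for i in range(model.n_exons)):
        status = "disrupted"
    else:
        status = "intact"
    truth = TruthRecord(
        species_id=species_id,
        cells=cells,
        status=status,
        ns_positions=tuple(tuple(sorted(p)) for p in applier.ns_pos),
    )
    return locus, truth


# ---------------------------------------------------------------------------
# Contig fragmentation


def fragment_to_contigs(
    locus: MutatedLocus,
    seed: int,
    n_breaks: int = 0,
    min_flank: int = 300,
    species_id: str = "sim",
    control_seq: Optional[str] = None,
) -> TargetGenome:
    """Split the mutated locus into WGS-like contigs.

    Breaks fall only in introns/intergenic sequence, at least ``min_flank``
    nt from every surviving exon, so that fragmentation never truncates an
    exon or strips its splice context. Translocated exons are emitted on
    their own contigs; contig names and order are randomized per seed.
    """
    rng = np.random.default_rng(seed)
    main = locus.main_seq
    legal = np.ones(len(main) + 1, dtype=bool)
    legal[: min(50, len(main))] = False
    legal[-min(50, len(main)) :] = False
    for region in locus.exon_regions:
        if region is None:
            continue
        s, e = region
        lo = max(0, s - min_flank)
        hi = min(len(main) + 1, e + min_flank)
        legal[lo:hi] = False
    positions: list[int] = []
    for _ in range(n_breaks):
        candidates = np.flatnonzero(legal)
        if candidates.size == 0:
            raise SimulationError("min_flank unsatisfiable: no legal break positions")
        p = int(rng.choice(candidates))
        positions.append(p)
        legal[max(0, p - 50) : p + 50] = False
    positions.sort()

    pieces = []
    prev = 0
    for p in positions:
        pieces.append(main[prev:p])
        prev = p
    pieces.append(main[prev:])
    pieces = [p for p in pieces if p]
    pieces.extend(locus.extra_contigs)
    if control_seq:
        pieces.append(control_seq)

    order = rng.permutation(len(pieces))
    ids = [f"CTG{int(x):07d}" for x in rng.choice(10 ** 7, size=len(pieces), replace=False)]
    contigs = {ids[rank]: pieces[int(i)] for rank, i in enumerate(order)}
    return TargetGenome(species_id=species_id, contigs=contigs)


# ---------------------------------------------------------------------------
# Randomized plan suite


def random_plan(model: GeneModel, seed: int) -> MutationPlan:
    """Sample a plan emulating the observed mixture of loss modes: intact
    genomes, point-mutation sets, exon/segment deletions, translocations,
    and whole-gene deletions."""
    rng = np.random.default_rng(seed)
    n = model.n_exons
    u = rng.random()
    events: list[Event] = []

    def sample_point(exon_pool: list[int], count: int) -> None:
        kinds = ["ns", "del", "ins", "sa", "sd", "del5", "del3"]
        weights = np.array([0.30, 0.22, 0.20, 0.10, 0.08, 0.05, 0.05])
        pool = list(exon_pool)
        rng.shuffle(pool)
        for e in pool[:count]:
            kind = str(rng.choice(kinds, p=weights / weights.sum()))
            if kind == "sa" and e == 1:
                kind = "ns"
            if kind == "sd" and e == n:
                kind = "ns"
            if kind == "del":
                events.append(Event("del", e, int(rng.integers(1, 26))))
            elif kind == "ins":
                events.append(Event("ins", e, int(rng.integers(1, 16))))
            elif kind in ("del5", "del3"):
                events.append(Event(kind, e, int(rng.integers(2, 14)) * 3))
            else:
                events.append(Event(kind, e))

    if u < 0.22:
        pass  # intact
    elif u < 0.52:
        sample_point(list(range(1, n + 1)), int(rng.integers(1, 5)))
    elif u < 0.72:
        run_len = int(rng.integers(1, 4))
        j = int(rng.integers(1, n - run_len + 2))
        k = j + run_len - 1
        if run_len == 1:
            events.append(Event("exon_del", j))
        else:
            events.append(Event("segment_del", (j, k)))
        pool = [e for e in range(1, n + 1) if e < j - 1 or e > k + 1]
        sample_point(pool, int(rng.integers(1, 4)))
    elif u < 0.77:
        j = int(rng.integers(1, n + 1))
        events.append(Event("exon_del", j))
    elif u < 0.88:
        t = int(rng.integers(2, n))
        events.append(Event("translocation", t))
        pool = [e for e in range(1, n + 1) if e != t]
        sample_point(pool, int(rng.integers(0, 3)))
    else:
        events.append(Event("gene_del"))
    return MutationPlan(events=tuple(events), seed=seed)


def simulate_species(
    model: GeneModel,
    plan: MutationPlan,
    species_id: str = "sim",
    n_breaks: int = 0,
    min_flank: int = 300,
    control_model: Optional[GeneModel] = None,
) -> tuple[TargetGenome, TruthRecord]:
    """Realize a plan and fragment the result into a TargetGenome."""
    locus, truth = apply_mutation_plan(model, plan, species_id=species_id)
    genome = fragment_to_contigs(
        locus,
        seed=plan.seed + 104729,
        n_breaks=n_breaks,
        min_flank=min_flank,
        species_id=species_id,
        control_seq=control_model.chrom_seq if control_model else None,
    )
    return genome, truth


def simulate_suite(
    model: GeneModel,
    n_genomes: int,
    seed: int,
    fragmented: bool = False,
    max_breaks: int = 3,
    control_model: Optional[GeneModel] = None,
) -> list[tuple[TargetGenome, TruthRecord, MutationPlan]]:
    """A reproducible suite of mutated genomes with truth tables."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_genomes):
        n_breaks = int(rng.integers(0, max_breaks + 1)) if fragmented else 0
        # rejection-sample plans: one whose events cannot all be placed
        # unambiguously on this reference is discarded and redrawn
        for _ in range(50):
            plan_seed = int(rng.integers(1, 2 ** 31 - 1))
            plan = random_plan(model, plan_seed)
            try:
                genome, truth = simulate_species(
                    model,
                    plan,
                    species_id=f"sim{i:04d}",
                    n_breaks=n_breaks,
                    control_model=control_model,
                )
            except SimulationError:
                continue
            break
        else:
            raise SimulationError("could not realize any sampled plan")
        out.append((genome, truth, plan))
    return out
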