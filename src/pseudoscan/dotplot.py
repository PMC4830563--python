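"""Pairwise genomic match coordinates for dotplot inspection of exon
deletions and translocations.

Exact k-mer matches are collapsed into maximal exact match runs on both
strands, then co-linear runs separated by at most ``merge_gap`` on both
axes are merged. The output is a table of coordinate pairs suitable for
any generic plotter; rendering is optional and untested surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .gene_model import GeneModel, reverse_complement


@dataclass(frozen=True)
class AnchorMatch:
    ref_start: int
    ref_end: int
    tgt_start: int
    tgt_end: int
    strand: str
    length: int


def _maximal_runs(ref: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= k nt as (ref_start, tgt_start, length)."""
    index: dict[str, list[int]] = {}
    for j in range(len(ref) - k + 1):
        kmer = ref[j : j + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(j)
    # active runs per diagonal: diag -> (run_start_t, last_t, ref_start)
    active: dict[int, tuple[int, int, int]] = {}
    runs: list[tuple[int, int, int]] = []
    for t in range(len(target) - k + 1):
        kmer = target[t : t + k]
        for j in index.get(kmer, ()):
            diag = j - t
            run = active.get(diag)
            if run is not None and run[1] == t - 1:
                active[diag] = (run[0], t, run[2])
            else:
                if run is not None:
                    runs.append((run[2], run[0], run[1] - run[0] + k))
                active[diag] = (t, t, j)
    for run in active.values():
        runs.append((run[2], run[0], run[1] - run[0] + k))
    return runs


def _merge_colinear(
    runs: list[tuple[int, int, int]], merge_gap: int
) -> list[tuple[int, int, int, int]]:
    """Merge co-linear (ref, tgt) runs separated by <= merge_gap on both
    axes; returns (ref_start, ref_end, tgt_start, tgt_end)."""
    intervals = [(r, r + l, t, t + l) for r, t, l in runs]
    intervals.sort(key=lambda x: (x[0], x[2]))
    merged: list[list[int]] = []
    for rs, re, ts, te in intervals:
        placed = False
        for m in merged:
            ref_gap = rs - m[1]
            tgt_gap = ts - m[3]
            if -merge_gap <= ref_gap <= merge_gap and -merge_gap <= tgt_gap <= merge_gap:
                m[1] = max(m[1], re)
                m[3] = max(m[3], te)
                placed = True
                break
        if not placed:
            merged.append([rs, re, ts, te])
    return [tuple(m) for m in merged]


def compute_anchors(
    ref: str, target: str, k: int = 16, merge_gap: int = 20
) -> list[AnchorMatch]:
    """All maximal exact k-mer match runs between ref and target on both
    strands, with co-linear merging; deterministic and symmetric under
    transposition of the two sequences."""
    ref = ref.upper()
    target = target.upper()
    if k > len(ref) or k > len(target):
        warnings.warn(
            f"k={k} exceeds a sequence length; returning no anchors", stacklevel=2
        )
        return []
    anchors: list[AnchorMatch] = []
    for rs, re_, ts, te in _merge_colinear(_maximal_runs(ref, target, k), merge_gap):
        anchors.append(AnchorMatch(rs, re_, ts, te, "+", re_ - rs))
    # minus strand: match ref against the reverse complement of target,
    # merge in that frame, then map target coordinates back
    rc = reverse_complement(target)
    n = len(target)
    for rs, re_, ts, te in _merge_colinear(_maximal_runs(ref, rc, k), merge_gap):
        anchors.append(AnchorMatch(rs, re_, n - te, n - ts, "-", re_ - rs))
    anchors.sort(key=lambda a: (a.ref_start, a.tgt_start, a.strand))
    return anchors


def annotate_exon_overlap(
    anchors: list[AnchorMatch], model: GeneModel
) -> dict[int, bool]:
    """Per-exon covered flag: True iff any anchor intersects the exon's
    reference interval (anchors must be computed against model.chrom_seq)."""
    covered = {}
    for e in range(1, model.n_exons + 1):
        s, end = model.exons[e - 1]
        covered[e] = any(
            a.ref_start < end and s < a.ref_end for a in anchors
        )
    return covered


def write_anchor_tsv(anchors: list[AnchorMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_start\tref_end\ttgt_start\ttgt_end\tstrand\n")
        for a in anchors:
            fh.write(
                f"{a.ref_start + 1}\t{a.ref_end}\t{a.tgt_start + 1}\t{a.tgt_end}\t{a.strand}\n"
            )
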