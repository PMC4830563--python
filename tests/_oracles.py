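"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (quadratic DP, exhaustive enumeration,
all-k-mer scans) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

NEG = -(10 ** 9)


def sw_local_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Smith-Waterman local score with Gotoh affine gaps; a gap of length L
    costs |gap_open| + L * |gap_extend|. N never matches."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def all_kmer_matches(ref: str, target: str, k: int) -> set[tuple[int, int]]:
    """Every (ref_pos, tgt_pos) pair where the two k-mers are identical."""
    index: dict[str, list[int]] = {}
    for j in range(len(ref) - k + 1):
        index.setdefault(ref[j : j + k], []).append(j)
    out = set()
    for i in range(len(target) - k + 1):
        for j in index.get(target[i : i + k], ()):
            out.add((j, i))
    return out


def three_frame_stops(seq: str) -> dict[int, list[int]]:
    """0-based stop-codon start offsets in each of the three frames."""
    stops = {"TAA", "TAG", "TGA"}
    out = {0: [], 1: [], 2: []}
    for frame in range(3):
        for i in range(frame, len(seq) - 2, 3):
            if seq[i : i + 3] in stops:
                out[frame].append(i)
    return out


def dollo_min_events(tree, lost_leaves: set[str]) -> int:
    """Minimal number of loss branches on a dendropy tree such that exactly
    ``lost_leaves`` are below at least one chosen branch (loss is
    irreversible). Exhaustive search over branch subsets."""
    nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    leaf_sets = []
    for n in nodes:
        leaves = frozenset(l.taxon.label for l in n.leaf_iter())
        # a loss branch may not sit above any intact leaf
        if leaves <= lost_leaves:
            leaf_sets.append(leaves)
    target = frozenset(lost_leaves)
    if not target:
        return 0
    for k in range(1, len(leaf_sets) + 1):
        for combo in itertools.combinations(leaf_sets, k):
            covered = frozenset().union(*combo)
            if covered == target:
                return k
    raise AssertionError("no Dollo assignment found")
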