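"""Map gene status onto a phylogeny and infer loss events.

Gene loss is modelled as a Dollo character: a functional gene can be lost
on a branch but never regained. The minimal reconstruction therefore
assigns one loss event to every maximal clade whose (scorable) leaves all
lack an intact gene. A multi-species loss clade is corroborated when its
members share at least one identical mutation (same exon, same code, same
reference-aligned position where available) — evidence that the
disruption predates their divergence. Lost clades with no shared mutation
are flagged: the data cannot distinguish a single ancestral loss followed
by divergent decay from independent losses in each lineage, and both
readings are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import dendropy

from .reporting import SpeciesReport


class LossInferenceError(ValueError):
    pass


@dataclass(frozen=True)
class LossEvent:
    clade: tuple[str, ...]  # leaf species below the loss branch
    event_class: str  # ancestral-shared | independent
    shared: frozenset = frozenset()
    no_shared_support: bool = False
    alternative: str = ""  # alternative reading for unsupported clades
    coarse_keys: bool = False


def shared_mutations(
    reports: Iterable[SpeciesReport], clade: Iterable[str]
) -> frozenset:
    """Exact-key intersection of mutation sets over the clade members.

    Keys are (exon, kind, length, position) when positions are available
    for every member, else coarse (exon, code) keys.
    """
    clade = list(clade)
    if not clade:
        raise LossInferenceError("empty clade")
    by_id = {r.species_id: r for r in reports}
    missing = [s for s in clade if s not in by_id]
    if missing:
        raise LossInferenceError(f"species missing from reports: {missing}")
    members = [by_id[s] for s in clade]
    coarse = any(m.coarse_keys for m in members)
    if coarse:
        key_sets = [
            frozenset((e, code) for e, code in m.all_codes() if code != "gd")
            for m in members
        ]
    else:
        key_sets = [m.keys() for m in members]
    out = key_sets[0]
    for ks in key_sets[1:]:
        out = out & ks
    return frozenset(out)


def _load_tree(tree: Union[str, dendropy.Tree]) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text:  # a path rather than newick text
        text = open(text).read()
    return dendropy.Tree.get(data=text, schema="newick")


def infer_loss_events(
    tree: Union[str, dendropy.Tree],
    reports: Iterable[SpeciesReport],
) -> list[LossEvent]:
    """Minimal Dollo reconstruction of gene-loss events.

    One event per maximal clade whose scorable leaves are all non-intact
    (status inconclusive = missing data, excluded from the character).
    Raises on leaves without a report.
    """
    reports = list(reports)
    by_id = {r.species_id: r for r in reports}
    t = _load_tree(tree)
    states: dict[int, Optional[bool]] = {}  # node id -> lost?
    for leaf in t.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is None or name not in by_id:
            raise LossInferenceError(f"unmatched tree leaf {name!r}")
        status = by_id[name].status
        if status == "intact":
            states[id(leaf)] = False
        elif status in ("disrupted", "gene_deleted"):
            states[id(leaf)] = True
        else:
            states[id(leaf)] = None  # missing

    def scorable_leaves(node):
        out = []
        for leaf in node.leaf_iter():
            if states[id(leaf)] is not None:
                out.append(leaf)
        return out

    def all_lost(node) -> bool:
        leaves = scorable_leaves(node)
        return bool(leaves) and all(states[id(l)] for l in leaves)

    events: list[LossEvent] = []
    coarse = any(r.coarse_keys for r in reports)
    for node in t.preorder_node_iter():
        if not all_lost(node):
            continue
        parent = node.parent_node
        if parent is not None and all_lost(parent):
            continue  # not maximal
        clade = tuple(
            l.taxon.label for l in node.leaf_iter() if states[id(l)] is not None
        )
        if len(clade) == 1:
            events.append(
                LossEvent(clade=clade, event_class="independent", coarse_keys=coarse)
            )
            continue
        shared = shared_mutations(reports, clade)
        if shared:
            events.append(
                LossEvent(
                    clade=clade,
                    event_class="ancestral-shared",
                    shared=shared,
                    coarse_keys=coarse,
                )
            )
        else:
            events.append(
                LossEvent(
                    clade=clade,
                    event_class="ancestral-shared",
                    no_shared_support=True,
                    alternative=(
                        f"{len(clade)} independent losses (one per lineage) "
                        "equally consistent with the data"
                    ),
                    coarse_keys=coarse,
                )
            )
    return events


def annotate_tree(
    tree: Union[str, dendropy.Tree], events: list[LossEvent]
) -> str:
    """Newick with loss branches tagged '[&loss]' via node labels."""
    t = _load_tree(tree)
    lost_clades = {frozenset(ev.clade) for ev in events}
    for node in t.preorder_node_iter():
        leaves = frozenset(
            l.taxon.label for l in node.leaf_iter() if l.taxon is not None
        )
        if leaves in lost_clades:
            if node.is_leaf():
                node.taxon.label = f"{node.taxon.label}|LOSS"
            else:
                node.label = "LOSS"
    return t.as_string(schema="newick").strip()
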