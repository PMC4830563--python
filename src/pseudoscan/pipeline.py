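"""End-to-end per-species analysis: map exons, call point and structural
mutations, classify gene status, and emit a SpeciesReport."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .exon_mapper import Scoring, assemble_virtual_cdna, best_hits, find_exon_hits
from .gene_model import GeneModel, TargetGenome
from .mutation_caller import (
    MutationCall,
    call_point_mutations,
    classify_gene_status,
)
from .reporting import SpeciesReport
from .structural_caller import (
    call_exon_deletions,
    call_gene_deletion,
    call_translocations,
)


@dataclass(frozen=True)
class AnalysisConfig:
    min_identity: float = 0.6
    min_coverage: float = 0.3
    seed_k: int = 11
    scoring: Scoring = Scoring()
    allow_gc_donor: bool = False


def analyze_species(
    model: GeneModel,
    genome: TargetGenome,
    control_model: Optional[GeneModel] = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> SpeciesReport:
    """Run the full detection pipeline on one target genome.

    Cell codes follow the canonical order: structural evidence (tl) first,
    then point codes 5' → 3'; exons in a confirmed genomic deletion carry
    ``ed``; a whole-gene deletion marks every cell ``gd``.
    """
    n = model.n_exons
    hits = find_exon_hits(
        model,
        genome,
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
        seed_k=config.seed_k,
        scoring=config.scoring,
    )
    best = best_hits(hits)

    # the control paralog only matters when the target gene is entirely
    # absent, so map it lazily
    control_best = None
    if control_model is not None and all(h is None for h in best.values()):
        control_best = best_hits(
            find_exon_hits(
                control_model,
                genome,
                min_identity=config.min_identity,
                min_coverage=config.min_coverage,
                seed_k=config.seed_k,
                scoring=config.scoring,
            )
        )

    gene_call = call_gene_deletion(best, control_best)
    structural_codes: dict[int, list[str]] = {e: [] for e in range(1, n + 1)}
    presence: dict[int, str] = {}
    calls_by_exon: dict[int, list[MutationCall]] = {e: [] for e in range(1, n + 1)}
    notes: list[str] = []

    if gene_call is not None:
        if gene_call.kind == "gd":
            for e in range(1, n + 1):
                structural_codes[e].append("gd")
                presence[e] = "absent_deleted"
        else:
            for e in range(1, n + 1):
                presence[e] = "absent_inconclusive"
            notes.append(gene_call.kind)
    else:
        ed_calls, resolution = call_exon_deletions(model, best, genome)
        for call in ed_calls:
            structural_codes[call.exon_index].append("ed")
        tl_calls = call_translocations(model, best, genome)
        for call in tl_calls:
            structural_codes[call.exon_index].append("tl")
        for e in range(1, n + 1):
            hit = best[e]
            if hit is None:
                presence[e] = resolution.get(e, "absent_inconclusive")
                continue
            presence[e] = "hit" if hit.ref_coverage >= 0.999 else "partial"
            calls = call_point_mutations(model, hit, allow_gc_donor=config.allow_gc_donor)
            calls_by_exon[e] = [c for c in calls if c.kind != "note"]
            notes.extend(f"e{e}: {c.note}" for c in calls if c.kind == "note")

    vcdna = assemble_virtual_cdna(model, best)
    status = classify_gene_status(
        calls_by_exon,
        presence,
        structural_codes,
        vcdna.translation,
        len(model.protein()),
    )

    cells = []
    keys = set()
    for e in range(1, n + 1):
        cell = list(structural_codes[e])
        for c in calls_by_exon[e]:
            cell.append(c.code)
            keys.add((e, c.kind, c.length, c.position))
        for code in structural_codes[e]:
            if code == "ed":
                keys.add((e, "ed", 0, 0))
        cells.append(tuple(cell))
    return SpeciesReport(
        species_id=genome.species_id,
        cells=tuple(cells),
        status=status,
        mutation_keys=frozenset(keys),
        coarse_keys=False,
        notes=tuple(notes),
    )
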