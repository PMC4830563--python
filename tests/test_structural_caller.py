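import pytest

from pseudoscan import (
    Event,
    MutationPlan,
    TargetGenome,
    analyze_species,
    apply_mutation_plan,
    best_hits,
    call_exon_deletions,
    call_gene_deletion,
    call_translocations,
    find_exon_hits,
    simulate_species,
)


def test_terminal_adjacent_run_deleted(model):
    """Exons 11-12 removed with exon 13 retained: both are called ed from
    co-located flanks (the e10 hit and the e13 hit on one contig)."""
    genome, truth = simulate_species(
        model, MutationPlan((Event("segment_del", (11, 12)),), seed=5)
    )
    rep = analyze_species(model, genome)
    assert rep.cells[10] == ("ed",) and rep.cells[11] == ("ed",)
    assert rep.cells[12] == ()
    assert rep.cells == truth.cells


def test_absent_exon_with_split_flanks_is_inconclusive(model):
    """Negative case of the deletion rule: e4 and e6 on different contigs
    give no ed for the missing e5."""
    locus, _ = apply_mutation_plan(model, MutationPlan((Event("exon_del", 5),), seed=3))
    junction = locus.exon_regions[3][1] + 250  # inside the residual intron
    genome = TargetGenome(
        species_id="t",
        contigs={"a": locus.main_seq[:junction], "b": locus.main_seq[junction:]},
    )
    best = best_hits(find_exon_hits(model, genome))
    assert best[5] is None
    assert best[4].contig_id != best[6].contig_id
    calls, resolution = call_exon_deletions(model, best, genome)
    assert calls == []
    assert resolution[5] == "absent_inconclusive"
    rep = analyze_species(model, genome)
    assert rep.cells[4] == ()
    assert rep.status == "inconclusive"


def test_multi_exon_segment_deletion_codes_every_exon(model):
    genome, truth = simulate_species(
        model, MutationPlan((Event("segment_del", (4, 11)),), seed=9)
    )
    rep = analyze_species(model, genome)
    assert all(rep.cells[i] == ("ed",) for i in range(3, 11))
    assert rep.cells == truth.cells


def test_translocation_called_with_co_located_neighbours(model):
    genome, truth = simulate_species(
        model, MutationPlan((Event("translocation", 12),), seed=15)
    )
    rep = analyze_species(model, genome)
    assert rep.cells[11] == ("tl",) == truth.cells[11]


def test_translocation_not_called_without_context(model):
    """The tl rule's negative case: when the would-be flanking exons sit on
    separate contigs the translocated exon gets no call."""
    locus, _ = apply_mutation_plan(model, MutationPlan((Event("translocation", 2),), seed=4))
    cut = locus.exon_regions[0][1] + 600  # between e1 and e3
    genome = TargetGenome(
        species_id="t",
        contigs={
            "a": locus.main_seq[:cut],
            "b": locus.main_seq[cut:],
            "c": locus.extra_contigs[0],
        },
    )
    best = best_hits(find_exon_hits(model, genome))
    assert best[2].contig_id == "c"
    assert best[1].contig_id != best[3].contig_id
    assert call_translocations(model, best, genome) == []


def test_ed_and_tl_mutually_exclusive(model):
    """No exon ever carries both structural codes."""
    genome, _ = simulate_species(
        model,
        MutationPlan((Event("segment_del", (5, 6)), Event("translocation", 9)), seed=19),
    )
    rep = analyze_species(model, genome)
    for cell in rep.cells:
        assert not ("ed" in cell and "tl" in cell)
    assert rep.cells[8] == ("tl",)
    assert rep.cells[4] == ("ed",) and rep.cells[5] == ("ed",)


def test_gene_deletion_verdicts(model, control_model):
    plan = MutationPlan((Event("gene_del"),), seed=8)
    # control present and detected -> gd
    genome, _ = simulate_species(model, plan, control_model=control_model)
    best = best_hits(find_exon_hits(model, genome))
    control_best = best_hits(find_exon_hits(control_model, genome))
    call = call_gene_deletion(best, control_best)
    assert call.kind == "gd"
    # control supplied but also absent -> inconclusive, never gd
    genome2, _ = simulate_species(model, plan)
    best2 = best_hits(find_exon_hits(model, genome2))
    control_best2 = best_hits(find_exon_hits(control_model, genome2))
    assert call_gene_deletion(best2, control_best2).kind == "no-sequence-found"
    # no control supplied -> no-sequence-found
    assert call_gene_deletion(best2, None).kind == "no-sequence-found"
    # any exon present -> no gene-level call
    intact_best = best_hits(find_exon_hits(model, TargetGenome("t", {"c": model.chrom_seq})))
    assert call_gene_deletion(intact_best, control_best) is None


def test_fragmentation_never_fabricates_structural_calls(model, control_model):
    """Across seeded fragmented replicates, breaks may cost a call but
    never create a false ed/tl/gd."""
    from pseudoscan import simulate_suite

    suite = simulate_suite(model, 25, seed=321, fragmented=True, control_model=control_model)
    for genome, truth, _ in suite:
        rep = analyze_species(model, genome, control_model=control_model)
        for t_cell, r_cell in zip(truth.cells, rep.cells):
            for code in ("ed", "tl", "gd"):
                if code in r_cell:
                    assert code in t_cell
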