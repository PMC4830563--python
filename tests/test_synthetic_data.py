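import pytest
from Bio.Seq import Seq

from pseudoscan import (
    Event,
    MutationPlan,
    apply_mutation_plan,
    fragment_to_contigs,
    make_reference,
    simulate_species,
    validate_gene_model,
)
from pseudoscan.synthetic_data import SimulationError


def test_make_reference_is_valid_and_deterministic():
    m1 = make_reference(1)
    m2 = make_reference(1)
    validate_gene_model(m1)
    assert m1.chrom_seq == m2.chrom_seq and m1.exons == m2.exons
    assert make_reference(2).chrom_seq != m1.chrom_seq


def test_protein_length_arithmetic(model):
    """13 exons summing to 1815 nt encode (1815/3) - 1 = 604 residues,
    checked by independent translation."""
    assert sum(model.exon_length(e) for e in range(1, 14)) == 1815
    aa = str(Seq(model.cds()).translate())
    assert aa.endswith("*")
    assert len(aa) - 1 == 604
    assert model.protein() == aa[:-1]


def test_make_reference_rejects_bad_lengths():
    with pytest.raises(Exception, match="multiple of 3"):
        make_reference(1, n_exons=2, exon_lengths=[50, 51], intron_lengths=[100])
    with pytest.raises(Exception, match="at least 2"):
        make_reference(1, n_exons=1, exon_lengths=[300], intron_lengths=[])


def test_empty_plan_is_identity(model):
    locus, truth = apply_mutation_plan(model, MutationPlan(events=(), seed=1))
    assert locus.main_seq == model.chrom_seq
    assert truth.status == "intact"
    assert all(cell == () for cell in truth.cells)


def test_manakin_style_plan_truth_codes(model):
    """A 17-nt deletion plus a donor-site mutation in exon 1 yields the
    cell 'd17, sd'."""
    plan = MutationPlan(events=(Event("del", 1, 17), Event("sd", 1)), seed=7)
    locus, truth = apply_mutation_plan(model, plan)
    assert truth.cells[0] == ("d17", "sd")
    assert truth.status == "disrupted"
    # donor dinucleotide after exon 1 is no longer gt
    e1 = locus.exon_regions[0]
    assert locus.main_seq[e1[1] : e1[1] + 2] != "GT"


def test_parrot_style_insertion_truth(model):
    plan = MutationPlan(events=(Event("ins", 4, 1),), seed=9)
    _, truth = apply_mutation_plan(model, plan)
    assert truth.cells[3] == ("i1",)
    assert all(truth.cells[i] == () for i in range(13) if i != 3)


def test_gene_del_plan(model):
    locus, truth = apply_mutation_plan(model, MutationPlan((Event("gene_del"),), seed=2))
    assert truth.status == "gene_deleted"
    assert all(cell == ("gd",) for cell in truth.cells)
    assert all(r is None for r in locus.exon_regions)
    for e in range(1, 14):
        assert model.exon_seq(e) not in locus.main_seq


def test_conflicting_plans_rejected(model):
    with pytest.raises(SimulationError, match="mutually exclusive"):
        apply_mutation_plan(
            model, MutationPlan((Event("exon_del", 5), Event("translocation", 5)), seed=1)
        )
    with pytest.raises(SimulationError, match="gene_del excludes"):
        apply_mutation_plan(
            model, MutationPlan((Event("gene_del"), Event("ns", 2)), seed=1)
        )
    with pytest.raises(SimulationError, match="no acceptor"):
        apply_mutation_plan(model, MutationPlan((Event("sa", 1),), seed=1))


def test_fragment_no_breaks_single_contig(model):
    locus, _ = apply_mutation_plan(model, MutationPlan(events=(), seed=3))
    genome = fragment_to_contigs(locus, seed=5, n_breaks=0)
    assert len(genome.contigs) == 1
    assert next(iter(genome.contigs.values())) == model.chrom_seq


def test_fragment_determinism(model):
    locus, _ = apply_mutation_plan(model, MutationPlan(events=(), seed=3))
    g1 = fragment_to_contigs(locus, seed=5, n_breaks=3)
    g2 = fragment_to_contigs(locus, seed=5, n_breaks=3)
    assert g1.contigs == g2.contigs
    assert len(g1.contigs) == 4


def test_translocated_exon_on_own_contig(model):
    """Substring-search oracle: the translocated exon leaves the main
    sequence and reappears, with context, on its own contig."""
    plan = MutationPlan((Event("translocation", 2),), seed=4)
    locus, truth = apply_mutation_plan(model, plan)
    e2 = model.exon_seq(2)
    assert e2 not in locus.main_seq
    assert len(locus.extra_contigs) == 1 and e2 in locus.extra_contigs[0]
    assert truth.cells[1] == ("tl",)
    # flanking exons e1/e3 remain in the main sequence
    assert model.exon_seq(1) in locus.main_seq
    assert model.exon_seq(3) in locus.main_seq
    genome = fragment_to_contigs(locus, seed=1, n_breaks=0)
    assert any(seq == locus.extra_contigs[0] for seq in genome.contigs.values())


def test_segment_del_retains_flanks(model):
    locus, truth = apply_mutation_plan(
        model, MutationPlan((Event("segment_del", (4, 11)),), seed=6)
    )
    assert all(truth.cells[i] == ("ed",) for i in range(3, 11))
    for e in (1, 2, 3, 12, 13):
        assert model.exon_seq(e) in locus.main_seq
    for e in range(4, 12):
        assert model.exon_seq(e) not in locus.main_seq
    # >= 200 nt of intron retained on each side of the breakpoint
    gap_start = locus.exon_regions[2][1]
    gap_end = locus.exon_regions[11][0]
    assert gap_end - gap_start >= 400


def test_min_flank_unsatisfiable(model):
    tiny = make_reference(
        21, n_exons=3, exon_lengths=[60, 63, 60], intron_lengths=[60, 60],
        flank_length=60,
    )
    locus, _ = apply_mutation_plan(tiny, MutationPlan(events=(), seed=1))
    with pytest.raises(SimulationError, match="min_flank"):
        fragment_to_contigs(locus, seed=1, n_breaks=1, min_flank=300)


def test_simulation_determinism(model):
    plan = MutationPlan((Event("del", 3, 8), Event("ns", 7)), seed=11)
    g1, t1 = simulate_species(model, plan, n_breaks=2)
    g2, t2 = simulate_species(model, plan, n_breaks=2)
    assert g1.contigs == g2.contigs
    assert t1 == t2
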