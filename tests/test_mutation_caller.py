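import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pseudoscan import (
    Event,
    MutationPlan,
    TargetGenome,
    analyze_species,
    parse_code,
    render_code,
    simulate_species,
)
from pseudoscan.mutation_caller import stop_scan
from pseudoscan.synthetic_data import _Applier  # white-box helper for codon search

from _oracles import three_frame_stops


def _single_contig(seq, species="t"):
    return TargetGenome(species_id=species, contigs={"c1": seq})


@settings(max_examples=200, derandomize=True)
@given(
    kind=st.sampled_from(["sa", "sd", "ns", "ed", "tl", "gd", "i", "d", "5d", "3d"]),
    length=st.integers(min_value=1, max_value=500),
)
def test_code_render_parse_roundtrip(kind, length):
    code = render_code(kind, length)
    k, l = parse_code(code)
    assert k == kind
    assert l == (length if kind in ("i", "d", "5d", "3d") else 0)


@pytest.mark.parametrize("bad", ["", "x7", "d0", "ins1", "5d", "gd2", "d-3"])
def test_unknown_codes_rejected(bad):
    with pytest.raises(ValueError):
        parse_code(bad)


def test_manakin_style_calls(model):
    """17-nt internal deletion plus donor gt→gg in exon 1 → 'd17, sd'."""
    plan = MutationPlan((Event("del", 1, 17), Event("sd", 1)), seed=7)
    genome, truth = simulate_species(model, plan)
    rep = analyze_species(model, genome)
    assert rep.cells[0] == ("d17", "sd") == truth.cells[0]
    assert rep.status == "disrupted"


def test_crow_style_5prime_truncation(model):
    """69 nt missing from the 5' end of exon 3 with the intron retained is
    coded 5d69 (and not sa: the acceptor survives the truncation)."""
    plan = MutationPlan((Event("del5", 3, 69),), seed=13)
    genome, truth = simulate_species(model, plan)
    rep = analyze_species(model, genome)
    assert rep.cells[2] == ("5d69",) == truth.cells[2]


def test_unmutated_exon_yields_no_calls(model):
    genome, _ = simulate_species(model, MutationPlan(events=(), seed=1))
    rep = analyze_species(model, genome)
    assert all(cell == () for cell in rep.cells)
    assert rep.status == "intact"


def test_nonsense_call_position_matches_frame_oracle(model):
    """A single substitution creating a stop is called ns at the position a
    brute-force scan of all three frames finds it."""
    e = 3  # phase 0 exon
    assert model.cds_phase_per_exon[e - 1] == 0
    exon = model.exon_seq(e)
    codon_idx, stop = next(
        (c, s)
        for c in range(4, 30)
        for s in [_Applier._stop_one_sub(exon[3 * c : 3 * c + 3])]
        if s is not None
    )
    s0 = model.exons[e - 1][0]
    mutated = (
        model.chrom_seq[: s0 + 3 * codon_idx]
        + stop
        + model.chrom_seq[s0 + 3 * codon_idx + 3 :]
    )
    rep = analyze_species(model, _single_contig(mutated))
    assert rep.cells[e - 1] == ("ns",)
    call_pos = next(p for (ex, kind, _, p) in rep.mutation_keys if kind == "ns")
    mut_exon = exon[: 3 * codon_idx] + stop + exon[3 * codon_idx + 3 :]
    oracle = three_frame_stops(mut_exon)
    assert oracle[0] == [3 * codon_idx]
    assert call_pos == 3 * codon_idx + 1


def test_in_frame_deletion_reported_but_translation_clean(model):
    """A 9-nt in-frame deletion yields d9, never ns, and shortens the
    protein by exactly 3 residues."""
    from pseudoscan import assemble_virtual_cdna, best_hits, find_exon_hits

    plan = MutationPlan((Event("del", 6, 9),), seed=17)
    genome, truth = simulate_species(model, plan)
    rep = analyze_species(model, genome)
    assert rep.cells[5] == ("d9",) == truth.cells[5]
    assert all("ns" not in cell for cell in rep.cells)
    vc = assemble_virtual_cdna(model, best_hits(find_exon_hits(model, genome)))
    assert vc.translation == vc.translation[:-1] + "*"
    assert len(vc.translation) - 1 == len(model.protein()) - 3


def test_frameshift_then_downstream_stop_paired_property(model):
    """Inserting 1 nt shifts the frame; a stop appearing downstream in the
    shifted frame is called ns alongside i1, and vanishes without the
    insertion."""
    e = 4
    phase = model.cds_phase_per_exon[e - 1]
    exon = model.exon_seq(e)
    s0 = model.exons[e - 1][0]
    found = None
    for p in range(40, len(exon) - 40):
        for base in "ACGT":
            realized = exon[:p] + base + exon[p:]
            stops = stop_scan(realized, phase)
            if stops and all(q > p for q in stops):
                found = (p, base, stops)
                break
        if found:
            break
    assert found, "no frameshift-revealed stop in this exon"
    p, base, stops = found
    mutated = model.chrom_seq[: s0 + p] + base + model.chrom_seq[s0 + p :]
    rep = analyze_species(model, _single_contig(mutated))
    codes = rep.cells[e - 1]
    assert "i1" in codes
    assert codes.count("ns") == len(stops)
    # without the insertion the same genome has no ns anywhere
    rep0 = analyze_species(model, _single_contig(model.chrom_seq))
    assert all("ns" not in cell for cell in rep0.cells)


def test_codons_with_N_are_ambiguous_not_nonsense(model):
    """An N inside what would be a stop codon suppresses the ns call."""
    e = 3
    exon = model.exon_seq(e)
    codon_idx, stop = next(
        (c, s)
        for c in range(4, 30)
        for s in [_Applier._stop_one_sub(exon[3 * c : 3 * c + 3])]
        if s is not None
    )
    s0 = model.exons[e - 1][0]
    with_n = stop[:1] + "N" + stop[2:]
    mutated = (
        model.chrom_seq[: s0 + 3 * codon_idx]
        + with_n
        + model.chrom_seq[s0 + 3 * codon_idx + 3 :]
    )
    rep = analyze_species(model, _single_contig(mutated))
    assert "ns" not in rep.cells[e - 1]


def test_splice_calls_suppressed_at_contig_edge(model):
    """A contig starting exactly at an exon leaves the acceptor unknowable:
    no sa call, an inconclusive-flank note instead."""
    s5, e5 = model.exons[4]
    edge_contig = model.chrom_seq[s5:]  # begins at exon 5, no left flank
    rep = analyze_species(model, _single_contig(edge_contig))
    assert "sa" not in rep.cells[4]
    assert any("inconclusive" in n for n in rep.notes)


def test_status_single_frameshift_is_disrupted(model):
    genome, _ = simulate_species(model, MutationPlan((Event("del", 9, 1),), seed=23))
    rep = analyze_species(model, genome)
    assert rep.status == "disrupted"


def test_status_gene_deleted_requires_control(model, control_model):
    genome, truth = simulate_species(
        model, MutationPlan((Event("gene_del"),), seed=29), control_model=control_model
    )
    rep = analyze_species(model, genome, control_model=control_model)
    assert rep.status == "gene_deleted" == truth.status
    assert all(cell == ("gd",) for cell in rep.cells)
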