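import itertools

import dendropy
import numpy as np
import pytest

from pseudoscan import infer_loss_events, load_bird_survey, shared_mutations
from pseudoscan.loss_inference import LossInferenceError
from pseudoscan.reporting import SpeciesReport

from _oracles import dollo_min_events


def _report(name, status, cells=None, n_exons=4):
    cells = cells or tuple(() for _ in range(n_exons))
    return SpeciesReport(species_id=name, cells=tuple(cells), status=status)


def _cells(*codes_by_exon):
    return tuple(tuple(c) for c in codes_by_exon)


def test_shared_mutations_identity_case():
    cells = _cells(("d1",), (), (), ())
    reps = [_report("A", "disrupted", cells), _report("B", "disrupted", cells)]
    assert shared_mutations(reps, ["A", "B"]) == frozenset({(1, "d1")})


def test_shared_mutations_empty_clade_errors():
    with pytest.raises(LossInferenceError, match="empty clade"):
        shared_mutations([_report("A", "intact")], [])


def test_penguins_share_no_mutation():
    table = load_bird_survey()
    shared = shared_mutations(table.reports(), ["Emperor penguin", "Adelie penguin"])
    assert shared == frozenset()


def test_passerines_share_ed_across_e4_to_e11():
    table = load_bird_survey()
    clade = [sp for sp in table.species if 2 <= table.numbers[sp] <= 10]
    assert len(clade) == 9
    shared = shared_mutations(table.reports(), clade)
    assert {(e, "ed") for e in range(4, 12)} <= shared


def test_all_intact_no_events():
    reps = [_report(n, "intact") for n in "ABCD"]
    assert infer_loss_events("((A,B),(C,D));", reps) == []


def test_shared_loss_on_internal_branch():
    cells = _cells(("d1",), (), (), ())
    reps = [
        _report("A", "disrupted", cells),
        _report("B", "disrupted", cells),
        _report("C", "intact"),
        _report("D", "intact"),
    ]
    events = infer_loss_events("((A,B),(C,D));", reps)
    assert len(events) == 1
    ev = events[0]
    assert set(ev.clade) == {"A", "B"}
    assert ev.event_class == "ancestral-shared"
    assert ev.shared == frozenset({(1, "d1")})
    assert not ev.no_shared_support


def test_disjoint_sister_losses_flagged():
    """Two sister species lost with disjoint mutations: one minimal clade
    event, flagged, with the independent reading reported."""
    reps = [
        _report("A", "disrupted", _cells(("ns",), (), (), ())),
        _report("B", "disrupted", _cells((), ("i2",), (), ())),
        _report("C", "intact"),
    ]
    events = infer_loss_events("((A,B),C);", reps)
    assert len(events) == 1
    ev = events[0]
    assert ev.no_shared_support
    assert "independent" in ev.alternative


def test_single_leaf_loss_is_independent():
    reps = [
        _report("A", "disrupted", _cells(("ns",), (), (), ())),
        _report("B", "intact"),
        _report("C", "intact"),
    ]
    events = infer_loss_events("((A,B),C);", reps)
    assert len(events) == 1
    assert events[0].event_class == "independent"


def test_inconclusive_species_excluded_from_character():
    reps = [
        _report("A", "disrupted", _cells(("ns",), (), (), ())),
        _report("B", "inconclusive"),
        _report("C", "intact"),
    ]
    events = infer_loss_events("((A,B),C);", reps)
    assert len(events) == 1
    assert events[0].clade == ("A",)


def test_unmatched_leaf_errors():
    with pytest.raises(LossInferenceError, match="unmatched"):
        infer_loss_events("(A,B);", [_report("A", "intact")])


def _random_tree_and_losses(rng, n_leaves):
    taxa = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=ns,
        num_extant_tips=n_leaves, rng=rng,
    )
    lost = {t for t in taxa if rng.random() < 0.45}
    return tree, taxa, lost


@pytest.mark.parametrize("trial", range(8))
def test_event_count_matches_exhaustive_dollo_oracle(trial):
    import random

    rng = random.Random(100 + trial)
    n_leaves = rng.randint(4, 12)
    tree, taxa, lost = _random_tree_and_losses(rng, n_leaves)
    reps = [
        _report(t, "disrupted" if t in lost else "intact",
                _cells((f"d{i + 1}",), (), (), ()) if t in lost else None)
        for i, t in enumerate(taxa)
    ]
    events = infer_loss_events(tree.as_string(schema="newick"), reps)
    assert len(events) == dollo_min_events(tree, lost)
    covered = set(itertools.chain.from_iterable(ev.clade for ev in events))
    assert covered == lost


def test_adding_intact_leaf_inside_lost_clade_increases_events():
    lost_cells = _cells(("ns",), (), (), ())
    reps = [
        _report("A", "disrupted", lost_cells),
        _report("B", "disrupted", lost_cells),
        _report("C", "disrupted", lost_cells),
        _report("D", "intact"),
    ]
    base = infer_loss_events("(((A,B),C),D);", reps)
    assert len(base) == 1
    flipped = [r if r.species_id != "B" else _report("B", "intact") for r in reps]
    more = infer_loss_events("(((A,B),C),D);", flipped)
    assert len(more) == 2
    assert len(more) > len(base)
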