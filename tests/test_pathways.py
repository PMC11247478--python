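"""Atom tracing, per-instance event sequences and pathway aggregation."""

import pytest

from reaxtrack.events import BondEvent, detect_all_events, detect_new_bonds, track_labeled_bonds
from reaxtrack.graph import frame_species
from reaxtrack.pathways import (
    dominant_pathway,
    event_sequence,
    frame_partitions,
    pathway_for_product,
    product_atom_trace,
)


@pytest.fixture(scope="module")
def analysis_a(scenario_a_noiseless, template_a):
    frames, log, layout, meta = scenario_a_noiseless
    instances = track_labeled_bonds(frames, template_a)
    events = detect_all_events(instances, 50, meta.frame_interval_ps)
    known = {i.atom_pair for i in instances}
    events += detect_new_bonds(frames, known, None, 50, meta.frame_interval_ps)
    partitions = frame_partitions(frames)
    return frames, log, events, partitions


class TestProductAtomTrace:
    def test_unreacted_o2_trace_is_constant(self, analysis_a):
        frames, _, _, partitions = analysis_a
        o2_final = [s for s in partitions[-1] if s.formula == "O2"]
        assert o2_final
        # an O2 that never reacted keeps the same containing set in every frame
        for inst in o2_final:
            trace = product_atom_trace(inst.atom_ids, partitions)
            for atom, species_by_frame in trace.items():
                sets = {s.atom_ids for s in species_by_frame}
                if sets == {inst.atom_ids}:
                    return
        pytest.fail("no unreacted O2 found")

    def test_co2_trace_passes_through_parent_and_radical(self, analysis_a):
        frames, _, _, partitions = analysis_a
        co2 = next(s for s in partitions[-1] if s.formula == "CO2")
        trace = product_atom_trace(co2.atom_ids, partitions)
        formulas_seen = {s.formula for traced in trace.values() for s in traced}
        # reactant -> dehydro/ethyl-eliminated parent -> CO2 radical chain
        assert "C19H30O3" in formulas_seen
        assert "CO2" in formulas_seen
        assert "C17H25O3" in formulas_seen

    def test_trace_matches_generator_containment_log(self, analysis_a):
        frames, log, _, partitions = analysis_a
        co2 = next(s for s in partitions[-1] if s.formula == "CO2")
        trace = product_atom_trace(co2.atom_ids, partitions)
        for atom, species_by_frame in trace.items():
            for k in (0, len(frames) // 2, len(frames) - 1):
                assert species_by_frame[k].atom_ids == log.containing_species(atom, k)

    def test_missing_atom_raises_conservation_error(self, analysis_a):
        _, _, _, partitions = analysis_a
        with pytest.raises(ValueError, match="conservation"):
            product_atom_trace(frozenset({10 ** 9}), partitions)


class TestEventSequence:
    def test_hydroperoxide_sequence(self, analysis_a):
        frames, _, events, partitions = analysis_a
        product = next(s for s in partitions[-1] if s.formula == "C2H6O2")
        trace = product_atom_trace(product.atom_ids, partitions)
        seq = event_sequence(product.atom_ids, events, trace)
        kinds = [(e.descriptor, e.event_type) for e in seq]
        assert kinds == [
            ("1A", "dissociation"),
            ("4A", "dissociation"),
            ("C-O", "formation"),
            ("H-O", "formation"),
        ]

    def test_co2_sequence(self, analysis_a):
        frames, _, events, partitions = analysis_a
        product = next(s for s in partitions[-1] if s.formula == "CO2")
        trace = product_atom_trace(product.atom_ids, partitions)
        seq = event_sequence(product.atom_ids, events, trace)
        kinds = [(e.descriptor, e.event_type) for e in seq]
        assert kinds == [
            ("4A", "dissociation"),
            ("3A", "single_to_double"),
            ("2A", "dissociation"),
        ]

    def test_feed_molecule_has_empty_sequence(self, analysis_a):
        frames, _, events, partitions = analysis_a
        feed = next(s for s in partitions[-1] if s.formula == "C19H30O3")
        trace = product_atom_trace(feed.atom_ids, partitions)
        assert event_sequence(feed.atom_ids, events, trace) == []


def make_event(desc, t, pair=(1, 2)):
    return BondEvent(descriptor=desc, molecule_index=0, event_type="dissociation",
                     time_ps=t, frame=int(t * 4), atom_pair=pair)


class TestDominantPathway:
    def test_identical_sequences_reproduce_with_full_support(self):
        seq = [make_event("1A", 10.0), make_event("4A", 20.0)]
        summary = dominant_pathway([seq] * 10, "X")
        assert [s.descriptor for s in summary.steps] == ["1A", "4A"]
        assert all(s.support == 1.0 for s in summary.steps)
        assert summary.n_instances == 10
        assert summary.precedence_conflicts == ()

    def test_mixed_orderings_follow_majority(self):
        # 7 instances run A(1) B(2) C(3); 3 run A(1) C(2) B(30).
        # Medians: B over {2*7, 30*3} = 2, C over {3*7, 2*3} = 3, so the
        # canonical order is A, B, C; pairwise B-before-C holds in 7/10,
        # consistent with the median order, so no conflict is flagged.
        ab_c = [make_event("A", 1.0), make_event("B", 2.0), make_event("C", 3.0)]
        a_cb = [make_event("A", 1.0), make_event("C", 2.0), make_event("B", 30.0)]
        summary = dominant_pathway([ab_c] * 7 + [a_cb] * 3, "X")
        assert [s.descriptor for s in summary.steps] == ["A", "B", "C"]
        assert all(s.support == 1.0 for s in summary.steps)
        assert summary.precedence_conflicts == ()

    def test_pairwise_conflict_detected(self):
        # X's median time comes mostly from instances where it fires alone and
        # early, so median order puts X first; but in every instance that
        # contains both steps, Y precedes X -> flagged as a conflict.
        x_alone = [[make_event("X", 5.0)]] + [[make_event("X", 10.0)]] * 3
        both = [[make_event("Y", 20.0), make_event("X", 30.0)]] * 3
        summary = dominant_pathway(x_alone + both, "P")
        # X median over {5,10,10,10,30,30,30} = 10; Y median = 20 -> X first
        assert [s.descriptor for s in summary.steps] == ["X", "Y"]
        assert len(summary.precedence_conflicts) == 1
        first, second, frac = summary.precedence_conflicts[0]
        assert first == ("X", "dissociation") and second == ("Y", "dissociation")
        assert frac == pytest.approx(1.0)  # Y before X in all co-occurrences

    def test_aggregation_invariant_to_instance_order(self):
        s1 = [make_event("A", 1.0), make_event("B", 2.0)]
        s2 = [make_event("B", 1.0), make_event("A", 2.0)]
        assert dominant_pathway([s1, s2, s1], "X") == dominant_pathway([s1, s1, s2], "X")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dominant_pathway([], "X")


class TestPathwayForProduct:
    def test_monomer_co2_pathway(self, analysis_a):
        frames, _, events, _ = analysis_a
        summary = pathway_for_product(frames, events, "CO2")
        assert [(s.descriptor, s.event_type) for s in summary.steps] == [
            ("4A", "dissociation"),
            ("3A", "single_to_double"),
            ("2A", "dissociation"),
        ]
        assert all(s.support == 1.0 for s in summary.steps)
        assert summary.n_instances == 3

    def test_monomer_hydroperoxide_pathway(self, analysis_a):
        frames, _, events, _ = analysis_a
        summary = pathway_for_product(frames, events, "C2H6O2")
        assert [(s.descriptor, s.event_type) for s in summary.steps] == [
            ("1A", "dissociation"),
            ("4A", "dissociation"),
            ("C-O", "formation"),
            ("H-O", "formation"),
        ]

    def test_dimer_water_pathway(self, scenario_b_noiseless, template_b):
        frames, _, _, meta = scenario_b_noiseless
        instances = track_labeled_bonds(frames, template_b)
        events = detect_all_events(instances, 50, meta.frame_interval_ps)
        known = {i.atom_pair for i in instances}
        events += detect_new_bonds(frames, known, None, 50, meta.frame_interval_ps)
        summary = pathway_for_product(frames, events, "H2O")
        keys = [(s.descriptor, s.event_type) for s in summary.steps]
        ho = keys.index(("H-O", "formation"))
        for lab in ("1B", "1B'", "4B", "4B'"):
            assert keys.index((lab, "dissociation")) < ho
        assert keys.index(("1B", "dissociation")) < keys.index(("4B", "dissociation"))

    def test_absent_product_rejected(self, analysis_a):
        frames, _, events, _ = analysis_a
        with pytest.raises(ValueError, match="absent"):
            pathway_for_product(frames, events, "C99")
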