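"""Event classification and block/unit signature extraction."""

import pytest
from hypothesis import given, strategies as st

from mitorearr.gene_order import parse_gene_order
from mitorearr.rearrangements import (
    DEFAULT_BLOCKS,
    DEFAULT_UNITS,
    classify_events,
    is_unit_rearranged,
    order_is_rearranged,
    orders_equivalent,
    unit_signature,
)

UNIT = {u.name: u for u in DEFAULT_UNITS}


class TestUnitSignature:
    def test_ancestral_unit1(self, ancestral):
        sig = unit_signature(ancestral, UNIT["1"], ancestral)
        assert sig.tokens == (("trnI", "+"), ("trnQ", "-"), ("trnM", "+"))
        assert not sig.absences
        assert not is_unit_rearranged(sig, ancestral)

    def test_trnw_intrusion_into_unit1(self, ancestral, record_by_prefix):
        order = record_by_prefix("Ptilocnemus").order
        sig = unit_signature(order, UNIT["1"], ancestral)
        assert sig.tokens == (("trnI", "+"), ("trnW", "+"),
                              ("trnQ", "-"), ("trnM", "+"))
        assert is_unit_rearranged(sig, ancestral)

    def test_qi_swap_unit1(self, ancestral, record_by_prefix):
        order = record_by_prefix("Aradidae spp.").order
        sig = unit_signature(order, UNIT["1"], ancestral)
        assert sig.tokens == (("trnQ", "-"), ("trnI", "+"), ("trnM", "+"))
        assert is_unit_rearranged(sig, ancestral)

    def test_absence_makes_unit_rearranged(self, ancestral, record_by_prefix):
        order = record_by_prefix("Nabis ferus").order
        sig = unit_signature(order, UNIT["1"], ancestral)
        assert sig.absences == {"trnI"}
        assert is_unit_rearranged(sig, ancestral)

    def test_unit_in_gap_is_unknown(self, ancestral, record_by_prefix):
        order = record_by_prefix("Ceratocombus").order
        sig = unit_signature(order, UNIT["4"], ancestral)  # trnT-trnP in gap
        assert sig.unknown
        assert not is_unit_rearranged(sig, ancestral)
        assert not sig.matches(sig)  # unknown compares equal to nothing

    def test_strand_flip_counts_as_rearranged(self, ancestral):
        flipped = parse_gene_order(
            "CR-trnI-trnQ-trnM-ND2")  # trnQ moved to majority strand
        sig = unit_signature(flipped, UNIT["1"], ancestral)
        assert is_unit_rearranged(sig, ancestral)

    def test_intact_unit_inside_shuffled_block(self, ancestral,
                                               record_by_prefix):
        # trnI-trnQ-trnM keeps its internal order in the relocated block-C
        # arrangement of the unique-headed bugs, so unit 1 is unchanged
        order = record_by_prefix("Aenictopecheidae").order
        sig = unit_signature(order, UNIT["1"], ancestral)
        assert not is_unit_rearranged(sig, ancestral)
        assert is_unit_rearranged(
            unit_signature(order, UNIT["4"], ancestral), ancestral)


class TestClassifyEvents:
    def test_ancestral_vs_itself(self, ancestral):
        call = classify_events(ancestral, ancestral)
        assert not call.rearranged
        assert not call.event_types
        assert not (call.moved_genes or call.duplicated_genes
                    or call.lost_genes or call.inverted_genes)

    def test_trnw_translocation(self, ancestral, record_by_prefix):
        call = classify_events(record_by_prefix("Ptilocnemus").order,
                               ancestral)
        assert call.event_types == {"translocation"}
        assert call.moved_genes == ("trnW",)
        assert call.affected_units == {"1", "2"}

    def test_tandem_duplication_only(self, ancestral, record_by_prefix):
        call = classify_events(record_by_prefix("Gerridae").order, ancestral)
        assert call.event_types == {"duplication"}
        assert call.duplicated_genes == ("trnF",)

    def test_trnv_translocation_with_unresolved_trny(self, ancestral,
                                                     record_by_prefix):
        call = classify_events(record_by_prefix("Ischnobaenella").order,
                               ancestral)
        assert call.event_types == {"translocation"}
        assert call.moved_genes == ("trnV",)
        assert call.unresolved_genes == ("trnY",)
        assert not call.lost_genes

    def test_loss_only_for_complete_genome(self, ancestral, record_by_prefix):
        call = classify_events(record_by_prefix("Nabis ferus").order,
                               ancestral)
        assert call.event_types == {"loss"}
        assert call.lost_genes == ("trnI",)

    def test_displaced_duplicate_is_also_translocation(self, ancestral,
                                                       record_by_prefix):
        call = classify_events(
            record_by_prefix("Reduviidae sp. (trnT duplication").order,
            ancestral)
        assert call.event_types == {"duplication", "translocation"}

    def test_rotation_invariance(self, ancestral, record_by_prefix):
        order = record_by_prefix("Pachynomidae").order
        baseline = classify_events(order, ancestral)
        for start in (5, 17, 30):
            call = classify_events(order.rotated(start), ancestral)
            assert call.event_types == baseline.event_types
            assert call.moved_genes == baseline.moved_genes
            assert call.lost_genes == baseline.lost_genes
            assert call.affected_units == baseline.affected_units

    def test_inversion_detected(self, ancestral):
        # same gene order but trnM flipped to the minority strand
        flipped = parse_gene_order(
            "CR-trnI-~trnQ-~trnM-ND2-trnW-~trnC-~trnY-COI-trnL2-COII-trnK-"
            "trnD-ATP8-ATP6-COIII-trnG-ND3-trnA-trnR-trnN-trnS1-trnE-~trnF-"
            "~ND5-~trnH-~ND4-~ND4L-trnT-~trnP-ND6-CYTB-trnS2-~ND1-~trnL1-"
            "~rrnL-~trnV-~rrnS")
        call = classify_events(flipped, ancestral)
        assert "inversion" in call.event_types
        assert call.inverted_genes == ("trnM",)

    def test_no_comparison_basis(self, ancestral):
        with pytest.raises(Exception, match="no comparison basis"):
            classify_events(parse_gene_order("NCR-CR"), ancestral)

    def test_affected_units_consistent_with_signatures(self, catalog):
        ancestral = catalog.ancestral
        for rec in catalog:
            call = classify_events(rec.order, ancestral)
            rearranged_units = {
                u.name for u in DEFAULT_UNITS
                if is_unit_rearranged(
                    unit_signature(rec.order, u, ancestral), ancestral)}
            assert call.affected_units == rearranged_units


class TestWholeOrderComparison:
    def test_rotations_are_same_arrangement(self, ancestral):
        assert orders_equivalent(ancestral, ancestral.rotated(11))
        assert not order_is_rearranged(ancestral.rotated(11), ancestral)

    def test_gap_matches_unobserved_run(self, ancestral):
        # arcs agree with the ground pattern; the gap hides trnL2..ND3
        partial = parse_gene_order(
            "CR-trnI-~trnQ-trnM-ND2-trnW-~trnC-~trnY-COI-//-trnA-trnR-trnN-"
            "trnS1-trnE-~trnF-~ND5-~trnH-~ND4-~ND4L-trnT-~trnP-ND6-CYTB-"
            "trnS2-~ND1-~trnL1-~rrnL-~trnV-~rrnS")
        assert orders_equivalent(partial, ancestral)
        assert not order_is_rearranged(partial, ancestral)

    def test_absence_differences_distinguish(self, record_by_prefix):
        nab1 = record_by_prefix("Nabis ferus").order
        nab2 = record_by_prefix("Nabidae sp.").order
        phym = record_by_prefix("Phymata").order
        assert orders_equivalent(nab1, phym)   # shared trnI-loss order
        assert not orders_equivalent(nab1, nab2)
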