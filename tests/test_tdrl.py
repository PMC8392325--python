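"""TDRL step application, enumeration, scenario search and remnants."""

import itertools

import pytest

from mitorearr.gene_order import (
    GeneOrder,
    GeneOrderError,
    GeneToken,
    canonicalize,
    parse_gene_order,
)
from mitorearr.tdrl import (
    TDRLStep,
    apply_tdrl,
    enumerate_single_tdrl,
    predict_remnants,
    search_scenarios,
)


def _order(*symbols):
    return GeneOrder(tuple(GeneToken(s) for s in symbols))


def brute_force_single_tdrl(order, max_segment):
    """Independent oracle: enumerate TDRL products by direct list surgery,
    no shared code with apply_tdrl."""
    toks = [(t.symbol, t.strand) for t in order.tokens]
    n = len(toks)
    results = set()
    for start in range(n):
        for length in range(1, min(max_segment, n - 1) + 1):
            seg = [toks[(start + i) % n] for i in range(length)]
            rest = [toks[(start + length + i) % n] for i in range(n - length)]
            for keep_first in itertools.product((True, False), repeat=length):
                first = [seg[i] for i in range(length) if keep_first[i]]
                second = [seg[i] for i in range(length) if not keep_first[i]]
                circle = first + second + rest
                # normalize rotation by smallest representation
                rots = [tuple(circle[i:] + circle[:i])
                        for i in range(len(circle))]
                results.add(min(rots))
    return results


class TestApply:
    def test_trnw_mechanism(self):
        # duplicate trnQ-trnM-ND2-trnW, delete Q/M/ND2 from the first copy
        # and trnW from the second
        frag = parse_gene_order("trnI-~trnQ-trnM-ND2-trnW-~trnC-~trnY")
        out = apply_tdrl(frag, TDRLStep(1, 4, ("first",) * 3 + ("second",)))
        assert out.equivalent(
            parse_gene_order("trnI-trnW-~trnQ-trnM-ND2-~trnC-~trnY"))

    def test_trnv_mechanism(self):
        # duplicate trnV-rrnS-CR, delete trnV from the first copy and
        # rrnS + CR from the second
        frag = parse_gene_order("~rrnL-~trnV-~rrnS-CR-trnI")
        out = apply_tdrl(frag, TDRLStep(1, 3, ("first", "second", "second")))
        assert out.equivalent(
            parse_gene_order("~rrnL-~rrnS-CR-~trnV-trnI"))

    def test_losing_entire_second_copy_is_noop(self):
        frag = parse_gene_order("~rrnL-~trnV-~rrnS-CR-trnI")
        out = apply_tdrl(frag, TDRLStep(0, 3, ("second",) * 3))
        assert out.equivalent(frag)

    def test_wrap_around_segment(self):
        order = _order("ND1", "ND2", "ND3", "ND4")
        out = apply_tdrl(order, TDRLStep(3, 2, ("first", "second")))
        assert len(out) == 4  # content conserved

    def test_extinction_guard(self):
        order = _order("ND1", "ND2", "ND3")
        with pytest.raises(GeneOrderError, match="extinction"):
            apply_tdrl(order, TDRLStep(0, 1, ("both",)))
        out = apply_tdrl(order, TDRLStep(0, 1, ("both",)),
                         allow_full_loss=True)
        assert out.absent == {"ND1"}
        assert "ND1" not in out.symbols()

    def test_strand_never_changes(self):
        order = parse_gene_order("trnI-~trnQ-trnM-ND2-trnW")
        strands = {t.symbol: t.strand for t in order.tokens}
        for start in range(len(order)):
            for losses in itertools.product(("first", "second"), repeat=2):
                out = apply_tdrl(order, TDRLStep(start, 2, losses))
                for tok in out.tokens:
                    assert tok.strand == strands[tok.symbol]

    def test_gene_content_conserved_without_full_loss(self):
        order = parse_gene_order("trnI-~trnQ-trnM-ND2-trnW-~trnC")
        before = set(order.symbols())
        for start in (0, 2, 4):
            out = apply_tdrl(order, TDRLStep(start, 3,
                                             ("second", "first", "first")))
            assert set(out.symbols()) == before


class TestEnumerate:
    def test_three_gene_order_matches_brute_force(self):
        order = _order("ND1", "ND2", "ND3")
        got = {tuple((t.symbol, t.strand) for t in canonicalize(o).tokens)
               for o in enumerate_single_tdrl(order, 2)}
        expected = set()
        for circle in brute_force_single_tdrl(order, 2):
            canon = canonicalize(GeneOrder(tuple(
                GeneToken(s, st) for s, st in circle)))
            expected.add(tuple((t.symbol, t.strand) for t in canon.tokens))
        assert got == expected

    def test_contains_identity_and_swap(self):
        order = _order("ND1", "ND2", "ND3")
        reachable = enumerate_single_tdrl(order, 2)
        assert any(o.equivalent(order) for o in reachable)
        assert any(o.equivalent(_order("ND2", "ND1", "ND3"))
                   for o in reachable)

    def test_max_segment_zero_is_empty(self):
        assert enumerate_single_tdrl(_order("ND1", "ND2", "ND3"), 0) == set()

    def test_plemur_target_reachable_in_one_step(self, ancestral,
                                                 record_by_prefix):
        target = record_by_prefix("Ptilocnemus").order
        reachable = enumerate_single_tdrl(ancestral, 6)
        assert any(o.equivalent(target) for o in reachable)


class TestSearch:
    def test_source_equals_target(self, ancestral):
        scens = search_scenarios(ancestral, ancestral.rotated(7))
        assert len(scens) == 1
        assert scens[0].n_steps == 0

    def test_parameter_validation(self, ancestral):
        with pytest.raises(ValueError):
            search_scenarios(ancestral, ancestral, max_steps=0)
        with pytest.raises(ValueError):
            search_scenarios(ancestral, ancestral, max_segment=0)

    def test_unreachable_returns_empty(self):
        source = _order("ND1", "ND2", "ND3")
        flipped = GeneOrder((GeneToken("ND1", "-"), GeneToken("ND2"),
                             GeneToken("ND3")))
        assert search_scenarios(source, flipped, max_steps=2,
                                max_segment=2) == []

    def test_replay_soundness(self, ancestral, record_by_prefix):
        target = record_by_prefix("Ptilocnemus").order
        scens = search_scenarios(ancestral, target)
        assert scens and all(s.n_steps == 1 for s in scens)
        for s in scens:
            assert s.verify()
            assert s.target.equivalent(canonicalize(target.with_taxon("")))

    def test_two_step_search_on_small_order(self):
        source = _order("ND1", "ND2", "ND3", "ND4", "ND5", "ND6")
        mid = apply_tdrl(source, TDRLStep(1, 3, ("first", "second", "first")))
        target = apply_tdrl(mid, TDRLStep(0, 2, ("second", "first")))
        scens = search_scenarios(source, target, max_steps=2, max_segment=3)
        assert scens
        assert scens[0].n_steps <= 2
        assert all(s.verify() for s in scens)

    def test_minimality_vs_single_step_witness(self):
        # anything enumerate reaches in one step must be found at one step
        source = _order("ND1", "ND2", "ND3", "ND4")
        for target in sorted(enumerate_single_tdrl(source, 3),
                             key=lambda o: o.symbols()):
            scens = search_scenarios(source, target, max_steps=2,
                                     max_segment=3)
            assert scens
            assert scens[0].n_steps <= 1


class TestRemnants:
    def test_broader_boundary_trnw_scenario_sites(self, ancestral):
        """The duplication spanning trnI..trnW leaves residue at the three
        intergenic sites flanking the relocated trnW."""
        syms = ancestral.symbols()
        start = syms.index("trnI")
        step = TDRLStep(start, 5,
                        ("second", "first", "first", "first", "second"))
        out = apply_tdrl(ancestral, step)
        from mitorearr.tdrl import TDRLScenario, _duplicate
        scen = TDRLScenario(ancestral, (step,),
                            (_duplicate(canonicalize(ancestral), step),),
                            (out,))
        sites = set(predict_remnants(scen).sites)
        assert sites == {("trnI", "trnW"), ("trnW", "trnQ"),
                         ("ND2", "trnC")}

    def test_empty_scenario_has_no_sites(self, ancestral):
        scens = search_scenarios(ancestral, ancestral)
        assert predict_remnants(scens[0]).sites == ()

    def test_unverified_scenario_rejected(self, ancestral):
        from mitorearr.tdrl import TDRLScenario
        bogus = TDRLScenario(ancestral,
                             (TDRLStep(0, 2, ("first", "second")),),
                             (ancestral,), (ancestral,))
        with pytest.raises(GeneOrderError, match="does not replay"):
            predict_remnants(bogus)

    def test_sites_are_final_order_adjacencies(self, ancestral,
                                               record_by_prefix):
        target = record_by_prefix("Ptilocnemus").order
        for scen in search_scenarios(ancestral, target):
            final = scen.target.symbols()
            n = len(final)
            adjacencies = {(final[i], final[(i + 1) % n]) for i in range(n)}
            for site in predict_remnants(scen).sites:
                assert site in adjacencies
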