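"""Structural validation and the deterministic planner."""

import pytest

from prosthoplan.chart import FindingsChart, PlanChart, parse_chart
from prosthoplan.rules import (
    validate_findings, find_gaps, count_replacement_needs,
    requires_rdp, plan_case, plan_case_explained, plan_contains_fdp,
)
from conftest import chart_with


def plan_of(text: str) -> str:
    return str(plan_case(parse_chart(text, "finding")))


class TestValidation:
    def test_all_sufficient_valid(self, all_sufficient):
        assert validate_findings(all_sufficient) == []

    def test_unanchored_pontic(self):
        v = validate_findings(chart_with(p5="b"))
        assert [x.rule_id for x in v] == ["R1"]

    def test_pontic_at_jaw_end_invalid(self):
        v = validate_findings(chart_with(p16="b", p15="k"))
        assert "R1" in {x.rule_id for x in v}

    def test_mixed_sufficiency_bridge(self):
        v = validate_findings(chart_with(p4="k", p5="bw", p6="k"))
        assert [x.rule_id for x in v] == ["R2"]

    def test_mixed_rdp_sufficiency(self):
        v = validate_findings(chart_with(p3="e", p12="ew"))
        assert [x.rule_id for x in v] == ["R3"]

    def test_valid_bridges_pass(self):
        assert validate_findings(chart_with(p4="k", p5="b", p6="k")) == []
        assert validate_findings(chart_with(p4="kw", p5="bw", p6="kw")) == []

    def test_adjacent_crown_merges_block(self):
        # a sufficient crown touching an insufficient bridge shares its block
        v = validate_findings(chart_with(p4="kw", p5="bw", p6="kw", p7="k"))
        assert [x.rule_id for x in v] == ["R2"]


class TestGaps:
    def test_no_gaps(self, all_sufficient):
        assert find_gaps(all_sufficient) == []

    def test_single_bounded_gap(self):
        segs = find_gaps(chart_with(p8="f"))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end) == (8, 8)
        assert seg.bounded_left and seg.bounded_right
        assert not seg.wisdom_only

    def test_wisdom_only_segments(self):
        segs = find_gaps(chart_with(p1="f", p16="f"))
        assert [(s.start, s.end) for s in segs] == [(1, 1), (16, 16)]
        assert all(s.wisdom_only for s in segs)

    def test_causes_recorded(self):
        seg = find_gaps(chart_with(p5="f", p6="x"))[0]
        assert seg.causes == ("f", "x")


class TestReplacementCount:
    @pytest.mark.parametrize("chart,expected", [
        (chart_with(), 0),
        (chart_with(p1="f"), 0),                     # wisdom gaps never count
        (chart_with(p5="f", p6="f", p9="x", p10="x"), 4),
        (chart_with(p1="f", p16="x", p8="f"), 1),
    ])
    def test_counts(self, chart, expected):
        assert count_replacement_needs(chart) == expected


class TestRequiresRdp:
    def test_nothing(self, all_sufficient):
        assert requires_rdp(all_sufficient) == (False, None)

    def test_four_or_more(self):
        flag, reason = requires_rdp(chart_with(p5="f", p6="f", p7="f", p8="f"))
        assert flag and reason == ">=4"

    def test_unbounded_gap(self):
        # tooth 2 missing with tooth 1 missing too: no left abutment
        flag, reason = requires_rdp(chart_with(p1="f", p2="f"))
        assert flag and reason == "unbounded gap"

    def test_gap_next_to_sufficient_bridge_unbounded(self):
        # a sufficient bridge cannot anchor a new pontic
        flag, reason = requires_rdp(
            chart_with(p4="k", p5="b", p6="k", p7="f"))
        assert flag and reason == "unbounded gap"

    def test_existing_rdp_renewal(self):
        flag, reason = requires_rdp(chart_with(p3="ew", p4="ew"))
        assert flag and reason == "rdp renewal"

    def test_small_bounded_gap_stays_fixed(self):
        assert requires_rdp(chart_with(p8="f"))[0] is False


class TestPlanCase:
    def test_nothing_to_treat(self):
        assert plan_of(". . . . . . . . . . . . . . . .") == \
            "- - - - - - - - - - - - - - - -"

    def test_single_gap_bridge(self):
        assert plan_of(". . . . . . . f . . . . . . . .") == \
            "- - - - - - K B K - - - - - - -"

    def test_four_gaps_removable(self):
        assert plan_of(". . . . f f f f . . . . . . . .") == \
            "- - - - E E E E - - - - - - - -"

    def test_rdp_renewal_pulls_in_new_gap(self):
        assert plan_of(". . ew ew . . . . . f . . . . . .") == \
            "- - E E - - - - - E - - - - - -"

    def test_insufficient_crown_renewed(self):
        assert plan_of(". . . . . kw . . . . . . . . . .") == \
            "- - - - - K - - - - - - - - - -"

    def test_insufficient_bridge_renewed(self):
        assert plan_of(". . . kw bw kw . . . . . . . . . .") == \
            "- - - K B K - - - - - - - - - -"

    def test_preservation_worthy_crowned(self):
        assert plan_of("ww . . . . . . . . . . . . . . .") == \
            "K - - - - - - - - - - - - - - -"

    def test_missing_wisdom_untreated(self):
        assert plan_of("f . . . . . . . . . . . . . . x") == \
            "- - - - - - - - - - - - - - - -"

    def test_sufficient_rdp_left_alone(self):
        assert plan_of(". . e e . . . . . . . . . . . .") == \
            "- - - - - - - - - - - - - - - -"

    def test_sufficient_rdp_extended_when_rdp_fires(self):
        # four new gaps force a removable prosthesis; the existing sufficient
        # denture is extended and its teeth go onto the new appliance
        assert plan_of(". . e e . f f . . f f . . . . .") == \
            "- - E E - E E - - E E - - - - -"

    def test_two_gaps_shared_abutment(self):
        assert plan_of(". . . f . f . . . . . . . . . .") == \
            "- - K B K B K - - - - - - - - -"

    def test_crown_recruited_as_abutment(self):
        assert plan_of(". . k f . . . . . . . . . . . .") == \
            "- - K B K - - - - - - - - - - -"

    def test_invalid_chart_rejected(self):
        with pytest.raises(ValueError, match="R1"):
            plan_case(chart_with(p5="b"))

    def test_explained_tags(self):
        plan, why = plan_case_explained(chart_with(p8="f", p1="f"))
        assert why[0] == "P1" and why[7] == "P3" and why[15] == "P6"


class TestPlanContainsFdp:
    def test_cases(self):
        assert not plan_contains_fdp(PlanChart(["-"] * 16))
        assert plan_contains_fdp(PlanChart(["K", "B", "K"] + ["-"] * 13))
        assert not plan_contains_fdp(PlanChart(["E"] * 16))


class TestPlannerInvariants:
    """Properties over every generator-emitted chart."""

    def test_plans_are_valid_and_deterministic(self, small_collection):
        for case in small_collection:
            again = plan_case(case.findings)
            assert again == case.plan
            assert len(again) == 16

    def test_no_cantilever_bridges(self, small_collection):
        for case in small_collection:
            p = case.plan.entries
            for i, sym in enumerate(p):
                if sym != "B":
                    continue
                left = p[i - 1] if i > 0 else None
                right = p[i + 1] if i < 15 else None
                assert left in ("K", "B"), case.findings
                assert right in ("K", "B"), case.findings

    def test_wisdom_positions_never_replaced_removably(self, small_collection):
        for case in small_collection:
            assert case.plan[0] != "E" and case.plan[15] != "E"

    def test_removable_implies_trigger(self, small_collection):
        for case in small_collection:
            if "E" not in case.plan.entries:
                continue
            flag, reason = requires_rdp(case.findings)
            assert flag
            needs = count_replacement_needs(case.findings)
            has_ew = "ew" in case.findings.entries
            assert needs >= 4 or has_ew or reason == "unbounded gap"

    def test_all_or_none_renewal(self, small_collection):
        for case in small_collection:
            ew_plans = {case.plan[i] for i, s in enumerate(case.findings)
                        if s == "ew"}
            assert ew_plans in (set(), {"E"})
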