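"""Combining-rule engine: worked examples, invariants, conflict handling."""

import pytest
from hypothesis import given, settings, strategies as st

from alsvarclass.evidence import (
    CODES,
    CriteriaSet,
    Direction,
    EvidenceAssignment,
    Strength,
    parse_criteria_string,
)
from alsvarclass.rules import VariantClass, classify, classify_batch


def C(text):
    return parse_criteria_string(text)


class TestClassify:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("PVS1 (very strong), PM2, PP3", VariantClass.PATHOGENIC),
            ("PM1, PM2, PM5, PP2", VariantClass.LIKELY_PATHOGENIC),
            ("PM1 (strong), PM2, PM5, PP2, PP3, PP5 (very strong)", VariantClass.PATHOGENIC),
            ("PM1, PP2, PP5 (very strong)", VariantClass.PATHOGENIC),
            ("PS1, PM1 (strong), PM2, PM5, PP2, PP3", VariantClass.PATHOGENIC),
            ("PM1, PM2, PP2, PP3", VariantClass.LIKELY_PATHOGENIC),
            ("", VariantClass.UNCERTAIN),
            ("BA1", VariantClass.BENIGN),
            ("BS1, BS4", VariantClass.BENIGN),
            ("BS1, BP7", VariantClass.LIKELY_BENIGN),
            ("BP4, BP7", VariantClass.LIKELY_BENIGN),
            ("PM2, PP3", VariantClass.UNCERTAIN),
            ("PVS1, PP3", VariantClass.UNCERTAIN),  # very strong + 1 supporting is not enough
        ],
    )
    def test_examples(self, text, expected):
        assert classify(C(text)).klass is expected

    def test_conflicting_directions_yield_uncertain_with_flag(self):
        res = classify(C("PS1, PS2, BS1, BS4"))
        assert res.klass is VariantClass.UNCERTAIN
        assert res.conflict
        assert res.fired_rule == ""

    def test_one_direction_supporting_does_not_raise_conflict(self):
        # pathogenic evidence present but no pathogenic rule fires
        res = classify(C("PP2, BA1"))
        assert res.klass is VariantClass.BENIGN
        assert not res.conflict

    def test_ba1_override_flag(self):
        cs = C("PS1, PS2, BA1")
        assert classify(cs).klass is VariantClass.UNCERTAIN
        forced = classify(cs, ba1_overrides_conflict=True)
        assert forced.klass is VariantClass.BENIGN
        assert forced.conflict

    def test_fired_rule_empty_iff_uncertain(self):
        for text in ("PVS1, PM2", "PM2", "BA1", ""):
            res = classify(C(text))
            assert (res.fired_rule == "") == (res.klass is VariantClass.UNCERTAIN)

    def test_class_ordering(self):
        assert (
            VariantClass.BENIGN
            < VariantClass.LIKELY_BENIGN
            < VariantClass.UNCERTAIN
            < VariantClass.LIKELY_PATHOGENIC
            < VariantClass.PATHOGENIC
        )


class TestBatch:
    def test_order_preserved_and_elementwise(self):
        rows = [("a", C("BA1")), ("b", C("PVS1, PM2, PP3")), ("c", C(""))]
        out = classify_batch(rows)
        assert [rid for rid, _ in out] == ["a", "b", "c"]
        assert [r.klass for _, r in out] == [
            VariantClass.BENIGN,
            VariantClass.PATHOGENIC,
            VariantClass.UNCERTAIN,
        ]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            classify_batch([("x", C("")), ("x", C("BA1"))])

    def test_empty_input(self):
        assert classify_batch([]) == []


class TestTable2RoundTrip:
    def test_all_twenty_printed_classes_reproduced(self, worked_examples):
        results = [classify(r.expected_criteria) for r in worked_examples]
        assert all(res.klass is r.expected_class for res, r in zip(results, worked_examples))
        labels = [res.klass for res in results]
        assert labels.count(VariantClass.PATHOGENIC) == 11
        assert labels.count(VariantClass.LIKELY_PATHOGENIC) == 9


# -- properties -----------------------------------------------------------

_PATH_CODES = sorted(c.code for c in CODES.values() if c.direction is Direction.PATHOGENIC)
_STRENGTHS = (Strength.SUPPORTING, Strength.MODERATE, Strength.STRONG, Strength.VERY_STRONG)


@st.composite
def _pathogenic_sets(draw):
    codes = draw(st.lists(st.sampled_from(_PATH_CODES), unique=True, max_size=6))
    return CriteriaSet(
        EvidenceAssignment(CODES[c], draw(st.sampled_from(_STRENGTHS))) for c in codes
    )


@settings(max_examples=300, derandomize=True)
@given(_pathogenic_sets(), st.sampled_from(_PATH_CODES), st.sampled_from(_STRENGTHS))
def test_monotonicity_adding_pathogenic_evidence(cs, code, strength):
    """With no benign evidence, adding a pathogenic assignment never moves
    the class toward benign."""
    if code in cs:
        return  # replacing an assignment is not "adding evidence"
    before = classify(cs).klass
    grown = CriteriaSet(list(cs))
    grown.add(EvidenceAssignment(CODES[code], strength))
    assert classify(grown).klass >= before


@settings(max_examples=300, derandomize=True)
@given(_pathogenic_sets())
def test_bucket_equivalence(cs):
    """Classification depends only on the strength histogram, not on which
    codes produced it: permuting strengths across codes keeps the class."""
    assignments = sorted(cs, key=lambda a: a.code)
    if len(assignments) < 2:
        return
    strengths = [a.applied_strength for a in assignments]
    rotated = strengths[1:] + strengths[:1]
    permuted = CriteriaSet(
        EvidenceAssignment(a.criterion, s) for a, s in zip(assignments, rotated)
    )
    assert classify(permuted).klass is classify(cs).klass
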