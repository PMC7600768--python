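"""Criterion vocabulary, strength handling and criteria-string notation."""

import pytest
from hypothesis import given, settings, strategies as st

from alsvarclass.evidence import (
    BENIGN_STRENGTHS,
    CODES,
    CriteriaSet,
    Direction,
    EvidenceAssignment,
    PATHOGENIC_STRENGTHS,
    Strength,
    assignment,
    format_criteria,
    parse_criteria_string,
    strength_histogram,
)


class TestVocabulary:
    def test_exactly_28_codes(self):
        assert len(CODES) == 28
        assert sum(c.direction is Direction.PATHOGENIC for c in CODES.values()) == 16
        assert sum(c.direction is Direction.BENIGN for c in CODES.values()) == 12

    def test_direction_follows_first_letter(self):
        for code in CODES.values():
            expected = Direction.PATHOGENIC if code.code.startswith("P") else Direction.BENIGN
            assert code.direction is expected

    def test_default_strength_follows_code_family(self):
        assert CODES["PVS1"].default_strength is Strength.VERY_STRONG
        for i in range(1, 5):
            assert CODES[f"PS{i}"].default_strength is Strength.STRONG
            assert CODES[f"BS{i}"].default_strength is Strength.STRONG
        for i in range(1, 7):
            assert CODES[f"PM{i}"].default_strength is Strength.MODERATE
        for i in range(1, 6):
            assert CODES[f"PP{i}"].default_strength is Strength.SUPPORTING
        for i in range(1, 8):
            assert CODES[f"BP{i}"].default_strength is Strength.SUPPORTING

    def test_ba1_is_the_only_stand_alone(self):
        stand_alone = [c for c in CODES.values() if c.default_strength is Strength.STAND_ALONE]
        assert [c.code for c in stand_alone] == ["BA1"]


class TestAssignments:
    def test_applied_strength_defaults_to_code_default(self):
        a = assignment("PM2")
        assert a.applied_strength is Strength.MODERATE
        assert not a.is_escalated

    def test_benign_very_strong_rejected_by_default_but_allowed_by_flag(self):
        with pytest.raises(ValueError):
            assignment("BP6", Strength.VERY_STRONG)
        a = assignment("BP6", Strength.VERY_STRONG, allow_benign_very_strong=True)
        assert a.applied_strength is Strength.VERY_STRONG

    def test_ba1_cannot_be_reweighted(self):
        with pytest.raises(ValueError):
            assignment("BA1", Strength.STRONG)

    def test_duplicate_codes_rejected(self):
        cs = CriteriaSet([assignment("PM1")])
        with pytest.raises(ValueError, match="duplicate"):
            cs.add(assignment("PM1", Strength.STRONG))


class TestParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            # worked-example rows, including parenthesised overrides
            (
                "PVS1 (very strong), PM2, PP3",
                {"PVS1": Strength.VERY_STRONG, "PM2": Strength.MODERATE, "PP3": Strength.SUPPORTING},
            ),
            (
                "PM1, PP2, PP5 (very strong)",
                {"PM1": Strength.MODERATE, "PP2": Strength.SUPPORTING, "PP5": Strength.VERY_STRONG},
            ),
            ("PM1, PM2, PM5, PP2, PP5(strong)", {
                "PM1": Strength.MODERATE, "PM2": Strength.MODERATE, "PM5": Strength.MODERATE,
                "PP2": Strength.SUPPORTING, "PP5": Strength.STRONG,
            }),
            ("", {}),
            ("pm1, pp5 (VERY_STRONG)", {"PM1": Strength.MODERATE, "PP5": Strength.VERY_STRONG}),
        ],
    )
    def test_parse(self, text, expected):
        cs = parse_criteria_string(text)
        assert {a.code: a.applied_strength for a in cs} == expected

    @pytest.mark.parametrize(
        "bad", ["PX9", "PM1, PM1", "PP5 (quite strong)", "PM1 PM2", "BA1 (strong)"]
    )
    def test_rejections(self, bad):
        with pytest.raises(ValueError):
            parse_criteria_string(bad)


class TestHistogram:
    def test_worked_example_counts(self):
        # one strong-escalated moderate counts in the strong bucket
        cs = parse_criteria_string("PS1, PM1 (strong), PM2, PM5, PP2, PP3")
        h = strength_histogram(cs)
        assert (h.very_strong, h.strong, h.moderate, h.supporting) == (0, 2, 2, 2)

    def test_empty_set_all_zero(self):
        assert strength_histogram(CriteriaSet()).total == 0

    def test_benign_buckets(self):
        h = strength_histogram(parse_criteria_string("BA1, BP4"))
        assert h.benign_stand_alone == 1
        assert h.benign_supporting == 1
        assert h.benign_strong == 0


# -- properties -----------------------------------------------------------

def _assignments():
    def build(code, data):
        crit = CODES[code]
        pool = (
            PATHOGENIC_STRENGTHS
            if crit.direction is Direction.PATHOGENIC
            else ((Strength.STAND_ALONE,) if code == "BA1" else BENIGN_STRENGTHS)
        )
        return EvidenceAssignment(crit, data.draw(st.sampled_from(pool)))

    return st.builds(
        lambda codes, data: CriteriaSet(build(c, data) for c in codes),
        st.lists(st.sampled_from(sorted(CODES)), unique=True, max_size=8),
        st.data(),
    )


@settings(max_examples=200, derandomize=True)
@given(_assignments())
def test_parse_format_round_trip(cs):
    """Formatting then re-parsing yields an identical criteria set."""
    assert parse_criteria_string(format_criteria(cs)) == cs


@settings(max_examples=200, derandomize=True)
@given(_assignments())
def test_histogram_total_equals_set_size(cs):
    assert strength_histogram(cs).total == len(cs)
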