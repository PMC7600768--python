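"""HGVS consequence typing and automatic criteria assignment."""

import pytest

from alsvarclass.annotate import (
    CatalogEntry,
    KnownVariantCatalog,
    VariantRecord,
    assign_criteria,
    classify_records,
    classify_variant,
    parse_protein_consequence,
)
from alsvarclass.evidence import CriteriaSet, Strength, assignment, format_criteria
from alsvarclass.frequency import PopulationFrequencies
from alsvarclass.rules import VariantClass


def zero_freqs():
    return PopulationFrequencies({"all": 0.0, "nfe": 0.0})


class TestProteinConsequence:
    @pytest.mark.parametrize(
        "p,c,cons,residue",
        [
            ("p.R229*", "c.684dupT", "nonsense", 229),
            ("p.E929Nfs*12", "c.2785_2786delGA", "frameshift", 929),
            ("p.A382T", "c.1144G>A", "missense", 382),
            ("p.L68=", "", "synonymous", 68),
            ("p.Gly294Val", "", "missense", 294),
            ("p.Q151*", "c.451C>T", "nonsense", 151),
            ("p.M1V", "", "start_loss", 1),
            ("p.*153Rext*12", "", "stop_loss", 153),
            ("p.G93_L95del", "", "inframe_indel", 93),
            ("", "c.1130+1G>A", "canonical_splice", None),
            ("", "c.1130-2A>G", "canonical_splice", None),
            ("", "c.1130+5G>A", "other", None),  # beyond the +-2 canonical window
        ],
    )
    def test_typing(self, p, c, cons, residue):
        assert parse_protein_consequence(p, c) == (cons, residue)

    def test_unparseable_is_other_never_a_crash(self):
        cons, _ = parse_protein_consequence("p.completely bogus!", "")
        assert cons == "other"

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            parse_protein_consequence("", "")


class TestAssignCriteria:
    def test_truncating_variant_in_lof_gene(self, kb, catalog, als_cfg):
        v = VariantRecord(
            id="x", gene="TBK1", cdna="c.684dupT", protein="p.R229*",
            freqs=zero_freqs(),
            predictions={"sift": "damaging", "polyphen": "damaging"},
        )
        cs = assign_criteria(v, kb, catalog, als_cfg)
        assert cs.codes() == {"PVS1", "PM2", "PP3"}
        assert cs.get("PVS1").applied_strength is Strength.VERY_STRONG

    def test_truncating_variant_outside_lof_gene_list(self, kb, catalog, als_cfg):
        v = VariantRecord(id="x", gene="SOD1", protein="p.G10*", freqs=zero_freqs())
        cs = assign_criteria(v, kb, catalog, als_cfg)
        assert "PVS1" not in cs

    def test_missense_with_neighbouring_pathogenic_change(self, kb, catalog, als_cfg):
        v = VariantRecord(
            id="x", gene="SOD1", protein="p.G86S", freqs=zero_freqs(),
            predictions={"sift": "damaging", "polyphen": "damaging"},
        )
        cs = assign_criteria(v, kb, catalog, als_cfg)
        assert cs.codes() == {"PM1", "PM2", "PM5", "PP2", "PP3"}

    def test_ps1_and_pm5_mutually_exclusive(self, kb, catalog, als_cfg):
        # catalog holds established G73S; the same change yields PS1, never both
        v = VariantRecord(id="x", gene="SOD1", protein="p.G73S", freqs=zero_freqs())
        cs = assign_criteria(v, kb, catalog, als_cfg)
        assert "PS1" in cs and "PM5" not in cs

    def test_synonymous_bp7(self, kb, catalog, als_cfg):
        v = VariantRecord(
            id="x", gene="SETX", protein="p.L68=",
            freqs=PopulationFrequencies({"all": 3e-5}),
            splice_predictions={"ada": "benign", "rf": "unknown"},
            conservation="not_conserved",
        )
        cs = assign_criteria(v, kb, catalog, als_cfg)
        assert "BP7" in cs

    def test_synonymous_with_predicted_splice_impact_no_bp7(self, kb, catalog, als_cfg):
        v = VariantRecord(
            id="x", gene="SETX", protein="p.L68=",
            freqs=PopulationFrequencies({"all": 3e-5}),
            splice_predictions={"ada": "damaging"},
            conservation="not_conserved",
        )
        assert "BP7" not in assign_criteria(v, kb, catalog, als_cfg)

    def test_pp2_excluded_gene_missense(self, kb, catalog, als_cfg):
        v = VariantRecord(id="x", gene="GLE1", protein="p.R100W", freqs=zero_freqs())
        assert "PP2" not in assign_criteria(v, kb, catalog, als_cfg)

    def test_inframe_indel_pm4(self, kb, catalog, als_cfg):
        v = VariantRecord(id="x", gene="FUS", protein="p.G223_G224del", freqs=zero_freqs())
        cs = assign_criteria(v, kb, catalog, als_cfg)
        assert "PM4" in cs and "PVS1" not in cs

    def test_disabled_codes_never_appear(self, kb, catalog, als_cfg):
        # manual BS2 is dropped under the ALS policy
        v = VariantRecord(
            id="x", gene="SOD1", protein="p.A5V", freqs=zero_freqs(),
            manual=CriteriaSet([assignment("BS2", source="manual")]),
        )
        cs = assign_criteria(v, kb, catalog, als_cfg)
        assert not cs.codes() & {"BS2", "BP1", "BP3"}

    def test_pm3_only_for_recessive_genes(self, kb, catalog, als_cfg):
        manual = CriteriaSet([assignment("PM3", source="manual")])
        ar = VariantRecord(id="a", gene="ALS2", protein="p.R100W", freqs=zero_freqs(), manual=manual)
        ad = VariantRecord(id="b", gene="TBK1", protein="p.R100W", freqs=zero_freqs(),
                           manual=CriteriaSet([assignment("PM3", source="manual")]))
        assert "PM3" in assign_criteria(ar, kb, catalog, als_cfg)
        assert "PM3" not in assign_criteria(ad, kb, catalog, als_cfg)

    def test_pp5_escalation_ladder(self, kb, als_cfg):
        def cat(reports):
            return KnownVariantCatalog(
                [CatalogEntry("TBK1", "R100W", established=False, reports=reports)]
            )

        v = VariantRecord(id="x", gene="TBK1", protein="p.R100W", freqs=zero_freqs())
        for reports, strength in ((1, Strength.SUPPORTING), (3, Strength.STRONG), (5, Strength.VERY_STRONG)):
            cs = assign_criteria(v, kb, cat(reports), als_cfg)
            assert cs.get("PP5").applied_strength is strength

    def test_unknown_gene_rejected(self, kb, catalog, als_cfg):
        v = VariantRecord(id="x", gene="NOTAGENE", protein="p.R100W")
        with pytest.raises(KeyError):
            assign_criteria(v, kb, catalog, als_cfg)

    def test_deterministic(self, kb, catalog, als_cfg, worked_examples):
        for r in worked_examples:
            a = format_criteria(assign_criteria(r, kb, catalog, als_cfg))
            b = format_criteria(assign_criteria(r, kb, catalog, als_cfg))
            assert a == b


class TestClassifyVariant:
    def test_worked_examples_records_reproduce_printed_classes(self, worked_examples, kb, catalog, als_cfg):
        for r in worked_examples:
            assert classify_variant(r, kb, catalog, als_cfg).klass is r.expected_class

    def test_auto_criteria_match_printed_except_ps1_pm5_rows(self, worked_examples, kb, catalog, als_cfg):
        for r in worked_examples:
            auto = assign_criteria(r, kb, catalog, als_cfg)
            if "PS1" in r.expected_criteria and "PM5" in r.expected_criteria:
                expected = CriteriaSet(a for a in r.expected_criteria if a.code != "PM5")
                assert auto == expected
            else:
                assert auto == r.expected_criteria

    def test_unannotated_record_with_midrange_af_is_vus(self, kb, catalog, als_cfg):
        v = VariantRecord(
            id="x", gene="SETX", protein="p.R100W",
            freqs=PopulationFrequencies({"all": 5e-5}),
        )
        res = classify_variant(v, kb, catalog, als_cfg)
        # PP2 alone (one supporting criterion) fires no rule
        assert res.klass is VariantClass.UNCERTAIN

    def test_repeat_expansion_classifies_by_policy(self, kb, catalog, als_cfg):
        pos = VariantRecord(id="x", gene="C9orf72", consequence="repeat_expansion",
                            cdna="exp", expansion_positive=True)
        neg = VariantRecord(id="y", gene="ATXN2", consequence="repeat_expansion",
                            cdna="exp", expansion_positive=True)
        assert classify_variant(pos, kb, catalog, als_cfg).klass is VariantClass.PATHOGENIC
        # ATXN2 intermediate expansions are risk factors, not policy-pathogenic
        assert classify_variant(neg, kb, catalog, als_cfg).klass is VariantClass.UNCERTAIN

    def test_classify_records_tolerates_unknown_gene(self, kb, catalog, als_cfg):
        good = VariantRecord(id="a", gene="SOD1", protein="p.A5V", freqs=zero_freqs())
        bad = VariantRecord(id="b", gene="NOTAGENE", protein="p.A5V")
        out = classify_records([good, bad], kb, catalog, als_cfg)
        assert len(out) == 2
        assert out[1].klass is VariantClass.UNCERTAIN
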