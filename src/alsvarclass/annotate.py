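"""Automatic criteria assignment for annotated variant records.

Given a variant annotated with its HGVS descriptions, population
frequencies, in-silico predictor verdicts and known-variant catalog hits,
this module derives the applicable ACMG criteria under a
:class:`~alsvarclass.policy.PolicyConfig` and classifies the merged
evidence. Manual evidence (segregation, de novo status, functional
studies, case-control data) cannot be computed from annotations and is
merged in from user-asserted assignments; repeat expansions enter as
pre-annotated flags and classify by policy, not by sequence criteria.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import json

from .evidence import (
    CriteriaSet,
    EvidenceAssignment,
    Strength,
    assignment,
)
from .frequency import PopulationFrequencies, assign_af_criteria
from .policy import (
    GeneKB,
    PolicyConfig,
    criterion_enabled,
    in_hotspot,
    pp2_applicable,
    pvs1_applicable,
)
from .rules import ClassificationResult, VariantClass, classify

logger = logging.getLogger(__name__)

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "canonical_splice",
    "inframe_indel",
    "synonymous",
    "start_loss",
    "stop_loss",
    "repeat_expansion",
    "other",
)

#: Null-variant consequence classes eligible for PVS1.
NULL_CONSEQUENCES = frozenset({"nonsense", "frameshift", "canonical_splice", "start_loss"})

#: Manual-evidence codes the engine accepts from user assertions.
MANUAL_CODES = frozenset(
    {"PS2", "PM6", "PM3", "BP2", "PP1", "BS4", "PS3", "BS3", "PS4", "PP4", "BP5", "PM1"}
)

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*", "Sec": "U",
}


def _normalize_protein(text: str) -> str:
    """Strip 'p.' and parentheses, collapse three-letter AA codes to one."""
    t = text.strip()
    if t.lower().startswith("p."):
        t = t[2:]
    t = t.strip("()")
    for three, one in _AA3TO1.items():
        t = t.replace(three, one)
    return t


_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_NONSENSE_RE = re.compile(r"^([A-Z])(\d+)\*$")
_SYNONYMOUS_RE = re.compile(r"^([A-Z])(\d+)=$")
_INTRON_OFFSET_RE = re.compile(r"c\.\d+(?:_\d+)?([+-])(\d+)")


def parse_protein_consequence(
    p_hgvs: str, c_hgvs: str = ""
) -> tuple[str, int | None]:
    """Classify an HGVS description pair into a consequence class.

    Returns ``(consequence, first_affected_residue)``; the residue is None
    when no protein coordinate is given (e.g. canonical splice variants).
    Unparseable text yields ``("other", None)`` with a logged warning,
    never an exception.
    """
    if not p_hgvs.strip() and not c_hgvs.strip():
        raise ValueError("at least one of the protein/cDNA descriptions is required")

    p = _normalize_protein(p_hgvs) if p_hgvs.strip() else ""
    residue: int | None = None
    m_num = re.search(r"(\d+)", p)
    if m_num:
        residue = int(m_num.group(1))

    if p:
        if "fs" in p:
            return "frameshift", residue
        if (m := _NONSENSE_RE.match(p)):
            return "nonsense", int(m.group(2))
        if (m := _SYNONYMOUS_RE.match(p)) or p == "=":
            return "synonymous", residue
        if p.startswith("*") or "ext" in p:
            return "stop_loss", residue
        if any(tok in p for tok in ("delins", "del", "ins", "dup")):
            return "inframe_indel", residue
        if (m := _MISSENSE_RE.match(p)):
            ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
            if ref == "M" and pos == 1:
                return "start_loss", 1
            if ref == alt:
                return "synonymous", pos
            return "missense", pos
        if p == "?":
            pass  # fall through to cDNA
        else:
            logger.warning("unparseable protein HGVS %r; typed as 'other'", p_hgvs)
            return "other", residue

    c = c_hgvs.strip()
    if c:
        m = _INTRON_OFFSET_RE.search(c)
        if m and int(m.group(2)) in (1, 2):
            return "canonical_splice", None
        logger.warning("cannot type variant from cDNA HGVS %r; typed as 'other'", c_hgvs)
    return "other", residue


@dataclass(frozen=True)
class CatalogEntry:
    """One known-variant assertion.

    ``established`` marks amino-acid changes whose pathogenicity rests on
    evaluable evidence (these anchor PS1/PM5); ``reports`` counts
    independent reputable-source assertions whose underlying evidence is
    not available (these drive PP5/BP6, with strength escalating with
    concordant report count).
    """

    gene: str
    protein_change: str  # e.g. "G294V"
    established: bool = True
    asserted_class: str = "pathogenic"  # pathogenic | benign
    reports: int = 0

    def __post_init__(self) -> None:
        if not _MISSENSE_RE.match(self.protein_change) and not _NONSENSE_RE.match(
            self.protein_change
        ):
            raise ValueError(f"catalog protein change not parseable: {self.protein_change!r}")
        if self.reports < 0:
            raise ValueError("report count must be >= 0")

    @property
    def residue(self) -> int:
        return int(re.search(r"(\d+)", self.protein_change).group(1))

    @property
    def alt(self) -> str:
        return self.protein_change[-1]


class KnownVariantCatalog:
    """Assertions keyed by (gene, residue)."""

    def __init__(self, entries: Iterable[CatalogEntry] = ()) -> None:
        self._by_residue: dict[tuple[str, int], list[CatalogEntry]] = {}
        for e in entries:
            self._by_residue.setdefault((e.gene, e.residue), []).append(e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_residue.values())

    def at_residue(self, gene: str, residue: int) -> list[CatalogEntry]:
        return list(self._by_residue.get((gene, residue), []))

    def same_change(self, gene: str, change: str) -> CatalogEntry | None:
        """Established pathogenic entry with exactly this amino-acid change."""
        res = int(re.search(r"(\d+)", change).group(1))
        for e in self.at_residue(gene, res):
            if e.established and e.asserted_class == "pathogenic" and e.protein_change == change:
                return e
        return None

    def different_change(self, gene: str, change: str) -> CatalogEntry | None:
        """Established pathogenic entry at the same residue, different change."""
        res = int(re.search(r"(\d+)", change).group(1))
        for e in self.at_residue(gene, res):
            if e.established and e.asserted_class == "pathogenic" and e.protein_change != change:
                return e
        return None

    def reported(self, gene: str, change: str) -> CatalogEntry | None:
        """Any entry asserting this exact variant with >=1 report."""
        res = int(re.search(r"(\d+)", change).group(1))
        for e in self.at_residue(gene, res):
            if e.protein_change == change and e.reports >= 1:
                return e
        return None

    @classmethod
    def from_json(cls, path: str | Path) -> "KnownVariantCatalog":
        data = json.loads(Path(path).read_text())
        entries = data["entries"] if isinstance(data, dict) else data
        return cls(CatalogEntry(**e) for e in entries)


@dataclass
class VariantRecord:
    """A single annotated variant observation."""

    id: str
    gene: str
    transcript: str = ""
    cdna: str = ""
    protein: str = ""
    exon: int | None = None
    consequence: str | None = None  # None -> derived from HGVS
    zygosity: str = "heterozygous"
    freqs: PopulationFrequencies = field(default_factory=lambda: PopulationFrequencies({}))
    predictions: Mapping[str, str] = field(default_factory=dict)
    splice_predictions: Mapping[str, str] = field(default_factory=dict)
    conservation: str = "unknown"  # conserved | not_conserved | unknown
    manual: CriteriaSet = field(default_factory=CriteriaSet)
    patient_count: int = 1
    familial: bool = False
    expansion_positive: bool = False
    expected_class: VariantClass | None = None
    expected_criteria: CriteriaSet | None = None

    def __post_init__(self) -> None:
        if self.patient_count < 1:
            raise ValueError(f"{self.id}: patient_count must be >= 1")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"{self.id}: unknown consequence {self.consequence!r}")

    def typed_consequence(self) -> tuple[str, int | None]:
        """The consequence class and first affected residue (deriving from
        HGVS when not pre-annotated)."""
        if self.protein.strip() or self.cdna.strip():
            cons, residue = parse_protein_consequence(self.protein, self.cdna)
        else:
            cons, residue = "other", None
        if self.consequence is not None:
            cons = self.consequence
        return cons, residue

    @property
    def protein_change(self) -> str:
        return _normalize_protein(self.protein) if self.protein.strip() else ""


def _prediction_counts(v: VariantRecord) -> tuple[int, int]:
    verdicts = list(v.predictions.values()) + list(v.splice_predictions.values())
    damaging = sum(1 for x in verdicts if x == "damaging")
    benign = sum(1 for x in verdicts if x == "benign")
    return damaging, benign


def _pp5_strength(reports: int, cfg: PolicyConfig) -> Strength:
    if reports >= cfg.pp5_very_strong_reports:
        return Strength.VERY_STRONG
    if reports >= cfg.pp5_strong_reports:
        return Strength.STRONG
    return Strength.SUPPORTING


def assign_criteria(
    v: VariantRecord,
    kb: GeneKB,
    catalog: KnownVariantCatalog,
    cfg: PolicyConfig,
) -> CriteriaSet:
    """Derive the criteria set for one record under a policy.

    The union of automatically computed criteria (sequence type, hotspot,
    catalog, frequency, in-silico) and enabled manual assignments.
    Deterministic given (record, KB, catalog, config); disabled codes and
    inapplicable manual evidence are dropped with a logged notice.
    """
    kb.require(v.gene)
    cs = CriteriaSet()
    cons, residue = v.typed_consequence()

    def add(code: str, strength: Strength | None = None, *, rationale: str = "", source: str = "auto") -> None:
        if not criterion_enabled(code, cfg):
            logger.info("%s: %s suppressed (disabled by policy %s)", v.id, code, cfg.name)
            return
        cs.replace(assignment(code, strength, rationale=rationale, source=source))

    if cons == "repeat_expansion":
        # Expansion status is a pre-annotated flag; sequence criteria do not apply.
        _merge_manual(cs, v, kb, cfg)
        return cs

    # Null variants in LoF-mechanism genes
    if cons in NULL_CONSEQUENCES and pvs1_applicable(v.gene, cfg):
        add("PVS1", Strength.VERY_STRONG, rationale=f"{cons} in LoF-mechanism gene")

    # Catalog: same or neighbouring amino-acid changes
    change = v.protein_change
    if cons == "missense" and change and _MISSENSE_RE.match(change):
        if catalog.same_change(v.gene, change):
            add("PS1", rationale="same amino-acid change as an established pathogenic variant")
        elif catalog.different_change(v.gene, change):
            add("PM5", rationale="different pathogenic change known at this residue")

    # Hotspot / functional domain
    if in_hotspot(v.gene, residue, cons, cfg, exon=v.exon):
        add("PM1", rationale="mutational hotspot / critical functional domain")

    # Protein-length changes
    if cons == "inframe_indel":
        add("PM4", rationale="in-frame protein length change")

    # Frequency criteria
    if v.freqs:
        for a in assign_af_criteria(v.freqs, cfg):
            add(a.code, a.applied_strength, rationale=a.rationale)

    # Missense constraint
    if cons == "missense" and pp2_applicable(v.gene, cfg):
        add("PP2", rationale="missense in a missense-constrained ALS gene")

    # In-silico consensus
    damaging, benign = _prediction_counts(v)
    if damaging >= cfg.pp3_min_damaging and benign == 0:
        add("PP3", rationale=f"{damaging} damaging predictions, none benign")
    elif benign >= cfg.bp4_min_benign and damaging == 0:
        add("BP4", rationale=f"{benign} benign predictions, none damaging")

    # Synonymous with no predicted splice impact and no conservation
    if (
        cons == "synonymous"
        and all(x != "damaging" for x in v.splice_predictions.values())
        and v.conservation == "not_conserved"
    ):
        add("BP7", rationale="synonymous, no splice impact predicted, not conserved")

    # Reputable-source assertions
    if change:
        entry = catalog.reported(v.gene, change)
        if entry is not None:
            if entry.asserted_class == "pathogenic":
                add(
                    "PP5",
                    _pp5_strength(entry.reports, cfg),
                    rationale=f"{entry.reports} concordant pathogenic report(s)",
                    source="catalog",
                )
            else:
                s = _pp5_strength(entry.reports, cfg)
                if s is Strength.VERY_STRONG and not cfg.allow_benign_very_strong:
                    s = Strength.STRONG
                cs_assignment = assignment(
                    "BP6",
                    s,
                    rationale=f"{entry.reports} concordant benign report(s)",
                    source="catalog",
                    allow_benign_very_strong=cfg.allow_benign_very_strong,
                )
                if criterion_enabled("BP6", cfg):
                    cs.replace(cs_assignment)

    _merge_manual(cs, v, kb, cfg)
    return cs


def _merge_manual(cs: CriteriaSet, v: VariantRecord, kb: GeneKB, cfg: PolicyConfig) -> None:
    for a in v.manual:
        if not criterion_enabled(a.code, cfg):
            logger.warning("%s: manual %s dropped (disabled by policy %s)", v.id, a.code, cfg.name)
            continue
        if a.code in ("PM3", "BP2") and not cfg.is_recessive(v.gene, kb):
            logger.warning(
                "%s: manual %s dropped (%s has no recessive inheritance)", v.id, a.code, v.gene
            )
            continue
        cs.replace(
            EvidenceAssignment(a.criterion, a.applied_strength, rationale=a.rationale, source="manual")
        )


def classify_variant(
    v: VariantRecord,
    kb: GeneKB,
    catalog: KnownVariantCatalog,
    cfg: PolicyConfig,
) -> ClassificationResult:
    """Assign criteria and combine them into a five-tier classification.

    Repeat-expansion records with a positive expansion flag classify by
    policy (the C9orf72 expansion is pathogenic); all other records go
    through criteria assignment and the combining rules.
    """
    cons, _ = v.typed_consequence()
    if cons == "repeat_expansion" and v.expansion_positive:
        if v.gene in cfg.pathogenic_expansion_genes:
            return ClassificationResult(
                VariantClass.PATHOGENIC,
                "expansion.policy",
                assign_criteria(v, kb, catalog, cfg),
            )
        return ClassificationResult(VariantClass.UNCERTAIN, "", CriteriaSet())
    cs = assign_criteria(v, kb, catalog, cfg)
    return classify(cs, ba1_overrides_conflict=cfg.ba1_overrides_conflict)


def classify_records(
    records: Iterable[VariantRecord],
    kb: GeneKB,
    catalog: KnownVariantCatalog,
    cfg: PolicyConfig,
) -> list[ClassificationResult]:
    """Lenient batch classification: a record whose gene is missing from
    the knowledge base classifies as uncertain significance with a logged
    warning instead of aborting the run."""
    out = []
    for v in records:
        try:
            out.append(classify_variant(v, kb, catalog, cfg))
        except KeyError as exc:
            logger.warning("%s: %s; classified as uncertain significance", v.id, exc)
            out.append(ClassificationResult(VariantClass.UNCERTAIN, "", CriteriaSet()))
    return out
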