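"""Five-tier combining rules over evidence-strength buckets.

The 2015 ACMG/AMP framework combines evidence criteria into one of five
classes: pathogenic, likely pathogenic, uncertain significance, likely
benign, benign. Combination depends only on how many criteria of each
applied strength point in each direction, never on which codes supplied
them — which is what makes curator strength escalations (e.g. PP5 counted
as very strong) behave exactly like native evidence of that level.

Pathogenic fires when:
  (P.1) 1 very strong AND (>=1 strong | >=2 moderate | 1 moderate + 1
        supporting | >=2 supporting); two or more very strong also satisfy
        this arm (an extension: the published table never combines two very
        strong criteria);
  (P.2) >=2 strong;
  (P.3) 1 strong AND (>=3 moderate | 2 moderate + >=2 supporting |
        1 moderate + >=4 supporting).
Likely pathogenic:
  (LP.1) 1 very strong + 1 moderate;
  (LP.2) 1 strong + 1-2 moderate;
  (LP.3) 1 strong + >=2 supporting;
  (LP.4) >=3 moderate;
  (LP.5) 2 moderate + >=2 supporting;
  (LP.6) 1 moderate + >=4 supporting.
Benign: (B.1) stand-alone (BA1); (B.2) >=2 benign strong.
Likely benign: (LB.1) 1 benign strong + 1 benign supporting;
  (LB.2) >=2 benign supporting.

If rules fire in both directions the variant is of uncertain significance
with the conflict flag raised (optionally BA1 may be allowed to override).
If nothing fires, uncertain significance.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from typing import Hashable, Iterable

from .evidence import CriteriaSet, StrengthHistogram


@functools.total_ordering
class VariantClass(enum.Enum):
    """The five classification tiers, ordered benign -> pathogenic."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    UNCERTAIN = "uncertain_significance"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"

    @property
    def rank(self) -> int:
        return _CLASS_ORDER.index(self)

    def __lt__(self, other: "VariantClass") -> bool:
        if not isinstance(other, VariantClass):
            return NotImplemented
        return self.rank < other.rank

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CLASS_ORDER = [
    VariantClass.BENIGN,
    VariantClass.LIKELY_BENIGN,
    VariantClass.UNCERTAIN,
    VariantClass.LIKELY_PATHOGENIC,
    VariantClass.PATHOGENIC,
]

#: Short labels used in curation tables.
CLASS_LABELS = {
    VariantClass.PATHOGENIC: "P",
    VariantClass.LIKELY_PATHOGENIC: "LP",
    VariantClass.UNCERTAIN: "VUS",
    VariantClass.LIKELY_BENIGN: "LB",
    VariantClass.BENIGN: "B",
}
LABEL_TO_CLASS = {v: k for k, v in CLASS_LABELS.items()}


@dataclass
class ClassificationResult:
    klass: VariantClass
    fired_rule: str = ""
    evidence_used: CriteriaSet = field(default_factory=CriteriaSet)
    conflict: bool = False

    @property
    def label(self) -> str:
        return CLASS_LABELS[self.klass]

    def to_json(self) -> dict:
        return {
            "class": self.klass.value,
            "fired_rule": self.fired_rule,
            "conflict": self.conflict,
            "criteria": self.evidence_used.to_json(),
        }


def _pathogenic_rule(h: StrengthHistogram) -> str:
    vs, s, m, p = h.very_strong, h.strong, h.moderate, h.supporting
    # Pathogenic combinations, strongest first
    if vs >= 1 and (vs >= 2 or s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2):
        return "P.1"
    if s >= 2:
        return "P.2"
    if s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)):
        return "P.3"
    # Likely pathogenic combinations
    if vs >= 1 and m >= 1:
        return "LP.1"
    if s >= 1 and 1 <= m <= 2:
        return "LP.2"
    if s >= 1 and p >= 2:
        return "LP.3"
    if m >= 3:
        return "LP.4"
    if m >= 2 and p >= 2:
        return "LP.5"
    if m >= 1 and p >= 4:
        return "LP.6"
    return ""


def _benign_rule(h: StrengthHistogram) -> str:
    if h.benign_stand_alone >= 1:
        return "B.1"
    if h.benign_strong >= 2:
        return "B.2"
    if h.benign_strong >= 1 and h.benign_supporting >= 1:
        return "LB.1"
    if h.benign_supporting >= 2:
        return "LB.2"
    return ""


def classify(cs: CriteriaSet, *, ba1_overrides_conflict: bool = False) -> ClassificationResult:
    """Combine a criteria set into a five-tier classification.

    Deterministic and order-independent: only the strength histogram
    matters. Conflicting combinations (rules firing in both directions)
    yield uncertain significance with ``conflict=True`` unless
    ``ba1_overrides_conflict`` is set and BA1 is present, in which case
    benign wins.
    """
    h = cs.histogram()
    prule = _pathogenic_rule(h)
    brule = _benign_rule(h)
    if prule and brule:
        if ba1_overrides_conflict and brule == "B.1":
            return ClassificationResult(VariantClass.BENIGN, brule, cs, conflict=True)
        return ClassificationResult(VariantClass.UNCERTAIN, "", cs, conflict=True)
    if prule:
        klass = VariantClass.PATHOGENIC if prule.startswith("P.") else VariantClass.LIKELY_PATHOGENIC
        return ClassificationResult(klass, prule, cs)
    if brule:
        klass = VariantClass.BENIGN if brule.startswith("B.") else VariantClass.LIKELY_BENIGN
        return ClassificationResult(klass, brule, cs)
    return ClassificationResult(VariantClass.UNCERTAIN, "", cs)


def classify_batch(
    rows: Iterable[tuple[Hashable, CriteriaSet]],
    *,
    ba1_overrides_conflict: bool = False,
) -> list[tuple[Hashable, ClassificationResult]]:
    """Element-wise :func:`classify`, preserving order; ids must be unique."""
    seen: set[Hashable] = set()
    out: list[tuple[Hashable, ClassificationResult]] = []
    for rid, cs in rows:
        if rid in seen:
            raise ValueError(f"duplicate id in batch: {rid!r}")
        seen.add(rid)
        out.append((rid, classify(cs, ba1_overrides_conflict=ba1_overrides_conflict)))
    return out
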