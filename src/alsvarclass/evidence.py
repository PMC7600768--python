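"""ACMG evidence vocabulary: criterion codes, strength levels, criteria sets.

The 2015 ACMG/AMP framework defines 28 evidence criteria. Sixteen argue for
pathogenicity (PVS1, PS1-4, PM1-6, PP1-5) and twelve for benignity (BA1,
BS1-4, BP1-7). Each code carries a default strength encoded in its name
(VS = very strong, S = strong, M = moderate, P = supporting; BA1 is the
single stand-alone benign criterion), but curators may apply a criterion at
a different strength — e.g. a reputable-source assertion (PP5) backed by
many concordant reports may be counted as strong or very strong. This
module models codes, applied strengths and sets of assignments, plus the
parenthesised text notation used in curation tables
(``"PS1, PM1 (strong), PM2"``).
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping


class Strength(enum.Enum):
    """Evidence strength buckets, in increasing order of weight."""

    SUPPORTING = "supporting"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"
    STAND_ALONE = "stand_alone"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Direction(enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


# canonical spellings accepted for strengths in text notation
_STRENGTH_WORDS = {
    "supporting": Strength.SUPPORTING,
    "moderate": Strength.MODERATE,
    "strong": Strength.STRONG,
    "very strong": Strength.VERY_STRONG,
    "very_strong": Strength.VERY_STRONG,
    "stand alone": Strength.STAND_ALONE,
    "stand_alone": Strength.STAND_ALONE,
    "stand-alone": Strength.STAND_ALONE,
}


@dataclass(frozen=True)
class CriterionCode:
    """One of the 28 ACMG criterion identifiers."""

    code: str
    direction: Direction
    default_strength: Strength

    def __str__(self) -> str:
        return self.code


def _build_codes() -> dict[str, CriterionCode]:
    codes: dict[str, CriterionCode] = {}

    def add(code: str, direction: Direction, strength: Strength) -> None:
        codes[code] = CriterionCode(code, direction, strength)

    add("PVS1", Direction.PATHOGENIC, Strength.VERY_STRONG)
    for i in range(1, 5):
        add(f"PS{i}", Direction.PATHOGENIC, Strength.STRONG)
    for i in range(1, 7):
        add(f"PM{i}", Direction.PATHOGENIC, Strength.MODERATE)
    for i in range(1, 6):
        add(f"PP{i}", Direction.PATHOGENIC, Strength.SUPPORTING)
    add("BA1", Direction.BENIGN, Strength.STAND_ALONE)
    for i in range(1, 5):
        add(f"BS{i}", Direction.BENIGN, Strength.STRONG)
    for i in range(1, 8):
        add(f"BP{i}", Direction.BENIGN, Strength.SUPPORTING)
    return codes


#: The full ACMG criterion vocabulary, keyed by code.
CODES: dict[str, CriterionCode] = _build_codes()

PATHOGENIC_CODES = tuple(c for c in CODES.values() if c.direction is Direction.PATHOGENIC)
BENIGN_CODES = tuple(c for c in CODES.values() if c.direction is Direction.BENIGN)

#: Strengths a pathogenic-direction criterion may legally carry.
PATHOGENIC_STRENGTHS = (
    Strength.SUPPORTING,
    Strength.MODERATE,
    Strength.STRONG,
    Strength.VERY_STRONG,
)
#: Strengths a benign-direction criterion may carry by default (BA1 is fixed
#: at stand-alone; very_strong escalation of benign evidence is opt-in).
BENIGN_STRENGTHS = (Strength.SUPPORTING, Strength.STRONG)


def get_code(code: str) -> CriterionCode:
    """Look up a criterion by its identifier (case-insensitive)."""
    try:
        return CODES[code.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown ACMG criterion code: {code!r}") from None


@dataclass(frozen=True)
class EvidenceAssignment:
    """One criterion applied to one variant, at a possibly adjusted strength."""

    criterion: CriterionCode
    applied_strength: Strength | None = None
    rationale: str = ""
    source: str = "auto"  # auto | manual | catalog

    def __post_init__(self) -> None:
        if self.applied_strength is None:
            object.__setattr__(self, "applied_strength", self.criterion.default_strength)

    @property
    def code(self) -> str:
        return self.criterion.code

    @property
    def is_escalated(self) -> bool:
        return self.applied_strength is not self.criterion.default_strength


def assignment(
    code: str,
    strength: Strength | str | None = None,
    *,
    rationale: str = "",
    source: str = "auto",
    allow_benign_very_strong: bool = False,
) -> EvidenceAssignment:
    """Build a validated :class:`EvidenceAssignment` from a code string.

    Raises ``ValueError`` for unknown codes, unknown strength words, or
    strengths a code may not carry (BA1 is always stand-alone; benign
    criteria cannot be very strong unless explicitly allowed).
    """
    crit = get_code(code)
    if strength is None:
        s = crit.default_strength
    elif isinstance(strength, Strength):
        s = strength
    else:
        key = strength.strip().lower()
        if key not in _STRENGTH_WORDS:
            raise ValueError(f"invalid strength {strength!r} for {crit.code}")
        s = _STRENGTH_WORDS[key]
    if crit.code == "BA1":
        if s is not Strength.STAND_ALONE:
            raise ValueError("BA1 is stand-alone and cannot be re-weighted")
    elif s is Strength.STAND_ALONE:
        raise ValueError(f"only BA1 may carry stand_alone strength, not {crit.code}")
    elif crit.direction is Direction.BENIGN:
        if s is Strength.VERY_STRONG and not allow_benign_very_strong:
            raise ValueError(
                f"benign criterion {crit.code} cannot be very_strong "
                "(pass allow_benign_very_strong=True to permit)"
            )
        if s is Strength.MODERATE:
            raise ValueError(f"benign criterion {crit.code} has no moderate level")
    return EvidenceAssignment(crit, s, rationale=rationale, source=source)


class CriteriaSet:
    """An unordered collection of evidence assignments, at most one per code."""

    __slots__ = ("_by_code",)

    def __init__(self, assignments: Iterable[EvidenceAssignment] = ()) -> None:
        self._by_code: dict[str, EvidenceAssignment] = {}
        for a in assignments:
            self.add(a)

    def add(self, a: EvidenceAssignment) -> None:
        if a.code in self._by_code:
            raise ValueError(f"duplicate criterion {a.code} in criteria set")
        self._by_code[a.code] = a

    def replace(self, a: EvidenceAssignment) -> None:
        """Add, overriding any existing assignment for the same code."""
        self._by_code[a.code] = a

    def discard(self, code: str) -> None:
        self._by_code.pop(code.upper(), None)

    def get(self, code: str) -> EvidenceAssignment | None:
        return self._by_code.get(code.upper())

    def __contains__(self, code: str) -> bool:
        return code.upper() in self._by_code

    def __iter__(self) -> Iterator[EvidenceAssignment]:
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CriteriaSet):
            return NotImplemented
        return {
            c: (a.applied_strength) for c, a in self._by_code.items()
        } == {c: (a.applied_strength) for c, a in other._by_code.items()}

    def __repr__(self) -> str:
        return f"CriteriaSet({format_criteria(self)!r})"

    def codes(self) -> frozenset[str]:
        return frozenset(self._by_code)

    def histogram(self) -> "StrengthHistogram":
        return strength_histogram(self)

    def to_json(self) -> list[dict]:
        return [
            {
                "code": a.code,
                "strength": a.applied_strength.value,
                "source": a.source,
                "rationale": a.rationale,
            }
            for a in sorted(self, key=lambda a: a.code)
        ]

    @classmethod
    def from_json(cls, items: Iterable[Mapping]) -> "CriteriaSet":
        return cls(
            assignment(
                d["code"],
                d.get("strength"),
                rationale=d.get("rationale", ""),
                source=d.get("source", "auto"),
            )
            for d in items
        )


@dataclass(frozen=True)
class StrengthHistogram:
    """Per-direction counts of applied strengths."""

    very_strong: int = 0
    strong: int = 0
    moderate: int = 0
    supporting: int = 0
    benign_stand_alone: int = 0
    benign_strong: int = 0
    benign_supporting: int = 0

    @property
    def total(self) -> int:
        return (
            self.very_strong
            + self.strong
            + self.moderate
            + self.supporting
            + self.benign_stand_alone
            + self.benign_strong
            + self.benign_supporting
        )


def strength_histogram(cs: CriteriaSet) -> StrengthHistogram:
    """Count applied strengths per direction.

    Classification depends only on these buckets: an escalated criterion
    counts exactly as a native criterion of its applied bucket.
    """
    counts = dict.fromkeys(
        (
            "very_strong",
            "strong",
            "moderate",
            "supporting",
            "benign_stand_alone",
            "benign_strong",
            "benign_supporting",
        ),
        0,
    )
    for a in cs:
        s = a.applied_strength
        if a.criterion.direction is Direction.PATHOGENIC:
            counts[s.value] += 1
        else:
            if s is Strength.STAND_ALONE:
                counts["benign_stand_alone"] += 1
            elif s in (Strength.STRONG, Strength.VERY_STRONG):
                # benign very_strong (opt-in) has no dedicated combining rule;
                # it is counted with the strong bucket
                counts["benign_strong"] += 1
            else:
                counts["benign_supporting"] += 1
    return StrengthHistogram(**counts)


_TOKEN_RE = re.compile(
    r"^\s*(?P<code>[A-Za-z]+\d+)\s*(?:\(\s*(?P<strength>[^()]*?)\s*\))?\s*$"
)


def parse_criteria_string(
    text: str, *, source: str = "auto", allow_benign_very_strong: bool = False
) -> CriteriaSet:
    """Parse comma-separated criteria notation, e.g. ``"PM1, PP5 (strong)"``.

    Unparenthesised codes carry their default strength. Whitespace and case
    are ignored; "very strong" and "very_strong" are both accepted.
    Unknown codes, invalid strength words and duplicates are rejected.
    """
    cs = CriteriaSet()
    text = text.strip()
    if not text:
        return cs
    for token in text.split(","):
        m = _TOKEN_RE.match(token)
        if not m:
            raise ValueError(f"cannot parse criteria token: {token.strip()!r}")
        cs.add(
            assignment(
                m.group("code"),
                m.group("strength"),
                source=source,
                allow_benign_very_strong=allow_benign_very_strong,
            )
        )
    return cs


_FAMILY_ORDER = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")


def _code_sort_key(a: EvidenceAssignment) -> tuple[int, int]:
    family = a.code.rstrip("0123456789")
    index = int(a.code[len(family):])
    return _FAMILY_ORDER.index(family), index


def format_criteria(cs: CriteriaSet) -> str:
    """Inverse of :func:`parse_criteria_string` (round-trips applied
    strengths); codes print in conventional curation order (PVS1, PS, PM,
    PP, then benign)."""
    parts = []
    for a in sorted(cs, key=_code_sort_key):
        if a.is_escalated:
            parts.append(f"{a.code} ({a.applied_strength.value.replace('_', ' ')})")
        else:
            parts.append(a.code)
    return ", ".join(parts)


def criteria_to_json_str(cs: CriteriaSet) -> str:
    return json.dumps(cs.to_json())
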