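"""Cohort-level aggregation: class tallies, gene counts, diagnostic yield.

Diagnostic yield is the fraction of a sub-cohort (sporadic or familial)
in which a causative genotype was identified — either a pathogenic repeat
expansion (supplied as pre-counted carrier totals, since expansions are
detected by PCR, not sequencing) or a pathogenic / likely pathogenic
sequence variant. Yields are reported as percentages rounded half-up to
one decimal.
"""

from __future__ import annotations

import csv
import io as _io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .annotate import VariantRecord, classify_variant
from .rules import CLASS_LABELS, ClassificationResult, VariantClass


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return float(
        (Decimal(numerator) / Decimal(denominator) * 100).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class CohortMeta:
    """Sub-cohort totals and repeat-expansion carrier counts."""

    sporadic_total: int
    familial_total: int
    expansion_sporadic: int = 0
    expansion_familial: int = 0

    def __post_init__(self) -> None:
        if self.sporadic_total <= 0 or self.familial_total <= 0:
            raise ValueError("sub-cohort totals must be positive")


@dataclass
class GeneTally:
    variants: int = 0
    patients: int = 0


@dataclass
class CohortSummary:
    class_counts: Counter
    gene_plp: dict[str, GeneTally]
    familial_plp_patients: int
    sporadic_plp_patients: int
    sporadic_yield: float
    familial_yield: float
    total_variants: int

    def to_json(self) -> dict:
        return {
            "class_counts": {k.value: v for k, v in self.class_counts.items()},
            "gene_plp": {
                g: {"variants": t.variants, "patients": t.patients}
                for g, t in sorted(self.gene_plp.items())
            },
            "familial_plp_patients": self.familial_plp_patients,
            "sporadic_plp_patients": self.sporadic_plp_patients,
            "sporadic_yield_percent": self.sporadic_yield,
            "familial_yield_percent": self.familial_yield,
            "total_variants": self.total_variants,
        }

    def to_text(self) -> str:
        lines = ["Cohort summary", "=============="]
        lines.append("Class counts:")
        for k in VariantClass:
            lines.append(f"  {CLASS_LABELS[k]:>3}: {self.class_counts.get(k, 0)}")
        lines.append("P/LP variants per gene (variants / patients):")
        for g, t in sorted(self.gene_plp.items()):
            lines.append(f"  {g}: {t.variants} / {t.patients}")
        lines.append(f"Sporadic diagnostic yield: {self.sporadic_yield}%")
        lines.append(f"Familial diagnostic yield: {self.familial_yield}%")
        return "\n".join(lines)


def summarize(
    results: Iterable[tuple[VariantRecord, ClassificationResult]],
    meta: CohortMeta,
) -> CohortSummary:
    """Aggregate per-variant classifications into cohort-level counts.

    A record's familial flag marks one familial patient among its carriers
    (the remaining ``patient_count - 1`` are sporadic). Yield combines
    expansion carriers with P/LP sequence-variant carriers over the
    sub-cohort totals.
    """
    class_counts: Counter = Counter()
    gene_plp: dict[str, GeneTally] = defaultdict(GeneTally)
    familial_patients = 0
    sporadic_patients = 0
    total = 0
    for rec, res in results:
        total += 1
        class_counts[res.klass] += 1
        if res.klass >= VariantClass.LIKELY_PATHOGENIC:
            t = gene_plp[rec.gene]
            t.variants += 1
            t.patients += rec.patient_count
            fam = 1 if rec.familial else 0
            familial_patients += fam
            sporadic_patients += rec.patient_count - fam
    return CohortSummary(
        class_counts=class_counts,
        gene_plp=dict(gene_plp),
        familial_plp_patients=familial_patients,
        sporadic_plp_patients=sporadic_patients,
        sporadic_yield=percent(meta.expansion_sporadic + sporadic_patients, meta.sporadic_total),
        familial_yield=percent(meta.expansion_familial + familial_patients, meta.familial_total),
        total_variants=total,
    )


@dataclass
class ReclassificationTable:
    """Cross-tabulation of class transitions between two policies."""

    counts: dict[tuple[VariantClass, VariantClass], int] = field(default_factory=dict)
    total: int = 0

    def add(self, before: VariantClass, after: VariantClass) -> None:
        key = (before, after)
        self.counts[key] = self.counts.get(key, 0) + 1
        self.total += 1

    def transitions(self, before: VariantClass, after: VariantClass) -> int:
        return self.counts.get((before, after), 0)

    @property
    def n_reclassified(self) -> int:
        return sum(v for (a, b), v in self.counts.items() if a != b)

    def row_sums(self) -> dict[VariantClass, int]:
        out: dict[VariantClass, int] = defaultdict(int)
        for (a, _), v in self.counts.items():
            out[a] += v
        return dict(out)

    def col_sums(self) -> dict[VariantClass, int]:
        out: dict[VariantClass, int] = defaultdict(int)
        for (_, b), v in self.counts.items():
            out[b] += v
        return dict(out)

    def to_csv(self) -> str:
        order = list(VariantClass)
        buf = _io.StringIO()
        w = csv.writer(buf)
        w.writerow(["before\\after"] + [CLASS_LABELS[c] for c in order])
        for a in order:
            w.writerow([CLASS_LABELS[a]] + [self.transitions(a, b) for b in order])
        return buf.getvalue()


def policy_diff(
    records: Sequence[VariantRecord],
    kb,
    catalog,
    cfg_a,
    cfg_b,
) -> ReclassificationTable:
    """Classify every record under two policies and tabulate transitions."""
    table = ReclassificationTable()
    for rec in records:
        before = classify_variant(rec, kb, catalog, cfg_a).klass
        after = classify_variant(rec, kb, catalog, cfg_b).klass
        table.add(before, after)
    return table
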