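"""Packaged machine-readable fixtures and criteria-set enumeration.

Ships the 20 worked pathogenic/likely-pathogenic classifications and the
52-gene knowledge base as TSV resources, the synthetic known-variant
catalog backing them, and an exhaustive enumerator of small criteria sets
used to cross-check the rule engine against a brute-force oracle.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Iterator

from .annotate import KnownVariantCatalog, VariantRecord
from .evidence import (
    CODES,
    CriteriaSet,
    Direction,
    EvidenceAssignment,
    PATHOGENIC_STRENGTHS,
    Strength,
)
from .policy import GeneKB, load_gene_kb

_DATA = resources.files("alsvarclass.data")

#: Pinned digests of the packaged fixtures; tests fail on silent edits.
FIXTURE_SHA256 = {
    "worked_variants.tsv": "aa07ed5a78f13ab21f601a88bf9e7ccc79fe6bd7133d1d41a655b2bdd5bc67a7",
    "als_genes.tsv": "28334048dd04ff349d15ee2eac05e8a4cc473b896b2f7ca0c8db8c3f61fdf7d9",
    "synthetic_catalog.json": "0fa84d3b8e63b725a7b89717740bfa35a52e8cec2d30875b383911dc1ceb9a8f",
}


def fixture_checksum(name: str) -> str:
    return hashlib.sha256((_DATA / name).read_bytes()).hexdigest()


def _data_path(name: str) -> Path:
    with resources.as_file(_DATA / name) as p:
        return Path(p)


def worked_examples_fixture() -> list[VariantRecord]:
    """The 20 worked P/LP classifications, as annotated variant records.

    Each record carries the printed criteria string (with strength
    overrides) in ``expected_criteria`` and the printed class in
    ``expected_class``, plus annotation columns (frequencies, predictor
    verdicts, catalog-backed evidence) sufficient for the auto-assigner to
    reproduce the printed classes.
    """
    from .io import read_variant_table

    records = read_variant_table(_data_path("worked_variants.tsv"))
    assert len(records) == 20, "packaged worked-example fixture must have 20 rows"
    return records


def gene_kb_fixture() -> GeneKB:
    """The 52-gene ALS knowledge base (inheritance + constraint metrics)."""
    return load_gene_kb(_data_path("als_genes.tsv"))


def catalog_fixture() -> KnownVariantCatalog:
    """The synthetic known-variant catalog backing the worked examples."""
    return KnownVariantCatalog.from_json(_data_path("synthetic_catalog.json"))


def enumerate_criteria_sets(
    max_assignments: int,
    strengths: Iterable[Strength] = (),
) -> Iterator[CriteriaSet]:
    """Exhaustively enumerate criteria sets with up to ``max_assignments``
    codes, duplicate-free.

    ``strengths`` lists applied-strength overrides additionally available
    to pathogenic-direction codes (each code always offers its default);
    benign codes keep their defaults. Capped at 6 assignments for
    tractability.
    """
    if max_assignments > 6:
        raise ValueError("enumeration is capped at 6 assignments")
    overrides = [s for s in strengths if s in PATHOGENIC_STRENGTHS]
    options: dict[str, list[Strength]] = {}
    for code in CODES.values():
        if code.direction is Direction.PATHOGENIC:
            opts = dict.fromkeys([code.default_strength, *overrides])
            options[code.code] = list(opts)
        else:
            options[code.code] = [code.default_strength]
    all_codes = list(CODES.values())
    for k in range(max_assignments + 1):
        for combo in combinations(all_codes, k):
            for choice in product(*(options[c.code] for c in combo)):
                yield CriteriaSet(
                    EvidenceAssignment(c, s) for c, s in zip(combo, choice)
                )
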