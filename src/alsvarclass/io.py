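"""Readers and writers for variant tables and annotated VCF.

Tables are tab-separated, UTF-8, with '.' for missing values; criteria
strengths appear in parentheses exactly as curation tables print them.
VCF annotations live in INFO fields (GENE, CDNA, PROTEIN, AF_*, PRED_*,
SPLICE_* ...); classification output is written back as ACMG_CLASS and
ACMG_CRITERIA INFO fields with proper header definitions. Genomic
coordinates are irrelevant to gene/HGVS-level classification and are
carried through untouched. Nothing is skipped silently: every dropped row
or record is logged with its position.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .annotate import VariantRecord
from .evidence import CriteriaSet, format_criteria, parse_criteria_string
from .frequency import PopulationFrequencies
from .rules import CLASS_LABELS, LABEL_TO_CLASS, ClassificationResult

logger = logging.getLogger(__name__)

_MISSING = {"", ".", "nan", "NA"}

_CLASS_WORDS = {
    "p": "P", "pathogenic": "P",
    "lp": "LP", "likely_pathogenic": "LP", "likely pathogenic": "LP",
    "vus": "VUS", "uncertain_significance": "VUS", "uncertain significance": "VUS",
    "lb": "LB", "likely_benign": "LB", "likely benign": "LB",
    "b": "B", "benign": "B",
}


def _cell(row, col: str) -> str:
    v = str(row.get(col, "")).strip()
    return "" if v in _MISSING else v


def _parse_class(text: str):
    key = text.strip().lower()
    if key in _CLASS_WORDS:
        return LABEL_TO_CLASS[_CLASS_WORDS[key]]
    raise ValueError(f"unknown class label {text!r}")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read annotated variant records from a TSV.

    Mandatory column: ``gene``; at least one of ``cdna``/``protein`` per
    row. Recognised columns: id, transcript, exon, cdna, protein, class,
    criteria, n_patients, familial, zygosity, consequence, conservation,
    manual, expansion_positive, plus ``af_<population>``, ``pred_<tool>``
    and ``splice_<tool>`` columns. A ``criteria``/``class`` column is
    parsed and retained as expected-outcome fixture data. Malformed rows
    are skipped with a logged line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene" not in df.columns:
        raise ValueError("variant table is missing mandatory column 'gene'")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    splice_cols = [c for c in df.columns if c.startswith("splice_")]
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            gene = _cell(row, "gene")
            if not gene:
                raise ValueError("empty gene")
            cdna, protein = _cell(row, "cdna"), _cell(row, "protein")
            freqs = {}
            for c in af_cols:
                v = _cell(row, c)
                freqs[c] = float(v) if v else None
            preds = {c.removeprefix("pred_"): _cell(row, c) or "unknown" for c in pred_cols}
            splice = {c.removeprefix("splice_"): _cell(row, c) or "unknown" for c in splice_cols}
            manual_text = _cell(row, "manual")
            expected_cls = _cell(row, "class")
            expected_crit = _cell(row, "criteria")
            rec = VariantRecord(
                id=_cell(row, "id") or f"{gene}:{cdna or protein}",
                gene=gene,
                transcript=_cell(row, "transcript"),
                exon=int(_cell(row, "exon")) if _cell(row, "exon") else None,
                cdna=cdna,
                protein=protein,
                consequence=_cell(row, "consequence") or None,
                zygosity=_cell(row, "zygosity") or "heterozygous",
                freqs=PopulationFrequencies(freqs),
                predictions=preds,
                splice_predictions=splice,
                conservation=_cell(row, "conservation") or "unknown",
                manual=parse_criteria_string(manual_text, source="manual"),
                patient_count=int(_cell(row, "n_patients") or 1),
                familial=_cell(row, "familial") in ("1", "true", "True", "yes"),
                expansion_positive=_cell(row, "expansion_positive") in ("1", "true", "True", "yes"),
                expected_class=_parse_class(expected_cls) if expected_cls else None,
                expected_criteria=(
                    parse_criteria_string(expected_crit) if expected_crit else None
                ),
            )
            records.append(rec)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping malformed row at line %d: %s", lineno, exc)
    return records


def write_variant_table(
    path: str | Path,
    rows: Iterable[tuple[VariantRecord, ClassificationResult]],
) -> None:
    """Write records plus their classifications back to TSV."""
    out = []
    for rec, res in rows:
        out.append(
            {
                "id": rec.id,
                "gene": rec.gene,
                "transcript": rec.transcript or ".",
                "exon": rec.exon if rec.exon is not None else ".",
                "cdna": rec.cdna or ".",
                "protein": rec.protein or ".",
                "class": CLASS_LABELS[res.klass],
                "criteria": format_criteria(res.evidence_used) or ".",
                "fired_rule": res.fired_rule or ".",
                "conflict": int(res.conflict),
                "n_patients": rec.patient_count,
                "familial": int(rec.familial),
            }
        )
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def write_annotated_table(
    path: str | Path,
    records: Sequence[VariantRecord],
    truth: Sequence | None = None,
) -> None:
    """Write records with their full annotations (frequencies, predictor
    verdicts, manual evidence) in a layout :func:`read_variant_table` can
    re-read; ``truth`` optionally fills the ``class`` column."""
    pops = sorted({p for r in records for p in r.freqs.freqs})
    tools = sorted({t for r in records for t in r.predictions})
    splice_tools = sorted({t for r in records for t in r.splice_predictions})
    rows = []
    for i, rec in enumerate(records):
        row = {
            "id": rec.id,
            "gene": rec.gene,
            "transcript": rec.transcript or ".",
            "exon": rec.exon if rec.exon is not None else ".",
            "cdna": rec.cdna or ".",
            "protein": rec.protein or ".",
            "class": CLASS_LABELS[truth[i]] if truth is not None else ".",
            "n_patients": rec.patient_count,
            "familial": int(rec.familial),
            "conservation": rec.conservation,
            "manual": format_criteria(rec.manual) or ".",
        }
        for p in pops:
            af = rec.freqs.freqs.get(p)
            row[p if p.startswith("af_") else f"af_{p}"] = "." if af is None else af
        for t in tools:
            row[f"pred_{t}"] = rec.predictions.get(t, ".")
        for t in splice_tools:
            row[f"splice_{t}"] = rec.splice_predictions.get(t, ".")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- VCF ------------------------------------------------------------------

_VCF_STR_FIELDS = {
    "GENE": "gene",
    "TRANSCRIPT": "transcript",
    "CDNA": "cdna",
    "PROTEIN": "protein",
    "CONSEQ": "consequence",
    "ZYG": "zygosity",
    "CONSERV": "conservation",
}


def _criteria_to_info(cs: CriteriaSet) -> str:
    # INFO-safe encoding: no spaces or commas
    return "|".join(
        format_criteria(CriteriaSet([a])).replace(" ", "").replace("(", "[").replace(")", "]")
        for a in sorted(cs, key=lambda a: a.code)
    ) or "."


def _criteria_from_info(text: str) -> CriteriaSet:
    if not text or text == ".":
        return CriteriaSet()
    return parse_criteria_string(
        text.replace("|", ",").replace("[", "(").replace("]", ")").replace("_", " ")
    )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read annotated records from a VCF; missing INFO keys leave the
    corresponding annotation empty (the record still classifies, as
    uncertain if nothing is known)."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for n, v in enumerate(vf.fetch() if vf.index else vf):
            info = dict(v.info)

            def sval(key: str) -> str:
                x = info.get(key, "")
                if isinstance(x, tuple):
                    x = x[0]
                return str(x) if x not in (None, ".") else ""

            gene = sval("GENE")
            if not gene:
                logger.warning("VCF record %d (%s:%s) lacks GENE annotation", n, v.chrom, v.pos)
            freqs = {
                k.lower(): float(info[k][0] if isinstance(info[k], tuple) else info[k])
                for k in info
                if k.startswith("AF_")
            }
            preds = {k.removeprefix("PRED_").lower(): sval(k) for k in info if k.startswith("PRED_")}
            splice = {
                k.removeprefix("SPLICE_").lower(): sval(k) for k in info if k.startswith("SPLICE_")
            }
            records.append(
                VariantRecord(
                    id=v.id or f"{v.chrom}:{v.pos}:{v.ref}>{','.join(v.alts or ['.'])}",
                    gene=gene or "NA",
                    transcript=sval("TRANSCRIPT"),
                    cdna=sval("CDNA"),
                    protein=sval("PROTEIN"),
                    consequence=sval("CONSEQ") or None,
                    zygosity=sval("ZYG") or "heterozygous",
                    freqs=PopulationFrequencies(freqs),
                    predictions=preds,
                    splice_predictions=splice,
                    conservation=sval("CONSERV") or "unknown",
                    manual=_criteria_from_info(sval("MANUAL")),
                    patient_count=int(sval("NPAT") or 1),
                    familial=sval("FAMILIAL") in ("1", "true"),
                    expansion_positive=sval("EXPANSION") in ("1", "true"),
                )
            )
    return records


def write_vcf(
    in_path: str | Path,
    out_path: str | Path,
    results: Sequence[ClassificationResult],
) -> None:
    """Copy a VCF, adding/overwriting ACMG_CLASS and ACMG_CRITERIA INFO
    fields (one result per input record, in order). Existing fields and
    records are preserved; re-annotating an annotated file overwrites the
    two fields instead of duplicating them."""
    with pysam.VariantFile(str(in_path)) as vin:
        header = vin.header.copy()
        for key, desc in (
            ("ACMG_CLASS", "Five-tier ACMG classification"),
            ("ACMG_CRITERIA", "Applied ACMG criteria with strengths, pipe-separated"),
        ):
            if key not in header.info:
                header.info.add(key, 1, "String", desc)
        with pysam.VariantFile(str(out_path), "w", header=header) as vout:
            for v, res in zip(vin, results):
                v.translate(header)
                v.info["ACMG_CLASS"] = CLASS_LABELS[res.klass]
                v.info["ACMG_CRITERIA"] = _criteria_to_info(res.evidence_used)
                vout.write(v)
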