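"""Truth-labelled synthetic variant sets for end-to-end stress testing.

The generator works backwards from a target five-tier class: it picks an
evidence combination valid for that class, then constructs the annotations
(consequence, population frequencies, catalog entries, predictor verdicts,
manual assignments) that make the auto-assigner produce exactly that
combination under the ALS policy. By construction the engine's
classification of every generated record equals its truth label, for any
seed — which is what the round-trip tests assert.

What this emulates: the *annotated* variant tables a curation pipeline
consumes. It does not simulate sequencing, transcript mapping or real
population-genetic frequency spectra; frequencies are drawn uniformly
inside the interval that realises the intended frequency criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotate import CatalogEntry, KnownVariantCatalog, VariantRecord
from .evidence import CriteriaSet, assignment
from .frequency import PopulationFrequencies
from .policy import GeneKB, PolicyConfig
from .rules import LABEL_TO_CLASS, VariantClass

_AA = "ACDEFGHIKLMNPQRSTVWY"
_POPS = ("af_exomes_all", "af_genomes_all", "af_exomes_nfe", "af_genomes_nfe")

# residue ranges are partitioned per gene so catalog entries planted for one
# template can never collide with records of another
_RANGES = {
    "p_ps1": ("SOD1", 5, 75),
    "lp_sod1": ("SOD1", 80, 150),
    "p_pp5vs": ("TARDBP", 280, 340),
    "lp_pm5": ("TARDBP", 350, 410),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Target composition of a synthetic variant set.

    ``counts`` maps class labels (P, LP, VUS, LB, B) to record counts.
    ``fraction_familial`` sets the chance a record's single familial flag
    is raised; ``fraction_strength_overrides`` the chance a
    pathogenic-class record realises its class through an escalated
    reputable-source assertion rather than native evidence.
    """

    counts: Mapping[str, int]
    seed: int = 0
    fraction_familial: float = 0.1
    fraction_strength_overrides: float = 0.4

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if label not in LABEL_TO_CLASS:
                raise ValueError(f"unknown class label {label!r} in synthetic spec")
            if n < 0:
                raise ValueError(f"negative count for class {label}")
        for name in ("fraction_familial", "fraction_strength_overrides"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticCohort:
    records: list[VariantRecord]
    truth: list[VariantClass]
    catalog: KnownVariantCatalog
    kb: GeneKB
    cfg: PolicyConfig


def _freqs(rng: np.random.Generator, low: float, high: float) -> PopulationFrequencies:
    # one population carries the popmax draw; the others sit below it
    vals = {p: 0.0 for p in _POPS}
    popmax = float(rng.uniform(low, high))
    pops = list(_POPS)
    vals[pops[int(rng.integers(len(pops)))]] = popmax
    for p in pops:
        if vals[p] == 0.0 and rng.random() < 0.5:
            vals[p] = float(rng.uniform(low * 0.1, popmax))
    return PopulationFrequencies(vals)


def _zero_freqs() -> PopulationFrequencies:
    return PopulationFrequencies({p: 0.0 for p in _POPS})


def _missense(rng: np.random.Generator, lo: int, hi: int) -> tuple[str, int, str, str]:
    pos = int(rng.integers(lo, hi + 1))
    ref, alt = rng.choice(list(_AA), size=2, replace=False)
    return f"p.{ref}{pos}{alt}", pos, str(ref), str(alt)


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Deterministically generate truth-labelled records for a spec."""
    from .fixtures import gene_kb_fixture

    rng = np.random.default_rng(spec.seed)
    cfg = PolicyConfig.preset("als")
    kb = gene_kb_fixture()
    bs1 = cfg.effective_bs1_threshold()
    records: list[VariantRecord] = []
    truth: list[VariantClass] = []
    entries: list[CatalogEntry] = []
    i = 0

    def base(gene: str, protein: str, **kw) -> VariantRecord:
        nonlocal i
        i += 1
        return VariantRecord(
            id=f"SYN{i:04d}",
            gene=gene,
            transcript="NM_000000",
            protein=protein,
            patient_count=int(rng.integers(1, 4)),
            familial=bool(rng.random() < spec.fraction_familial),
            **kw,
        )

    def make_p() -> VariantRecord:
        if rng.random() < spec.fraction_strength_overrides:
            gene, lo, hi = _RANGES["p_pp5vs"]
            protein, pos, ref, alt = _missense(rng, lo, hi)
            alt2 = next(a for a in _AA if a not in (ref, alt))
            entries.append(CatalogEntry(gene, f"{ref}{pos}{alt2}", established=True))
            entries.append(
                CatalogEntry(
                    gene, f"{ref}{pos}{alt}", established=False,
                    reports=int(rng.integers(cfg.pp5_very_strong_reports, 9)),
                )
            )
            # -> PM1, PM2, PM5, PP2, PP3, PP5(very strong): pathogenic
            return base(gene, protein, freqs=_zero_freqs(),
                        predictions={"sift": "damaging", "polyphen": "damaging"})
        if rng.random() < 0.5:
            gene = ["TBK1", "OPTN", "NEK1"][int(rng.integers(3))]
            pos = int(rng.integers(50, 500))
            ref = str(rng.choice(list(_AA)))
            # -> PVS1, PM2, PP3: pathogenic
            return base(gene, f"p.{ref}{pos}*", freqs=_zero_freqs(),
                        predictions={"sift": "damaging", "polyphen": "damaging"})
        gene, lo, hi = _RANGES["p_ps1"]
        protein, pos, ref, alt = _missense(rng, lo, hi)
        entries.append(CatalogEntry(gene, f"{ref}{pos}{alt}", established=True))
        # -> PS1, PM1, PM2, PP2, PP3: pathogenic
        return base(gene, protein, freqs=_zero_freqs(),
                    predictions={"sift": "damaging", "polyphen": "damaging"})

    def make_lp() -> VariantRecord:
        if rng.random() < 0.5:
            gene, lo, hi = _RANGES["lp_pm5"]
            protein, pos, ref, alt = _missense(rng, lo, hi)
            alt2 = next(a for a in _AA if a not in (ref, alt))
            entries.append(CatalogEntry(gene, f"{ref}{pos}{alt2}", established=True))
            # -> PM1, PM2, PM5, PP2: likely pathogenic
            return base(gene, protein, freqs=_zero_freqs(),
                        predictions={"sift": "unknown", "polyphen": "unknown"})
        gene, lo, hi = _RANGES["lp_sod1"]
        protein, pos, ref, alt = _missense(rng, lo, hi)
        # -> PM1, PM2, PP2, PP3: likely pathogenic
        return base(gene, protein, freqs=_zero_freqs(),
                    predictions={"sift": "damaging", "polyphen": "damaging"})

    def make_vus() -> VariantRecord:
        if rng.random() < 0.5:
            gene = "GLE1"  # PP2-excluded: a rare missense accrues nothing
            protein, *_ = _missense(rng, 20, 600)
            return base(gene, protein, freqs=_freqs(rng, 1e-6, bs1 * 0.5),
                        predictions={"sift": "damaging", "polyphen": "benign"})
        gene = "SQSTM1"  # PP2 + PP3 only: two supporting, no rule fires
        protein, *_ = _missense(rng, 20, 400)
        return base(gene, protein, freqs=_freqs(rng, 1e-6, bs1 * 0.5),
                    predictions={"sift": "damaging", "polyphen": "damaging"})

    def make_lb() -> VariantRecord:
        common = dict(freqs=_freqs(rng, bs1 * 2, 0.04))
        if rng.random() < 0.5:
            gene = "SETX"
            pos = int(rng.integers(20, 2000))
            ref = str(rng.choice(list(_AA)))
            # -> BS1, BP4, BP7: likely benign
            return base(gene, f"p.{ref}{pos}=", conservation="not_conserved",
                        splice_predictions={"ada": "benign", "rf": "benign"}, **common)
        gene = "EWSR1"  # PP2-excluded missense with BS1 + BP4
        protein, *_ = _missense(rng, 20, 600)
        return base(gene, protein,
                    predictions={"sift": "benign", "polyphen": "benign"}, **common)

    def make_b() -> VariantRecord:
        if rng.random() < 0.5:
            gene = "DAO"
            protein, *_ = _missense(rng, 20, 340)
            # -> BA1 (stand-alone): benign
            return base(gene, protein, freqs=_freqs(rng, 0.06, 0.4),
                        predictions={"sift": "damaging", "polyphen": "benign"})
        gene = "TAF15"  # BS1 + manual lack-of-segregation: two benign strong
        pos = int(rng.integers(20, 580))
        ref = str(rng.choice(list(_AA)))
        return base(gene, f"p.{ref}{pos}=", freqs=_freqs(rng, bs1 * 2, 0.04),
                    conservation="conserved",
                    manual=CriteriaSet([assignment("BS4", source="manual")]))

    makers = {
        VariantClass.PATHOGENIC: make_p,
        VariantClass.LIKELY_PATHOGENIC: make_lp,
        VariantClass.UNCERTAIN: make_vus,
        VariantClass.LIKELY_BENIGN: make_lb,
        VariantClass.BENIGN: make_b,
    }
    for label, n in spec.counts.items():
        klass = LABEL_TO_CLASS[label]
        for _ in range(n):
            records.append(makers[klass]())
            truth.append(klass)
    return SyntheticCohort(records, truth, KnownVariantCatalog(entries), kb, cfg)
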