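"""Maximum credible population allele frequency and frequency criteria.

A variant cannot credibly cause a monogenic disease if it is more common in
reference populations than the disease genetics allow. For a monoallelic
(dominant) architecture the maximum credible population allele frequency is

    maxAF = prevalence x heterogeneity x 1/2 / penetrance

where *prevalence* is the lifetime risk of disease, *heterogeneity* the
combined genetic x allelic contribution of the single most common causal
variant, and the factor 1/2 converts a carrier (genotype) frequency into an
allele frequency. For ALS the defaults are lifetime risk ~1/300, allelic
heterogeneity 0.05 (no gene explains more than ~5% of cases, repeat
expansions aside), and penetrance 0.8, giving ~1.0e-4 -- about 1 in 10,000
alleles. An alternative conservative heterogeneity of 0.1 (at least ten
pathogenic variants per gene) gives ~1/5,000 and ships as a named preset.

Frequency-based criteria derived from these thresholds: BA1 (stand-alone
benign) above 5%, BS1 (strong benign) above the maximum credible AF, PM2
(moderate pathogenic) for variants absent from all reference populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .evidence import EvidenceAssignment, assignment


@dataclass(frozen=True)
class AFThresholdParams:
    """Inputs to the maximum credible population AF.

    All fractions are dimensionless in (0, 1]; ``prevalence`` is lifetime
    risk (fraction of individuals), ``heterogeneity`` the genetic x allelic
    contribution of the most common credible variant, ``penetrance`` the
    probability a carrier develops disease. Only the monoallelic
    (heterozygous-dominant) mode is supported; recessive and oligogenic
    architectures need thresholds of their own.
    """

    prevalence: float = 1 / 300
    heterogeneity: float = 0.05
    penetrance: float = 0.8
    inheritance: str = "monoallelic"

    def __post_init__(self) -> None:
        if self.prevalence <= 0 or self.prevalence > 1:
            raise ValueError(f"prevalence must be in (0, 1], got {self.prevalence}")
        for name in ("heterogeneity", "penetrance"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


#: Named parameterisations of the ALS threshold.
PRESETS: dict[str, AFThresholdParams] = {
    "als-conservative": AFThresholdParams(heterogeneity=0.05),
    "als-lenient": AFThresholdParams(heterogeneity=0.1),
}


def max_credible_af(p: AFThresholdParams) -> float:
    """Maximum credible population allele frequency (monoallelic model)."""
    if p.inheritance != "monoallelic":
        raise ValueError(
            f"unsupported inheritance mode {p.inheritance!r}: only the "
            "monoallelic model is defined"
        )
    if p.penetrance <= 0:
        raise ValueError("penetrance must be > 0")
    return p.prevalence * p.heterogeneity * 0.5 / p.penetrance


@dataclass(frozen=True)
class PopulationFrequencies:
    """Per-population allele frequencies; None marks 'not observed'."""

    freqs: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, af in self.freqs.items():
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency for {pop} outside [0, 1]: {af}")

    @classmethod
    def from_dict(cls, d: Mapping[str, float | None]) -> "PopulationFrequencies":
        return cls(dict(d))

    def __bool__(self) -> bool:
        return bool(self.freqs)

    @property
    def popmax(self) -> float:
        """Maximum frequency over configured populations (0 if all absent)."""
        vals = [af for af in self.freqs.values() if af is not None]
        return max(vals) if vals else 0.0

    @property
    def absent_everywhere(self) -> bool:
        return all(af is None or af == 0.0 for af in self.freqs.values())


def assign_af_criteria(freqs: PopulationFrequencies, cfg) -> list[EvidenceAssignment]:
    """Emit at most one frequency criterion: BA1, BS1 or PM2.

    Popmax (the most conservative aggregation) is compared against the
    configured thresholds; PM2 requires absence from every configured
    population unless the policy's relaxed mode accepts frequencies below a
    tenth of the BS1 threshold.
    """
    if not freqs:
        raise ValueError("at least one population frequency is required")
    popmax = freqs.popmax
    bs1 = cfg.effective_bs1_threshold()
    if popmax > cfg.ba1_threshold:
        return [assignment("BA1", rationale=f"popmax {popmax:g} > {cfg.ba1_threshold:g}")]
    if bs1 is not None and popmax > bs1:
        return [
            assignment(
                "BS1", rationale=f"popmax {popmax:g} > maximum credible AF {bs1:g}"
            )
        ]
    if freqs.absent_everywhere:
        return [assignment("PM2", rationale="absent from all configured populations")]
    if cfg.pm2_relaxed and bs1 is not None and popmax < bs1 / 10:
        return [assignment("PM2", rationale=f"popmax {popmax:g} < maxAF/10")]
    return []


def maf_filter(freqs: PopulationFrequencies, cutoff: float) -> bool:
    """Inclusion filter: frequency below ``cutoff`` in every population."""
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    return all(af is None or af < cutoff for af in freqs.freqs.values())
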