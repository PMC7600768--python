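"""Gene knowledge base and ALS-specific criterion applicability policy.

ALS complicates generic ACMG usage in gene-specific ways: loss of function
is an established disease mechanism for only a handful of genes (so PVS1
is gated to a short list), nearly every major ALS gene tolerates so little
benign missense variation that PP2 applies by default (with a short
exclusion list), penetrance is age-dependent and incomplete (so BS2 is
unusable), repeat expansions are a common mechanism (so BP3 is unusable),
and mutational hotspots are protein domains known from the literature
rather than anything InterVar-style software detects reliably. This module
holds the per-gene knowledge base (inheritance, gnomAD constraint metrics)
and a :class:`PolicyConfig` that encodes those decisions, with two named
presets: ``als`` (the specialised policy) and ``baseline`` (generic
behaviour, useful for reclassification comparisons).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .evidence import get_code
from .frequency import AFThresholdParams, max_credible_af

#: Codes the ALS policy never applies (complete penetrance at an early age
#: is never expected; pathogenic missense is common; repeat regions are a
#: pathogenic mechanism, not a benign one).
ALS_DISABLED_CRITERIA = frozenset({"BS2", "BP1", "BP3"})

#: Genes for which loss of function is an accepted ALS mechanism. NEK1 is
#: included on the strength of the worked frameshift classification even
#: though narrative summaries sometimes omit it.
ALS_PVS1_GENES = frozenset({"ALS2", "SPG11", "TBK1", "OPTN", "NEK1"})

#: Genes whose missense variation is not depleted enough for PP2.
ALS_PP2_EXCLUDED = frozenset(
    {"ATXN2", "EPHA4", "CHRNA4", "EWSR1", "ARPP21", "C9orf72", "GLE1"}
)


@dataclass(frozen=True)
class GeneInfo:
    """One gene row of the knowledge base (inheritance + constraint metrics).

    ``pli`` is the gnomAD probability of loss-of-function intolerance;
    sources print very small values as "<0.01", kept here as the bound with
    ``pli_censored=True``. ``oe_mis_upper`` / ``oe_lof_upper`` are upper
    bounds of the 90% CI of the observed/expected missense and pLoF ratios
    (LOEUF); lower means more constrained.
    """

    symbol: str
    als_locus: str = ""
    chromosome: str = ""
    omim: str = ""
    inheritance: str = ""
    oe_mis_upper: float | None = None
    oe_lof_upper: float | None = None
    pli: float | None = None
    pli_censored: bool = False
    phenotypes: str = ""
    ref: str = ""

    def __post_init__(self) -> None:
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"{self.symbol}: pLI {self.pli} outside [0, 1]")
        for name in ("oe_mis_upper", "oe_lof_upper"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.symbol}: {name} must be > 0, got {v}")

    @property
    def modes(self) -> frozenset[str]:
        """Inheritance modes, major and parenthetical-minor alike."""
        raw = self.inheritance.replace("(", "").replace(")", "")
        return frozenset(m.strip() for m in raw.split(",") if m.strip())

    @property
    def minor_modes(self) -> frozenset[str]:
        return frozenset(
            tok.strip("()")
            for tok in (t.strip() for t in self.inheritance.split(","))
            if tok.startswith("(") and tok.endswith(")")
        )

    @property
    def recessive(self) -> bool:
        return "AR" in self.modes


class GeneKB(Mapping[str, GeneInfo]):
    """Symbol-keyed collection of :class:`GeneInfo` rows."""

    def __init__(self, genes: Iterable[GeneInfo]) -> None:
        self._genes: dict[str, GeneInfo] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise ValueError(f"duplicate gene symbol in knowledge base: {g.symbol}")
            self._genes[g.symbol] = g

    def __getitem__(self, symbol: str) -> GeneInfo:
        return self._genes[symbol]

    def __iter__(self):
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def require(self, symbol: str) -> GeneInfo:
        if symbol not in self._genes:
            raise KeyError(f"gene {symbol!r} not present in the knowledge base")
        return self._genes[symbol]

    def recessive_genes(self) -> frozenset[str]:
        return frozenset(s for s, g in self._genes.items() if g.recessive)


_KB_COLUMNS = [
    "gene",
    "als_locus",
    "chromosome",
    "omim",
    "inheritance",
    "oe_mis_upper",
    "oe_lof_upper",
    "pli",
    "phenotypes",
    "ref",
]


def _parse_pli(text: str) -> tuple[float | None, bool]:
    text = text.strip()
    if not text or text == ".":
        return None, False
    if text.startswith("<"):
        return float(text[1:]), True
    return float(text), False


def load_gene_kb(path: str | Path) -> GeneKB:
    """Read a gene knowledge base from TSV (or a JSON list of row objects).

    Mandatory columns: ``gene``, ``inheritance``, ``oe_mis_upper``,
    ``oe_lof_upper``, ``pli``; '.' marks missing values. Schema violations
    name the offending field; duplicate symbols are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise ValueError("gene KB JSON must be a list of row objects")
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) == 0:
        return GeneKB([])
    for col in ("gene", "inheritance", "oe_mis_upper", "oe_lof_upper", "pli"):
        if col not in df.columns:
            raise ValueError(f"gene KB is missing mandatory column {col!r}")
    genes = []
    for _, row in df.iterrows():
        def cell(col: str) -> str:
            v = str(row.get(col, "")).strip()
            return "" if v in (".", "nan") else v

        try:
            pli, censored = _parse_pli(cell("pli"))
            genes.append(
                GeneInfo(
                    symbol=cell("gene"),
                    als_locus=cell("als_locus"),
                    chromosome=cell("chromosome"),
                    omim=cell("omim"),
                    inheritance=cell("inheritance"),
                    oe_mis_upper=float(cell("oe_mis_upper")) if cell("oe_mis_upper") else None,
                    oe_lof_upper=float(cell("oe_lof_upper")) if cell("oe_lof_upper") else None,
                    pli=pli,
                    pli_censored=censored,
                    phenotypes=cell("phenotypes"),
                    ref=cell("ref"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"gene KB row {row.get('gene', '?')!r}: {exc}") from exc
    return GeneKB(genes)


@dataclass(frozen=True)
class Hotspot:
    """A mutational-hotspot scope: a protein residue interval or an
    exon-scoped splice region."""

    kind: str  # "residues" | "splice_exon"
    start: int | None = None
    end: int | None = None
    exon: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "residues":
            if not (self.start and self.end and 1 <= self.start <= self.end):
                raise ValueError(f"invalid residue hotspot interval: {self}")
        elif self.kind == "splice_exon":
            if not self.exon or self.exon < 1:
                raise ValueError(f"invalid splice hotspot exon: {self}")
        else:
            raise ValueError(f"unknown hotspot kind {self.kind!r}")


def default_hotspots() -> dict[str, tuple[Hotspot, ...]]:
    """Curation defaults: literature-named domains mapped to coordinates.

    The source literature names domains, not residue ranges; the interval
    bounds below are curation choices and fully configurable.
    """
    return {
        "TARDBP": (Hotspot("residues", 274, 414, label="C-terminal glycine-rich domain"),),
        "FUS": (
            Hotspot("residues", 156, 267, label="glycine-rich domain"),
            Hotspot("residues", 500, 526, label="C-terminal nuclear localization signal"),
        ),
        "SOD1": (Hotspot("residues", 1, 153, label="whole protein (curation: hotspot-dense)"),),
        "VCP": (Hotspot("residues", 1, 208, label="N-terminal CDC48 domain"),),
        "KIF5A": (Hotspot("splice_exon", exon=27, label="exon 27 splice region"),),
    }


@dataclass
class PolicyConfig:
    """All tunable knobs of the classification policy."""

    name: str = "als"
    pvs1_genes: frozenset[str] | None = field(default_factory=lambda: ALS_PVS1_GENES)
    pp2_enabled: bool = True
    pp2_excluded_genes: frozenset[str] = field(default_factory=lambda: ALS_PP2_EXCLUDED)
    disabled_criteria: frozenset[str] = field(default_factory=lambda: ALS_DISABLED_CRITERIA)
    hotspots: dict[str, tuple[Hotspot, ...]] = field(default_factory=default_hotspots)
    recessive_genes: frozenset[str] | None = None  # None -> derive from KB (AR modes)
    af_params: AFThresholdParams = field(default_factory=AFThresholdParams)
    ba1_threshold: float = 0.05
    bs1_threshold: float | None = None  # None -> max credible AF from af_params
    bs1_enabled: bool = True
    pm2_relaxed: bool = False  # accept AF below bs1/10 as "effectively absent"
    pp3_min_damaging: int = 2
    bp4_min_benign: int = 2
    pp5_strong_reports: int = 3
    pp5_very_strong_reports: int = 5
    allow_benign_very_strong: bool = False
    ba1_overrides_conflict: bool = False
    pathogenic_expansion_genes: frozenset[str] = field(default_factory=lambda: frozenset({"C9orf72"}))

    def effective_bs1_threshold(self) -> float | None:
        if not self.bs1_enabled:
            return None
        if self.bs1_threshold is not None:
            return self.bs1_threshold
        return max_credible_af(self.af_params)

    def is_recessive(self, gene: str, kb: GeneKB | None = None) -> bool:
        if self.recessive_genes is not None:
            return gene in self.recessive_genes
        if kb is not None and gene in kb:
            return kb[gene].recessive
        return False

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["pvs1_genes"] = sorted(self.pvs1_genes) if self.pvs1_genes is not None else None
        d["pp2_excluded_genes"] = sorted(self.pp2_excluded_genes)
        d["disabled_criteria"] = sorted(self.disabled_criteria)
        d["recessive_genes"] = (
            sorted(self.recessive_genes) if self.recessive_genes is not None else None
        )
        d["pathogenic_expansion_genes"] = sorted(self.pathogenic_expansion_genes)
        d["hotspots"] = {
            g: [dataclasses.asdict(h) for h in hs] for g, hs in self.hotspots.items()
        }
        d["af_params"] = dataclasses.asdict(self.af_params)
        return d

    @classmethod
    def from_json(cls, d: Mapping) -> "PolicyConfig":
        kwargs = dict(d)
        for key in ("pvs1_genes", "recessive_genes"):
            if kwargs.get(key) is not None:
                kwargs[key] = frozenset(kwargs[key])
        for key in ("pp2_excluded_genes", "disabled_criteria", "pathogenic_expansion_genes"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        if "hotspots" in kwargs:
            kwargs["hotspots"] = {
                g: tuple(Hotspot(**h) for h in hs) for g, hs in kwargs["hotspots"].items()
            }
        if "af_params" in kwargs and not isinstance(kwargs["af_params"], AFThresholdParams):
            kwargs["af_params"] = AFThresholdParams(**kwargs["af_params"])
        return cls(**kwargs)

    @classmethod
    def preset(cls, name: str) -> "PolicyConfig":
        if name == "als":
            return cls(name="als")
        if name == "baseline":
            # Generic behaviour: PVS1 for any gene, no ALS criterion gating,
            # no curated hotspots, no maxAF-derived BS1.
            return cls(
                name="baseline",
                pvs1_genes=None,
                pp2_enabled=False,
                pp2_excluded_genes=frozenset(),
                disabled_criteria=frozenset(),
                hotspots={},
                bs1_enabled=False,
            )
        raise ValueError(f"unknown policy preset {name!r} (expected 'als' or 'baseline')")


def load_policy(path_or_name: str | Path) -> PolicyConfig:
    """Load a preset by name ('als'/'baseline') or a PolicyConfig JSON file."""
    if str(path_or_name) in ("als", "baseline"):
        return PolicyConfig.preset(str(path_or_name))
    return PolicyConfig.from_json(json.loads(Path(path_or_name).read_text()))


# -- applicability predicates ---------------------------------------------

def pvs1_applicable(gene: str, cfg: PolicyConfig, kb: GeneKB | None = None) -> bool:
    """Loss-of-function gating: is PVS1 usable for this gene?"""
    if kb is not None:
        kb.require(gene)
    return cfg.pvs1_genes is None or gene in cfg.pvs1_genes


def pp2_applicable(gene: str, cfg: PolicyConfig, kb: GeneKB | None = None) -> bool:
    """Missense-constraint gating: is PP2 usable for this gene?"""
    if kb is not None:
        kb.require(gene)
    return cfg.pp2_enabled and gene not in cfg.pp2_excluded_genes


def in_hotspot(
    gene: str,
    protein_position: int | None,
    consequence: str,
    cfg: PolicyConfig,
    *,
    exon: int | None = None,
) -> bool:
    """True iff the position (or exon, for splice hotspots) falls inside a
    configured hotspot for the gene. Genes without entries simply return
    False."""
    if protein_position is not None and protein_position < 1:
        raise ValueError("protein_position must be >= 1")
    for h in cfg.hotspots.get(gene, ()):
        if h.kind == "residues":
            if (
                consequence in ("missense", "inframe_indel")
                and protein_position is not None
                and h.start <= protein_position <= h.end
            ):
                return True
        elif h.kind == "splice_exon":
            if consequence == "canonical_splice" and exon is not None and exon == h.exon:
                return True
    return False


def criterion_enabled(code: str, cfg: PolicyConfig) -> bool:
    """False for criteria the policy disables (BS2/BP1/BP3 under ``als``)."""
    return get_code(code).code not in cfg.disabled_criteria
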