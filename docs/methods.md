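# Methods

## The classification model

`alsvarclass` implements the five-tier ACMG/AMP variant-interpretation
framework as a deterministic rule engine, specialised for amyotrophic
lateral sclerosis (ALS) gene-panel data.

The framework's 28 evidence criteria (16 pathogenic-direction: PVS1,
PS1–4, PM1–6, PP1–5; 12 benign-direction: BA1, BS1–4, BP1–7) each carry a
default strength encoded in the code name, but a curator may apply a
criterion at a different strength — reputable-source assertions (PP5/BP6)
in particular scale with the number of concordant independent reports.
The engine models strength escalation as **bucket re-assignment**: an
escalated criterion counts exactly as a native criterion of its applied
bucket, and classification depends only on the per-direction histogram of
applied strengths, never on which codes produced it. This is the only
reading under which published worked classifications such as
"PM1, PP2, PP5 (very strong) → pathogenic" are reproducible, and it is
enforced by a property test (permuting strengths across codes preserves
the class).

The combining rules are the published 2015 combinations, evaluated
pathogenic-tier first (P.1–P.3, then LP.1–LP.6) and benign-tier in
parallel (B.1–B.2, LB.1–LB.2); the full list is in the `rules` module
docstring. Two deliberate dialect choices:

* **Two or more very-strong criteria** are not covered by the published
  table (it never combines two very-strong items). We count a second
  very-strong criterion as satisfying the "very strong + strong" arm,
  so ≥2 very strong → pathogenic. The brute-force oracle in the test
  suite transcribes the same choice, stated once in each place.
* **Conflict policy**: when combinations fire in both directions the
  result is uncertain significance with `conflict=True`. A configuration
  flag (`ba1_overrides_conflict`, default off) lets BA1 force benign,
  matching common practice; the default is the conservative reading.

Benign-direction criteria cannot carry very-strong weight unless
explicitly allowed (`allow_benign_very_strong`); the symmetric escalation
of BP6 is plausible but undemonstrated in practice, so it is opt-in.

## The ALS policy

The `als` preset encodes gene-specific applicability:

* **PVS1** only for genes where loss of function is an accepted ALS
  mechanism: ALS2, SPG11, TBK1, OPTN, and NEK1. NEK1 is included because
  worked classifications apply PVS1 to a NEK1 frameshift even where
  summary tables omit it. SOD1 is deliberately excluded (ALS-associated
  SOD1 variation is almost entirely missense with a toxic
  gain-of-function; a homozygous SOD1 null causes a different syndrome).
* **PP2** by default for all panel missense variants except in ATXN2,
  EPHA4, CHRNA4, EWSR1, ARPP21, C9orf72 and GLE1. A constraint-metric
  threshold that would derive this list automatically is not
  operationalised (none is defined in the literature); the knowledge base
  ships the gnomAD metrics so users can curate their own.
* **PM1 hotspots** are shipped as configurable curation entries, because
  the literature names domains, not coordinates: TARDBP 274–414
  (C-terminal glycine-rich domain), FUS 156–267 (glycine-rich) and
  500–526 (C-terminal NLS), VCP 1–208 (N-domain), KIF5A exon-27 splice
  scope, and SOD1 1–153 (whole protein — SOD1 harbours more reported
  variants than residues, and every worked SOD1 example carries PM1).
  Residue hotspots apply to protein-altering point changes (missense,
  in-frame indels); splice hotspots match on exon scope.
* **Disabled criteria**: BS2 (ALS penetrance is never complete at an
  early age), BP1 (pathogenic missense is common in ALS genes), BP3
  (repeat expansions are a pathogenic mechanism, so repetitive-region
  indels cannot default to benign). Disabled codes are dropped from both
  automatic and manual evidence, with a logged notice.
* **PM3/BP2** (phase-dependent criteria) are honoured only for genes
  whose knowledge-base inheritance includes AR, and only as manual
  evidence — phase cannot be derived from a single-variant record.
* **Repeat expansions** enter as pre-annotated flags; a positive
  expansion in a policy-listed gene (default: C9orf72) classifies
  pathogenic directly, anything else stays uncertain.

The `baseline` preset (generic behaviour: PVS1 for any gene, no PP2, no
curated hotspots, no maxAF-based BS1, nothing disabled) exists to support
reclassification comparisons (`policy_diff`), mirroring the comparison
between an InterVar-style default run and the specialised policy.

## Frequency thresholds

For a monoallelic architecture the maximum credible population allele
frequency is

    maxAF = prevalence × heterogeneity × ½ / penetrance

with ALS defaults: lifetime risk 1/300, combined genetic×allelic
heterogeneity 0.05, penetrance 0.8, giving 1.042×10⁻⁴ ≈ 1/10,000 alleles.
The heterogeneity default of 0.05 (no single gene explains more than ~5%
of cases, the C9orf72 expansion aside) is the value that reproduces the
1/10,000 figure; the alternative reading of 0.1 (at least ten pathogenic
variants per gene) ships as the `als-lenient` preset (~1/5,000). Only the
monoallelic model is supported: recessive and oligogenic architectures
need thresholds of their own, and the calculator refuses them rather than
guessing.

Criteria ladder (at most one emitted per variant): BA1 above 5% popmax,
BS1 above the maxAF threshold, PM2 when absent from every configured
population. Popmax — the maximum over configured populations — is the
conservative aggregation and the default. PM2 optionally relaxes to
"below maxAF/10" (`pm2_relaxed`, off by default). Allele-count-aware
confidence intervals (filtering AF) are not implemented; raw frequencies
only.

## Automatic assignment

Consequence typing is a lenient single-variant HGVS parser
(canonical-transcript, 1-based residues, three- and one-letter amino-acid
codes normalised to one-letter); canonical splice status is decided from
±1/±2 intronic offsets in the cDNA description; unparseable text types as
`other` with a warning, never an exception.

Catalog semantics: entries distinguish *established* changes (evidence
evaluable — these anchor PS1 for the identical change and PM5 for a
different change at the same residue) from *reported* assertions (PP5/BP6,
escalating supporting → strong at ≥3 concordant reports → very strong at
≥5; all thresholds configurable). PS1 and PM5 are mutually exclusive on
one variant — when both could apply, PS1 wins. Published worked examples
occasionally print both on one row; the engine reproduces their class
regardless, because PS1 dominates PM5 in every firing combination.

In-silico consensus (no published rule exists, so the default is
deliberate): PP3 requires ≥2 damaging verdicts and zero benign across the
missense and splice predictors; BP4 requires the mirror image. BP7
additionally requires a synonymous change, no damaging splice verdict and
a not-conserved site.

## Synthetic data

The generator works backwards from a target class: it selects an evidence
combination valid for that class, then constructs annotations
(consequence, frequencies, catalog entries, predictor verdicts, manual
assignments) that force the auto-assigner to produce exactly that
combination under the ALS policy. Gene/residue ranges are partitioned per
template so planted catalog entries cannot collide across records, and the
templates are closed under the benign (engine-visible) collisions that
remain: a record that accidentally matches another record's planted entry
shifts between PS1 and PM5 but never changes tier. It emulates annotated
curation tables, not sequencing: no read-level error model, no transcript
mapping, and frequencies drawn uniformly inside the interval realising
the intended criterion rather than from a realistic site-frequency
spectrum. Passing round-trip tests therefore demonstrate the internal
consistency of assignment + combination, not performance on real cohort
noise. Determinism is by construction (single `numpy` generator seeded
from the spec).

## Cohort reporting

Diagnostic yield = (expansion carriers + P/LP sequence-variant carriers) /
sub-cohort total, as a percentage rounded half-up to one decimal. A
record's familial flag marks one familial patient among its carriers; the
remainder count as sporadic. With the packaged worked examples and the
published familial sub-cohort inputs (42 familial cases, 19 familial
expansion carriers) this reproduces the published familial yield of 66.7%
(28/42). The published sporadic yield is *not* reconstructible from the
printed per-variant tables (the printed sporadic expansion and P/LP
carrier counts sum to 40, while the published figure is 38/456); the
report computes from its inputs and makes no attempt to force the printed
number. Likewise the source cohort's full 280-variant list is not
published, so its reclassification counts (26 or 28 VUS→LB/B — the two
printed figures disagree — and 8 VUS→LP) are covered by property tests on
planted synthetic records, not reproduced exactly.

## Numerical and scale choices

* Criteria-set enumeration for the oracle-equivalence check covers all
  sets of up to 4 assignments with pathogenic codes offered additionally
  at strong/very strong (~316k sets, a few seconds); the brute-force
  oracle is an independent literal transcription of the rule list.
* The synthetic round-trip check uses 180 records × 3 seeds (540 total)
  spanning all five classes.
* Knowledge-base pLI values printed "<0.01" are stored as the bound with
  a censored flag; the verbatim text stays in the fixture.
* Packaged fixture integrity is pinned by SHA-256 in the test suite.

## Known limitations

* Single-variant, canonical-transcript reasoning only: no phase, no
  transcript mapping, no liftover, no multi-variant (oligogenic)
  genotypes — the engine classifies variants, not patients.
* The known-variant catalog is a synthetic stand-in covering the packaged
  worked examples; production use requires exporting real ClinVar/ALSoD
  assertions into the same JSON schema.
* PM1(strong)-style expert escalations are manual evidence; hotspot
  membership alone yields the default moderate weight.
* Frequency handling ignores allele counts, so a singleton in a tiny
  reference population weighs as much as a well-sampled frequency.
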