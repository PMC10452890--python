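"""Small-variant (SNP/indel) prioritization cascade.

Stages, in order, over VQSR-passed annotated records:

1. rarity — both panel frequencies (1000 Genomes ALL, non-TCGA ExAC ALL)
   strictly below ``af_max``; a missing frequency passes (novel = rare);
2. deleteriousness — CADD scaled score strictly above ``cadd_min``;
   missing CADD fails (no evidence);
3. region stratification — coding (exonic) vs noncoding (everything else);
4. predictor consensus — at least ``predictor_quorum`` of the four
   predictors call the variant deleterious; missing calls count against
   the quorum. Applied to both tracks;
5. RegulomeDB — applied downstream of sharing classification, to
   group-exclusive noncoding variants only: rank strictly below
   ``regulomedb_max``; missing rank fails.

All inequalities are strict, as the thresholds are stated with strict
operators; boundary values fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variants import DELETERIOUS, SmallVariantRecord

NONCODING_REGION_ROWS = (
    ("intergenic", "Intergenic"),
    ("intronic", "Intronic"),
    ("ncRNA_intronic", "ncRNA_intronic"),
    ("UTR3", "3'UTR"),
    ("upstream", "Upstream and Downstream"),
    ("downstream", "Upstream and Downstream"),
    ("UTR5", "5'UTR"),
    ("ncRNA_exonic", "ncRNA_exonic"),
)
# display order of Table-style region rows
REGION_ROW_ORDER = (
    "Intergenic", "Intronic", "ncRNA_intronic", "3'UTR",
    "Upstream and Downstream", "5'UTR", "ncRNA_exonic",
)


@dataclass(frozen=True)
class SmallVariantThresholds:
    af_max: float = 0.01
    cadd_min: float = 10.0
    predictor_quorum: int = 3
    regulomedb_max: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.af_max <= 1:
            raise ValueError("af_max must lie in (0, 1]")
        if not 1 <= self.predictor_quorum <= 4:
            raise ValueError("predictor_quorum must lie in 1..4")


@dataclass
class CascadeTrace:
    """Per-stage surviving counts; non-increasing along the cascade."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def record(self, stage: str, survivors: int) -> None:
        if self.stages and survivors > self.stages[-1][1]:
            raise AssertionError(
                f"cascade not monotone: {stage} has {survivors} survivors "
                f"after {self.stages[-1]}"
            )
        self.stages.append((stage, survivors))

    def as_rows(self) -> list[tuple[str, int]]:
        return list(self.stages)


def passes_af(rec: SmallVariantRecord, thresholds: SmallVariantThresholds) -> bool:
    ok_1000g = rec.af_1000g is None or rec.af_1000g < thresholds.af_max
    ok_exac = rec.af_exac_nontcga is None or rec.af_exac_nontcga < thresholds.af_max
    return ok_1000g and ok_exac


def passes_cadd(rec: SmallVariantRecord, thresholds: SmallVariantThresholds) -> bool:
    return rec.cadd_phred is not None and rec.cadd_phred > thresholds.cadd_min


def passes_consensus(rec: SmallVariantRecord, thresholds: SmallVariantThresholds) -> bool:
    return rec.deleterious_votes() >= thresholds.predictor_quorum


def passes_regulome(rec: SmallVariantRecord, thresholds: SmallVariantThresholds) -> bool:
    return rec.regulomedb is not None and rec.regulomedb < thresholds.regulomedb_max


def filter_af(records, thresholds=SmallVariantThresholds(), trace: CascadeTrace | None = None):
    kept = [r for r in records if passes_af(r, thresholds)]
    if trace is not None:
        trace.record("af", len(kept))
    return kept


def filter_cadd(records, thresholds=SmallVariantThresholds(), trace: CascadeTrace | None = None):
    kept = [r for r in records if passes_cadd(r, thresholds)]
    if trace is not None:
        trace.record("cadd", len(kept))
    return kept


def stratify_region(records):
    """Split into (coding, noncoding); coding is exactly the exonic class."""
    coding = [r for r in records if r.region == "exonic"]
    noncoding = [r for r in records if r.region != "exonic"]
    return coding, noncoding


def filter_deleterious_consensus(records, thresholds=SmallVariantThresholds(),
                                 trace: CascadeTrace | None = None):
    kept = [r for r in records if passes_consensus(r, thresholds)]
    if trace is not None:
        trace.record("consensus", len(kept))
    return kept


def filter_regulome(records, thresholds=SmallVariantThresholds()):
    """RegulomeDB gate for group-exclusive noncoding records."""
    return [r for r in records if passes_regulome(r, thresholds)]


def first_failing_stage(rec: SmallVariantRecord,
                        thresholds: SmallVariantThresholds = SmallVariantThresholds()) -> str:
    """Name of the first cascade stage the record fails, or ``survivor``.

    The RegulomeDB gate is excluded: it applies only post-sharing to
    exclusive noncoding records, not to the main cascade.
    """
    if not passes_af(rec, thresholds):
        return "af"
    if not passes_cadd(rec, thresholds):
        return "cadd"
    if not passes_consensus(rec, thresholds):
        return "consensus"
    return "survivor"


@dataclass
class SmallVariantCascadeResult:
    coding: list[SmallVariantRecord]
    noncoding: list[SmallVariantRecord]
    trace: CascadeTrace
    coding_pre_consensus: int = 0
    noncoding_pre_consensus: int = 0


def run_cascade(records, thresholds: SmallVariantThresholds = SmallVariantThresholds()
                ) -> SmallVariantCascadeResult:
    """Run stages 1-4; the RegulomeDB gate is applied after sharing."""
    trace = CascadeTrace()
    trace.record("input", len(records))
    after_af = filter_af(records, thresholds, trace)
    after_cadd = filter_cadd(after_af, thresholds, trace)
    coding, noncoding = stratify_region(after_cadd)
    coding_kept = filter_deleterious_consensus(coding, thresholds)
    noncoding_kept = filter_deleterious_consensus(noncoding, thresholds)
    trace.record("consensus", len(coding_kept) + len(noncoding_kept))
    return SmallVariantCascadeResult(
        coding=coding_kept,
        noncoding=noncoding_kept,
        trace=trace,
        coding_pre_consensus=len(coding),
        noncoding_pre_consensus=len(noncoding),
    )


def tabulate_regions(noncoding_records, sharing_by_id) -> dict[str, dict[str, int]]:
    """Region x sharing cross-tabulation of noncoding records.

    ``sharing_by_id`` maps variant_id to a set of sharing-class labels as
    produced by :func:`riskcluster.sharing.classify_sharing`. Two columns
    are tabulated: variants shared by all subjects, and variants shared by
    all members of at least one group without being shared by everyone.
    """
    region_to_row = dict(NONCODING_REGION_ROWS)
    table = {row: {"all_subjects": 0, "within_group": 0} for row in REGION_ROW_ORDER}
    for rec in noncoding_records:
        row = region_to_row.get(rec.region)
        if row is None:  # exonic records do not belong here
            continue
        kinds = sharing_by_id.get(rec.variant_id, set())
        if any(k.kind == "shared_all_samples" for k in kinds):
            table[row]["all_subjects"] += 1
        elif any(k.kind == "shared_within_group" for k in kinds):
            table[row]["within_group"] += 1
    return table
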