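"""Structural-variant prioritization cascade.

Stages, in order, over called SVs (DEL/DUP/INV/BND):

1. depth gate — DEL and DUP must carry a positive duphold depth-validation
   flag; BND and INV are exempt (the gate is not applicable to them);
2. rarity — both panel frequencies (1000 Genomes ALL, gnomAD) strictly
   below ``af_max``; missing passes (novel = rare);
3. functional ranking — AnnotSV ranking strictly above ``ranking_min``
   (default 3, so only classes 4-5, (likely) pathogenic, survive);
   missing fails;
4. length — DEL/DUP/INV must span at least ``min_length`` bp (inclusive);
   BND has no defined length and is exempt.

Breakends are counted per record throughout; mates are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variants import SVRecord, SV_TYPES

SV_LOCATION_ROWS = ("Intronic", "Exonic", "txStart-txEnd", "NA")
_LOCATION_TO_ROW = {
    "intronic": "Intronic",
    "exonic": "Exonic",
    "txStart-txEnd": "txStart-txEnd",
    "NA": "NA",
}


@dataclass(frozen=True)
class SVThresholds:
    af_max: float = 0.01
    ranking_min: int = 3  # strictly-greater gate
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be non-negative")
        if not 0 <= self.ranking_min <= 5:
            raise ValueError("ranking_min must lie in 0..5")


@dataclass
class SVCascadeTrace:
    """Per-stage surviving counts split by SV type."""

    stages: list[tuple[str, dict[str, int]]] = field(default_factory=list)

    def record(self, stage: str, records) -> None:
        counts = {t: 0 for t in SV_TYPES}
        for r in records:
            counts[r.svtype] += 1
        if self.stages:
            prev = self.stages[-1][1]
            for t in SV_TYPES:
                if counts[t] > prev[t]:
                    raise AssertionError(
                        f"cascade not monotone for {t} at stage {stage}"
                    )
        self.stages.append((stage, counts))


def passes_depth(rec: SVRecord) -> bool:
    if rec.svtype in ("DEL", "DUP"):
        return rec.depth_validated is True
    return True  # gate not applicable to BND/INV


def passes_sv_af(rec: SVRecord, thresholds: SVThresholds) -> bool:
    ok_1000g = rec.af_1000g is None or rec.af_1000g < thresholds.af_max
    ok_gnomad = rec.af_gnomad is None or rec.af_gnomad < thresholds.af_max
    return ok_1000g and ok_gnomad


def passes_ranking(rec: SVRecord, thresholds: SVThresholds) -> bool:
    return rec.annotsv_ranking is not None and rec.annotsv_ranking > thresholds.ranking_min


def passes_length(rec: SVRecord, thresholds: SVThresholds) -> bool:
    if rec.svtype == "BND":
        return True  # no defined length
    return rec.length >= thresholds.min_length


def gate_depth(records, trace: SVCascadeTrace | None = None):
    kept = [r for r in records if passes_depth(r)]
    if trace is not None:
        trace.record("depth", kept)
    return kept


def filter_sv_af(records, thresholds=SVThresholds(), trace: SVCascadeTrace | None = None):
    kept = [r for r in records if passes_sv_af(r, thresholds)]
    if trace is not None:
        trace.record("af", kept)
    return kept


def filter_ranking(records, thresholds=SVThresholds(), trace: SVCascadeTrace | None = None):
    kept = [r for r in records if passes_ranking(r, thresholds)]
    if trace is not None:
        trace.record("ranking", kept)
    return kept


def filter_length(records, thresholds=SVThresholds(), trace: SVCascadeTrace | None = None):
    kept = [r for r in records if passes_length(r, thresholds)]
    if trace is not None:
        trace.record("length", kept)
    return kept


def first_failing_stage(rec: SVRecord, thresholds: SVThresholds = SVThresholds()) -> str:
    """First cascade stage the record fails, or ``survivor``."""
    if not passes_depth(rec):
        return "depth"
    if not passes_sv_af(rec, thresholds):
        return "af"
    if not passes_ranking(rec, thresholds):
        return "ranking"
    if not passes_length(rec, thresholds):
        return "length"
    return "survivor"


@dataclass
class SVCascadeResult:
    survivors: list[SVRecord]
    trace: SVCascadeTrace


def run_cascade(records, thresholds: SVThresholds = SVThresholds()) -> SVCascadeResult:
    trace = SVCascadeTrace()
    trace.record("input", records)
    out = gate_depth(records, trace)
    out = filter_sv_af(out, thresholds, trace)
    out = filter_ranking(out, thresholds, trace)
    out = filter_length(out, thresholds, trace)
    return SVCascadeResult(survivors=out, trace=trace)


def tabulate_sv_locations(records, sharing_by_id) -> dict[str, dict[str, int]]:
    """Location x SV-type cross-tabulation of within-group shared records.

    Restricted to records classified shared-within-group that are not
    shared by all subjects, mirroring the familial location breakdown.
    """
    table = {row: {t: 0 for t in SV_TYPES} for row in SV_LOCATION_ROWS}
    for rec in records:
        kinds = sharing_by_id.get(rec.sv_id, set())
        if any(k.kind == "shared_all_samples" for k in kinds):
            continue
        if not any(k.kind == "shared_within_group" for k in kinds):
            continue
        row = _LOCATION_TO_ROW.get(rec.location, "NA")
        table[row][rec.svtype] += 1
    return table
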