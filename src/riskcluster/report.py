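"""End-to-end orchestration and rendering of the summary tables.

``run_pipeline`` drives the full analysis over a cohort (pedigree, two
annotated VCFs, knowledgebase): risk-group assignment, both prioritization
cascades, sharing classification, the RegulomeDB gate on group-exclusive
noncoding variants, the region/location cross-tabulations, cancer
annotation and the per-group cancer-gene summary. Results are bundled
with a manifest that fully determines a reproducible re-run.

Percentage cells are truncated (not rounded) to two decimals, matching
the arithmetic of the published cascade summaries; a zero denominator
renders NA.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .knowledgebase import annotate_cancer, load_knowledgebase, summarize_cancer_genes
from .pedigree import RISK_GROUPS, groups_map, read_pedigree, sequenced_order
from .sharing import classify_records, count_by_class, write_sharing_tsv
from .small_variants import (
    SmallVariantThresholds,
    filter_regulome,
    run_cascade as run_small_cascade,
    tabulate_regions,
    REGION_ROW_ORDER,
)
from .svs import SVThresholds, run_cascade as run_sv_cascade, tabulate_sv_locations, SV_LOCATION_ROWS
from .variants import SV_TYPES, AnnotationKeys, read_small_variants, read_svs


def render_percentage(numerator: int, denominator: int) -> str:
    """Percentage truncated to two decimals; NA on a zero denominator."""
    if denominator == 0:
        return "NA"
    value = 10000 * numerator // denominator  # floor at 2 decimals
    return f"{value / 100:.2f}"


@dataclass
class RunManifest:
    inputs: dict[str, str]
    config_hash: str
    seed: int | None
    stage_counts: dict[str, int | dict]
    version: str = __version__
    timestamp: str = ""

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class ReportBundle:
    small_trace: list[tuple[str, int]]
    sv_trace: list[tuple[str, dict[str, int]]]
    small_counts: object  # SharingCounts for surviving coding variants
    noncoding_counts: object
    sv_counts: object
    region_table: dict
    sv_location_table: dict
    regulome_survivors: list
    exclusive_noncoding: list
    cancer_summary: dict
    small_table_rows: list[dict]
    sv_table_rows: list[dict]
    manifest: RunManifest


def _config_hash(*objs) -> str:
    blob = json.dumps([getattr(o, "__dict__", str(o)) for o in objs],
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    ped_path: str | Path,
    small_vcf: str | Path,
    sv_vcf: str | Path,
    kb_path: str | Path,
    small_thresholds: SmallVariantThresholds = SmallVariantThresholds(),
    sv_thresholds: SVThresholds = SVThresholds(),
    keys: AnnotationKeys = AnnotationKeys(),
    seed: int | None = None,
) -> ReportBundle:
    ped = read_pedigree(ped_path)
    order = sequenced_order(ped)
    groups = groups_map(ped)
    kb = load_knowledgebase(kb_path)

    small = read_small_variants(small_vcf, order, keys)
    svs = read_svs(sv_vcf, order, keys)

    small_result = run_small_cascade(small, small_thresholds)
    sv_result = run_sv_cascade(svs, sv_thresholds)

    surviving_small = small_result.coding + small_result.noncoding
    small_sharing = classify_records(surviving_small, order, groups)
    coding_sharing = classify_records(small_result.coding, order, groups)
    noncoding_sharing = classify_records(small_result.noncoding, order, groups)
    sv_sharing = classify_records(sv_result.survivors, order, groups, id_attr="sv_id")

    # RegulomeDB gate: group-exclusive noncoding survivors only
    exclusive_nc = [
        r for r in small_result.noncoding
        if any(c.kind == "exclusive_to_group"
               for c in noncoding_sharing[r.variant_id])
    ]
    regulome_survivors = filter_regulome(exclusive_nc, small_thresholds)

    region_table = tabulate_regions(small_result.noncoding, noncoding_sharing)
    sv_location_table = tabulate_sv_locations(sv_result.survivors, sv_sharing)

    coding_ids = {r.variant_id for r in small_result.coding}
    small_annotations = annotate_cancer(surviving_small, kb, "small", coding_ids)
    sv_annotations = annotate_cancer(sv_result.survivors, kb, "sv")
    cancer_summary = {
        "small": summarize_cancer_genes(surviving_small, small_annotations, small_sharing),
        "sv": summarize_cancer_genes(sv_result.survivors, sv_annotations, sv_sharing,
                                     id_attr="sv_id"),
    }

    small_rows = []
    for r in surviving_small:
        ann = small_annotations[r.variant_id]
        flags = {
            g: "Yes" if all(r.presence[order.index(s)] for s in sorted(groups[g])) and groups[g]
            else "-" for g in RISK_GROUPS
        }
        small_rows.append({
            "gene": r.gene or "NA", "variant_id": r.variant_id,
            **{g: flags[g] for g in RISK_GROUPS},
            "af": "NA" if r.af_1000g is None else f"{r.af_1000g:.4f}",
            "region": r.region,
            "cancer_related": ann.render_cancer(), "crc_related": ann.render_crc(),
            "oncogenic_class": ann.render_class(), "tumor_driver": ann.render_driver(),
        })
    sv_rows = []
    for r in sv_result.survivors:
        ann = sv_annotations[r.sv_id]
        flags = {
            g: "Yes" if groups[g] and all(r.presence[order.index(s)] for s in sorted(groups[g]))
            else "-" for g in RISK_GROUPS
        }
        sv_rows.append({
            "gene": r.gene or "NA", "sv_id": r.sv_id,
            **{g: flags[g] for g in RISK_GROUPS},
            "af": "NA" if r.af_1000g is None else f"{r.af_1000g:.4f}",
            "location": r.location,
            "cancer_related": ann.render_cancer(), "crc_related": ann.render_crc(),
        })

    manifest = RunManifest(
        inputs={"pedigree": str(ped_path), "small_vcf": str(small_vcf),
                "sv_vcf": str(sv_vcf), "knowledgebase": str(kb_path)},
        config_hash=_config_hash(small_thresholds, sv_thresholds, keys),
        seed=seed,
        stage_counts={
            "small": dict(small_result.trace.as_rows()),
            "sv": {stage: counts for stage, counts in sv_result.trace.stages},
            "regulome_survivors": len(regulome_survivors),
        },
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    return ReportBundle(
        small_trace=small_result.trace.as_rows(),
        sv_trace=sv_result.trace.stages,
        small_counts=count_by_class(coding_sharing),
        noncoding_counts=count_by_class(noncoding_sharing),
        sv_counts=count_by_class(sv_sharing),
        region_table=region_table,
        sv_location_table=sv_location_table,
        regulome_survivors=regulome_survivors,
        exclusive_noncoding=exclusive_nc,
        cancer_summary=cancer_summary,
        small_table_rows=small_rows,
        sv_table_rows=sv_rows,
        manifest=manifest,
    )


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def render_tables(bundle: ReportBundle, outdir: str | Path, format: str = "tsv") -> dict[str, Path]:
    """Write the report bundle; returns name -> path.

    ``format`` is ``tsv`` or ``markdown`` (markdown wraps the same cells
    in pipe tables).
    """
    if format not in ("tsv", "markdown"):
        raise ValueError(f"unknown format {format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if format == "tsv" else "md"
    out: dict[str, Path] = {}

    def emit(name: str, header: list[str], rows: list[list]) -> None:
        path = outdir / f"{name}.{ext}"
        if format == "tsv":
            _write_tsv(path, header, rows)
        else:
            lines = ["| " + " | ".join(header) + " |",
                     "|" + "---|" * len(header)]
            lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
            path.write_text("\n".join(lines) + "\n")
        out[name] = path

    n0 = bundle.small_trace[0][1] if bundle.small_trace else 0
    rows = []
    prev = n0
    for stage, n in bundle.small_trace:
        rows.append([stage, n, render_percentage(n, prev) if stage != "input" else ""])
        prev = n
    emit("small_cascade_trace", ["stage", "surviving", "pct_of_previous"], rows)

    rows = [[stage] + [counts[t] for t in SV_TYPES]
            for stage, counts in bundle.sv_trace]
    emit("sv_cascade_trace", ["stage", *SV_TYPES], rows)

    rows = [[row, bundle.region_table[row]["all_subjects"],
             bundle.region_table[row]["within_group"]] for row in REGION_ROW_ORDER]
    emit("noncoding_region_table", ["region", "shared_by_all", "shared_within_group"], rows)

    rows = [[row] + [bundle.sv_location_table[row][t] for t in SV_TYPES]
            for row in SV_LOCATION_ROWS]
    emit("sv_location_table", ["location", *SV_TYPES], rows)

    for name, tbl in (("small_variant_table", bundle.small_table_rows),
                      ("sv_table", bundle.sv_table_rows)):
        if tbl:
            header = list(tbl[0])
            emit(name, header, [[r[h] for h in header] for r in tbl])
        else:
            emit(name, ["empty"], [])

    summary_rows = []
    for track in ("small", "sv"):
        for group, buckets in sorted(bundle.cancer_summary[track].items()):
            summary_rows.append([track, group,
                                 ";".join(sorted(buckets["crc"])) or "-",
                                 ";".join(sorted(buckets["non_crc"])) or "-"])
    emit("cancer_gene_summary", ["track", "group", "crc_genes", "other_cancer_genes"],
         summary_rows)

    bundle.manifest.write(outdir / "manifest.json")
    out["manifest"] = outdir / "manifest.json"
    return out
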