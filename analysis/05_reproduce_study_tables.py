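#!/usr/bin/env python
"""Reproduce the published per-variant table tallies from the fixtures.

Recomputes, from the packaged transcriptions of the study's prioritized
variant tables and the local cancer knowledgebase: the per-group coding
sharing occurrences, the SV within-group counts by type, the location
cross-tabulation, and the cancer/CRC gene lists. Writes
results/study_tallies.tsv.
"""

from collections import Counter
from pathlib import Path

from riskcluster.fixtures_io import (
    load_fixture,
    load_packaged_knowledgebase,
    load_printed_cascade_counts,
)
from riskcluster.knowledgebase import annotate_cancer, summarize_cancer_genes
from riskcluster.report import render_percentage
from riskcluster.sharing import classify_records, count_by_class
from riskcluster.svs import tabulate_sv_locations

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    rows = []
    printed = load_printed_cascade_counts()["small_variants"]
    pct_af = render_percentage(printed["af_filter"], printed["vqsr_total"])
    pct_cadd = render_percentage(printed["cadd_filter"], printed["af_filter"])
    rows += [("pct_af_filter", pct_af), ("pct_cadd_filter", pct_cadd)]
    print(f"rarity filter kept {pct_af}% of called variants; "
          f"CADD kept {pct_cadd}% of those")

    table3 = load_fixture("table3")
    kb = load_packaged_knowledgebase()
    coding = [r for r, row in zip(table3.records, table3.expected)
              if row["track"] == "coding"]
    counts = count_by_class(
        classify_records(coding, table3.subject_order, table3.groups))
    rows += [(f"coding_shared_{g}", counts.shared_within[g])
             for g in ("HRLS", "IRLS", "LRLS")]
    print(f"coding sharing occurrences: {dict(counts.shared_within)} "
          f"(39 genes over {len(table3.records)} rows)")

    coding_ids = {r.variant_id for r in coding}
    anns = annotate_cancer(table3.records, kb, "small", coding_ids)
    summary = summarize_cancer_genes(table3.records, anns)
    print(f"CRC-associated small-variant genes: {sorted(summary['ALL']['crc'])}")
    print(f"other cancer-associated genes: {sorted(summary['ALL']['non_crc'])}")

    table5 = load_fixture("table5")
    sharing5 = classify_records(table5.records, table5.subject_order,
                                table5.groups, id_attr="sv_id")
    within = Counter()
    for rec in table5.records:
        classes = sharing5[rec.sv_id]
        if any(c.kind == "shared_within_group" for c in classes) and \
                not any(c.kind == "shared_all_samples" for c in classes):
            within[rec.svtype] += 1
    rows += [(f"sv_within_group_{t}", within[t]) for t in sorted(within)]
    print(f"within-group shared SVs by type: {dict(within)}")

    loc = tabulate_sv_locations(table5.records, sharing5)
    print(f"intronic BND/DEL: {loc['Intronic']['BND']}/{loc['Intronic']['DEL']}; "
          f"txStart-txEnd INV: {loc['txStart-txEnd']['INV']}")

    anns5 = annotate_cancer(table5.records, kb, "sv")
    summary5 = summarize_cancer_genes(table5.records, anns5, id_attr="sv_id")
    print(f"digestive/CRC-related SV genes: {sorted(summary5['ALL']['crc'])}; "
          f"other: {sorted(summary5['ALL']['non_crc'])}")

    ROOT.mkdir(exist_ok=True)
    (ROOT / "study_tallies.tsv").write_text(
        "quantity\tvalue\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n")
    print(f"-> {ROOT / 'study_tallies.tsv'}")
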