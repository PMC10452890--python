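#!/usr/bin/env python
"""Classify the familial sharing pattern of every prioritized variant.

Assigns each surviving record of both tracks its sharing classes over the
three risk groups (shared by all, shared within a group, exclusive to a
group) and tabulates the summary counts with per-group multiplicity.
"""

from pathlib import Path

from riskcluster.pedigree import groups_map, read_pedigree, sequenced_order
from riskcluster.sharing import classify_records, count_by_class, write_sharing_tsv
from riskcluster.variants import read_small_variants_tsv, read_svs_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    ped = read_pedigree(ROOT / "cohort" / "cohort.ped")
    order = sequenced_order(ped)
    groups = groups_map(ped)
    small = read_small_variants_tsv(ROOT / "small_survivors.tsv")
    svs = read_svs_tsv(ROOT / "sv_survivors.tsv")
    for name, records, id_attr in [("small", small, "variant_id"),
                                   ("sv", svs, "sv_id")]:
        sharing = classify_records(records, order, groups, id_attr=id_attr)
        write_sharing_tsv(sharing, ROOT / f"{name}_sharing.tsv")
        counts = count_by_class(sharing)
        print(f"{name}: shared by all {counts.shared_all}; "
              f"within-group {dict(counts.shared_within)} "
              f"(total {counts.shared_within_total}); "
              f"exclusive {dict(counts.exclusive)}")
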