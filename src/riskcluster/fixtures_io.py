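"""Loaders for the packaged fixtures (see ``fixtures/README.md``).

The per-variant tables are loaded both as display rows (the printed cells,
for classification checks) and as materialized record objects whose
presence vectors realize the printed per-group sharing flags over the
packaged pedigree: a ``Yes`` under a group marks the variant present in
every sequenced member of that group, ``-`` in none of them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .knowledgebase import Knowledgebase, load_knowledgebase
from .pedigree import Pedigree, groups_map, read_pedigree, sequenced_order
from .variants import SVRecord, SmallVariantRecord

_REGION_CODES = {"EX": "exonic", "INT": "intronic", "NA": "intergenic"}
_LOCATION_CODES = {"INT": "intronic", "EX": "exonic", "TX": "txStart-txEnd", "NA": "NA"}


def fixture_path(name: str) -> Path:
    path = resources.files("riskcluster") / "fixtures" / name
    with resources.as_file(path) as p:
        return Path(p)


def load_pedigree_fixture() -> Pedigree:
    return read_pedigree(fixture_path("pedigree.ped"))


def load_packaged_knowledgebase() -> Knowledgebase:
    return load_knowledgebase(fixture_path("knowledgebase.tsv"))


def load_printed_cascade_counts() -> dict:
    return yaml.safe_load(fixture_path("printed_cascade_counts.yaml").read_text())


def _presence_from_flags(row, groups: dict[str, set[str]], order: list[str]) -> tuple[bool, ...]:
    carriers: set[str] = set()
    for label in ("HRLS", "IRLS", "LRLS"):
        if row[label.lower()] == "Yes":
            carriers |= groups[label]
    return tuple(sid in carriers for sid in order)


@dataclass
class FixtureTable:
    """Materialized records plus the printed expected cells per row."""

    records: list
    expected: list[dict]
    subject_order: list[str]
    groups: dict[str, set[str]]


def _load_rows(name: str) -> list[dict]:
    with open(fixture_path(name), newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_fixture(name: str) -> FixtureTable:
    """Load ``table3`` (small variants) or ``table5`` (SVs)."""
    ped = load_pedigree_fixture()
    order = sequenced_order(ped)
    groups = groups_map(ped)
    if name == "table3":
        rows = _load_rows("table3_small_variants.tsv")
        records = []
        for i, row in enumerate(rows, start=1):
            records.append(SmallVariantRecord(
                chrom="1", pos=i, ref="A", alt="T",
                rsid=None if row["rsid"] == "NA" else row["rsid"],
                af_1000g=None if row["af_1000g"] == "NA" else float(row["af_1000g"]),
                region=_REGION_CODES[row["region"]],
                gene=row["gene"],
                presence=_presence_from_flags(row, groups, order),
            ))
        return FixtureTable(records, rows, order, groups)
    if name == "table5":
        rows = _load_rows("table5_svs.tsv")
        records = []
        for row in rows:
            chrom, start, end, svtype, n = row["sv_id"].rsplit("_", 4)
            records.append(SVRecord(
                sv_id=row["sv_id"], chrom=chrom, start=int(start), end=int(end),
                svtype=svtype,
                af_1000g=None if row["af_1000g"] == "NA" else float(row["af_1000g"]),
                gene=None if row["gene"] == "NA" else row["gene"],
                location=_LOCATION_CODES[row["location"]],
                presence=_presence_from_flags(row, groups, order),
            ))
        return FixtureTable(records, rows, order, groups)
    raise ValueError(f"unknown fixture {name!r}; expected 'table3' or 'table5'")
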