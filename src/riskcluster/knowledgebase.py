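"""Local cancer-association knowledgebase and variant/gene cross-referencing.

A packaged, versioned TSV stands in for the web knowledgebases the field
queries (OncoKB, My Cancer Genome, Cancer Genome Interpreter, GAD): each
row keys a gene symbol or an rsid to its cancer-type associations, a
CRC-relatedness flag (stored, never inferred from strings), an oncogenic
classification (Driver / Passenger / Not protein-affecting) and a
tumor-driver flag. Variant-keyed (rsid) entries take precedence over
gene-keyed entries; conflicts across sources resolve by a source-priority
list.

Records that hit no entry receive track-dependent defaults: coding records
with an rsid default to Passenger / non-driver, noncoding records to
"Not protein-affecting", and records with no usable key stay unknown.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DEFAULT_SOURCE_PRIORITY = ("OncoKB", "My Cancer Genome", "CGI", "GAD", "SNPnexus")

UNKNOWN = "unknown"


@dataclass(frozen=True)
class KnowledgebaseEntry:
    key: str
    key_type: str  # gene | rsid
    cancer_types: tuple[str, ...] = ()
    crc_types: tuple[str, ...] = ()
    crc_related: bool = False
    oncogenic_class: str = UNKNOWN  # Driver | Passenger | Not protein-affecting | unknown
    tumor_driver: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.key_type not in ("gene", "rsid"):
            raise ValueError(f"key_type must be gene or rsid, got {self.key_type!r}")
        if self.crc_related and not (self.cancer_types or self.crc_types):
            raise ValueError(
                f"{self.key}: crc_related requires cancer_types or an explicit CRC tag"
            )


@dataclass
class Knowledgebase:
    by_gene: dict[str, list[KnowledgebaseEntry]] = field(default_factory=dict)
    by_rsid: dict[str, list[KnowledgebaseEntry]] = field(default_factory=dict)
    source_priority: tuple[str, ...] = DEFAULT_SOURCE_PRIORITY

    def add(self, entry: KnowledgebaseEntry) -> None:
        index = self.by_rsid if entry.key_type == "rsid" else self.by_gene
        key = entry.key if entry.key_type == "rsid" else entry.key.upper()
        bucket = index.setdefault(key, [])
        if any(e.source == entry.source for e in bucket):
            raise ValueError(f"duplicate knowledgebase key ({entry.key!r}, {entry.source!r})")
        bucket.append(entry)

    def _best(self, bucket: list[KnowledgebaseEntry] | None) -> KnowledgebaseEntry | None:
        if not bucket:
            return None
        def rank(e: KnowledgebaseEntry) -> tuple[int, str]:
            try:
                return (self.source_priority.index(e.source), e.source)
            except ValueError:
                return (len(self.source_priority), e.source)
        return sorted(bucket, key=rank)[0]

    def lookup_gene(self, symbol: str | None) -> KnowledgebaseEntry | None:
        if symbol is None:
            return None
        return self._best(self.by_gene.get(symbol.upper()))

    def lookup_rsid(self, rsid: str | None) -> KnowledgebaseEntry | None:
        if rsid is None:
            return None
        return self._best(self.by_rsid.get(rsid))

    def entries(self) -> list[KnowledgebaseEntry]:
        out = [e for b in self.by_gene.values() for e in b]
        out += [e for b in self.by_rsid.values() for e in b]
        return out


_COLUMNS = ["key", "key_type", "cancer_types", "crc_types", "crc_related",
            "oncogenic_class", "tumor_driver", "source"]


def _split(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell or cell in ("-", "NA"):
        return ()
    return tuple(part.strip() for part in cell.split(";") if part.strip())


def load_knowledgebase(path: str | Path,
                       source_priority: Sequence[str] = DEFAULT_SOURCE_PRIORITY) -> Knowledgebase:
    """Load the TSV; malformed rows are skipped with a warning."""
    import logging

    logger = logging.getLogger(__name__)
    kb = Knowledgebase(source_priority=tuple(source_priority))
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                kb.add(KnowledgebaseEntry(
                    key=row["key"],
                    key_type=row["key_type"],
                    cancer_types=_split(row["cancer_types"]),
                    crc_types=_split(row["crc_types"]),
                    crc_related=row["crc_related"].strip().lower() in ("1", "true", "yes"),
                    oncogenic_class=row["oncogenic_class"],
                    tumor_driver=row["tumor_driver"].strip().lower() in ("1", "true", "yes"),
                    source=row["source"],
                ))
            except (KeyError, TypeError) as exc:
                logger.warning("%s:%d: malformed knowledgebase row skipped (%s)", path, i, exc)
            except ValueError as exc:
                if "duplicate" in str(exc):
                    raise
                logger.warning("%s:%d: malformed knowledgebase row skipped (%s)", path, i, exc)
    return kb


def write_knowledgebase(kb: Knowledgebase, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for e in sorted(kb.entries(), key=lambda e: (e.key_type, e.key, e.source)):
            w.writerow([
                e.key, e.key_type, ";".join(e.cancer_types), ";".join(e.crc_types),
                "true" if e.crc_related else "false", e.oncogenic_class,
                "true" if e.tumor_driver else "false", e.source,
            ])


@dataclass(frozen=True)
class CancerAnnotation:
    """The four classification cells attached to an output row.

    ``known=False`` marks a record that carried no usable lookup key at
    all (every cell renders NA). A record that *was* queryable but has no
    cancer association renders "-" in the association cells; a record
    with no oncogenic classification (``oncogenic_class=None``) renders
    NA in the classification cells only.
    """

    cancer_types: tuple[str, ...] = ()
    crc_types: tuple[str, ...] = ()
    crc_related: bool = False
    oncogenic_class: str | None = None
    tumor_driver: bool | None = None
    source: str = ""
    known: bool = True

    def render_cancer(self) -> str:
        if not self.known:
            return "NA"
        return "; ".join(self.cancer_types) if self.cancer_types else "-"

    def render_crc(self) -> str:
        if not self.known:
            return "NA"
        return "; ".join(self.crc_types) if self.crc_types else "-"

    def render_class(self) -> str:
        return self.oncogenic_class if self.known and self.oncogenic_class else "NA"

    def render_driver(self) -> str:
        if not self.known or self.tumor_driver is None:
            return "NA"
        return str(self.tumor_driver)


_UNKNOWN_ANNOTATION = CancerAnnotation(known=False)


def _from_entry(entry: KnowledgebaseEntry) -> CancerAnnotation:
    return CancerAnnotation(
        cancer_types=entry.cancer_types,
        crc_types=entry.crc_types,
        crc_related=entry.crc_related,
        oncogenic_class=entry.oncogenic_class,
        tumor_driver=entry.tumor_driver,
        source=entry.source,
    )


def annotate_small_variant(record, kb: Knowledgebase,
                           coding: bool,
                           default_coding_class: str = "Passenger") -> CancerAnnotation:
    """Annotate one small variant; rsid entries beat gene entries.

    No-hit defaults: coding records with an rsid become
    ``default_coding_class`` / non-driver; noncoding records become
    "Not protein-affecting"; records without an rsid stay unknown
    (there is no key the knowledgebases could have been queried with).
    """
    entry = kb.lookup_rsid(record.rsid) or kb.lookup_gene(record.gene)
    if entry is not None:
        return _from_entry(entry)
    if record.rsid is None:
        # no key the knowledgebases could have been queried with: the
        # association cells stay "-" but classification is NA
        return CancerAnnotation(oncogenic_class=None, tumor_driver=None)
    if coding:
        return CancerAnnotation(oncogenic_class=default_coding_class, tumor_driver=False)
    return CancerAnnotation(oncogenic_class="Not protein-affecting", tumor_driver=False)


def annotate_sv(record, kb: Knowledgebase) -> CancerAnnotation:
    """Annotate one SV by its overlapped gene; no gene means unknown."""
    entry = kb.lookup_gene(record.gene)
    if entry is not None:
        return _from_entry(entry)
    if record.gene is None:
        return _UNKNOWN_ANNOTATION
    return CancerAnnotation(oncogenic_class="Passenger", tumor_driver=False)


def annotate_cancer(records, kb: Knowledgebase, track: str,
                    coding_ids: set[str] | None = None) -> dict[str, CancerAnnotation]:
    """Annotate a batch; returns a mapping keyed by record id.

    ``track`` is ``small`` or ``sv``. For the small track, ``coding_ids``
    names the records on the coding branch (others default noncoding).
    Annotation is a pure function of (record, kb), hence idempotent.
    """
    out: dict[str, CancerAnnotation] = {}
    if track == "small":
        coding_ids = coding_ids or set()
        for r in records:
            out[r.variant_id] = annotate_small_variant(r, kb, r.variant_id in coding_ids)
    elif track == "sv":
        for r in records:
            out[r.sv_id] = annotate_sv(r, kb)
    else:
        raise ValueError(f"unknown track {track!r}")
    return out


def summarize_cancer_genes(
    records, annotations: Mapping[str, CancerAnnotation],
    sharing_by_id: Mapping[str, set] | None = None,
    id_attr: str = "variant_id",
) -> dict[str, dict[str, set[str]]]:
    """Per-risk-group cancer-gene lists, split CRC-related vs not.

    Returns ``{group: {"crc": genes, "non_crc": genes}}`` plus an ``ALL``
    pseudo-group aggregating every record regardless of sharing.
    """
    from .pedigree import RISK_GROUPS

    out = {g: {"crc": set(), "non_crc": set()} for g in (*RISK_GROUPS, "ALL")}
    for r in records:
        ann = annotations.get(getattr(r, id_attr))
        if ann is None or not ann.cancer_types and not ann.crc_types:
            continue
        gene = getattr(r, "gene", None)
        if gene is None:
            continue
        bucket = "crc" if ann.crc_related else "non_crc"
        out["ALL"][bucket].add(gene)
        if sharing_by_id:
            for c in sharing_by_id.get(getattr(r, id_attr), set()):
                if c.group is not None:
                    out[c.group][bucket].add(gene)
    return out
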