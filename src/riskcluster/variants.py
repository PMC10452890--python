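"""Annotated variant data model and VCF/TSV input/output.

Two record types carry the prioritization cascades' covariates:

* :class:`SmallVariantRecord` — an SNV/indel split per ALT allele, with
  dual-panel allele frequencies (1000 Genomes ALL, non-TCGA ExAC ALL), the
  CADD scaled (Phred) score, four deleteriousness predictor calls
  (MutationTaster, PolyPhen2, PROVEAN, SIFT), the RefSeq region class, the
  gene symbol, the RegulomeDB rank, and a per-sequenced-subject presence
  vector.
* :class:`SVRecord` — a structural variant (DEL/DUP/INV/BND) with
  1000 Genomes/gnomAD frequencies, the AnnotSV ranking class, the duphold
  depth-validation flag (DEL/DUP only), the overlapped gene, the AnnotSV
  location class, and the same presence vector.

Breakends are handled per VCF record: each BND line yields one
:class:`SVRecord`; mate pairs are linked but never merged, so n breakend
lines count as n records.

INFO keys are configurable through :class:`AnnotationKeys` because
annotator output dialects vary; the defaults below are the ones the
packaged writers emit.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pysam
import yaml

logger = logging.getLogger(__name__)

PREDICTOR_TOOLS = ("MutationTaster", "PolyPhen2", "PROVEAN", "SIFT")

REGION_CLASSES = (
    "exonic",
    "intronic",
    "intergenic",
    "ncRNA_intronic",
    "ncRNA_exonic",
    "UTR3",
    "UTR5",
    "upstream",
    "downstream",
)

SV_TYPES = ("DEL", "DUP", "INV", "BND")
SV_LOCATIONS = ("intronic", "exonic", "txStart-txEnd", "NA")

DELETERIOUS = "deleterious"
TOLERATED = "tolerated"
MISSING = "missing"

# dbNSFP-style letter codes per tool
_PREDICTOR_CODES = {
    "MutationTaster": {"A": DELETERIOUS, "D": DELETERIOUS},
    "PolyPhen2": {"D": DELETERIOUS, "P": DELETERIOUS, "B": TOLERATED},
    "PROVEAN": {"D": DELETERIOUS, "N": TOLERATED},
    "SIFT": {"D": DELETERIOUS, "T": TOLERATED},
}


def normalize_predictor_call(tool: str, code: str | None) -> str:
    """Map a raw predictor letter code to deleterious/tolerated/missing."""
    if code is None:
        return MISSING
    return _PREDICTOR_CODES.get(tool, {}).get(str(code).strip(), MISSING)


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO-key mapping for both VCF dialects, overridable from YAML."""

    af_1000g: str = "AF_1000G"
    af_exac_nontcga: str = "AF_EXAC_NONTCGA"
    cadd_phred: str = "CADD_PHRED"
    mutation_taster: str = "MT"
    polyphen2: str = "PP2"
    provean: str = "PROVEAN"
    sift: str = "SIFT"
    regulomedb: str = "REGDB"
    gene: str = "GENE"
    region: str = "REGION"
    # SV-specific
    af_gnomad: str = "GNOMAD_AF"
    ranking: str = "RANKING"
    duphold_ok: str = "DUPHOLD_OK"
    location: str = "LOCATION"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnnotationKeys":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown annotation-key names: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SmallVariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: str | None = None
    af_1000g: float | None = None
    af_exac_nontcga: float | None = None
    cadd_phred: float | None = None
    predictors: dict[str, str] = field(
        default_factory=lambda: {t: MISSING for t in PREDICTOR_TOOLS}
    )
    region: str = "intergenic"
    gene: str | None = None
    regulomedb: int | None = None
    presence: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        for af in (self.af_1000g, self.af_exac_nontcga):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} outside [0, 1]")
        if self.region not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region!r}")
        self.presence = tuple(self.presence)

    @property
    def variant_id(self) -> str:
        return self.rsid or f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    def deleterious_votes(self) -> int:
        return sum(1 for c in self.predictors.values() if c == DELETERIOUS)


@dataclass
class SVRecord:
    chrom: str
    start: int  # 1-based
    end: int
    svtype: str
    af_1000g: float | None = None
    af_gnomad: float | None = None
    annotsv_ranking: int | None = None
    depth_validated: bool | None = None
    gene: str | None = None
    location: str = "NA"
    mate: tuple[str, int] | None = None  # BND partner coordinate
    mate_id: str | None = None
    presence: tuple[bool, ...] = ()
    sv_id: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.location not in SV_LOCATIONS:
            raise ValueError(f"unknown SV location class {self.location!r}")
        if self.svtype != "BND" and self.mate is not None:
            raise ValueError("only BND records carry a mate coordinate")
        if self.svtype not in ("DEL", "DUP"):
            self.depth_validated = None
        self.presence = tuple(self.presence)
        if not self.sv_id:
            self.sv_id = f"{self.chrom}_{self.start}_{self.end}_{self.svtype}_1"

    @property
    def length(self) -> int | None:
        """end - start for DEL/DUP/INV; undefined (None) for BND."""
        if self.svtype == "BND":
            return None
        return self.end - self.start


def _unique_sv_ids(records: list[SVRecord]) -> None:
    """Renumber the trailing _n so ids are unique in file order."""
    seen: dict[str, int] = {}
    for rec in records:
        base = f"{rec.chrom}_{rec.start}_{rec.end}_{rec.svtype}"
        seen[base] = seen.get(base, 0) + 1
        rec.sv_id = f"{base}_{seen[base]}"


# ---------------------------------------------------------------------------
# VCF reading

def _info_float(info, key: str, where: str) -> float | None:
    if key not in info:
        return None
    val = info[key]
    if isinstance(val, tuple):
        val = val[0] if val else None
    if val is None:
        return None
    try:
        return float(val)
    except (TypeError, ValueError):
        logger.warning("%s: unparseable %s value %r; treated as missing", where, key, val)
        return None


def _info_int(info, key: str, where: str) -> int | None:
    val = _info_float(info, key, where)
    return None if val is None else int(val)


def _info_str(info, key: str) -> str | None:
    if key not in info:
        return None
    val = info[key]
    if isinstance(val, tuple):
        val = val[0] if val else None
    return None if val is None else str(val)


def _presence(vrec, subjects: Sequence[str], alt_index: int) -> tuple[bool, ...]:
    """True iff the subject's genotype contains this ALT allele.

    Missing genotypes count as absent."""
    out = []
    for sid in subjects:
        gt = vrec.samples[sid].get("GT")
        out.append(gt is not None and alt_index in [a for a in gt if a is not None])
    return tuple(out)


def _check_samples(vf: pysam.VariantFile, subjects: Sequence[str], path) -> None:
    missing = [s for s in subjects if s not in vf.header.samples]
    if missing:
        raise ValueError(f"{path}: required samples absent from VCF: {missing}")


def read_small_variants(
    path: str | Path,
    subjects: Sequence[str],
    keys: AnnotationKeys = AnnotationKeys(),
) -> list[SmallVariantRecord]:
    """Read an annotated small-variant VCF; one record per ALT allele."""
    records: list[SmallVariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        _check_samples(vf, subjects, path)
        for vrec in vf:
            where = f"{path}:{vrec.chrom}:{vrec.pos}"
            for ai, alt in enumerate(vrec.alts or (), start=1):
                region = _info_str(vrec.info, keys.region) or "intergenic"
                if region not in REGION_CLASSES:
                    logger.warning("%s: unknown region %r; treated as intergenic", where, region)
                    region = "intergenic"
                records.append(
                    SmallVariantRecord(
                        chrom=vrec.chrom,
                        pos=vrec.pos,
                        ref=vrec.ref,
                        alt=alt,
                        rsid=None if vrec.id in (None, ".") else vrec.id,
                        af_1000g=_info_float(vrec.info, keys.af_1000g, where),
                        af_exac_nontcga=_info_float(vrec.info, keys.af_exac_nontcga, where),
                        cadd_phred=_info_float(vrec.info, keys.cadd_phred, where),
                        predictors={
                            "MutationTaster": normalize_predictor_call(
                                "MutationTaster", _info_str(vrec.info, keys.mutation_taster)),
                            "PolyPhen2": normalize_predictor_call(
                                "PolyPhen2", _info_str(vrec.info, keys.polyphen2)),
                            "PROVEAN": normalize_predictor_call(
                                "PROVEAN", _info_str(vrec.info, keys.provean)),
                            "SIFT": normalize_predictor_call(
                                "SIFT", _info_str(vrec.info, keys.sift)),
                        },
                        region=region,
                        gene=_info_str(vrec.info, keys.gene),
                        regulomedb=_info_int(vrec.info, keys.regulomedb, where),
                        presence=_presence(vrec, subjects, ai),
                    )
                )
    return records


_BND_ALT = re.compile(r"[\[\]](?P<chrom>[^:\[\]]+):(?P<pos>\d+)[\[\]]")


def read_svs(
    path: str | Path,
    subjects: Sequence[str],
    keys: AnnotationKeys = AnnotationKeys(),
) -> list[SVRecord]:
    """Read an SV VCF. Each BND line yields one record (mates not merged)."""
    records: list[SVRecord] = []
    ids_seen: set[str] = set()
    mate_ids: list[str | None] = []
    with pysam.VariantFile(str(path)) as vf:
        _check_samples(vf, subjects, path)
        for vrec in vf:
            where = f"{path}:{vrec.chrom}:{vrec.pos}"
            svtype = _info_str(vrec.info, "SVTYPE")
            if svtype not in SV_TYPES:
                logger.warning("%s: unknown SVTYPE %r; record skipped", where, svtype)
                continue
            mate = None
            if svtype == "BND":
                end = vrec.pos + 1
                alt = (vrec.alts or ("",))[0]
                m = _BND_ALT.search(alt)
                if m:
                    mate = (m.group("chrom"), int(m.group("pos")))
            else:
                # pysam surfaces INFO/END as record.stop; with END absent
                # stop degenerates to pos (the 1-bp reference span)
                end = vrec.stop
                if end <= vrec.pos:
                    raise ValueError(f"{where}: {svtype} record lacks END")
            rec = SVRecord(
                chrom=vrec.chrom,
                start=vrec.pos,
                end=end,
                svtype=svtype,
                af_1000g=_info_float(vrec.info, keys.af_1000g, where),
                af_gnomad=_info_float(vrec.info, keys.af_gnomad, where),
                annotsv_ranking=_info_int(vrec.info, keys.ranking, where),
                depth_validated=(
                    bool(vrec.info.get(keys.duphold_ok))
                    if svtype in ("DEL", "DUP") and keys.duphold_ok in vrec.info
                    else None
                ),
                gene=_info_str(vrec.info, keys.gene),
                location=_info_str(vrec.info, keys.location) or "NA",
                mate=mate,
                mate_id=_info_str(vrec.info, "MATEID"),
                presence=_presence(vrec, subjects, 1),
            )
            ids_seen.add(vrec.id or "")
            mate_ids.append(rec.mate_id)
            records.append(rec)
    _unique_sv_ids(records)
    dangling = [m for m in mate_ids if m and m not in ids_seen]
    for m in dangling:
        logger.warning("%s: dangling MATEID %r; mate left unresolved", path, m)
    return records


# ---------------------------------------------------------------------------
# Writing

def _small_header(subjects: Sequence[str], keys: AnnotationKeys, contigs) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in contigs:
        h.contigs.add(c)
    for key, num, typ, desc in [
        (keys.af_1000g, 1, "Float", "1000 Genomes ALL allele frequency"),
        (keys.af_exac_nontcga, 1, "Float", "non-TCGA ExAC ALL allele frequency"),
        (keys.cadd_phred, 1, "Float", "CADD scaled (Phred) score"),
        (keys.mutation_taster, 1, "String", "MutationTaster call"),
        (keys.polyphen2, 1, "String", "PolyPhen2 call"),
        (keys.provean, 1, "String", "PROVEAN call"),
        (keys.sift, 1, "String", "SIFT call"),
        (keys.regulomedb, 1, "Integer", "RegulomeDB rank category"),
        (keys.gene, 1, "String", "Gene symbol"),
        (keys.region, 1, "String", "RefSeq region class"),
    ]:
        h.info.add(key, num, typ, desc)
    h.formats.add("GT", 1, "String", "Genotype")
    for s in subjects:
        h.add_sample(s)
    return h


def _sv_header(subjects: Sequence[str], keys: AnnotationKeys, contigs) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in contigs:
        h.contigs.add(c)
    for key, num, typ, desc in [
        ("SVTYPE", 1, "String", "Structural variant type"),
        ("END", 1, "Integer", "End coordinate"),
        ("MATEID", 1, "String", "Mate breakend id"),
        (keys.af_1000g, 1, "Float", "1000 Genomes ALL allele frequency"),
        (keys.af_gnomad, 1, "Float", "gnomAD allele frequency"),
        (keys.ranking, 1, "Integer", "AnnotSV ranking class (1-5)"),
        (keys.duphold_ok, 0, "Flag", "duphold depth validation passed"),
        (keys.gene, 1, "String", "Overlapped gene symbol"),
        (keys.location, 1, "String", "AnnotSV location class"),
    ]:
        h.info.add(key, num, typ, desc)
    h.formats.add("GT", 1, "String", "Genotype")
    for s in subjects:
        h.add_sample(s)
    return h


_PRED_LETTER = {DELETERIOUS: "D", TOLERATED: "T", MISSING: None}
# PolyPhen2 "T" is not a dbNSFP code; use B for tolerated on write
_PRED_LETTER_PP2 = {DELETERIOUS: "D", TOLERATED: "B", MISSING: None}


def write_small_variants_vcf(
    records: Iterable[SmallVariantRecord],
    path: str | Path,
    subjects: Sequence[str],
    keys: AnnotationKeys = AnnotationKeys(),
) -> None:
    records = list(records)
    contigs = sorted({r.chrom for r in records})
    header = _small_header(subjects, keys, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            if len(r.presence) != len(subjects):
                raise ValueError(f"{r.variant_id}: presence vector does not cover roster")
            v = vf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt), id=r.rsid,
            )
            info = v.info
            if r.af_1000g is not None:
                info[keys.af_1000g] = r.af_1000g
            if r.af_exac_nontcga is not None:
                info[keys.af_exac_nontcga] = r.af_exac_nontcga
            if r.cadd_phred is not None:
                info[keys.cadd_phred] = r.cadd_phred
            for tool, key, table in [
                ("MutationTaster", keys.mutation_taster, _PRED_LETTER),
                ("PolyPhen2", keys.polyphen2, _PRED_LETTER_PP2),
                ("PROVEAN", keys.provean, _PRED_LETTER),
                ("SIFT", keys.sift, _PRED_LETTER),
            ]:
                letter = table[r.predictors.get(tool, MISSING)]
                if letter is not None:
                    info[key] = letter
            if r.regulomedb is not None:
                info[keys.regulomedb] = r.regulomedb
            if r.gene is not None:
                info[keys.gene] = r.gene
            info[keys.region] = r.region
            for i, sid in enumerate(subjects):
                v.samples[sid]["GT"] = (0, 1) if r.presence[i] else (0, 0)
            vf.write(v)


def write_svs_vcf(
    records: Iterable[SVRecord],
    path: str | Path,
    subjects: Sequence[str],
    keys: AnnotationKeys = AnnotationKeys(),
) -> None:
    records = list(records)
    contigs = sorted({r.chrom for r in records} | {r.mate[0] for r in records if r.mate})
    header = _sv_header(subjects, keys, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            if len(r.presence) != len(subjects):
                raise ValueError(f"{r.sv_id}: presence vector does not cover roster")
            if r.svtype == "BND":
                mate = r.mate or (r.chrom, r.start)
                alleles = ("N", f"N[{mate[0]}:{mate[1]}[")
                v = vf.new_record(contig=r.chrom, start=r.start - 1,
                                  stop=r.start, alleles=alleles, id=r.sv_id)
            else:
                v = vf.new_record(contig=r.chrom, start=r.start - 1, stop=r.end,
                                  alleles=("N", f"<{r.svtype}>"), id=r.sv_id)
            v.info["SVTYPE"] = r.svtype
            if r.mate_id:
                v.info["MATEID"] = r.mate_id
            if r.af_1000g is not None:
                v.info[keys.af_1000g] = r.af_1000g
            if r.af_gnomad is not None:
                v.info[keys.af_gnomad] = r.af_gnomad
            if r.annotsv_ranking is not None:
                v.info[keys.ranking] = r.annotsv_ranking
            if r.depth_validated:
                v.info[keys.duphold_ok] = True
            if r.gene is not None:
                v.info[keys.gene] = r.gene
            v.info[keys.location] = r.location
            for i, sid in enumerate(subjects):
                v.samples[sid]["GT"] = (0, 1) if r.presence[i] else (0, 0)
            vf.write(v)


# ---------------------------------------------------------------------------
# TSV round-trip (Tables 3/5-style column layout)

_SMALL_TSV_COLS = [
    "chrom", "pos", "ref", "alt", "rsid", "af_1000g", "af_exac_nontcga",
    "cadd_phred", "MutationTaster", "PolyPhen2", "PROVEAN", "SIFT",
    "region", "gene", "regulomedb", "presence",
]
_SV_TSV_COLS = [
    "sv_id", "chrom", "start", "end", "svtype", "af_1000g", "af_gnomad",
    "annotsv_ranking", "depth_validated", "gene", "location",
    "mate", "mate_id", "presence",
]


def _fmt(val) -> str:
    if val is None:
        return "NA"
    if isinstance(val, bool):
        return "1" if val else "0"
    if isinstance(val, float):
        return repr(val)
    return str(val)


def _parse(val: str):
    return None if val == "NA" else val


def write_small_variants_tsv(records: Iterable[SmallVariantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SMALL_TSV_COLS)
        for r in records:
            w.writerow([
                r.chrom, r.pos, r.ref, r.alt, _fmt(r.rsid), _fmt(r.af_1000g),
                _fmt(r.af_exac_nontcga), _fmt(r.cadd_phred),
                r.predictors["MutationTaster"], r.predictors["PolyPhen2"],
                r.predictors["PROVEAN"], r.predictors["SIFT"],
                r.region, _fmt(r.gene), _fmt(r.regulomedb),
                "".join("1" if p else "0" for p in r.presence),
            ])


def read_small_variants_tsv(path: str | Path) -> list[SmallVariantRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(SmallVariantRecord(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                rsid=_parse(row["rsid"]),
                af_1000g=None if row["af_1000g"] == "NA" else float(row["af_1000g"]),
                af_exac_nontcga=None if row["af_exac_nontcga"] == "NA" else float(row["af_exac_nontcga"]),
                cadd_phred=None if row["cadd_phred"] == "NA" else float(row["cadd_phred"]),
                predictors={t: row[t] for t in PREDICTOR_TOOLS},
                region=row["region"], gene=_parse(row["gene"]),
                regulomedb=None if row["regulomedb"] == "NA" else int(row["regulomedb"]),
                presence=tuple(c == "1" for c in row["presence"]),
            ))
    return out


def write_svs_tsv(records: Iterable[SVRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SV_TSV_COLS)
        for r in records:
            w.writerow([
                r.sv_id, r.chrom, r.start, r.end, r.svtype, _fmt(r.af_1000g),
                _fmt(r.af_gnomad), _fmt(r.annotsv_ranking), _fmt(r.depth_validated),
                _fmt(r.gene), r.location,
                f"{r.mate[0]}:{r.mate[1]}" if r.mate else "NA", _fmt(r.mate_id),
                "".join("1" if p else "0" for p in r.presence),
            ])


def read_svs_tsv(path: str | Path) -> list[SVRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mate = None
            if row["mate"] != "NA":
                mc, mp = row["mate"].rsplit(":", 1)
                mate = (mc, int(mp))
            out.append(SVRecord(
                sv_id=row["sv_id"], chrom=row["chrom"], start=int(row["start"]),
                end=int(row["end"]), svtype=row["svtype"],
                af_1000g=None if row["af_1000g"] == "NA" else float(row["af_1000g"]),
                af_gnomad=None if row["af_gnomad"] == "NA" else float(row["af_gnomad"]),
                annotsv_ranking=None if row["annotsv_ranking"] == "NA" else int(row["annotsv_ranking"]),
                depth_validated=None if row["depth_validated"] == "NA" else row["depth_validated"] == "1",
                gene=_parse(row["gene"]), location=row["location"],
                mate=mate, mate_id=_parse(row["mate_id"]),
                presence=tuple(c == "1" for c in row["presence"]),
            ))
    return out


def write_records(records: Sequence, path: str | Path, format: str, subjects: Sequence[str] | None = None,
                  keys: AnnotationKeys = AnnotationKeys()) -> None:
    """Dispatching writer: ``format`` is ``VCF`` or ``TSV``.

    The record kind (small variant vs SV) is inferred from the records;
    an empty list with format VCF requires ``subjects`` and writes a
    header-only small-variant file.
    """
    fmt = format.upper()
    if fmt not in ("VCF", "TSV"):
        raise ValueError(f"unknown format {format!r}")
    is_sv = bool(records) and isinstance(records[0], SVRecord)
    if fmt == "TSV":
        (write_svs_tsv if is_sv else write_small_variants_tsv)(records, path)
    else:
        if subjects is None:
            subjects = []
        (write_svs_vcf if is_sv else write_small_variants_vcf)(records, path, subjects, keys)
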