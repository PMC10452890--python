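"""Synthetic pedigree cohorts with planted per-record truth labels.

The generator emulates the study conditions the cascades assume — a
three-group pedigree cohort (default 3 HRLS / 4 IRLS / 6 LRLS sequenced
members) carrying annotated small variants and SVs — while planting, for
every record, (a) the first cascade stage it should fail (or *survivor*)
and (b) its familial sharing class. Annotations are drawn so they are
consistent with the planted label by construction: e.g. a record planted
to fail the CADD stage carries panel frequencies that pass the rarity
filter and a CADD score at or below the threshold. Sharing patterns are
planted by assigning presence vectors directly, not by simulating
transmission: the downstream analysis tests set algebra over carriers,
not an inheritance model.

Only threshold-crossing behaviour matters to the cascades, so frequency
draws are a two-component mixture: a *rare* component uniform on
[0, 0.009] and a *common* component uniform on [0.05, 0.5], with a
configurable missing-frequency probability (missing = not seen in the
panel = novel).

Everything is driven by one integer seed; two runs with the same config
produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .pedigree import RISK_GROUPS
from .variants import (
    AnnotationKeys,
    DELETERIOUS,
    MISSING,
    PREDICTOR_TOOLS,
    REGION_CLASSES,
    SVRecord,
    SmallVariantRecord,
    TOLERATED,
    write_small_variants_vcf,
    write_svs_vcf,
)

SMALL_STAGES = ("af", "cadd", "consensus", "survivor")
SV_STAGES = ("depth", "af", "ranking", "length", "survivor")

SHARING_PATTERNS = (
    "shared_all",
    "within_HRLS", "within_IRLS", "within_LRLS",
    "exclusive_HRLS", "exclusive_IRLS", "exclusive_LRLS",
    "other",
)


@dataclass
class SimulationConfig:
    seed: int
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HRLS": 3, "IRLS": 4, "LRLS": 6})
    n_small_variants: int = 500
    n_svs: int = 200
    # AF mixture: P(common draw) among non-missing; remainder rare
    p_common_af: float = 0.35
    p_missing_af: float = 0.25
    rare_af_range: tuple[float, float] = (0.0, 0.009)
    common_af_range: tuple[float, float] = (0.05, 0.5)
    cadd_range: tuple[float, float] = (0.0, 40.0)
    # per-tool P(deleterious call) given the record must meet / miss quorum
    deleterious_vote_probs: dict[str, float] = field(
        default_factory=lambda: {"survivor": 0.9, "failer": 0.25})
    # planted first-failure mixture per track
    small_stage_mix: dict[str, float] = field(
        default_factory=lambda: {"af": 0.50, "cadd": 0.30, "consensus": 0.12,
                                 "survivor": 0.08})
    sv_stage_mix: dict[str, float] = field(
        default_factory=lambda: {"depth": 0.15, "af": 0.40, "ranking": 0.28,
                                 "length": 0.05, "survivor": 0.12})
    # called SV type mixture (matches the study's called proportions)
    sv_type_mix: dict[str, float] = field(
        default_factory=lambda: {"DEL": 0.369, "DUP": 0.017, "BND": 0.587,
                                 "INV": 0.027})
    sharing_mix: dict[str, float] = field(
        default_factory=lambda: {
            "shared_all": 0.10,
            "within_HRLS": 0.14, "within_IRLS": 0.13, "within_LRLS": 0.13,
            "exclusive_HRLS": 0.07, "exclusive_IRLS": 0.07, "exclusive_LRLS": 0.07,
            "other": 0.29})

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("small_stage_mix", "sv_stage_mix", "sv_type_mix", "sharing_mix"):
            mix = getattr(self, name)
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name}: negative proportion")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: proportions must sum to 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if self.n_small_variants < 0 or self.n_svs < 0:
            raise ValueError("record counts must be non-negative")
        for label in RISK_GROUPS:
            if self.group_sizes.get(label, 0) == 0 and (
                self.sharing_mix.get(f"within_{label}", 0) > 0
                or self.sharing_mix.get(f"exclusive_{label}", 0) > 0
            ):
                raise ValueError(
                    f"sharing pattern requested for empty group {label}")
        n_groups_ge1 = sum(1 for n in self.group_sizes.values() if n >= 1)
        if self.sharing_mix.get("other", 0) > 0 and n_groups_ge1 < 2:
            raise ValueError("'other' sharing pattern needs two non-empty groups")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))


@dataclass
class TruthRecord:
    variant_id: str
    track: str  # small | sv
    first_failure: str  # stage name or 'survivor'
    sharing: str  # one of SHARING_PATTERNS
    group: str  # group label or NA
    cancer_key: str  # rsid / gene / NA


@dataclass
class SimulatedCohort:
    ped_path: Path
    small_vcf: Path
    sv_vcf: Path
    truth_path: Path
    subject_order: list[str]
    groups: dict[str, list[str]]
    small_records: list[SmallVariantRecord]
    sv_records: list[SVRecord]
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------

def _make_subjects(config: SimulationConfig):
    """Subject ids per group plus the PED lines realizing each label.

    HRLS members are affected; IRLS members get an affected father;
    LRLS members get two unaffected parents.
    """
    groups: dict[str, list[str]] = {}
    lines = []
    for label in RISK_GROUPS:
        n = config.group_sizes.get(label, 0)
        groups[label] = [f"{label}_{i+1}" for i in range(n)]
    for sid in groups["HRLS"]:
        lines.append(f"FAM1 {sid} 0 0 1 2 1")
    for sid in groups["IRLS"]:
        lines.append(f"FAM1 {sid}_F 0 0 1 2")
        lines.append(f"FAM1 {sid}_M 0 0 2 1")
        lines.append(f"FAM1 {sid} {sid}_F {sid}_M 2 1 1")
    for sid in groups["LRLS"]:
        lines.append(f"FAM1 {sid}_F 0 0 1 1")
        lines.append(f"FAM1 {sid}_M 0 0 2 1")
        lines.append(f"FAM1 {sid} {sid}_F {sid}_M 1 1 1")
    return groups, lines


def _draw_af(rng: np.random.Generator, config: SimulationConfig, kind: str) -> float | None:
    """kind: 'rare' forces a passing draw (missing allowed); 'common' forces
    a failing draw; 'any' is the unconditional mixture."""
    if kind == "common":
        return float(rng.uniform(*config.common_af_range))
    if rng.random() < config.p_missing_af:
        return None
    if kind == "rare":
        return float(rng.uniform(*config.rare_af_range))
    if rng.random() < config.p_common_af:
        return float(rng.uniform(*config.common_af_range))
    return float(rng.uniform(*config.rare_af_range))


def _draw_sharing(rng, config) -> str:
    labels = list(config.sharing_mix)
    probs = np.array([config.sharing_mix[k] for k in labels])
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def _plant_presence(rng, pattern: str, groups: dict[str, list[str]],
                    order: list[str]) -> tuple[bool, ...]:
    members = {g: set(groups[g]) for g in groups}
    carriers: set[str] = set()
    if pattern == "shared_all":
        carriers = set(order)
    elif pattern.startswith("within_"):
        g = pattern.split("_", 1)[1]
        carriers = set(members[g])
        others = [s for s in order if s not in carriers]
        extra = {s for s in others if rng.random() < 0.3}
        # never let a within-group pattern extend to the full roster or to
        # the full membership of another group (keeps the planted label
        # the maximal within-group statement)
        for h in groups:
            if h != g and members[h] and members[h] <= carriers | extra:
                extra -= {sorted(members[h])[0]}
        if extra == set(others):
            extra -= {sorted(others)[0]} if others else set()
        carriers |= extra
    elif pattern.startswith("exclusive_"):
        g = pattern.split("_", 1)[1]
        pool = sorted(members[g])
        k = int(rng.integers(1, len(pool) + 1))
        idx = rng.choice(len(pool), size=k, replace=False)
        carriers = {pool[i] for i in sorted(idx)}
        # avoid the full-group case only when another class would not apply;
        # full membership is still exclusive, so it is allowed
    elif pattern == "other":
        nonempty = [g for g in RISK_GROUPS if members.get(g)]
        g1, g2 = nonempty[0], nonempty[1]
        # one partial pick from two groups: spans groups (not exclusive),
        # covers no full group of size >= 2, and misses the rest
        carriers = {sorted(members[g1])[0], sorted(members[g2])[0]}
        for g in (g1, g2):
            if len(members[g]) == 1:
                raise ValueError("'other' pattern needs groups of size >= 2")
    else:
        raise ValueError(f"unknown sharing pattern {pattern!r}")
    return tuple(s in carriers for s in order)


def _draw_votes(rng, config, want_quorum: bool) -> dict[str, str]:
    """Predictor calls with >= 3 deleterious iff want_quorum."""
    p = config.deleterious_vote_probs["survivor" if want_quorum else "failer"]
    while True:
        calls = {}
        for tool in PREDICTOR_TOOLS:
            if rng.random() < p:
                calls[tool] = DELETERIOUS
            else:
                calls[tool] = TOLERATED if rng.random() < 0.5 else MISSING
        n = sum(1 for c in calls.values() if c == DELETERIOUS)
        if (n >= 3) == want_quorum:
            return calls


_REGION_WEIGHTS = {
    "intergenic": 0.43, "intronic": 0.35, "exonic": 0.08,
    "ncRNA_intronic": 0.06, "UTR3": 0.02, "UTR5": 0.01,
    "upstream": 0.015, "downstream": 0.015, "ncRNA_exonic": 0.01,
}


def _draw_region(rng) -> str:
    labels = list(_REGION_WEIGHTS)
    probs = np.array(list(_REGION_WEIGHTS.values()))
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def _simulate_small(rng, config, groups, order):
    records, truth = [], []
    stages = list(config.small_stage_mix)
    stage_probs = np.array([config.small_stage_mix[s] for s in stages])
    stage_probs = stage_probs / stage_probs.sum()
    for i in range(config.n_small_variants):
        stage = stages[int(rng.choice(len(stages), p=stage_probs))]
        if stage == "af":
            af1 = _draw_af(rng, config, "common")
            af2 = _draw_af(rng, config, "any")
            if rng.random() < 0.5:
                af1, af2 = af2, af1
            # ensure at least one panel is actually common
            if not ((af1 is not None and af1 >= 0.01) or (af2 is not None and af2 >= 0.01)):
                af1 = _draw_af(rng, config, "common")
            cadd = float(rng.uniform(*config.cadd_range))
            votes = _draw_votes(rng, config, bool(rng.random() < 0.3))
        else:
            af1 = _draw_af(rng, config, "rare")
            af2 = _draw_af(rng, config, "rare")
            if stage == "cadd":
                cadd = float(rng.uniform(config.cadd_range[0], 10.0))
                votes = _draw_votes(rng, config, bool(rng.random() < 0.3))
            else:
                # keep a margin above the threshold so the value survives
                # rounding and 32-bit VCF storage
                cadd = float(rng.uniform(10.001, config.cadd_range[1]))
                votes = _draw_votes(rng, config, stage == "survivor")
        sharing = _draw_sharing(rng, config)
        presence = _plant_presence(rng, sharing, groups, order)
        group = sharing.split("_", 1)[1] if "_" in sharing else "NA"
        rsid = f"rs9{i:06d}" if rng.random() < 0.7 else None
        gene = f"GENE{i % 97}" if rng.random() < 0.8 else None
        rec = SmallVariantRecord(
            chrom=str(1 + i % 22), pos=1000 + i * 10, ref="A",
            alt=["C", "G", "T"][i % 3], rsid=rsid,
            af_1000g=af1, af_exac_nontcga=af2, cadd_phred=round(cadd, 3),
            predictors=votes, region=_draw_region(rng), gene=gene,
            regulomedb=int(rng.integers(1, 8)) if rng.random() < 0.7 else None,
            presence=presence,
        )
        records.append(rec)
        truth.append(TruthRecord(rec.variant_id, "small", stage, sharing,
                                 group, rsid or gene or "NA"))
    return records, truth


def _draw_sv_type(rng, config, stage: str) -> str:
    """Type consistent with the planted stage (depth needs DEL/DUP,
    length needs DEL/DUP/INV)."""
    allowed = {
        "depth": ("DEL", "DUP"),
        "length": ("DEL", "DUP", "INV"),
    }.get(stage, ("DEL", "DUP", "BND", "INV"))
    labels = [t for t in config.sv_type_mix if t in allowed]
    probs = np.array([config.sv_type_mix[t] for t in labels])
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def _simulate_svs(rng, config, groups, order):
    records, truth = [], []
    stages = list(config.sv_stage_mix)
    stage_probs = np.array([config.sv_stage_mix[s] for s in stages])
    stage_probs = stage_probs / stage_probs.sum()
    pending_mate = None  # (record_index,) for BND pairing
    for i in range(config.n_svs):
        stage = stages[int(rng.choice(len(stages), p=stage_probs))]
        svtype = _draw_sv_type(rng, config, stage)
        chrom = str(1 + int(rng.integers(0, 22)))
        start = int(rng.integers(10_000, 100_000_000))
        if svtype == "BND":
            end = start + 1
        elif stage == "length":
            end = start + int(rng.integers(1, 50))
        else:
            end = start + int(rng.integers(50, 10_000))
        af1 = _draw_af(rng, config, "common" if stage == "af" else "rare")
        af2 = _draw_af(rng, config, "any" if stage == "af" else "rare")
        if stage == "af" and rng.random() < 0.5:
            af1, af2 = af2, af1
        if stage == "af" and not (
            (af1 is not None and af1 >= 0.01) or (af2 is not None and af2 >= 0.01)
        ):
            af1 = _draw_af(rng, config, "common")
        ranking = (int(rng.integers(1, 4)) if rng.random() < 0.8 else None) \
            if stage == "ranking" else int(rng.integers(4, 6))
        depth_ok = None
        if svtype in ("DEL", "DUP"):
            depth_ok = stage != "depth"
        sharing = _draw_sharing(rng, config)
        presence = _plant_presence(rng, sharing, groups, order)
        group = sharing.split("_", 1)[1] if "_" in sharing else "NA"
        gene = f"GENE{i % 61}" if rng.random() < 0.85 else None
        loc_labels = ("intronic", "exonic", "txStart-txEnd", "NA")
        loc = loc_labels[int(rng.choice(4, p=np.array([0.6, 0.1, 0.05, 0.25])))]
        rec = SVRecord(
            chrom=chrom, start=start, end=end, svtype=svtype,
            af_1000g=af1, af_gnomad=af2, annotsv_ranking=ranking,
            depth_validated=depth_ok, gene=gene, location=loc,
            presence=presence,
        )
        if svtype == "BND":
            if pending_mate is None:
                pending_mate = len(records)
            else:
                prev = records[pending_mate]
                prev.mate = (rec.chrom, rec.start)
                rec.mate = (prev.chrom, prev.start)
                pending_mate = None
        records.append(rec)
        truth.append(TruthRecord("", "sv", stage, sharing, group, gene or "NA"))
    # assign unique ids, then mate ids
    from .variants import _unique_sv_ids

    _unique_sv_ids(records)
    for rec, t in zip(records, truth):
        t.variant_id = rec.sv_id
    by_coord = {(r.chrom, r.start): r.sv_id for r in records if r.svtype == "BND"}
    for r in records:
        if r.svtype == "BND" and r.mate is not None:
            r.mate_id = by_coord.get(r.mate)
    return records, truth


def write_truth(truth: list[TruthRecord], path: Path, config: SimulationConfig) -> None:
    lines = [f"#config={config.to_json()}",
             "variant_id\ttrack\tfirst_failure\tsharing\tgroup\tcancer_key"]
    for t in truth:
        lines.append(f"{t.variant_id}\t{t.track}\t{t.first_failure}\t"
                     f"{t.sharing}\t{t.group}\t{t.cancer_key}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: Path) -> tuple[list[TruthRecord], dict]:
    config = None
    truth = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#config="):
            config = json.loads(line[len("#config="):])
            continue
        if line.startswith("variant_id\t") or not line.strip():
            continue
        vid, track, stage, sharing, group, key = line.split("\t")
        truth.append(TruthRecord(vid, track, stage, sharing, group, key))
    return truth, config


def simulate_cohort(config: SimulationConfig, outdir: str | Path,
                    keys: AnnotationKeys = AnnotationKeys()) -> SimulatedCohort:
    """Generate the four cohort files; deterministic given the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    groups, ped_lines = _make_subjects(config)
    order = [sid for g in RISK_GROUPS for sid in groups[g]]

    ped_path = outdir / "cohort.ped"
    header = f"# generated by riskcluster simulate; config={config.to_json()}"
    ped_path.write_text("\n".join([header] + ped_lines) + "\n")

    small_records, small_truth = _simulate_small(rng, config, groups, order)
    sv_records, sv_truth = _simulate_svs(rng, config, groups, order)

    small_vcf = outdir / "small_variants.vcf"
    sv_vcf = outdir / "svs.vcf"
    write_small_variants_vcf(small_records, small_vcf, order, keys)
    write_svs_vcf(sv_records, sv_vcf, order, keys)
    truth_path = outdir / "truth.tsv"
    write_truth(small_truth + sv_truth, truth_path, config)
    return SimulatedCohort(
        ped_path=ped_path, small_vcf=small_vcf, sv_vcf=sv_vcf,
        truth_path=truth_path, subject_order=order,
        groups={g: list(groups[g]) for g in groups},
        small_records=small_records, sv_records=sv_records,
        truth=small_truth + sv_truth,
    )
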