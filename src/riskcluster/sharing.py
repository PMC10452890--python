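"""Familial sharing classification — the "variant risk cluster" assignment.

Each prioritized variant's presence vector over the sequenced subjects is
reduced to a set of sharing classes over the three familial risk groups:

* ``shared_all_samples`` — present in every sequenced subject;
* ``shared_within_group(g)`` — present in every member of group *g*,
  independently of presence elsewhere (a variant can be shared within
  several groups at once);
* ``exclusive_to_group(g)`` — carried by at least one member of *g* and by
  nobody outside *g*;
* ``other`` — none of the above (including the degenerate case of a
  variant absent from everyone, which is flagged rather than dropped).

Exclusivity does not require all of *g* to carry the variant; the strict
variant (exclusive and shared by all of *g*) is exposed separately as
``is_exclusive_and_shared``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .pedigree import RISK_GROUPS


@dataclass(frozen=True, order=True)
class SharingClass:
    kind: str  # shared_all_samples | shared_within_group | exclusive_to_group | other
    group: str | None = None

    def __post_init__(self) -> None:
        if self.kind in ("shared_within_group", "exclusive_to_group"):
            if self.group not in RISK_GROUPS:
                raise ValueError(f"{self.kind} requires a risk-group label")
        elif self.group is not None:
            raise ValueError(f"{self.kind} carries no group")

    def __str__(self) -> str:
        return f"{self.kind}({self.group})" if self.group else self.kind


def classify_sharing(
    presence: Mapping[str, bool],
    groups: Mapping[str, Iterable[str]],
) -> set[SharingClass]:
    """Classify one presence map (subject id -> carrier flag).

    ``groups`` maps each risk-group label to its member ids; the union of
    the groups is the sequenced roster. Raises on an empty roster or a
    presence map that does not cover it.
    """
    roster = {sid for members in groups.values() for sid in members}
    if not roster:
        raise ValueError("empty subject roster")
    missing = roster - set(presence)
    if missing:
        raise ValueError(f"presence vector undefined for subjects: {sorted(missing)}")
    carriers = {sid for sid in roster if presence[sid]}

    out: set[SharingClass] = set()
    if carriers == roster:
        out.add(SharingClass("shared_all_samples"))
    for label, members in groups.items():
        members = set(members)
        if members and members <= carriers:
            out.add(SharingClass("shared_within_group", label))
        if carriers and carriers <= members:
            out.add(SharingClass("exclusive_to_group", label))
    if not out:
        out.add(SharingClass("other"))
    return out


def is_exclusive_and_shared(
    presence: Mapping[str, bool], groups: Mapping[str, Iterable[str]], label: str
) -> bool:
    """Strict exclusivity: carriers are exactly the full membership of ``label``."""
    roster = {sid for members in groups.values() for sid in members}
    carriers = {sid for sid in roster if presence[sid]}
    return bool(carriers) and carriers == set(groups[label])


def presence_map(record, subject_order: Sequence[str]) -> dict[str, bool]:
    """Zip a record's positional presence vector with the subject roster."""
    if len(record.presence) != len(subject_order):
        raise ValueError(
            f"presence vector length {len(record.presence)} != roster size {len(subject_order)}"
        )
    return dict(zip(subject_order, record.presence))


def classify_records(
    records, subject_order: Sequence[str], groups: Mapping[str, Iterable[str]],
    id_attr: str = "variant_id",
) -> dict[str, set[SharingClass]]:
    """Sharing classes for every record, keyed by its id."""
    return {
        getattr(r, id_attr): classify_sharing(presence_map(r, subject_order), groups)
        for r in records
    }


@dataclass
class SharingCounts:
    """Summary counts in the convention of the cascade tables.

    Per-group shared occurrences are summed with multiplicity: a variant
    shared within all three groups contributes one count to each.
    """

    shared_all: int = 0
    shared_within: Counter = None  # group -> count
    exclusive: Counter = None

    def __post_init__(self) -> None:
        if self.shared_within is None:
            self.shared_within = Counter({g: 0 for g in RISK_GROUPS})
        if self.exclusive is None:
            self.exclusive = Counter({g: 0 for g in RISK_GROUPS})

    @property
    def shared_within_total(self) -> int:
        return sum(self.shared_within.values())

    @property
    def exclusive_total(self) -> int:
        return sum(self.exclusive.values())


def count_by_class(sharing_by_id: Mapping[str, set[SharingClass]]) -> SharingCounts:
    counts = SharingCounts()
    for classes in sharing_by_id.values():
        for c in classes:
            if c.kind == "shared_all_samples":
                counts.shared_all += 1
            elif c.kind == "shared_within_group":
                counts.shared_within[c.group] += 1
            elif c.kind == "exclusive_to_group":
                counts.exclusive[c.group] += 1
    return counts


def write_sharing_tsv(sharing_by_id: Mapping[str, set[SharingClass]], path) -> None:
    """One row per record: id, semicolon-joined kinds, groups involved."""
    from pathlib import Path

    lines = ["variant_id\tsharing\tgroups"]
    for vid in sorted(sharing_by_id):
        classes = sorted(sharing_by_id[vid])
        kinds = ";".join(str(c) for c in classes)
        groups = ";".join(sorted({c.group for c in classes if c.group}))
        lines.append(f"{vid}\t{kinds}\t{groups or 'NA'}")
    Path(path).write_text("\n".join(lines) + "\n")
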