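"""Pedigree parsing and familial risk-group assignment.

A sequenced cohort drawn from a Lynch-syndrome pedigree is stratified into
three familial risk groups by a per-subject "immediate triplet" rule
(the subject and both parents):

* ``HRLS`` (high risk): the subject is affected.
* ``IRLS`` (intermediate risk): the subject is unaffected and at least one
  parent is affected.
* ``LRLS`` (low risk): the subject and both parents are unaffected.

Affection dominates: an affected subject is HRLS regardless of parental
status. The three labels partition the sequenced subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

RISK_GROUPS = ("HRLS", "IRLS", "LRLS")


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass
class Subject:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders. ``sequenced``
    marks the members whose genomes enter the variant analysis.
    """

    subject_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: Affection
    sequenced: bool = False


class PedigreeError(ValueError):
    """Structural pedigree defect (duplicate id, cyclic parentage, ...)."""


class UnclassifiableError(ValueError):
    """A sequenced subject cannot be assigned a risk group.

    Raised when the subject's own affection status is unknown, or the
    subject is unaffected and a parent's status is unknown (the triplet
    rule refuses to guess)."""


# PED column-6 affection codes; 0 and -9 both mean unknown.
_AFFECTION_CODES = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}
_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_MISSING_PARENT = {"0", "-9", ""}


@dataclass
class Pedigree:
    """A validated collection of subjects with resolved parent links."""

    subjects: dict[str, Subject] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects.values())

    def __getitem__(self, subject_id: str) -> Subject:
        return self.subjects[subject_id]

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.subjects

    @property
    def sequenced(self) -> list[Subject]:
        return [s for s in self if s.sequenced]

    def add(self, subject: Subject) -> None:
        if subject.subject_id in self.subjects:
            raise PedigreeError(f"duplicate subject id {subject.subject_id!r}")
        self.subjects[subject.subject_id] = subject

    def parents(self, subject: Subject) -> tuple[Subject | None, Subject | None]:
        father = self.subjects.get(subject.father_id) if subject.father_id else None
        mother = self.subjects.get(subject.mother_id) if subject.mother_id else None
        return father, mother

    def validate(self) -> None:
        """Check acyclicity of the parentage graph."""
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(sid: str, stack: list[str]) -> None:
            if state.get(sid) == 1:
                return
            if state.get(sid) == 0:
                raise PedigreeError(
                    "cyclic parentage involving " + " -> ".join(stack + [sid])
                )
            state[sid] = 0
            subj = self.subjects[sid]
            for pid in (subj.father_id, subj.mother_id):
                if pid and pid in self.subjects:
                    visit(pid, stack + [sid])
            state[sid] = 1

        for sid in self.subjects:
            visit(sid, [])


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED file (6 mandatory whitespace-separated columns).

    Columns: family, subject, father, mother, sex (1=male, 2=female),
    affection (1=unaffected, 2=affected, 0/-9=unknown). An optional 7th
    column equal to ``1`` flags the subject as sequenced. Unknown sex or
    affection codes parse as *unknown* with a logged warning. Lines that
    are empty or start with ``#`` are skipped.
    """
    ped = Pedigree()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected >= 6 columns, got {len(cols)}")
        fam, sid, fid, mid, sex_code, aff_code = cols[:6]
        sex = _SEX_CODES.get(sex_code)
        if sex is None:
            if sex_code not in _MISSING_PARENT:
                logger.warning("%s:%d: unknown sex code %r", path, lineno, sex_code)
            sex = Sex.UNKNOWN
        affected = _AFFECTION_CODES.get(aff_code)
        if affected is None:
            if aff_code not in _MISSING_PARENT:
                logger.warning("%s:%d: unknown affection code %r", path, lineno, aff_code)
            affected = Affection.UNKNOWN
        ped.add(
            Subject(
                subject_id=sid,
                family_id=fam,
                father_id=None if fid in _MISSING_PARENT else fid,
                mother_id=None if mid in _MISSING_PARENT else mid,
                sex=sex,
                affected=affected,
                sequenced=len(cols) >= 7 and cols[6] == "1",
            )
        )
    ped.validate()
    return ped


def assign_risk_group(subject: Subject, pedigree: Pedigree) -> str:
    """Assign one of HRLS / IRLS / LRLS to a sequenced subject.

    Raises :class:`UnclassifiableError` if the subject's affection is
    unknown, or the subject is unaffected and a parent's affection is
    unknown (including missing parent records for non-founders).
    """
    if subject.affected is Affection.UNKNOWN:
        raise UnclassifiableError(
            f"subject {subject.subject_id}: affection status unknown"
        )
    if subject.affected is Affection.AFFECTED:
        return "HRLS"
    father, mother = pedigree.parents(subject)
    statuses = []
    for parent, pid in ((father, subject.father_id), (mother, subject.mother_id)):
        if pid is None:
            # declared founder parent slot: no parent, contributes no affection
            statuses.append(Affection.UNAFFECTED)
        elif parent is None or parent.affected is Affection.UNKNOWN:
            raise UnclassifiableError(
                f"subject {subject.subject_id}: parent {pid!r} affection unknown"
            )
        else:
            statuses.append(parent.affected)
    if Affection.AFFECTED in statuses:
        return "IRLS"
    return "LRLS"


def assign_all(pedigree: Pedigree) -> dict[str, str]:
    """Risk-group label for every sequenced subject (deterministic order)."""
    return {s.subject_id: assign_risk_group(s, pedigree) for s in pedigree.sequenced}


def group_members(pedigree: Pedigree, label: str) -> set[str]:
    """Sequenced subject ids carrying the given risk-group label."""
    if label not in RISK_GROUPS:
        raise ValueError(f"unknown risk group {label!r}")
    return {sid for sid, g in assign_all(pedigree).items() if g == label}


def groups_map(pedigree: Pedigree) -> dict[str, set[str]]:
    """Mapping of every risk-group label to its sequenced member ids."""
    out: dict[str, set[str]] = {g: set() for g in RISK_GROUPS}
    for sid, g in assign_all(pedigree).items():
        out[g].add(sid)
    return out


def write_groups(pedigree: Pedigree, path: str | Path) -> None:
    """Write the assignment as a 2-column TSV (subject_id, group)."""
    lines = ["subject_id\tgroup"]
    lines += [f"{sid}\t{g}" for sid, g in sorted(assign_all(pedigree).items())]
    Path(path).write_text("\n".join(lines) + "\n")


def sequenced_order(pedigree: Pedigree) -> list[str]:
    """Stable subject-id order used for presence vectors (file order)."""
    return [s.subject_id for s in pedigree.sequenced]
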