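"""Pedigree parsing, validation, role inference and trio enumeration.

A pedigree is a directed acyclic graph of samples with recorded sex and
affection status.  Two sample roles matter for cosegregation analysis:

* ``in_family`` — descends from (or is) a lineage founder; affected
  in-family members are the obligate carriers of a cosegregating variant.
* ``marry_in`` — joined the pedigree by marriage; obligate non-carrier.

Roles may be given explicitly (7th PED column, ``IN``/``MARRY``) or
inferred: a founder (no parents listed) who co-parents with a non-founder
married into the lineage; every other sample is in-family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError

MISSING_PARENT = "0"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    CASE = "case"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Role(str, Enum):
    IN_FAMILY = "in_family"
    MARRY_IN = "marry_in"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_AFFECTION_CODES = {
    "1": Affection.UNAFFECTED,
    "2": Affection.CASE,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_ROLE_CODES = {"IN": Role.IN_FAMILY, "MARRY": Role.MARRY_IN}


@dataclass
class Sample:
    sample_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affection: Affection
    role: Role | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Trio:
    child_id: str
    father_id: str
    mother_id: str


@dataclass
class Pedigree:
    family_id: str
    samples: dict[str, Sample] = field(default_factory=dict)
    # Samples actually present in the genotype data; defaults to all members.
    sequenced_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequenced_ids:
            self.sequenced_ids = set(self.samples)

    def add(self, sample: Sample) -> None:
        if sample.sample_id in self.samples:
            raise ValidationError(
                f"duplicate sample_id {sample.sample_id!r} in family {self.family_id!r}"
            )
        self.samples[sample.sample_id] = sample
        self.sequenced_ids.add(sample.sample_id)

    # -- queries -----------------------------------------------------------
    def members(self) -> list[Sample]:
        return list(self.samples.values())

    def sequenced(self) -> list[Sample]:
        return [s for s in self.samples.values() if s.sample_id in self.sequenced_ids]

    def cases(self, sequenced_only: bool = True) -> list[Sample]:
        pool = self.sequenced() if sequenced_only else self.members()
        return [s for s in pool if s.affection is Affection.CASE]

    def children_of(self, sample_id: str) -> list[Sample]:
        return [
            s
            for s in self.samples.values()
            if sample_id in (s.father_id, s.mother_id)
        ]

    def co_parents(self, sample_id: str) -> set[str]:
        out: set[str] = set()
        for child in self.children_of(sample_id):
            for pid in (child.father_id, child.mother_id):
                if pid is not None and pid != sample_id:
                    out.add(pid)
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check parent sex consistency and acyclicity."""
        for s in self.samples.values():
            for pid, want in ((s.father_id, Sex.MALE), (s.mother_id, Sex.FEMALE)):
                if pid is None or pid not in self.samples:
                    continue  # explicitly absent parent is allowed
                psex = self.samples[pid].sex
                if psex is not Sex.UNKNOWN and psex is not want:
                    raise ValidationError(
                        f"{s.sample_id}: parent {pid} has sex {psex.value}, "
                        f"expected {want.value}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {sid: WHITE for sid in self.samples}

        def parents(sid: str) -> list[str]:
            s = self.samples[sid]
            return [p for p in (s.father_id, s.mother_id) if p in self.samples]

        for start in self.samples:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            color[start] = GREY
            while stack:
                sid, idx = stack[-1]
                ps = parents(sid)
                if idx < len(ps):
                    stack[-1] = (sid, idx + 1)
                    p = ps[idx]
                    if color[p] == GREY:
                        raise ValidationError(
                            f"pedigree cycle involving {p!r} in family {self.family_id!r}"
                        )
                    if color[p] == WHITE:
                        color[p] = GREY
                        stack.append((p, 0))
                else:
                    color[sid] = BLACK
                    stack.pop()


# ---------------------------------------------------------------------------
# PED I/O


def _parse_line(fields: list[str], path: str, lineno: int) -> Sample:
    fam, sid, fid, mid, sex_code, aff_code = fields[:6]
    if sid == MISSING_PARENT:
        raise ParseError("sample_id '0' is reserved for missing parents", path, lineno)
    if sid in (fid, mid):
        raise ValidationError(f"sample {sid!r} listed as its own parent (line {lineno})")
    if aff_code not in _AFFECTION_CODES:
        raise ParseError(
            f"unrecognized affection code {aff_code!r} (expected 1/2/0/-9)", path, lineno
        )
    role = None
    if len(fields) >= 7 and fields[6]:
        code = fields[6].upper()
        if code not in _ROLE_CODES:
            raise ParseError(
                f"unrecognized role {fields[6]!r} (expected IN or MARRY)", path, lineno
            )
        role = _ROLE_CODES[code]
    return Sample(
        sample_id=sid,
        family_id=fam,
        father_id=None if fid == MISSING_PARENT else fid,
        mother_id=None if mid == MISSING_PARENT else mid,
        sex=_SEX_CODES.get(sex_code, Sex.UNKNOWN),
        affection=_AFFECTION_CODES[aff_code],
        role=role,
    )


def parse_ped(path: str | Path) -> list[Pedigree]:
    """Parse a whitespace-delimited PED file into per-family pedigrees.

    Columns: family, sample, father, mother, sex (1/2/0), affection
    (1=unaffected, 2=case, 0/-9=unknown), optional role (IN/MARRY).
    Returns pedigrees sorted by family_id; each is validated (unique ids,
    parent sex consistency, acyclicity).
    """
    path = Path(path)
    pedigrees: dict[str, Pedigree] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"expected >=6 whitespace-delimited columns, got {len(fields)}",
                    str(path),
                    lineno,
                )
            sample = _parse_line(fields, str(path), lineno)
            ped = pedigrees.setdefault(sample.family_id, Pedigree(sample.family_id, {}, set()))
            ped.add(sample)
    out = [pedigrees[fam] for fam in sorted(pedigrees)]
    for ped in out:
        ped.validate()
    return out


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.UNAFFECTED: "1", Affection.CASE: "2", Affection.UNKNOWN: "0"}
    role_out = {Role.IN_FAMILY: "IN", Role.MARRY_IN: "MARRY", None: ""}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for s in ped.members():
                cols = [
                    s.family_id,
                    s.sample_id,
                    s.father_id or MISSING_PARENT,
                    s.mother_id or MISSING_PARENT,
                    sex_out[s.sex],
                    aff_out[s.affection],
                ]
                if s.role is not None:
                    cols.append(role_out[s.role])
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Role inference


def infer_roles(ped: Pedigree, explicit: Mapping[str, Role] | None = None) -> Pedigree:
    """Assign in_family / marry_in roles to every sample.

    Explicit assignments (7th PED column or the ``explicit`` map) always win.
    The inference fallback: a founder who co-parents with a *non-founder*
    married into the lineage; all other samples (non-founders, and founder
    couples at the top of the pedigree) are in-family.
    """
    explicit = dict(explicit or {})
    for sid, role in explicit.items():
        if sid not in ped.samples:
            raise ValidationError(f"explicit role for unknown sample {sid!r}")
        given = ped.samples[sid].role
        if given is not None and given is not role:
            raise ValidationError(
                f"conflicting explicit roles for {sid!r}: {given.value} vs {role.value}"
            )
    for s in ped.samples.values():
        if s.sample_id in explicit:
            s.role = explicit[s.sample_id]
        elif s.role is None:
            s.role = _infer_one(ped, s)
    return ped


def _infer_one(ped: Pedigree, s: Sample) -> Role:
    if not s.is_founder:
        return Role.IN_FAMILY
    partners = ped.co_parents(s.sample_id)
    if partners and any(
        pid in ped.samples and not ped.samples[pid].is_founder for pid in partners
    ):
        return Role.MARRY_IN
    return Role.IN_FAMILY


# ---------------------------------------------------------------------------
# Trio enumeration


def enumerate_trios(ped: Pedigree) -> list[Trio]:
    """One trio per sample whose two parents are both pedigree members and
    all three individuals are sequenced."""
    trios = []
    for s in ped.members():
        if s.sample_id not in ped.sequenced_ids:
            continue
        if s.father_id in ped.samples and s.mother_id in ped.samples:
            if s.father_id in ped.sequenced_ids and s.mother_id in ped.sequenced_ids:
                trios.append(Trio(s.sample_id, s.father_id, s.mother_id))
    return trios


def exclude_samples(pedigrees: Iterable[Pedigree], drop: Iterable[str]) -> list[Pedigree]:
    """Remove named samples from pedigrees (QC exclusions: failed sequencing,
    relatedness discordance).  Children of a removed sample keep it as an
    explicitly-absent parent reference."""
    drop = set(drop)
    out = []
    for ped in pedigrees:
        kept = {sid: replace(s) for sid, s in ped.samples.items() if sid not in drop}
        out.append(
            Pedigree(ped.family_id, kept, {sid for sid in ped.sequenced_ids if sid in kept})
        )
    return out
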