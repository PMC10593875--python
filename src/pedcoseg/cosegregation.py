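"""Family-private screening, Mendelian consistency and cosegregation patterns.

A variant is *family-private* when every usable carrier in the cohort sits in
exactly one pedigree.  Within that pedigree the genotype configuration is
classified as

* ``full``    — every sequenced in-family case carries the alt allele, and no
                in-family control or marry-in sample carries it;
* ``reduced`` — exactly one sequenced in-family case does not carry it,
                everything else as in ``full``;
* ``none``    — anything else.

Carriage is dominant (het and hom-alt count equally).  Under the default
strict policy a required carrier must be affirmatively genotyped as a
carrier and a required non-carrier affirmatively genotyped as homozygous
reference: a masked or missing genotype in a constrained role disqualifies
the pattern.  ``lenient`` treats missing genotypes as compatible with any
requirement.  Samples with unknown affection follow ``unknown_policy``:
``ignore`` (default) places no constraint on them; ``treat_as_control``
requires them to be non-carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product

import numpy as np

from .errors import ConfigurationError
from .pedigree import Affection, Pedigree, Role, Trio, Sex
from .variant_qc import MISSING, SiteGenotypes

# ---------------------------------------------------------------------------


class Pattern(str, Enum):
    FULL = "full"
    REDUCED = "reduced"
    NONE = "none"


class ChromClass(str, Enum):
    AUTOSOME = "autosome"
    CHRX = "chrX"
    CHRY = "chrY"


def chrom_class(chrom: str) -> ChromClass:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.upper() == "X":
        return ChromClass.CHRX
    if name.upper() == "Y":
        return ChromClass.CHRY
    return ChromClass.AUTOSOME


@dataclass(frozen=True)
class CosegregationConfig:
    strict: bool = True
    unknown_policy: str = "ignore"  # "ignore" | "treat_as_control"
    min_cases_reduced: int = 3

    def __post_init__(self) -> None:
        if self.unknown_policy not in ("ignore", "treat_as_control"):
            raise ConfigurationError("unknown_policy must be 'ignore' or 'treat_as_control'")
        if self.min_cases_reduced < 2:
            raise ConfigurationError("min_cases_reduced must be >= 2")


@dataclass
class CosegregationResult:
    key: tuple[str, int, str, str]
    family_id: str
    pattern: Pattern
    carrier_cases: set[str] = field(default_factory=set)
    noncarrier_cases: set[str] = field(default_factory=set)
    carrier_controls: set[str] = field(default_factory=set)
    carrier_marryins: set[str] = field(default_factory=set)
    n_missing_relevant: int = 0


# ---------------------------------------------------------------------------
# Family-private screen


def find_family_private(
    geno: SiteGenotypes, sample_families: np.ndarray
) -> str | None:
    """Return the unique family holding all usable carriers, or None.

    ``sample_families`` is an array of family ids parallel to the call set's
    sample list.  Zero carriers anywhere also yields None.
    """
    carriers = geno.usable_carrier()
    fams = np.unique(sample_families[carriers])
    if fams.size == 1:
        return str(fams[0])
    return None


# ---------------------------------------------------------------------------
# Mendelian consistency

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _transmissible(g: int) -> tuple[int, ...]:
    return tuple(sorted(set(_ALLELES[g])))


def _autosomal_consistent(gf: int, gm: int, gc: int) -> bool:
    child = _ALLELES[gc]
    for fa in _transmissible(gf):
        for ma in _transmissible(gm):
            if tuple(sorted((fa, ma))) == child:
                return True
    return False


# Precomputed 27-entry lookup; index = gf*9 + gm*3 + gc.
_AUTOSOMAL_TABLE = np.array(
    [
        _autosomal_consistent(gf, gm, gc)
        for gf, gm, gc in product(range(3), range(3), range(3))
    ],
    dtype=bool,
)


def _hemizygous_allele(g: int) -> int | None:
    """Dosage -> single allele for a hemizygous genotype; het is invalid."""
    return {0: 0, 2: 1}.get(g)


def trio_consistent(
    gf: int, gm: int, gc: int, cclass: ChromClass, child_sex: Sex
) -> bool:
    """Mendelian consistency of one trio's unmasked genotypes.

    Autosomes: the child's two alleles must be drawable one from each parent.
    chrX: a male child is hemizygous and draws his single allele from the
    mother; a female child draws the father's single X allele plus one
    maternal allele; a het-coded hemizygous genotype is a violation.
    chrY: father-to-son transmission of the single allele; females carry no Y.
    """
    if cclass is ChromClass.AUTOSOME:
        return bool(_AUTOSOMAL_TABLE[gf * 9 + gm * 3 + gc])
    if cclass is ChromClass.CHRX:
        if child_sex is Sex.MALE:
            a = _hemizygous_allele(gc)
            if a is None:
                return False
            return a in _transmissible(gm)
        fa = _hemizygous_allele(gf)
        if fa is None:
            return False
        return any(tuple(sorted((fa, ma))) == _ALLELES[gc] for ma in _transmissible(gm))
    # chrY
    if child_sex is not Sex.MALE:
        return gc == 0  # a female carrying a Y alt is a violation
    a, fa = _hemizygous_allele(gc), _hemizygous_allele(gf)
    if a is None or fa is None:
        return False
    return a == fa


def mendelian_consistent(
    geno: SiteGenotypes,
    trios: list[tuple[Trio, int, int, int, Sex]],
    cclass: ChromClass = ChromClass.AUTOSOME,
) -> tuple[bool, list[Trio]]:
    """Screen all trios at one site; a trio with any masked or missing member
    is skipped.  ``trios`` carries (Trio, child_idx, father_idx, mother_idx,
    child_sex) with indices into the call set's sample order.
    Returns (no_violation, violating_trios)."""
    violations = []
    ac, masked = geno.ac, geno.masked
    for trio, ci, fi, mi in _iter_idx(trios):
        trio_obj, child_sex = trio
        gs = (int(ac[fi]), int(ac[mi]), int(ac[ci]))
        if MISSING in gs or masked[ci] or masked[fi] or masked[mi]:
            continue
        if not trio_consistent(gs[0], gs[1], gs[2], cclass, child_sex):
            violations.append(trio_obj)
    return (not violations, violations)


def _iter_idx(trios):
    for trio, ci, fi, mi, sex in trios:
        yield (trio, sex), ci, fi, mi


def index_trios(
    ped: Pedigree, trios: list[Trio], sample_index: dict[str, int]
) -> list[tuple[Trio, int, int, int, Sex]]:
    """Attach call-set column indices and child sex to each trio."""
    out = []
    for t in trios:
        if not all(sid in sample_index for sid in (t.child_id, t.father_id, t.mother_id)):
            continue
        out.append(
            (
                t,
                sample_index[t.child_id],
                sample_index[t.father_id],
                sample_index[t.mother_id],
                ped.samples[t.child_id].sex,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pattern classification


def classify_pattern(
    key: tuple[str, int, str, str],
    geno: SiteGenotypes,
    ped: Pedigree,
    sample_index: dict[str, int],
    cfg: CosegregationConfig | None = None,
) -> CosegregationResult:
    """Classify one family-private variant's cosegregation pattern.

    Obligate carriers: sequenced in-family cases.  Obligate non-carriers:
    sequenced in-family controls, marry-in samples of any affection, and —
    under ``unknown_policy='treat_as_control'`` — in-family unknowns.
    """
    cfg = cfg or CosegregationConfig()
    res = CosegregationResult(key=key, family_id=ped.family_id, pattern=Pattern.NONE)

    cases, controls, marryins = [], [], []
    for s in ped.sequenced():
        if s.sample_id not in sample_index:
            continue
        if s.role is Role.MARRY_IN:
            marryins.append(s.sample_id)
        elif s.affection is Affection.CASE:
            cases.append(s.sample_id)
        elif s.affection is Affection.UNAFFECTED:
            controls.append(s.sample_id)
        elif cfg.unknown_policy == "treat_as_control":
            controls.append(s.sample_id)
    if not cases:
        raise ConfigurationError(
            f"family {ped.family_id!r} has no sequenced cases; cosegregation undefined"
        )

    def state(sid: str) -> str:
        i = sample_index[sid]
        if geno.ac[i] == MISSING or geno.masked[i]:
            return "missing"
        return "carrier" if geno.ac[i] >= 1 else "noncarrier"

    n_missing = 0
    ok_required = True  # no constrained non-carrier (control/marry-in) carries
    for sid in controls:
        st = state(sid)
        if st == "carrier":
            res.carrier_controls.add(sid)
            ok_required = False
        elif st == "missing":
            n_missing += 1
            if cfg.strict:
                ok_required = False
    for sid in marryins:
        st = state(sid)
        if st == "carrier":
            res.carrier_marryins.add(sid)
            ok_required = False
        elif st == "missing":
            n_missing += 1
            if cfg.strict:
                ok_required = False

    case_missing = 0
    for sid in cases:
        st = state(sid)
        if st == "carrier":
            res.carrier_cases.add(sid)
        elif st == "noncarrier":
            res.noncarrier_cases.add(sid)
        else:
            case_missing += 1
            n_missing += 1
    res.n_missing_relevant = n_missing

    if not ok_required or (cfg.strict and case_missing > 0):
        return res
    # Under lenient policy a missing case genotype is compatible with
    # carrying, so only the affirmatively genotyped cases are constrained.
    n_required = len(cases) - case_missing
    n_noncarrier = len(res.noncarrier_cases)
    if n_noncarrier == 0 and len(res.carrier_cases) == n_required and n_required > 0:
        res.pattern = Pattern.FULL
    elif (
        n_noncarrier == 1
        and len(res.carrier_cases) == n_required - 1
        and len(cases) >= cfg.min_cases_reduced
    ):
        res.pattern = Pattern.REDUCED
    return res
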