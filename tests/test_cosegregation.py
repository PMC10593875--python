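"""Family-private screen, Mendelian checking, cosegregation patterns."""

import itertools

import numpy as np
import pytest

from pedcoseg.cosegregation import (
    ChromClass,
    CosegregationConfig,
    Pattern,
    chrom_class,
    classify_pattern,
    find_family_private,
    index_trios,
    mendelian_consistent,
    trio_consistent,
)
from pedcoseg.errors import ConfigurationError
from pedcoseg.pedigree import (
    Affection,
    Pedigree,
    Role,
    Sample,
    Sex,
    Trio,
    enumerate_trios,
)
from pedcoseg.variant_qc import MISSING, SiteGenotypes


def make_geno(ac, masked=None):
    ac = np.asarray(ac, dtype=np.int8)
    n = ac.size
    return SiteGenotypes(
        ac=ac,
        gq=np.full(n, 99.0, np.float32),
        dp=np.full(n, 30.0, np.float32),
        masked=np.zeros(n, bool) if masked is None else np.asarray(masked, bool),
    )


# ---------------------------------------------------------------------------
# family-private


def test_private_single_family():
    fams = np.array(["K1546"] * 3 + ["K1494"] * 3)
    assert find_family_private(make_geno([0, 1, 1, 0, 0, 0]), fams) == "K1546"


def test_private_two_families_is_none():
    fams = np.array(["A", "A", "B", "B"])
    assert find_family_private(make_geno([1, 0, 1, 0]), fams) is None


def test_private_no_carriers_is_none():
    fams = np.array(["A", "B"])
    assert find_family_private(make_geno([0, 0]), fams) is None


def test_private_masked_carrier_does_not_count():
    fams = np.array(["A", "B"])
    g = make_geno([1, 1], masked=[True, False])
    assert find_family_private(g, fams) == "B"


def test_private_random_matches_cardinality_oracle(rng):
    fams = np.array([f"F{i}" for i in range(6) for _ in range(6)])
    for _ in range(300):
        ac = rng.integers(0, 3, fams.size).astype(np.int8)
        ac[rng.random(fams.size) < 0.7] = 0
        got = find_family_private(make_geno(ac), fams)
        carrier_fams = {fams[i] for i in range(fams.size) if ac[i] >= 1}
        expected = next(iter(carrier_fams)) if len(carrier_fams) == 1 else None
        assert got == expected


# ---------------------------------------------------------------------------
# Mendelian screen


def autosomal_oracle(gf, gm, gc):
    """Enumerate transmissions: one allele from each parent."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    child = tuple(sorted(alleles[gc]))
    return any(
        tuple(sorted((fa, ma))) == child
        for fa in alleles[gf]
        for ma in alleles[gm]
    )


def test_autosomal_exhaustive_27_combinations():
    for gf, gm, gc in itertools.product(range(3), repeat=3):
        assert trio_consistent(gf, gm, gc, ChromClass.AUTOSOME, Sex.MALE) == (
            autosomal_oracle(gf, gm, gc)
        ), (gf, gm, gc)


def test_de_novo_pattern_is_violation():
    assert not trio_consistent(0, 0, 1, ChromClass.AUTOSOME, Sex.FEMALE)


def test_het_parent_transmission_consistent():
    assert trio_consistent(1, 0, 1, ChromClass.AUTOSOME, Sex.MALE)


def test_chrx_male_child_from_mother_only():
    # carrier father, non-carrier mother: son cannot carry
    assert not trio_consistent(2, 0, 2, ChromClass.CHRX, Sex.MALE)
    assert trio_consistent(0, 1, 2, ChromClass.CHRX, Sex.MALE)
    # het-coded male X is itself a violation
    assert not trio_consistent(0, 1, 1, ChromClass.CHRX, Sex.MALE)


def test_chrx_female_child_gets_paternal_allele():
    assert trio_consistent(2, 0, 1, ChromClass.CHRX, Sex.FEMALE)
    assert not trio_consistent(2, 0, 0, ChromClass.CHRX, Sex.FEMALE)


def test_chry_father_to_son():
    assert trio_consistent(2, 0, 2, ChromClass.CHRY, Sex.MALE)
    assert not trio_consistent(0, 0, 2, ChromClass.CHRY, Sex.MALE)
    assert trio_consistent(2, 0, 0, ChromClass.CHRY, Sex.FEMALE)  # no Y in females
    assert not trio_consistent(2, 0, 2, ChromClass.CHRY, Sex.FEMALE)


def test_chrom_class():
    assert chrom_class("chrX") is ChromClass.CHRX
    assert chrom_class("Y") is ChromClass.CHRY
    assert chrom_class("chr12") is ChromClass.AUTOSOME


def _trio_fixture(gf, gm, gc, masked=(False, False, False)):
    ped = Pedigree(
        "F",
        {
            "C": Sample("C", "F", "D", "M", Sex.MALE, Affection.CASE),
            "D": Sample("D", "F", None, None, Sex.MALE, Affection.UNKNOWN),
            "M": Sample("M", "F", None, None, Sex.FEMALE, Affection.UNKNOWN),
        },
        set(),
    )
    sample_index = {"C": 0, "D": 1, "M": 2}
    trios = index_trios(ped, enumerate_trios(ped), sample_index)
    geno = make_geno([gc, gf, gm], masked=list(masked))
    return geno, trios


def test_mendelian_violating_trio_reported():
    geno, trios = _trio_fixture(0, 0, 1)
    ok, violations = mendelian_consistent(geno, trios)
    assert not ok
    assert [v.child_id for v in violations] == ["C"]


def test_mendelian_masked_member_skips_trio():
    geno, trios = _trio_fixture(0, 0, 1, masked=(False, True, False))
    ok, violations = mendelian_consistent(geno, trios)
    assert ok and violations == []


def test_mendelian_missing_member_skips_trio():
    geno, trios = _trio_fixture(0, MISSING, 1)
    ok, _ = mendelian_consistent(geno, trios)
    assert ok


# ---------------------------------------------------------------------------
# pattern classification


def build_pedigree(n_cases, n_controls, n_marryins):
    samples = {}
    for i in range(n_cases):
        sid = f"CASE{i}"
        samples[sid] = Sample(sid, "F", None, None, Sex.MALE, Affection.CASE, Role.IN_FAMILY)
    for i in range(n_controls):
        sid = f"CTRL{i}"
        samples[sid] = Sample(sid, "F", None, None, Sex.FEMALE, Affection.UNAFFECTED, Role.IN_FAMILY)
    for i in range(n_marryins):
        sid = f"MARRY{i}"
        samples[sid] = Sample(sid, "F", None, None, Sex.FEMALE, Affection.UNAFFECTED, Role.MARRY_IN)
    return Pedigree("F", samples, set())


KEY = ("chr1", 100, "A", "G")


def classify(ped, ac, masked=None, cfg=None):
    index = {sid: i for i, sid in enumerate(ped.samples)}
    return classify_pattern(KEY, make_geno(ac, masked), ped, index, cfg)


def test_full_pattern_all_cases_carry():
    ped = build_pedigree(4, 2, 1)
    res = classify(ped, [1, 1, 1, 1, 0, 0, 0])
    assert res.pattern is Pattern.FULL
    assert len(res.carrier_cases) == 4


def test_reduced_pattern_exactly_one_noncarrier_case():
    ped = build_pedigree(5, 1, 1)
    res = classify(ped, [1, 1, 1, 1, 0, 0, 0])
    assert res.pattern is Pattern.REDUCED
    assert res.noncarrier_cases == {"CASE4"}


def test_control_carrier_breaks_pattern():
    ped = build_pedigree(4, 2, 1)
    res = classify(ped, [1, 1, 1, 1, 1, 0, 0])
    assert res.pattern is Pattern.NONE
    assert res.carrier_controls == {"CTRL0"}


def test_marryin_carrier_breaks_pattern():
    ped = build_pedigree(4, 0, 1)
    res = classify(ped, [1, 1, 1, 1, 1])
    assert res.pattern is Pattern.NONE
    assert res.carrier_marryins == {"MARRY0"}


def test_masked_carrier_case_degrades_full_to_none():
    """Under strict policy a masked case genotype is not a non-carrier: the
    pattern collapses to none, never to reduced."""
    ped = build_pedigree(4, 1, 1)
    full = classify(ped, [1, 1, 1, 1, 0, 0])
    assert full.pattern is Pattern.FULL
    degraded = classify(ped, [1, 1, 1, 1, 0, 0], masked=[1, 0, 0, 0, 0, 0])
    assert degraded.pattern is Pattern.NONE


def test_lenient_mode_tolerates_missing_case():
    ped = build_pedigree(4, 1, 1)
    cfg = CosegregationConfig(strict=False)
    res = classify(ped, [MISSING, 1, 1, 1, 0, 0], cfg=cfg)
    assert res.pattern is Pattern.FULL


def test_reduced_requires_min_cases():
    ped = build_pedigree(2, 1, 1)
    res = classify(ped, [1, 0, 0, 0])  # "all but one" of 2 degenerates
    assert res.pattern is Pattern.NONE


def test_zero_cases_raises():
    ped = build_pedigree(0, 2, 1)
    with pytest.raises(ConfigurationError):
        classify(ped, [0, 0, 0])


def test_hom_alt_counts_as_carrier():
    ped = build_pedigree(3, 1, 0)
    res = classify(ped, [2, 1, 1, 0])
    assert res.pattern is Pattern.FULL


def test_unknown_policy_ignore_vs_control():
    ped = build_pedigree(3, 0, 0)
    ped.samples["UNK"] = Sample("UNK", "F", None, None, Sex.MALE, Affection.UNKNOWN, Role.IN_FAMILY)
    ped.sequenced_ids.add("UNK")
    res = classify(ped, [1, 1, 1, 1])
    assert res.pattern is Pattern.FULL  # unknown carrier ignored
    res2 = classify(ped, [1, 1, 1, 1], cfg=CosegregationConfig(unknown_policy="treat_as_control"))
    assert res2.pattern is Pattern.NONE


def test_extra_noncarrier_control_never_degrades():
    ped = build_pedigree(4, 1, 1)
    base = classify(ped, [1, 1, 1, 1, 0, 0])
    ped2 = build_pedigree(4, 2, 1)
    more = classify(ped2, [1, 1, 1, 1, 0, 0, 0])
    assert base.pattern is more.pattern is Pattern.FULL


def brute_force_pattern(ped, ac, masked, cfg):
    """Direct predicate evaluation of the pattern definitions."""
    state = {}
    for i, sid in enumerate(ped.samples):
        if ac[i] == MISSING or masked[i]:
            state[sid] = "missing"
        else:
            state[sid] = "carrier" if ac[i] >= 1 else "non"
    cases = [s.sample_id for s in ped.sequenced()
             if s.role is not Role.MARRY_IN and s.affection is Affection.CASE]
    controls = [s.sample_id for s in ped.sequenced()
                if s.role is not Role.MARRY_IN and s.affection is Affection.UNAFFECTED]
    if cfg.unknown_policy == "treat_as_control":
        controls += [s.sample_id for s in ped.sequenced()
                     if s.role is not Role.MARRY_IN and s.affection is Affection.UNKNOWN]
    marryins = [s.sample_id for s in ped.sequenced() if s.role is Role.MARRY_IN]
    noncarrier_roles = controls + marryins
    if any(state[sid] == "carrier" for sid in noncarrier_roles):
        return Pattern.NONE
    if cfg.strict and any(state[sid] == "missing" for sid in noncarrier_roles + cases):
        return Pattern.NONE
    typed = [sid for sid in cases if state[sid] != "missing"]
    n_carrier = sum(state[sid] == "carrier" for sid in typed)
    if typed and n_carrier == len(typed):
        return Pattern.FULL
    if n_carrier == len(typed) - 1 and len(cases) >= cfg.min_cases_reduced:
        return Pattern.REDUCED
    return Pattern.NONE


@pytest.mark.parametrize("strict", [True, False])
def test_classification_matches_brute_force_oracle(rng, strict):
    cfg = CosegregationConfig(strict=strict)
    for _ in range(400):
        ped = build_pedigree(
            int(rng.integers(1, 7)), int(rng.integers(0, 4)), int(rng.integers(0, 3))
        )
        n = len(ped.samples)
        ac = rng.integers(0, 3, n).astype(np.int8)
        ac[rng.random(n) < 0.1] = MISSING
        masked = rng.random(n) < 0.1
        got = classify(ped, ac, masked=masked, cfg=cfg)
        expected = brute_force_pattern(ped, ac, masked, cfg)
        assert got.pattern is expected, (list(ac), list(masked), strict)


def test_planted_patterns_classify_correctly(small_dataset):
    """Generator-planted full/reduced variants classify as planted, with
    probability 1 under zero artifact rates."""
    idx = {sid: i for i, sid in enumerate(small_dataset.sample_order)}
    peds = {p.family_id: p for p in small_dataset.pedigrees}
    truth = {(t.chrom, t.pos, t.ref, t.alt): t for t in small_dataset.truth.variants}
    checked = 0
    for site in small_dataset.sites:
        key = (site.chrom, site.pos, site.ref, site.alt)
        if key not in truth:
            continue
        t = truth[key]
        geno = make_geno(site.dosage)
        res = classify_pattern(key, geno, peds[t.family], idx)
        assert res.pattern.value == t.pattern
        checked += 1
    assert checked == len(small_dataset.truth.variants)
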