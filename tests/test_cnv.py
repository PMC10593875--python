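"""CNV consensus merging and family-aware filtering."""

import itertools

import numpy as np
import pytest

from pedcoseg.cnv import (
    CnvCall,
    CnvCluster,
    RiskLocus,
    breakpoint_support_filter,
    collapse_within,
    covered_length,
    merge_consensus,
    normalize_svtype,
    pedigree_support_filter,
    reciprocal_overlap,
    repeat_fraction,
    repeat_fraction_filter,
    screen_known_loci,
    union_intervals,
)
from pedcoseg.errors import ValidationError


def call(start, end, caller="cnvnator", sample="S1", svtype="DEL", chrom="chr1", sf=None):
    return CnvCall(sample, chrom, start, end, svtype, caller, sf)


def cluster(start, end, members, svtype="DEL", chrom="chr1", family=None, route=None):
    c = CnvCluster(chrom, start, end, svtype, members, family)
    c.support_route = route
    return c


# ---------------------------------------------------------------------------
# reciprocal overlap


def test_ro_identity():
    assert reciprocal_overlap((0, 100), (0, 100)) == 1.0


def test_ro_closed_form():
    assert reciprocal_overlap((0, 100), (50, 150)) == 0.5


def test_ro_disjoint():
    assert reciprocal_overlap((0, 100), (100, 200)) == 0.0


def test_ro_empty_interval_rejected():
    with pytest.raises(ValidationError):
        reciprocal_overlap((5, 5), (0, 10))


def test_ro_matches_arithmetic_oracle(rng):
    for _ in range(500):
        a0 = int(rng.integers(0, 1000)); a1 = a0 + int(rng.integers(1, 500))
        b0 = int(rng.integers(0, 1000)); b1 = b0 + int(rng.integers(1, 500))
        ov = max(0, min(a1, b1) - max(a0, b0))
        expected = min(ov / (a1 - a0), ov / (b1 - b0)) if ov else 0.0
        assert reciprocal_overlap((a0, a1), (b0, b1)) == pytest.approx(expected)


def test_svtype_normalization():
    assert normalize_svtype("deletion") == "DEL"
    assert normalize_svtype("Gain") == "DUP"
    with pytest.raises(ValidationError):
        normalize_svtype("INV")


# ---------------------------------------------------------------------------
# collapse


def test_collapse_disjoint_unchanged():
    calls = [call(0, 100), call(500, 600)]
    assert len(collapse_within(calls)) == 2


def test_collapse_three_mutually_overlapping_to_union():
    calls = [call(0, 100), call(20, 120), call(40, 140)]
    out = collapse_within(calls)
    assert len(out) == 1
    assert (out[0].start, out[0].end) == (0, 140)


def test_collapse_different_callers_kept_separate():
    calls = [call(0, 100, "cnvnator"), call(0, 100, "erds")]
    assert len(collapse_within(calls)) == 2


def transitive_closure_clusters(spans):
    """Union-find over the >=0.5 reciprocal-overlap graph of the raw spans."""
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(spans)), 2):
        if reciprocal_overlap(spans[i], spans[j]) >= 0.5:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(spans)):
        groups.setdefault(find(i), []).append(spans[i])
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )


def test_collapse_matches_transitive_closure_oracle(rng):
    """On clustered random call sets the iterative union-merge fixpoint
    equals the transitive closure of the pairwise >=0.5 overlap graph."""
    for _ in range(100):
        spans = []
        for _ in range(int(rng.integers(2, 6))):  # well-separated cluster seeds
            anchor = int(rng.integers(0, 20)) * 10_000
            size = int(rng.integers(500, 1500))
            for _ in range(int(rng.integers(1, 4))):
                jitter = int(rng.integers(-100, 100))
                spans.append((anchor + jitter, anchor + size + jitter))
        calls = [call(s, e) for s, e in spans]
        out = collapse_within(calls)
        got = sorted((c.start, c.end) for c in out)
        assert got == transitive_closure_clusters(spans)


def test_collapse_chain_merges_left_to_right():
    """A chain where each neighbor pair overlaps >=50% but the growing union
    dilutes the overlap: the left pair merges, the widened union no longer
    reaches the third call (reciprocal overlap of (0,140) vs (80,180) is
    60/140 < 0.5), which therefore stays separate at the fixpoint."""
    calls = [call(0, 100), call(40, 140), call(80, 180)]
    out = collapse_within(calls)
    spans = sorted((c.start, c.end) for c in out)
    assert spans == [(0, 140), (80, 180)]


def test_collapse_idempotent(rng):
    spans = [(int(s), int(s) + 800) for s in rng.integers(0, 50_000, size=20)]
    once = collapse_within([call(s, e) for s, e in spans])
    twice = collapse_within(once)
    assert [(c.start, c.end) for c in once] == [(c.start, c.end) for c in twice]


# ---------------------------------------------------------------------------
# two-stage consensus


def test_consensus_four_callers_single_cluster():
    calls = [call(0, 1000, c) for c in ("cnvnator", "erds", "lumpy", "manta")]
    out = merge_consensus(calls)
    assert len(out) == 1
    assert out[0].callers == {"cnvnator", "erds", "lumpy", "manta"}


def test_consensus_type_mismatch_not_merged():
    calls = [call(0, 1000, "cnvnator", svtype="DEL"), call(0, 1000, "lumpy", svtype="DUP")]
    out = merge_consensus(calls)
    assert len(out) == 2


def test_consensus_preserves_every_input_call():
    calls = [call(0, 1000, "cnvnator"), call(100, 1100, "erds"), call(5000, 6000, "manta")]
    out = merge_consensus(calls)
    assert sum(len(c.members) for c in out) == len(calls)


def test_consensus_samples_not_merged_together():
    calls = [call(0, 1000, "cnvnator", "S1"), call(0, 1000, "cnvnator", "S2")]
    assert len(merge_consensus(calls)) == 2


def test_two_stage_matches_single_stage_on_generated_data(rng):
    """With tight per-event call placement, the two-stage (within-class then
    between-class) merge yields the same clustering as one global stage."""
    for _ in range(50):
        calls = []
        for _ in range(int(rng.integers(1, 5))):
            anchor = int(rng.integers(0, 10)) * 50_000
            size = int(rng.integers(2_000, 8_000))
            for caller in ("cnvnator", "erds", "lumpy", "manta"):
                if rng.random() < 0.8:
                    j = int(rng.integers(-50, 50))
                    calls.append(call(anchor + j, anchor + size + j, caller))
        if not calls:
            continue
        two_stage = merge_consensus(calls)
        single = collapse_within(calls)  # per-caller collapse, no-op here
        spans = [(c.start, c.end) for c in single]
        assert sorted((c.start, c.end) for c in two_stage) == sorted(
            transitive_closure_clusters(spans)
        )


# ---------------------------------------------------------------------------
# repeat fraction


def test_repeat_fraction_fully_inside():
    c = cluster(100, 200, [call(100, 200)])
    kept, dropped = repeat_fraction_filter([c], {"chr1": [(0, 1000)]})
    assert kept == [] and dropped[0][1] == 1.0


def test_repeat_fraction_boundary_half_kept():
    c = cluster(0, 100, [call(0, 100)])
    kept, dropped = repeat_fraction_filter([c], {"chr1": [(50, 100)]})
    assert kept == [c] and dropped == []  # exactly 50%: "over 50%" not met


def test_repeat_fraction_base_counting_oracle(rng):
    """Fraction matches a base-by-base membership count on small coordinates,
    and is invariant to track fragmentation after pre-unioning."""
    for _ in range(100):
        raw = []
        for _ in range(int(rng.integers(1, 10))):
            s = int(rng.integers(0, 900))
            raw.append((s, s + int(rng.integers(1, 120))))
        track = {"chr1": union_intervals(raw)}
        s = int(rng.integers(0, 900))
        c = cluster(s, s + int(rng.integers(1, 100)), [call(s, s + 1)])
        base_hits = sum(
            any(t0 <= b < t1 for t0, t1 in raw) for b in range(c.start, c.end)
        )
        assert repeat_fraction(c, track) == pytest.approx(base_hits / (c.end - c.start))


def test_union_intervals_coalesces():
    assert union_intervals([(0, 10), (5, 20), (30, 40)]) == [(0, 20), (30, 40)]
    assert covered_length((0, 50), [(0, 20), (30, 40)]) == 30


# ---------------------------------------------------------------------------
# pedigree / breakpoint support


def _fam(*clusters):
    for c in clusters:
        c.family_id = "F1"
    return list(clusters)


def test_single_caller_single_sample_dropped():
    c = cluster(0, 1000, [call(0, 1000, "cnvnator", "S1")])
    assert pedigree_support_filter(_fam(c)) == []


def test_two_callers_single_sample_kept():
    c = cluster(0, 1000, [call(0, 1000, "cnvnator", "S1"), call(0, 1000, "erds", "S1")])
    kept = pedigree_support_filter(_fam(c))
    assert kept == [c] and c.support_route == "multi_caller"


def test_single_caller_matched_in_sibling_kept():
    c1 = cluster(0, 1000, [call(0, 1000, "lumpy", "S1", sf=0.6)])
    c2 = cluster(10, 1010, [call(10, 1010, "lumpy", "S2", sf=0.6)])
    kept = pedigree_support_filter(_fam(c1, c2))
    assert set(map(id, kept)) == {id(c1), id(c2)}
    assert c1.support_route == "multi_individual"


def test_sibling_match_requires_same_svtype():
    c1 = cluster(0, 1000, [call(0, 1000, "lumpy", "S1")], svtype="DEL")
    c2 = cluster(0, 1000, [call(0, 1000, "lumpy", "S2", svtype="DUP")], svtype="DUP")
    assert pedigree_support_filter(_fam(c1, c2)) == []


def test_pedigree_support_random_rule_oracle(rng):
    samples = [f"S{i}" for i in range(4)]
    for _ in range(100):
        clusters = []
        for i in range(int(rng.integers(1, 8))):
            anchor = int(rng.integers(0, 6)) * 10_000
            sid = str(rng.choice(samples))
            callers = list(
                rng.choice(
                    ["cnvnator", "erds", "lumpy", "manta"],
                    size=int(rng.integers(1, 3)),
                    replace=False,
                )
            )
            members = [call(anchor, anchor + 5_000, cl, sid) for cl in callers]
            clusters.append(cluster(anchor, anchor + 5_000, members))
        kept = pedigree_support_filter(_fam(*clusters))
        for c in clusters:
            matched = {
                s
                for o in clusters
                if o.svtype == c.svtype
                and reciprocal_overlap(c.span, o.span) >= 0.5
                for s in o.samples
            }
            expect = len(c.callers) >= 2 or len(matched | c.samples) >= 2
            assert (c in kept) == expect


def test_breakpoint_support_all_low_dropped():
    c1 = cluster(0, 1000, [call(0, 1000, "lumpy", "S1", sf=0.05)], route="multi_individual")
    kept, dropped = breakpoint_support_filter([c1], 0.2)
    assert kept == [] and dropped == [c1]


def test_breakpoint_support_one_member_ok_kept():
    c1 = cluster(
        0,
        1000,
        [call(0, 1000, "lumpy", "S1", sf=0.05), call(0, 1000, "lumpy", "S2", sf=0.5)],
        route="multi_individual",
    )
    kept, _ = breakpoint_support_filter([c1], 0.2)
    assert kept == [c1]


def test_breakpoint_support_only_applies_to_single_caller_multi_individual():
    c1 = cluster(
        0, 1000, [call(0, 1000, "cnvnator", "S1", sf=0.01), call(0, 1000, "erds", "S1", sf=0.01)],
        route="multi_caller",
    )
    kept, _ = breakpoint_support_filter([c1], 0.2)
    assert kept == [c1]


def test_breakpoint_support_missing_data_passes():
    c1 = cluster(0, 1000, [call(0, 1000, "lumpy", "S1")], route="multi_individual")
    kept, _ = breakpoint_support_filter([c1], 0.2)
    assert kept == [c1]


def test_breakpoint_support_threshold_oracle(rng):
    for _ in range(200):
        sfs = rng.uniform(0, 0.6, size=int(rng.integers(1, 5)))
        members = [call(0, 1000, "lumpy", f"S{i}", sf=float(s)) for i, s in enumerate(sfs)]
        c = cluster(0, 1000, members, route="multi_individual")
        kept, _ = breakpoint_support_filter([c], 0.2)
        assert (c in kept) == (not all(s < 0.2 for s in sfs))


# ---------------------------------------------------------------------------
# risk-locus screen


LOCUS = RiskLocus("chr2", 1000, 2000, "DUP", "locus1")


def test_screen_matching_dup_reported():
    c = cluster(900, 2100, [call(900, 2100, "cnvnator", "S1", svtype="DUP", chrom="chr2")],
                svtype="DUP", chrom="chr2")
    hits = screen_known_loci([c], [LOCUS])
    assert len(hits) == 1 and hits[0].coverage == 1.0


def test_screen_type_mismatch_ignored():
    c = cluster(900, 2100, [call(900, 2100, svtype="DEL", chrom="chr2")], svtype="DEL", chrom="chr2")
    assert screen_known_loci([c], [LOCUS]) == []


def test_screen_coverage_oracle(rng):
    for _ in range(200):
        s = int(rng.integers(0, 3000))
        e = s + int(rng.integers(1, 2000))
        c = cluster(s, e, [call(s, e, svtype="DUP", chrom="chr2")], svtype="DUP", chrom="chr2")
        hits = screen_known_loci([c], [LOCUS])
        cov = max(0, min(e, 2000) - max(s, 1000)) / 1000
        assert bool(hits) == (cov >= 0.5)
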