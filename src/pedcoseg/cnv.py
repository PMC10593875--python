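"""Family-aware consensus merging and filtering of multi-caller CNV calls.

Calls from two read-depth callers (CNVnator, ERDS) and two paired-end /
split-read callers (LUMPY, Manta) are combined per sample in three steps:

1. *collapse* — within one sample+caller+svtype, calls reciprocally
   overlapping >= 50% are iteratively merged to their union span;
2. *consensus* — a two-stage merge, first within each method class
   (read-depth callers together, PE/SR callers together), then between the
   resulting class-level sets, again at >= 50% reciprocal overlap with
   matching svtype;
3. *filters* — drop clusters with > 50% of their span in repeat /
   low-complexity regions; within each pedigree drop clusters seen by a
   single caller in a single individual; screen remaining single-caller,
   multi-individual clusters for breakpoint read support; finally report
   clusters covering >= 50% of any known risk locus with matching svtype.

Coordinates are 0-based half-open throughout (BED convention); VCF-style
1-based POS/END inputs are converted on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, ParseError, ValidationError
from .pedigree import Pedigree

METHOD_CLASS = {
    "cnvnator": "read_depth",
    "erds": "read_depth",
    "lumpy": "pe_sr",
    "manta": "pe_sr",
}

_SVTYPE_ALIASES = {
    "del": "DEL",
    "deletion": "DEL",
    "loss": "DEL",
    "dup": "DUP",
    "duplication": "DUP",
    "gain": "DUP",
}


def normalize_svtype(label: str) -> str:
    key = label.strip().lower()
    if key not in _SVTYPE_ALIASES:
        raise ValidationError(
            f"unmappable CNV type {label!r}; accepted: {sorted(_SVTYPE_ALIASES)}"
        )
    return _SVTYPE_ALIASES[key]


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    svtype: str  # DEL | DUP
    caller: str
    support_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"empty CNV interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.caller not in METHOD_CLASS:
            raise ValidationError(
                f"unknown caller {self.caller!r}; accepted: {sorted(METHOD_CLASS)}"
            )
        if self.support_fraction is not None and not (
            0.0 <= self.support_fraction <= 1.0
        ):
            raise ValidationError("support_fraction must lie in [0, 1]")

    @property
    def method_class(self) -> str:
        return METHOD_CLASS[self.caller]


@dataclass
class CnvCluster:
    chrom: str
    start: int
    end: int
    svtype: str
    members: list[CnvCall]
    family_id: str | None = None
    # how the pedigree-support rule kept this cluster (set by that filter)
    support_route: str | None = None

    @property
    def callers(self) -> set[str]:
        return {m.caller for m in self.members}

    @property
    def samples(self) -> set[str]:
        return {m.sample_id for m in self.members}

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# Interval arithmetic


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise ValidationError("reciprocal overlap undefined for empty intervals")
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / (a1 - a0), ov / (b1 - b0))


def union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Coalesce overlapping/adjacent intervals into a sorted disjoint set."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def covered_length(span: tuple[int, int], track: Sequence[tuple[int, int]]) -> int:
    """Bases of ``span`` covered by a pre-unioned (disjoint, sorted) track."""
    s0, s1 = span
    total = 0
    for t0, t1 in track:
        if t1 <= s0:
            continue
        if t0 >= s1:
            break
        total += min(s1, t1) - max(s0, t0)
    return total


# ---------------------------------------------------------------------------
# Collapse and consensus merge


def _merge_clusters(clusters: list[CnvCluster], min_ro: float = 0.5) -> list[CnvCluster]:
    """Iteratively merge clusters (same chrom+svtype assumed) whose spans
    reciprocally overlap >= min_ro, unioning spans, until a fixpoint."""
    work = sorted(clusters, key=lambda c: (c.start, c.end))
    changed = True
    while changed:
        changed = False
        out: list[CnvCluster] = []
        for c in work:
            merged = False
            for o in out:
                if reciprocal_overlap(o.span, c.span) >= min_ro:
                    o.start = min(o.start, c.start)
                    o.end = max(o.end, c.end)
                    o.members.extend(c.members)
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(
                    CnvCluster(c.chrom, c.start, c.end, c.svtype, list(c.members), c.family_id)
                )
        work = sorted(out, key=lambda c: (c.start, c.end))
    return work


def _group(calls: Iterable[CnvCall], keyfunc):
    groups: dict[tuple, list[CnvCall]] = {}
    for c in calls:
        groups.setdefault(keyfunc(c), []).append(c)
    return groups


def collapse_within(calls: Sequence[CnvCall], min_ro: float = 0.5) -> list[CnvCall]:
    """Collapse redundant calls of one sample+caller+svtype: calls with
    reciprocal overlap >= min_ro merge to their union span (fixpoint).
    Output spans replace the inputs; provenance is one representative call
    per collapsed group with the maximum support fraction."""
    out: list[CnvCall] = []
    for (sid, caller, svtype, chrom), grp in _group(
        calls, lambda c: (c.sample_id, c.caller, c.svtype, c.chrom)
    ).items():
        seeds = [CnvCluster(chrom, c.start, c.end, svtype, [c]) for c in grp]
        for cl in _merge_clusters(seeds, min_ro):
            sfs = [m.support_fraction for m in cl.members if m.support_fraction is not None]
            out.append(
                CnvCall(
                    sample_id=sid,
                    chrom=chrom,
                    start=cl.start,
                    end=cl.end,
                    svtype=svtype,
                    caller=caller,
                    support_fraction=max(sfs) if sfs else None,
                )
            )
    return sorted(out, key=lambda c: (c.chrom, c.start, c.end, c.caller, c.sample_id))


def merge_consensus(calls: Sequence[CnvCall], min_ro: float = 0.5) -> list[CnvCluster]:
    """Two-stage per-sample consensus: merge within each method class, then
    merge the two class-level call sets, at svtype-matched reciprocal
    overlap >= min_ro.  Every input call lands in exactly one cluster."""
    clusters: list[CnvCluster] = []
    for (sid, chrom, svtype), grp in _group(
        calls, lambda c: (c.sample_id, c.chrom, c.svtype)
    ).items():
        stage1: list[CnvCluster] = []
        for mclass in ("read_depth", "pe_sr"):
            seeds = [
                CnvCluster(chrom, c.start, c.end, svtype, [c])
                for c in grp
                if c.method_class == mclass
            ]
            stage1.extend(_merge_clusters(seeds, min_ro))
        clusters.extend(_merge_clusters(stage1, min_ro))
    return sorted(clusters, key=lambda c: (c.chrom, c.start, c.end, sorted(c.samples)))


# ---------------------------------------------------------------------------
# Filters


def repeat_fraction(
    cluster: CnvCluster, track: dict[str, Sequence[tuple[int, int]]]
) -> float:
    """Fraction of the cluster span covered by the (pre-unioned) repeat /
    low-complexity track."""
    cov = covered_length(cluster.span, track.get(cluster.chrom, ()))
    return cov / (cluster.end - cluster.start)


def repeat_fraction_filter(
    clusters: Iterable[CnvCluster],
    track: dict[str, Sequence[tuple[int, int]]],
    max_fraction: float = 0.5,
) -> tuple[list[CnvCluster], list[tuple[CnvCluster, float]]]:
    """Drop clusters with repeat fraction strictly above max_fraction
    ("over 50%"); exactly 50% is kept.  Returns (kept, dropped+fractions)."""
    kept, dropped = [], []
    for c in clusters:
        f = repeat_fraction(c, track)
        if f > max_fraction:
            dropped.append((c, f))
        else:
            kept.append(c)
    return kept, dropped


def assign_families(clusters: Iterable[CnvCluster], pedigrees: Iterable[Pedigree]) -> None:
    fam_of = {
        sid: ped.family_id for ped in pedigrees for sid in ped.samples
    }
    for c in clusters:
        fams = {fam_of.get(s) for s in c.samples}
        if None in fams:
            unknown = sorted(s for s in c.samples if s not in fam_of)
            raise ConfigurationError(f"CNV samples absent from all pedigrees: {unknown}")
        if len(fams) != 1:
            raise ValidationError(f"cluster spans multiple families: {sorted(fams)}")
        c.family_id = fams.pop()


def pedigree_support_filter(
    clusters: Sequence[CnvCluster], min_ro: float = 0.5
) -> list[CnvCluster]:
    """Within each pedigree, keep a cluster iff it was seen by >= 2 callers
    or matches (same svtype, reciprocal overlap >= min_ro) a cluster in
    >= 2 individuals of that pedigree.  Sets ``support_route`` to
    'multi_caller' or 'multi_individual' on kept clusters."""
    kept: list[CnvCluster] = []
    by_family: dict[str, list[CnvCluster]] = {}
    for c in clusters:
        by_family.setdefault(c.family_id or "", []).append(c)
    for fam_clusters in by_family.values():
        for c in fam_clusters:
            if len(c.callers) >= 2:
                c.support_route = "multi_caller"
                kept.append(c)
                continue
            matched_samples = set(c.samples)
            for o in fam_clusters:
                if o is c or o.svtype != c.svtype or o.chrom != c.chrom:
                    continue
                if o.samples == c.samples:
                    continue
                if reciprocal_overlap(c.span, o.span) >= min_ro:
                    matched_samples |= o.samples
            if len(matched_samples) >= 2:
                c.support_route = "multi_individual"
                kept.append(c)
    return sorted(kept, key=lambda c: (c.chrom, c.start, c.end, sorted(c.samples)))


def breakpoint_support_filter(
    clusters: Iterable[CnvCluster], min_fraction: float = 0.2
) -> tuple[list[CnvCluster], list[CnvCluster]]:
    """For clusters kept solely by the multiple-individual route with a
    single caller, drop those whose member calls all have breakpoint support
    below min_fraction; clusters lacking support data pass.  Returns
    (kept, dropped)."""
    if not (0.0 <= min_fraction <= 1.0):
        raise ConfigurationError("min_fraction must lie in [0, 1]")
    kept, dropped = [], []
    for c in clusters:
        if c.support_route != "multi_individual" or len(c.callers) >= 2:
            kept.append(c)
            continue
        sfs = [m.support_fraction for m in c.members if m.support_fraction is not None]
        if not sfs:
            kept.append(c)
        elif all(sf < min_fraction for sf in sfs):
            dropped.append(c)
        else:
            kept.append(c)
    return kept, dropped


@dataclass
class RiskLocus:
    chrom: str
    start: int
    end: int
    svtype: str
    name: str


@dataclass
class RiskLocusHit:
    locus: RiskLocus
    cluster: CnvCluster
    coverage: float


def screen_known_loci(
    clusters: Iterable[CnvCluster],
    loci: Iterable[RiskLocus],
    min_coverage: float = 0.5,
) -> list[RiskLocusHit]:
    """Report clusters whose overlap covers >= min_coverage of a risk locus
    with matching svtype."""
    hits = []
    for locus in loci:
        llen = locus.end - locus.start
        for c in clusters:
            if c.chrom != locus.chrom or c.svtype != locus.svtype:
                continue
            ov = min(c.end, locus.end) - max(c.start, locus.start)
            if ov > 0 and ov / llen >= min_coverage:
                hits.append(RiskLocusHit(locus, c, ov / llen))
    return hits


# ---------------------------------------------------------------------------
# I/O


def read_cnv_tsv(path: str | Path, caller: str | None = None) -> list[CnvCall]:
    """6-column TSV: sample, chrom, start, end, svtype, support_fraction
    ('.' for absent); an optional 7th column names the caller when the file
    mixes callers."""
    calls = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("CNV TSV needs >=6 columns", str(path), lineno)
            call_caller = fields[6] if len(fields) >= 7 else caller
            if call_caller is None:
                raise ParseError("no caller column and no caller given", str(path), lineno)
            sf = None if fields[5] in (".", "") else float(fields[5])
            calls.append(
                CnvCall(
                    sample_id=fields[0],
                    chrom=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                    svtype=normalize_svtype(fields[4]),
                    caller=call_caller.lower(),
                    support_fraction=sf,
                )
            )
    return calls


def read_bed_track(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED3+ -> per-chrom pre-unioned interval lists."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED needs >=3 columns", str(path), lineno)
            raw.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return {chrom: union_intervals(ivs) for chrom, ivs in raw.items()}


def read_risk_loci(path: str | Path) -> list[RiskLocus]:
    """BED4+: chrom, start, end, name, [svtype] (svtype defaults to DEL)."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("risk-locus BED needs >=4 columns", str(path), lineno)
            svtype = normalize_svtype(fields[4]) if len(fields) >= 5 else "DEL"
            loci.append(RiskLocus(fields[0], int(fields[1]), int(fields[2]), svtype, fields[3]))
    return loci


def write_clusters_tsv(clusters: Iterable[CnvCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsvtype\tfamily\tsamples\tcallers\tn_calls\troute\n")
        for c in clusters:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        c.svtype,
                        c.family_id or ".",
                        ",".join(sorted(c.samples)),
                        ",".join(sorted(c.callers)),
                        str(len(c.members)),
                        c.support_route or ".",
                    ]
                )
                + "\n"
            )
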