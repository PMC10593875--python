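"""Functional prioritization of cosegregating variants.

Candidates surviving the cosegregation screen are restricted to the coding
sequence of protein-coding genes and then passed through a three-clause
conjunction derived from exome meta-analytic burden results:

1. ultrarare — gnomAD exome minor allele count <= 5;
2. functionally relevant — a protein-truncating consequence (frameshift,
   stop gained, splice acceptor/donor) or a predicted-deleterious missense
   (MPC > 2, strict);
3. constrained gene — pLI > 0.9 (strict).

MPC class labels are reported alongside: class I = MPC >= 3,
class II = 2 <= MPC < 3.  Annotations are ingested from a TSV keyed on
(chrom, pos, ref, alt, gene); one row per variant-gene pair, evaluated on
the gene's canonical transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, ParseError

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "consequence",
    "MPC",
    "CADD",
    "SIFT",
    "PolyPhen2",
    "gnomAD_AC",
    "pLI",
    "mis_Z",
    "LOEUF",
]

MISSENSE_TERMS = {"missense_variant"}


class FunctionalClass(str, Enum):
    PTV = "ptv"
    MISSENSE_DELETERIOUS = "missense_deleterious"
    OTHER = "other"


@dataclass(frozen=True)
class PrioritizationThresholds:
    mac_max: int = 5
    mpc_min: float = 2.0  # exclusive
    pli_min: float = 0.9  # exclusive
    ptv_consequences: frozenset[str] = frozenset(
        {
            "frameshift_variant",
            "stop_gained",
            "splice_acceptor_variant",
            "splice_donor_variant",
        }
    )

    def __post_init__(self) -> None:
        if not self.ptv_consequences:
            raise ConfigurationError("ptv_consequences must be non-empty")


@dataclass
class AnnotationRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str | None = None
    consequence: frozenset[str] = frozenset()
    mpc: float | None = None
    cadd: float | None = None
    sift: str | None = None
    polyphen2: str | None = None
    gnomad_mac: int = 0  # absent from gnomAD == 0
    pli: float | None = None
    mis_z: float | None = None
    loeuf: float | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_annotations(path: str | Path) -> dict[tuple[str, int, str, str], list[AnnotationRecord]]:
    """Load the annotation TSV into records keyed by variant; one record per
    (variant, gene) pair."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"annotation TSV missing columns: {missing}", str(path))
    out: dict[tuple[str, int, str, str], list[AnnotationRecord]] = {}
    for row in df.itertuples(index=False):
        mac = getattr(row, "gnomAD_AC")
        pli = getattr(row, "pLI")
        if pd.notna(pli) and not (0.0 <= float(pli) <= 1.0):
            raise ParseError(f"pLI {pli} outside [0, 1] for gene {row.gene}", str(path))
        rec = AnnotationRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            gene=str(row.gene),
            transcript=None if pd.isna(row.transcript) else str(row.transcript),
            consequence=frozenset(str(row.consequence).split("&")),
            mpc=None if pd.isna(row.MPC) else float(row.MPC),
            cadd=None if pd.isna(row.CADD) else float(row.CADD),
            sift=None if pd.isna(row.SIFT) else str(row.SIFT),
            polyphen2=None if pd.isna(row.PolyPhen2) else str(row.PolyPhen2),
            gnomad_mac=0 if pd.isna(mac) else int(mac),
            pli=None if pd.isna(pli) else float(pli),
            mis_z=None if pd.isna(row.mis_Z) else float(row.mis_Z),
            loeuf=None if pd.isna(row.LOEUF) else float(row.LOEUF),
        )
        out.setdefault(rec.key, []).append(rec)
    return out


# ---------------------------------------------------------------------------
# Coding-sequence restriction


class GeneModel:
    """CDS intervals per contig (0-based half-open), queried with 1-based
    variant coordinates."""

    def __init__(self, intervals: list[tuple[str, int, int, str]]):
        if not intervals:
            raise ConfigurationError("gene model is empty")
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, gene in intervals:
            if end <= start:
                raise ConfigurationError(f"empty CDS interval {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, gene)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneModel":
        """4-column CDS BED: chrom, start, end, gene."""
        intervals = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError("CDS BED needs >=4 columns", str(path), lineno)
                intervals.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
        return cls(intervals)

    def overlapping_genes(self, chrom: str, pos: int, ref: str) -> list[str]:
        """Genes whose CDS intersects the variant's reference span
        [pos-1, pos-1+len(ref)) in 0-based coordinates."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos - 1, pos - 1 + len(ref))
        return sorted({iv.data for iv in hits})


def coding_filter(
    chrom: str, pos: int, ref: str, model: GeneModel
) -> tuple[bool, list[str]]:
    genes = model.overlapping_genes(chrom, pos, ref)
    return (bool(genes), genes)


# ---------------------------------------------------------------------------
# Functional classification


def classify_functional(
    rec: AnnotationRecord, t: PrioritizationThresholds | None = None
) -> tuple[FunctionalClass, str | None]:
    """Return (functional class, MPC class label).

    PTV when any consequence term is in the PTV set; otherwise a missense
    with MPC > mpc_min is deleterious.  A missense lacking MPC is 'other'.
    The MPC class label (I / II) is independent of the filter decision.
    """
    t = t or PrioritizationThresholds()
    schema_class = None
    if rec.mpc is not None:
        if rec.mpc >= 3.0:
            schema_class = "I"
        elif rec.mpc >= 2.0:
            schema_class = "II"
    if rec.consequence & t.ptv_consequences:
        return FunctionalClass.PTV, schema_class
    if rec.consequence & MISSENSE_TERMS and rec.mpc is not None and rec.mpc > t.mpc_min:
        return FunctionalClass.MISSENSE_DELETERIOUS, schema_class
    return FunctionalClass.OTHER, schema_class


# ---------------------------------------------------------------------------
# The three-clause conjunction

CLAUSE_ULTRARARE = "Ultrarare in gnomAD"
CLAUSE_FUNCTIONAL = "Functional Relevance"
CLAUSE_CONSTRAINT = "LoF-Intolerant Gene"


def evaluate_record(
    rec: AnnotationRecord, t: PrioritizationThresholds | None = None
) -> tuple[bool, list[str]]:
    """Evaluate the conjunction on one (variant, gene) record; returns
    (retained, failing clause labels in funnel order)."""
    t = t or PrioritizationThresholds()
    failing = []
    if rec.gnomad_mac > t.mac_max:
        failing.append(CLAUSE_ULTRARARE)
    fclass, _ = classify_functional(rec, t)
    if fclass is FunctionalClass.OTHER:
        failing.append(CLAUSE_FUNCTIONAL)
    if rec.pli is None or not rec.pli > t.pli_min:
        failing.append(CLAUSE_CONSTRAINT)
    return (not failing, failing)


@dataclass
class PrioritizedRow:
    key: tuple[str, int, str, str]
    family_id: str
    pattern: str
    gene: str
    record: AnnotationRecord | None
    retained: bool
    functional_class: FunctionalClass | None = None
    schema_class: str | None = None
    failing_clauses: list[str] = field(default_factory=list)
    unannotated: bool = False


def prioritize(
    candidates: list[tuple[tuple[str, int, str, str], str, str]],
    annotations: dict[tuple[str, int, str, str], list[AnnotationRecord]],
    t: PrioritizationThresholds | None = None,
) -> list[PrioritizedRow]:
    """Apply the conjunction to cosegregating candidates.

    ``candidates`` rows are (variant key, family_id, pattern).  Per-gene
    annotation records are evaluated independently; a variant is retained if
    any of its gene rows is retained.  A candidate with no annotation is
    reported as unannotatable rather than silently dropped.
    """
    t = t or PrioritizationThresholds()
    rows: list[PrioritizedRow] = []
    for key, family_id, pattern in candidates:
        recs = annotations.get(key, [])
        if not recs:
            rows.append(
                PrioritizedRow(
                    key=key,
                    family_id=family_id,
                    pattern=pattern,
                    gene=".",
                    record=None,
                    retained=False,
                    unannotated=True,
                )
            )
            continue
        for rec in recs:
            retained, failing = evaluate_record(rec, t)
            fclass, sclass = classify_functional(rec, t)
            rows.append(
                PrioritizedRow(
                    key=key,
                    family_id=family_id,
                    pattern=pattern,
                    gene=rec.gene,
                    record=rec,
                    retained=retained,
                    functional_class=fclass,
                    schema_class=sclass,
                    failing_clauses=failing,
                )
            )
    return rows


def rows_to_frame(rows: list[PrioritizedRow]) -> pd.DataFrame:
    """Tabular report mirroring the per-variant candidate table layout."""
    out = []
    for r in rows:
        rec = r.record
        out.append(
            {
                "family": r.family_id,
                "chrom": r.key[0],
                "pos": r.key[1],
                "ref": r.key[2],
                "alt": r.key[3],
                "gene": r.gene,
                "pattern": r.pattern,
                "MAC": rec.gnomad_mac if rec else None,
                "MPC": rec.mpc if rec else None,
                "CADD": rec.cadd if rec else None,
                "SIFT": rec.sift if rec else None,
                "PolyPhen2": rec.polyphen2 if rec else None,
                "pLI": rec.pli if rec else None,
                "class": r.schema_class,
                "retained": r.retained,
                "failing_clauses": ";".join(r.failing_clauses),
            }
        )
    return pd.DataFrame(out)
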