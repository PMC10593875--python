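"""End-to-end orchestration: SNV/indel prioritization and CNV consensus.

The SNV funnel runs the stages in a fixed order — QC, family-private
screen, Mendelian screen, cosegregation classification, coding-sequence
restriction, then the three prioritization clauses — and reports per-stage
variant counts split by cosegregation pattern (full vs reduced).  Every
removal is attributable: the retained-variant table carries, for each
candidate that reached prioritization, the clause that eliminated it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnvmod
from .cosegregation import (
    ChromClass,
    CosegregationConfig,
    CosegregationResult,
    Pattern,
    chrom_class,
    classify_pattern,
    find_family_private,
    index_trios,
    mendelian_consistent,
)
from .errors import ConfigurationError
from .pedigree import Pedigree, enumerate_trios, infer_roles, parse_ped
from .prioritization import (
    CLAUSE_CONSTRAINT,
    CLAUSE_FUNCTIONAL,
    CLAUSE_ULTRARARE,
    GeneModel,
    PrioritizationThresholds,
    PrioritizedRow,
    prioritize,
    read_annotations,
    rows_to_frame,
)
from .variant_qc import CallSet, QcFunnel, QcThresholds, read_vcf, run_qc

log = logging.getLogger(__name__)

STAGE_QC = "Quality Control Filters"
STAGE_PRIVATE = "Family-Private Variants"
STAGE_MENDELIAN = "Mendelian Consistency"
STAGE_COSEG = "Cosegregation Pattern"
STAGE_CODING = "In the Coding Sequence"
PRIORITIZATION_STAGES = (CLAUSE_ULTRARARE, CLAUSE_FUNCTIONAL, CLAUSE_CONSTRAINT)


@dataclass
class FunnelReport:
    """Ordered per-stage counts; after the cosegregation branch point the
    counts split into parallel full/reduced branches."""

    shared: list[tuple[str, int]] = field(default_factory=list)
    branched: list[tuple[str, dict[str, int]]] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def log_shared(self, stage: str, count: int) -> None:
        self.shared.append((stage, count))

    def log_branched(self, stage: str, full: int, reduced: int) -> None:
        self.branched.append((stage, {"full": full, "reduced": reduced}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s, "full": c, "reduced": c, "branch": "shared"}
            for s, c in self.shared
        ]
        rows += [
            {"stage": s, "full": d["full"], "reduced": d["reduced"], "branch": "split"}
            for s, d in self.branched
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k in sorted(self.metadata):
                fh.write(f"# {k}: {self.metadata[k]}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def validate_monotone(self) -> None:
        counts = [c for _, c in self.shared]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"funnel not monotone: {self.shared}")
        for branch in ("full", "reduced"):
            bs = [d[branch] for _, d in self.branched]
            if any(b > a for a, b in zip(bs, bs[1:])):
                raise AssertionError(f"{branch} branch not monotone: {self.branched}")


@dataclass
class SnvPipelineResult:
    retained: list[PrioritizedRow]
    all_rows: list[PrioritizedRow]
    coseg_results: list[CosegregationResult]
    funnel: FunnelReport
    qc_funnel: QcFunnel
    callset: CallSet

    def retained_frame(self) -> pd.DataFrame:
        return rows_to_frame(self.retained)


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _prepare_pedigrees(ped_path, samples: list[str]) -> list[Pedigree]:
    pedigrees = parse_ped(ped_path)
    known = {sid for ped in pedigrees for sid in ped.samples}
    orphans = [s for s in samples if s not in known]
    if orphans:
        raise ConfigurationError(
            f"VCF samples absent from all pedigrees: {orphans}"
        )
    for ped in pedigrees:
        ped.sequenced_ids = {sid for sid in ped.samples if sid in set(samples)}
        infer_roles(ped)
    return pedigrees


def run_snv_pipeline(
    vcf_path: str | Path,
    ped_path: str | Path,
    annotation_path: str | Path,
    gene_model_path: str | Path,
    qc: QcThresholds | None = None,
    coseg_cfg: CosegregationConfig | None = None,
    thresholds: PrioritizationThresholds | None = None,
) -> SnvPipelineResult:
    qc = qc or QcThresholds()
    coseg_cfg = coseg_cfg or CosegregationConfig()
    thresholds = thresholds or PrioritizationThresholds()

    callset = read_vcf(vcf_path, qc)
    pedigrees = _prepare_pedigrees(ped_path, callset.samples)
    model = GeneModel.from_bed(gene_model_path)
    annotations = read_annotations(annotation_path)

    funnel = FunnelReport(
        metadata={
            "vcf": _file_digest(vcf_path),
            "ped": _file_digest(ped_path),
            "annotations": _file_digest(annotation_path),
            "gene_model": _file_digest(gene_model_path),
        }
    )

    callset, qc_funnel = run_qc(callset, qc)
    funnel.log_shared(STAGE_QC, len(callset.records))

    sample_index = {sid: i for i, sid in enumerate(callset.samples)}
    sample_families = np.array(
        [
            next(p.family_id for p in pedigrees if sid in p.samples)
            for sid in callset.samples
        ]
    )
    ped_by_id = {p.family_id: p for p in pedigrees}
    trios_by_family = {
        p.family_id: index_trios(p, enumerate_trios(p), sample_index) for p in pedigrees
    }
    all_trios = [t for ts in trios_by_family.values() for t in ts]

    # family-private screen
    private: list[tuple] = []  # (record, family_id)
    for rec in callset.records:
        fam = find_family_private(rec.geno, sample_families)
        if fam is not None:
            private.append((rec, fam))
    funnel.log_shared(STAGE_PRIVATE, len(private))

    # Mendelian screen over every sequenced trio in the cohort
    consistent = []
    for rec, fam in private:
        cclass = chrom_class(rec.site.chrom)
        ok, _violations = mendelian_consistent(rec.geno, all_trios, cclass)
        if ok:
            consistent.append((rec, fam))
    funnel.log_shared(STAGE_MENDELIAN, len(consistent))

    # cosegregation classification within the private family
    coseg_results: list[CosegregationResult] = []
    survivors: dict[str, list[tuple]] = {"full": [], "reduced": []}
    for rec, fam in consistent:
        res = classify_pattern(rec.site.key, rec.geno, ped_by_id[fam], sample_index, coseg_cfg)
        coseg_results.append(res)
        if res.pattern is not Pattern.NONE:
            survivors[res.pattern.value].append((rec, fam, res.pattern.value))
    funnel.log_branched(
        STAGE_COSEG, len(survivors["full"]), len(survivors["reduced"])
    )

    # coding-sequence restriction
    coding: dict[str, list[tuple]] = {"full": [], "reduced": []}
    for branch, items in survivors.items():
        for rec, fam, pattern in items:
            keep, _genes = (
                lambda g: (bool(g), g)
            )(model.overlapping_genes(rec.site.chrom, rec.site.pos, rec.site.ref))
            if keep:
                coding[branch].append((rec, fam, pattern))
    funnel.log_branched(STAGE_CODING, len(coding["full"]), len(coding["reduced"]))

    # prioritization conjunction with per-stage branch counts
    candidates = [
        (rec.site.key, fam, pattern)
        for branch in ("full", "reduced")
        for rec, fam, pattern in coding[branch]
    ]
    rows = prioritize(candidates, annotations, thresholds)
    by_variant: dict[tuple, list[PrioritizedRow]] = {}
    for r in rows:
        by_variant.setdefault((r.key, r.family_id, r.pattern), []).append(r)

    stage_survivor_counts = {s: {"full": 0, "reduced": 0} for s in PRIORITIZATION_STAGES}
    for (key, fam, pattern), vrows in by_variant.items():
        surviving = [r for r in vrows if not r.unannotated]
        for stage in PRIORITIZATION_STAGES:
            surviving = [r for r in surviving if stage not in r.failing_clauses]
            if surviving:
                stage_survivor_counts[stage][pattern] += 1
    for stage in PRIORITIZATION_STAGES:
        funnel.log_branched(
            stage,
            stage_survivor_counts[stage]["full"],
            stage_survivor_counts[stage]["reduced"],
        )

    retained = [r for r in rows if r.retained]
    funnel.validate_monotone()
    return SnvPipelineResult(
        retained=retained,
        all_rows=rows,
        coseg_results=coseg_results,
        funnel=funnel,
        qc_funnel=qc_funnel,
        callset=callset,
    )


# ---------------------------------------------------------------------------
# CNV pipeline


@dataclass
class CnvPipelineResult:
    clusters: list[cnvmod.CnvCluster]
    screen_hits: list[cnvmod.RiskLocusHit]
    stage_counts: list[tuple[str, int]]


def run_cnv_pipeline(
    call_files: dict[str, str | Path],
    ped_path: str | Path,
    repeat_track_path: str | Path,
    risk_loci_path: str | Path,
    min_ro: float = 0.5,
    max_repeat_fraction: float = 0.5,
    min_support: float = 0.2,
) -> CnvPipelineResult:
    """collapse -> two-stage consensus -> repeat filter -> pedigree support
    -> breakpoint support -> risk-locus screen, with per-stage counts."""
    pedigrees = parse_ped(ped_path)
    calls = []
    for caller, path in sorted(call_files.items()):
        calls.extend(cnvmod.read_cnv_tsv(path, caller=caller.lower()))
    # canonical order: output invariant under permutation of input files
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.caller, c.sample_id))
    stages = [("Raw Calls", len(calls))]

    collapsed = cnvmod.collapse_within(calls, min_ro)
    stages.append(("Collapsed Calls", len(collapsed)))

    clusters = cnvmod.merge_consensus(collapsed, min_ro)
    stages.append(("Consensus Clusters", len(clusters)))

    track = cnvmod.read_bed_track(repeat_track_path)
    clusters, _dropped = cnvmod.repeat_fraction_filter(clusters, track, max_repeat_fraction)
    stages.append(("Repeat Fraction", len(clusters)))

    cnvmod.assign_families(clusters, pedigrees)
    clusters = cnvmod.pedigree_support_filter(clusters, min_ro)
    stages.append(("Pedigree Support", len(clusters)))

    clusters, _lowsupp = cnvmod.breakpoint_support_filter(clusters, min_support)
    stages.append(("Breakpoint Support", len(clusters)))

    loci = cnvmod.read_risk_loci(risk_loci_path)
    hits = cnvmod.screen_known_loci(clusters, loci, min_coverage=0.5)
    stages.append(("Risk Locus Hits", len(hits)))

    return CnvPipelineResult(clusters=clusters, screen_hits=hits, stage_counts=stages)
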