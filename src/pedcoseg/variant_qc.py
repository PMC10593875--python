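"""Post-genotyping quality control of a jointly genotyped multi-sample VCF.

The funnel, in order:

1. chromosome restriction to the 23 standard pairs (1-22, X, Y);
2. site depth outliers (> mean + 5 SD of cohort site depth) removed;
3. hard filters on non-SNV/non-indel sites
   (QD < 2, ReadPosRankSum < -20, FS > 200, SOR > 10, strict inequalities);
4. genotype masking (GQ < 20 or DP < 10 -> missing);
5. site removal when FILTER is set or missingness > 20%.

Multiallelic sites are split into biallelic records at read time; a sample
carrying a different alt allele is coded 0 for the current alt (the
bcftools-norm convention), configurable to missing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError

log = logging.getLogger(__name__)

STANDARD_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}

MISSING = -1  # allele-count sentinel in genotype arrays

_SIMPLE_ALLELE = re.compile(r"^[ACGTNacgtn]+$")


class VType(str, Enum):
    SNV = "snv"
    INDEL = "indel"
    OTHER = "other"


@dataclass(frozen=True)
class QcThresholds:
    gq_min: float = 20.0
    dp_min: int = 10
    missingness_max: float = 0.20
    depth_sd_mult: float = 5.0
    qd_min: float = 2.0
    rprs_min: float = -20.0
    fs_max: float = 200.0
    sor_max: float = 10.0
    # policy for a sample carrying a *different* alt after biallelic split
    other_alt_policy: str = "ref"  # "ref" | "missing"

    def __post_init__(self) -> None:
        if not (0.0 < self.missingness_max <= 1.0):
            raise ConfigurationError("missingness_max must lie in (0, 1]")
        for name in ("gq_min", "depth_sd_mult", "qd_min", "rprs_min", "fs_max", "sor_max"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.other_alt_policy not in ("ref", "missing"):
            raise ConfigurationError("other_alt_policy must be 'ref' or 'missing'")


@dataclass
class VariantSite:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    site_dp: float | None = None
    qd: float | None = None
    fs: float | None = None
    sor: float | None = None
    read_pos_rank_sum: float | None = None
    filter_flags: frozenset[str] = frozenset()
    vtype: VType = VType.SNV

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


@dataclass
class SiteGenotypes:
    """Per-sample genotype data for one biallelic site, column-parallel with
    the call set's sample list.  ``ac`` is the alt-allele count (0/1/2,
    MISSING when uncalled); ``masked`` marks low-quality genotypes."""

    ac: np.ndarray  # int8
    gq: np.ndarray  # float32, NaN = absent
    dp: np.ndarray  # float32, NaN = absent
    masked: np.ndarray  # bool

    def usable_carrier(self) -> np.ndarray:
        return (self.ac >= 1) & ~self.masked

    def missing_or_masked(self) -> np.ndarray:
        return (self.ac == MISSING) | self.masked


@dataclass
class SiteRecord:
    site: VariantSite
    geno: SiteGenotypes


@dataclass
class CallSet:
    samples: list[str]
    records: list[SiteRecord]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Allele handling


def classify_vtype(ref: str, alt: str) -> VType:
    if not _SIMPLE_ALLELE.match(ref) or not _SIMPLE_ALLELE.match(alt):
        return VType.OTHER
    if len(ref) == 1 and len(alt) == 1:
        return VType.SNV
    if len(ref) != len(alt):
        return VType.INDEL
    return VType.OTHER  # MNPs and other balanced substitutions


def minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping >=1 base of each allele.

    This yields the parsimonious representation of an allele after a
    multiallelic split; full left-alignment against the reference sequence is
    not needed for parsimony-trimmed synthetic data.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotype_pairs: np.ndarray,
    *,
    site_dp: float | None = None,
    qd: float | None = None,
    fs: float | None = None,
    sor: float | None = None,
    read_pos_rank_sum: float | None = None,
    filter_flags: Iterable[str] = (),
    other_alt_policy: str = "ref",
) -> list[SiteRecord]:
    """Split a raw record into one biallelic SiteRecord per alt allele.

    ``genotype_pairs`` is an (n_samples, 2) integer array of allele indices
    with -1 for missing.  For alt k (1-based index in the original record),
    the per-sample allele count is the number of alleles equal to k; alleles
    pointing at a *different* alt are coded 0 under the default policy, or
    the whole genotype is set missing under ``other_alt_policy='missing'``.
    GQ/DP arrays are attached by the caller.
    """
    flags = frozenset(filter_flags)
    out = []
    a = genotype_pairs
    missing_any = (a < 0).any(axis=1)
    for k, alt in enumerate(alts, start=1):
        if not _SIMPLE_ALLELE.match(alt):
            # symbolic alt inside a multiallelic record: routed untouched
            log.warning("symbolic alt %s at %s:%d routed to vtype=other", alt, chrom, pos)
            npos, nref, nalt = pos, ref, alt
        else:
            npos, nref, nalt = minimal_representation(pos, ref, alt)
        ac = (a == k).sum(axis=1).astype(np.int8)
        ac[missing_any] = MISSING
        if other_alt_policy == "missing":
            other = ((a > 0) & (a != k)).any(axis=1)
            ac[other] = MISSING
        site = VariantSite(
            chrom=chrom,
            pos=npos,
            ref=nref,
            alt=nalt,
            site_dp=site_dp,
            qd=qd,
            fs=fs,
            sor=sor,
            read_pos_rank_sum=read_pos_rank_sum,
            filter_flags=flags,
            vtype=classify_vtype(nref, nalt),
        )
        n = a.shape[0]
        geno = SiteGenotypes(
            ac=ac,
            gq=np.full(n, np.nan, dtype=np.float32),
            dp=np.full(n, np.nan, dtype=np.float32),
            masked=np.zeros(n, dtype=bool),
        )
        out.append(SiteRecord(site, geno))
    return out


# ---------------------------------------------------------------------------
# VCF reading


def read_vcf(path: str | Path, thresholds: QcThresholds | None = None) -> CallSet:
    """Read a (possibly bgzipped) VCF into a CallSet, splitting multiallelic
    sites.  Site depth comes from INFO/DP, falling back to summed FORMAT/DP."""
    from cyvcf2 import VCF

    t = thresholds or QcThresholds()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[SiteRecord] = []
    for rec in vcf:
        pairs = np.asarray([g[:2] for g in rec.genotypes], dtype=np.int16)
        gq = _format_field(rec, "GQ", len(samples))
        dp = _format_field(rec, "DP", len(samples))
        site_dp = rec.INFO.get("DP")
        if site_dp is None and not np.isnan(dp).all():
            site_dp = float(np.nansum(dp))
        flags = () if rec.FILTER is None else tuple(rec.FILTER.split(";"))
        splits = split_multiallelic(
            rec.CHROM,
            rec.POS,
            rec.REF,
            list(rec.ALT),
            pairs,
            site_dp=None if site_dp is None else float(site_dp),
            qd=_info_float(rec, "QD"),
            fs=_info_float(rec, "FS"),
            sor=_info_float(rec, "SOR"),
            read_pos_rank_sum=_info_float(rec, "ReadPosRankSum"),
            filter_flags=flags,
            other_alt_policy=t.other_alt_policy,
        )
        for sr in splits:
            sr.geno.gq = gq.copy()
            sr.geno.dp = dp.copy()
        records.extend(splits)
    return CallSet(samples, records)


def _info_float(rec, key):
    v = rec.INFO.get(key)
    return None if v is None else float(v)


def _format_field(rec, key: str, n: int) -> np.ndarray:
    out = np.full(n, np.nan, dtype=np.float32)
    try:
        arr = rec.format(key)
    except KeyError:
        arr = None
    if arr is not None:
        vals = np.asarray(arr, dtype=np.float32).reshape(n, -1)[:, 0]
        vals[vals < 0] = np.nan  # cyvcf2 encodes missing as large negatives
        out = vals
    return out


# ---------------------------------------------------------------------------
# Filters


def chromosome_filter(site: VariantSite) -> bool:
    """Keep iff the contig is one of the 23 standard pairs (X and Y included,
    MT and unplaced/decoy contigs excluded); 'chr' prefix optional."""
    name = site.chrom[3:] if site.chrom.lower().startswith("chr") else site.chrom
    return name.upper() in STANDARD_CHROMS


def depth_outlier_filter(
    records: Sequence[SiteRecord], sd_mult: float = 5.0
) -> tuple[list[SiteRecord], int, tuple[float, float] | None]:
    """Remove sites whose depth exceeds mean + sd_mult * SD of site depth
    over the input set.  Mean/SD use the population (n) denominator.
    Returns (kept, n_removed, (mean, sd))."""
    dps = np.array(
        [r.site.site_dp for r in records if r.site.site_dp is not None], dtype=float
    )
    if dps.size == 0:
        log.warning("no site depth present; depth outlier filter is a no-op")
        return list(records), 0, None
    mean, sd = float(dps.mean()), float(dps.std(ddof=0))
    cutoff = mean + sd_mult * sd
    kept = [r for r in records if r.site.site_dp is None or r.site.site_dp <= cutoff]
    return kept, len(records) - len(kept), (mean, sd)


def hard_filter_other(site: VariantSite, t: QcThresholds) -> bool:
    """Keep/drop decision for vtype=other sites.  Drop iff any annotation
    crosses its threshold (strict inequalities); absent annotations never
    trigger a drop."""
    if site.qd is not None and site.qd < t.qd_min:
        return False
    if site.read_pos_rank_sum is not None and site.read_pos_rank_sum < t.rprs_min:
        return False
    if site.fs is not None and site.fs > t.fs_max:
        return False
    if site.sor is not None and site.sor > t.sor_max:
        return False
    return True


def mask_genotypes(geno: SiteGenotypes, t: QcThresholds) -> SiteGenotypes:
    """Mask genotypes with GQ < gq_min or DP < dp_min (strict); a genotype
    with absent GQ or DP is masked — quality cannot be certified."""
    with np.errstate(invalid="ignore"):
        fail = (geno.gq < t.gq_min) | (geno.dp < t.dp_min)
    fail |= np.isnan(geno.gq) | np.isnan(geno.dp)
    geno.masked = fail
    return geno


def missingness_filter(record: SiteRecord, t: QcThresholds) -> bool:
    """Keep/drop after masking: drop iff FILTER is set or the fraction of
    missing-or-masked genotypes exceeds missingness_max (strict)."""
    if record.site.filter_flags and record.site.filter_flags != frozenset({"PASS"}):
        return False
    frac = record.geno.missing_or_masked().mean()
    return frac <= t.missingness_max


# ---------------------------------------------------------------------------
# Funnel


@dataclass
class QcFunnel:
    stages: list[tuple[str, int]] = field(default_factory=list)

    def log(self, stage: str, count: int) -> None:
        self.stages.append((stage, count))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tvariants\n")
            for stage, count in self.stages:
                fh.write(f"{stage}\t{count}\n")


def run_qc(callset: CallSet, t: QcThresholds | None = None) -> tuple[CallSet, QcFunnel]:
    """Apply the full QC funnel to an already-split CallSet."""
    t = t or QcThresholds()
    funnel = QcFunnel()
    funnel.log("Input Biallelic Sites", len(callset.records))

    records = [r for r in callset.records if chromosome_filter(r.site)]
    funnel.log("Standard Chromosomes", len(records))

    records, n_removed, _ = depth_outlier_filter(records, t.depth_sd_mult)
    funnel.log("Depth Outliers Removed", len(records))

    records = [
        r
        for r in records
        if r.site.vtype is not VType.OTHER or hard_filter_other(r.site, t)
    ]
    funnel.log("Hard Filters (other types)", len(records))

    for r in records:
        mask_genotypes(r.geno, t)
    records = [r for r in records if missingness_filter(r, t)]
    funnel.log("Quality Control Filters", len(records))

    return CallSet(callset.samples, records), funnel
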