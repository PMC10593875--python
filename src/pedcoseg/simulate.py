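"""Synthetic multiplex-pedigree datasets with recorded ground truth.

The generator emulates the study design this pipeline targets: a handful of
multi-generation pedigrees densely affected with a dominant phenotype,
jointly genotyped SNVs/indels with genotype-quality artifacts, per-variant
functional annotations, and multi-caller CNV call sets with breakpoint
jitter and per-caller dropout — all on a miniature genome (3 autosomal
contigs of 1 Mb) so base-level oracles stay cheap.

Affection status is assigned from a latent founder gene-drop: in-family
carriers of the latent haplotype become cases, everyone else is unaffected.
Planted variants then reuse that haplotype, which makes full and reduced
cosegregation patterns Mendelian-consistent *by construction*:

* ``full``    — genotypes equal the latent carrier set;
* ``reduced`` — the latent set minus one transmission-leaf case (a case
  none of whose children carry), which preserves consistency;
* ``none``    — the latent set plus one het marry-in founder.

Every random draw flows from one seed through named substreams (pedigree,
genotypes, artifacts, annotations, site_info, cnv), so adding a component
never perturbs the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import count
from pathlib import Path

import numpy as np

from .cnv import CnvCall, RiskLocus
from .errors import ConfigurationError
from .pedigree import Affection, Pedigree, Role, Sample, Sex, write_ped

CALLERS = ("cnvnator", "erds", "lumpy", "manta")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PlantedVariantSpec:
    """One planted signal or decoy.

    ``pattern`` is the cosegregation pattern realized in the genotypes;
    ``coding=False`` drops the variant outside any CDS (a cosegregating but
    non-coding decoy).  Annotation values decide the prioritization fate and
    are recorded in the ground truth together with the eliminating stage.
    """

    pattern: str = "full"  # full | reduced | none
    consequence: str = "missense_variant"
    mpc: float | None = 2.2
    pli: float | None = 1.0
    gnomad_mac: int = 0
    coding: bool = True
    family: str | None = None  # default: round-robin over families
    label: str = ""


def default_planted_panel() -> list[PlantedVariantSpec]:
    """One pass-all signal per pattern plus one decoy per eliminating clause."""
    return [
        PlantedVariantSpec(pattern="full", label="full_passall"),
        PlantedVariantSpec(pattern="reduced", label="reduced_passall"),
        PlantedVariantSpec(
            pattern="full", consequence="stop_gained", mpc=None, label="full_ptv"
        ),
        PlantedVariantSpec(pattern="full", gnomad_mac=12, label="decoy_mac"),
        PlantedVariantSpec(pattern="full", mpc=1.5, label="decoy_mpc"),
        PlantedVariantSpec(pattern="full", pli=0.5, label="decoy_pli"),
        PlantedVariantSpec(pattern="reduced", coding=False, label="decoy_noncoding"),
        PlantedVariantSpec(pattern="none", label="decoy_noncoseg"),
    ]


@dataclass
class CnvSimSpec:
    n_true_events: int = 2  # per family, carried by >=2 members, all callers
    breakpoint_jitter_bp: int = 0
    caller_dropout: dict[str, float] = field(default_factory=dict)
    n_false_private: int = 2  # per family: single caller, single sample
    n_low_support_shared: int = 1  # per family: single caller, 2 carriers, low support
    n_repeat_heavy: int = 1  # per family: inside the repeat block
    plant_risk_locus_dup: bool = True
    event_size_bp: tuple[int, int] = (5_000, 50_000)
    repeat_track_density: float = 0.5  # within the designated repeat region
    support_range: tuple[float, float] = (0.5, 0.95)
    low_support: float = 0.05


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 6
    generations: int = 3
    cases_per_family: tuple[int, int] = (4, 6)
    planted_variants: list[PlantedVariantSpec] = field(default_factory=default_planted_panel)
    background_variant_count: int = 2_000
    masking_rate: float = 0.0
    missing_rate: float = 0.0
    n_depth_outliers: int = 0
    stress_planted: bool = False  # allow artifacts on planted genotypes
    contigs: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    genes_per_contig: int = 30
    cnv: CnvSimSpec = field(default_factory=CnvSimSpec)
    background_af_beta: tuple[float, float] = (0.2, 2.0)


_STREAMS = ("pedigree", "genotypes", "artifacts", "annotations", "site_info", "cnv")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class PlantedVariantTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    family: str
    gene: str | None
    pattern: str
    label: str
    carriers: list[str]
    expected_retained: bool
    eliminating_stage: str | None  # funnel stage that removes it, if any
    failing_clauses: list[str]


@dataclass
class CnvEventTruth:
    kind: str  # true | false_private | low_support_shared | repeat_heavy | risk_locus_dup
    chrom: str
    start: int
    end: int
    svtype: str
    family: str
    carriers: list[str]
    callers: list[str]
    expected_survives: bool
    expected_removed_by: str | None


@dataclass
class GroundTruth:
    roles: dict[str, str]
    affections: dict[str, str]
    latent_carriers: dict[str, list[str]]
    variants: list[PlantedVariantTruth]
    cnv_events: list[CnvEventTruth]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "roles": self.roles,
            "affections": self.affections,
            "latent_carriers": self.latent_carriers,
            "variants": [asdict(v) for v in self.variants],
            "cnv_events": [asdict(e) for e in self.cnv_events],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Pedigree generation


def _build_structure(
    rng: np.random.Generator, family_id: str, generations: int
) -> tuple[list[Sample], dict[str, Role]]:
    ids = count(1)

    def new(sex: Sex, father: Sample | None = None, mother: Sample | None = None) -> Sample:
        return Sample(
            sample_id=f"{family_id}_{next(ids)}",
            family_id=family_id,
            father_id=None if father is None else father.sample_id,
            mother_id=None if mother is None else mother.sample_id,
            sex=sex,
            affection=Affection.UNKNOWN,
        )

    samples: list[Sample] = []
    roles: dict[str, Role] = {}
    top_f, top_m = new(Sex.MALE), new(Sex.FEMALE)
    samples += [top_f, top_m]
    roles[top_f.sample_id] = roles[top_m.sample_id] = Role.IN_FAMILY
    couples = [(top_f, top_m)]
    for gen in range(2, generations + 1):
        children: list[Sample] = []
        for father, mother in couples:
            for _ in range(int(rng.integers(2, 5))):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                child = new(sex, father=father, mother=mother)
                samples.append(child)
                roles[child.sample_id] = Role.IN_FAMILY
                children.append(child)
        if gen == generations:
            break
        # every intermediate generation contributes at least one marriage,
        # so each family carries marry-in samples (as multiplex rosters do)
        marrying = [c for c in children if rng.random() < 0.7] or children[:1]
        next_couples = []
        for child in marrying:
            spouse = new(Sex.FEMALE if child.sex is Sex.MALE else Sex.MALE)
            samples.append(spouse)
            roles[spouse.sample_id] = Role.MARRY_IN
            pair = (child, spouse) if child.sex is Sex.MALE else (spouse, child)
            next_couples.append(pair)
        couples = next_couples
    return samples, roles


def _latent_drop(
    rng: np.random.Generator, samples: list[Sample], roles: dict[str, Role]
) -> set[str]:
    """Drop one het founder allele down the pedigree; returns carrier ids."""
    carriers: set[str] = {samples[0].sample_id}  # top founder is the origin
    for s in samples:
        if s.is_founder:
            continue
        if (s.father_id in carriers) != (s.mother_id in carriers):
            if rng.random() < 0.5:
                carriers.add(s.sample_id)
        elif s.father_id in carriers and s.mother_id in carriers:
            # cannot occur with a single founder origin, kept for safety
            if rng.random() < 0.75:
                carriers.add(s.sample_id)
    return carriers


def generate_pedigree(
    rng: np.random.Generator,
    family_id: str,
    generations: int = 3,
    cases_range: tuple[int, int] = (4, 6),
) -> tuple[Pedigree, dict[str, Role], set[str]]:
    """Build one pedigree whose latent-haplotype carriers (= cases) number
    within ``cases_range``; returns (pedigree, true roles, latent carriers)."""
    if generations < 2:
        raise ConfigurationError("generations must be >= 2")
    lo, hi = cases_range
    for _ in range(60):
        samples, roles = _build_structure(rng, family_id, generations)
        for _ in range(300):
            carriers = _latent_drop(rng, samples, roles)
            if lo <= len(carriers) <= hi:
                for s in samples:
                    if roles[s.sample_id] is Role.MARRY_IN:
                        s.affection = Affection.UNAFFECTED
                    else:
                        s.affection = (
                            Affection.CASE
                            if s.sample_id in carriers
                            else Affection.UNAFFECTED
                        )
                    s.role = roles[s.sample_id]
                ped = Pedigree(family_id, {s.sample_id: s for s in samples}, set())
                ped.validate()
                return ped, roles, carriers
    raise ConfigurationError(
        f"case count {cases_range} unrealizable for {generations} generations"
    )


def _transmission_leaf_cases(ped: Pedigree, carriers: set[str]) -> list[str]:
    """Carrier cases none of whose children carry (safe to drop from the
    carrier set without breaking Mendelian transmission)."""
    leaves = []
    for sid in sorted(carriers):
        kids = ped.children_of(sid)
        if not any(k.sample_id in carriers for k in kids):
            leaves.append(sid)
    return leaves


# ---------------------------------------------------------------------------
# Gene model and site placement


@dataclass
class SimGene:
    name: str
    chrom: str
    start: int  # 0-based half-open CDS interval
    end: int


def build_gene_model(cfg: SimulationConfig) -> list[SimGene]:
    genes = []
    for ci, (chrom, _length) in enumerate(sorted(cfg.contigs.items()), start=1):
        for gi in range(cfg.genes_per_contig):
            start = 10_000 + gi * 20_000
            genes.append(SimGene(f"GENE{ci}_{gi + 1}", chrom, start, start + 1_500))
    return genes


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class SimSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosage: np.ndarray  # int8 over sample_order, -1 = missing GT
    gq: np.ndarray  # int
    dp: np.ndarray  # int
    info_dp: float
    qd: float
    fs: float
    sor: float
    rprs: float
    planted_label: str | None = None


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pedigrees: list[Pedigree]
    sample_order: list[str]
    sites: list[SimSite]
    genes: list[SimGene]
    annotation_rows: list[dict]
    cnv_calls: list[CnvCall]
    repeat_track: dict[str, list[tuple[int, int]]]
    risk_loci: list[RiskLocus]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Genotype simulation

_BASES = np.array(list("ACGT"))


def _founder_topo_order(ped: Pedigree) -> list[Sample]:
    ordered, placed = [], set()
    pending = ped.members()
    while pending:
        progressed = False
        rest = []
        for s in pending:
            deps = [p for p in (s.father_id, s.mother_id) if p in ped.samples]
            if all(p in placed for p in deps):
                ordered.append(s)
                placed.add(s.sample_id)
                progressed = True
            else:
                rest.append(s)
        if not progressed:
            raise ConfigurationError(f"pedigree {ped.family_id} is not acyclic")
        pending = rest
    return ordered


def _simulate_background(
    rng: np.random.Generator,
    pedigrees: list[Pedigree],
    sample_order: list[str],
    n_sites: int,
    beta: tuple[float, float],
) -> np.ndarray:
    """Gene-drop background variants: founder haplotypes Bernoulli(p) with
    p ~ Beta(a, b) per site, children inherit one allele per parent.
    Returns an (n_sites, n_samples) int8 dosage matrix."""
    idx = {sid: i for i, sid in enumerate(sample_order)}
    af = rng.beta(beta[0], beta[1], size=n_sites).astype(np.float32)
    hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    dosage = np.zeros((n_sites, len(sample_order)), dtype=np.int8)
    for ped in pedigrees:
        for s in _founder_topo_order(ped):
            pats: list[np.ndarray] = []
            for pid in (s.father_id, s.mother_id):
                if pid in hap:
                    h0, h1 = hap[pid]
                    pick = rng.integers(0, 2, size=n_sites).astype(bool)
                    pats.append(np.where(pick, h1, h0))
                else:
                    pats.append((rng.random(n_sites) < af).astype(np.int8))
            hap[s.sample_id] = (pats[0], pats[1])
            dosage[:, idx[s.sample_id]] = pats[0] + pats[1]
    return dosage


# ---------------------------------------------------------------------------
# Top-level generation


def generate(cfg: SimulationConfig) -> SyntheticDataset:
    streams = _rng_streams(cfg.seed)
    ped_rng = streams["pedigree"]

    pedigrees, roles_truth, latent = [], {}, {}
    for i in range(cfg.n_families):
        fam = f"FAM{i + 1}"
        ped, roles, carriers = generate_pedigree(
            ped_rng, fam, cfg.generations, cfg.cases_per_family
        )
        pedigrees.append(ped)
        roles_truth.update({sid: r.value for sid, r in roles.items()})
        latent[fam] = carriers
    sample_order = [s.sample_id for ped in pedigrees for s in ped.members()]
    n = len(sample_order)
    idx = {sid: i for i, sid in enumerate(sample_order)}

    genes = build_gene_model(cfg)
    genes_by_contig: dict[str, list[SimGene]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.chrom, []).append(g)

    # ---- planted variants -------------------------------------------------
    ann_rng = streams["annotations"]
    geno_rng = streams["genotypes"]
    contig_names = sorted(cfg.contigs)
    used_positions: set[tuple[str, int]] = set()
    planted_sites: list[SimSite] = []
    variant_truth: list[PlantedVariantTruth] = []

    for vi, spec in enumerate(cfg.planted_variants):
        fam = spec.family or pedigrees[vi % len(pedigrees)].family_id
        ped = next(p for p in pedigrees if p.family_id == fam)
        carriers = set(latent[fam])
        if spec.pattern == "reduced":
            leaves = _transmission_leaf_cases(ped, carriers)
            if not leaves:
                raise ConfigurationError("reduced pattern unrealizable: no leaf case")
            carriers.discard(leaves[int(geno_rng.integers(0, len(leaves)))])
        elif spec.pattern == "none":
            marryins = sorted(
                sid for sid, r in roles_truth.items()
                if r == Role.MARRY_IN.value and sid in ped.samples
            )
            if not marryins:
                raise ConfigurationError("'none' decoy needs a marry-in sample")
            carriers.add(marryins[int(geno_rng.integers(0, len(marryins)))])
        elif spec.pattern != "full":
            raise ConfigurationError(f"unknown planted pattern {spec.pattern!r}")

        gene = None
        if spec.coding:
            pool = genes_by_contig[contig_names[vi % len(contig_names)]]
            gene = pool[vi % len(pool)]
            chrom = gene.chrom
            pos = int(gene.start + 1 + ann_rng.integers(0, gene.end - gene.start))
        else:
            chrom = contig_names[vi % len(contig_names)]
            pos = int(5_000 + ann_rng.integers(0, 4_000))  # upstream of every gene
        while (chrom, pos) in used_positions:
            pos += 1
        used_positions.add((chrom, pos))

        ref, alt = "A", "G"
        dosage = np.zeros(n, dtype=np.int8)
        for sid in carriers:
            dosage[idx[sid]] = 1
        site = SimSite(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            dosage=dosage,
            gq=np.full(n, 99, dtype=np.int32),
            dp=np.full(n, 40, dtype=np.int32),
            info_dp=0.0,  # filled with the cohort baseline below
            qd=20.0,
            fs=1.0,
            sor=1.0,
            rprs=0.0,
            planted_label=spec.label or f"planted_{vi}",
        )
        planted_sites.append(site)
        variant_truth.append(
            _plant_truth(spec, site, fam, gene, sorted(carriers))
        )

    # ---- background variants ----------------------------------------------
    site_rng = streams["site_info"]
    n_bg = cfg.background_variant_count
    bg_dosage = _simulate_background(
        geno_rng, pedigrees, sample_order, n_bg, cfg.background_af_beta
    )
    bg_sites: list[SimSite] = []
    contig_lengths = np.array([cfg.contigs[c] for c in contig_names])
    probs = contig_lengths / contig_lengths.sum()
    for i in range(n_bg):
        chrom = contig_names[int(site_rng.choice(len(contig_names), p=probs))]
        pos = int(site_rng.integers(1, cfg.contigs[chrom] + 1))
        while (chrom, pos) in used_positions:
            pos = int(site_rng.integers(1, cfg.contigs[chrom] + 1))
        used_positions.add((chrom, pos))
        ref, alt = site_rng.choice(4, size=2, replace=False)
        bg_sites.append(
            SimSite(
                chrom=chrom,
                pos=pos,
                ref=str(_BASES[ref]),
                alt=str(_BASES[alt]),
                dosage=bg_dosage[i].copy(),
                gq=site_rng.integers(60, 100, size=n).astype(np.int32),
                dp=site_rng.integers(20, 61, size=n).astype(np.int32),
                info_dp=0.0,
                qd=float(site_rng.uniform(5, 30)),
                fs=float(site_rng.uniform(0, 5)),
                sor=float(site_rng.uniform(0.3, 2.5)),
                rprs=float(site_rng.normal(0, 1)),
            )
        )

    sites = planted_sites + bg_sites
    base_dp = 30.0 * n
    for s in sites:
        s.info_dp = float(site_rng.normal(base_dp, 0.1 * base_dp))
    n_out = min(cfg.n_depth_outliers, len(bg_sites))
    if n_out:
        for i in site_rng.choice(len(bg_sites), size=n_out, replace=False):
            bg_sites[int(i)].info_dp = base_dp * 10  # far beyond mean + 5 SD

    # ---- QC artifacts -----------------------------------------------------
    art_rng = streams["artifacts"]
    for s in sites:
        if s.planted_label is not None and not cfg.stress_planted:
            continue
        if cfg.masking_rate > 0:
            hit = art_rng.random(n) < cfg.masking_rate
            low_gq = art_rng.random(n) < 0.5
            s.gq[hit & low_gq] = art_rng.integers(0, 20)
            s.dp[hit & ~low_gq] = art_rng.integers(0, 10)
        if cfg.missing_rate > 0:
            s.dosage[art_rng.random(n) < cfg.missing_rate] = -1

    sites.sort(key=lambda s: (contig_names.index(s.chrom), s.pos))

    # ---- annotations -------------------------------------------------------
    annotation_rows = _build_annotations(cfg, ann_rng, sites, genes_by_contig, variant_truth)

    # ---- CNVs ---------------------------------------------------------------
    repeat_track, risk_loci, cnv_calls, cnv_truth = _simulate_cnvs(
        cfg, streams["cnv"], pedigrees
    )

    truth = GroundTruth(
        roles=roles_truth,
        affections={
            s.sample_id: s.affection.value for ped in pedigrees for s in ped.members()
        },
        latent_carriers={fam: sorted(c) for fam, c in latent.items()},
        variants=variant_truth,
        cnv_events=cnv_truth,
    )
    return SyntheticDataset(
        config=cfg,
        pedigrees=pedigrees,
        sample_order=sample_order,
        sites=sites,
        genes=genes,
        annotation_rows=annotation_rows,
        cnv_calls=cnv_calls,
        repeat_track=repeat_track,
        risk_loci=risk_loci,
        truth=truth,
    )


def _plant_truth(
    spec: PlantedVariantSpec,
    site: SimSite,
    fam: str,
    gene: SimGene | None,
    carriers: list[str],
) -> PlantedVariantTruth:
    from .prioritization import (
        CLAUSE_CONSTRAINT,
        CLAUSE_FUNCTIONAL,
        CLAUSE_ULTRARARE,
        AnnotationRecord,
        evaluate_record,
    )

    if spec.pattern == "none":
        return PlantedVariantTruth(
            site.chrom, site.pos, site.ref, site.alt, fam, gene.name if gene else None,
            spec.pattern, spec.label, carriers, False, "Cosegregation Pattern", []
        )
    if not spec.coding:
        return PlantedVariantTruth(
            site.chrom, site.pos, site.ref, site.alt, fam, None,
            spec.pattern, spec.label, carriers, False, "In the Coding Sequence", []
        )
    rec = AnnotationRecord(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alt=site.alt,
        gene=gene.name,
        consequence=frozenset({spec.consequence}),
        mpc=spec.mpc,
        gnomad_mac=spec.gnomad_mac,
        pli=spec.pli,
    )
    retained, failing = evaluate_record(rec)
    stage_order = [CLAUSE_ULTRARARE, CLAUSE_FUNCTIONAL, CLAUSE_CONSTRAINT]
    eliminating = next((s for s in stage_order if s in failing), None)
    return PlantedVariantTruth(
        site.chrom, site.pos, site.ref, site.alt, fam, gene.name,
        spec.pattern, spec.label, carriers, retained, eliminating, failing
    )


def _build_annotations(cfg, rng, sites, genes_by_contig, variant_truth) -> list[dict]:
    truth_by_key = {(t.chrom, t.pos, t.ref, t.alt): t for t in variant_truth}
    spec_by_label = {
        (s.label or f"planted_{i}"): s for i, s in enumerate(cfg.planted_variants)
    }
    rows = []
    for site in sites:
        key = (site.chrom, site.pos, site.ref, site.alt)
        if site.planted_label is not None:
            t = truth_by_key[key]
            if t.gene is None:
                continue  # non-coding plant: deliberately unannotated
            spec = spec_by_label[t.label]
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": site.alt,
                    "gene": t.gene,
                    "transcript": f"{t.gene}_T1",
                    "consequence": spec.consequence,
                    "MPC": "" if spec.mpc is None else spec.mpc,
                    "CADD": round(float(rng.uniform(20, 35)), 1),
                    "SIFT": "damaging",
                    "PolyPhen2": "deleterious",
                    "gnomAD_AC": spec.gnomad_mac,
                    "pLI": "" if spec.pli is None else spec.pli,
                    "mis_Z": round(float(rng.uniform(2, 5)), 2),
                    "LOEUF": round(float(rng.uniform(0.1, 0.4)), 2),
                }
            )
            continue
        # annotate coding background variants with benign profiles
        for g in genes_by_contig.get(site.chrom, []):
            if g.start < site.pos <= g.end:  # 1-based pos vs half-open CDS
                rows.append(
                    {
                        "chrom": site.chrom,
                        "pos": site.pos,
                        "ref": site.ref,
                        "alt": site.alt,
                        "gene": g.name,
                        "transcript": f"{g.name}_T1",
                        "consequence": "synonymous_variant",
                        "MPC": "",
                        "CADD": round(float(rng.uniform(0, 10)), 1),
                        "SIFT": "tolerated",
                        "PolyPhen2": "benign",
                        "gnomAD_AC": int(rng.integers(0, 200)),
                        "pLI": round(float(rng.random()), 2),
                        "mis_Z": round(float(rng.normal(0, 1)), 2),
                        "LOEUF": round(float(rng.uniform(0.2, 1.5)), 2),
                    }
                )
    return rows


# ---------------------------------------------------------------------------
# CNV simulation

_REPEAT_REGION = (750_000, 990_000)  # repeats confined here on every contig
_EVENT_REGION = (10_000, 500_000)  # true/false events placed here
_RISK_LOCUS = ("chr2", 600_000, 700_000)  # emulates a recurrent risk locus


def _simulate_cnvs(cfg: SimulationConfig, rng: np.random.Generator, pedigrees):
    spec = cfg.cnv
    contig_names = sorted(cfg.contigs)

    # repeat track: random blocks filling `repeat_track_density` of the region
    repeat_track: dict[str, list[tuple[int, int]]] = {}
    lo, hi = _REPEAT_REGION
    for chrom in contig_names:
        blocks, cursor = [], lo
        while cursor < hi:
            blk = int(rng.integers(2_000, 20_000))
            gap = int(blk * (1 - spec.repeat_track_density) / max(spec.repeat_track_density, 1e-9))
            if rng.random() < 0.9:
                blocks.append((cursor, min(cursor + blk, hi)))
            cursor += blk + max(gap, 500)
        if not blocks:
            blocks.append((lo, lo + 10_000))
        repeat_track[chrom] = blocks

    risk_loci = [RiskLocus(_RISK_LOCUS[0], _RISK_LOCUS[1], _RISK_LOCUS[2], "DUP", "locus_16p11_like")]

    calls: list[CnvCall] = []
    truth: list[CnvEventTruth] = []

    def emit(samples, chrom, start, end, svtype, callers, support):
        for sid in samples:
            for caller in callers:
                j = spec.breakpoint_jitter_bp
                s = start + (int(rng.integers(-j, j + 1)) if j else 0)
                e = end + (int(rng.integers(-j, j + 1)) if j else 0)
                if e <= s:
                    e = s + 1
                calls.append(
                    CnvCall(
                        sample_id=sid,
                        chrom=chrom,
                        start=max(s, 0),
                        end=e,
                        svtype=svtype,
                        caller=caller,
                        support_fraction=round(float(support), 3),
                    )
                )

    for ped in pedigrees:
        members = sorted(ped.samples)
        fam = ped.family_id
        placed: dict[str, list[tuple[int, int]]] = {}

        def rand_span(chrom: str) -> tuple[int, int]:
            # reject spans touching any event already placed in this family,
            # so per-event filter expectations cannot cross-contaminate
            for _ in range(200):
                size = int(rng.integers(*spec.event_size_bp))
                start = int(rng.integers(_EVENT_REGION[0], _EVENT_REGION[1] - size))
                end = start + size
                if all(e <= start or s >= end for s, e in placed.get(chrom, [])):
                    placed.setdefault(chrom, []).append((start, end))
                    return start, end
            raise ConfigurationError("could not place a non-overlapping CNV event")

        for _ in range(spec.n_true_events):
            chrom = contig_names[int(rng.integers(0, len(contig_names)))]
            start, end = rand_span(chrom)
            svtype = "DEL" if rng.random() < 0.5 else "DUP"
            k = int(rng.integers(2, min(4, len(members)) + 1))
            carriers = sorted(rng.choice(members, size=k, replace=False))
            kept_callers = [
                c for c in CALLERS if rng.random() >= spec.caller_dropout.get(c, 0.0)
            ]
            if not kept_callers:
                kept_callers = [CALLERS[int(rng.integers(0, len(CALLERS)))]]
            emit(carriers, chrom, start, end, svtype, kept_callers, rng.uniform(*spec.support_range))
            truth.append(
                CnvEventTruth(
                    "true", chrom, start, end, svtype, fam, list(carriers),
                    list(kept_callers), True, None
                )
            )

        for _ in range(spec.n_false_private):
            chrom = contig_names[int(rng.integers(0, len(contig_names)))]
            start, end = rand_span(chrom)
            svtype = "DEL" if rng.random() < 0.5 else "DUP"
            sid = str(rng.choice(members))
            caller = CALLERS[int(rng.integers(0, len(CALLERS)))]
            emit([sid], chrom, start, end, svtype, [caller], rng.uniform(*spec.support_range))
            truth.append(
                CnvEventTruth(
                    "false_private", chrom, start, end, svtype, fam, [sid],
                    [caller], False, "pedigree_support"
                )
            )

        for _ in range(spec.n_low_support_shared):
            chrom = contig_names[int(rng.integers(0, len(contig_names)))]
            start, end = rand_span(chrom)
            svtype = "DEL" if rng.random() < 0.5 else "DUP"
            carriers = sorted(rng.choice(members, size=2, replace=False))
            caller = CALLERS[int(rng.integers(0, len(CALLERS)))]
            emit(carriers, chrom, start, end, svtype, [caller], spec.low_support)
            truth.append(
                CnvEventTruth(
                    "low_support_shared", chrom, start, end, svtype, fam,
                    list(carriers), [caller], False, "breakpoint_support"
                )
            )

        for _ in range(spec.n_repeat_heavy):
            chrom = contig_names[int(rng.integers(0, len(contig_names)))]
            block = repeat_track[chrom][int(rng.integers(0, len(repeat_track[chrom])))]
            start = block[0]
            end = min(block[1], start + int(rng.integers(*spec.event_size_bp)))
            if end - start < 1_000:
                end = start + 1_000
            carriers = sorted(rng.choice(members, size=2, replace=False))
            emit(carriers, chrom, start, end, "DEL", ["cnvnator", "erds"],
                 rng.uniform(*spec.support_range))
            truth.append(
                CnvEventTruth(
                    "repeat_heavy", chrom, start, end, "DEL", fam, list(carriers),
                    ["cnvnator", "erds"], False, "repeat_fraction"
                )
            )

    if spec.plant_risk_locus_dup and pedigrees:
        ped = pedigrees[0]
        sid = sorted(ped.samples)[0]
        chrom, lstart, lend = _RISK_LOCUS
        start, end = lstart - 2_000, lend + 3_000
        emit([sid], chrom, start, end, "DUP", ["cnvnator", "erds"],
             rng.uniform(*spec.support_range))
        truth.append(
            CnvEventTruth(
                "risk_locus_dup", chrom, start, end, "DUP", ped.family_id, [sid],
                ["cnvnator", "erds"], True, None
            )
        )

    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.caller, c.sample_id))
    return repeat_track, risk_loci, calls, truth


# ---------------------------------------------------------------------------
# File writers


def write_vcf(ds: SyntheticDataset, path: str | Path) -> None:
    contig_names = sorted(ds.config.contigs)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contig_names:
            fh.write(f"##contig=<ID={c},length={ds.config.contigs[c]}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand">\n')
        fh.write('##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">\n')
        fh.write(
            '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
            + "FORMAT\t"
            + "\t".join(ds.sample_order)
            + "\n"
        )
        gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for s in ds.sites:
            info = (
                f"DP={int(round(s.info_dp))};QD={s.qd:.2f};FS={s.fs:.2f};"
                f"SOR={s.sor:.2f};ReadPosRankSum={s.rprs:.2f}"
            )
            cols = [s.chrom, str(s.pos), ".", s.ref, s.alt, "100", "PASS", info, "GT:GQ:DP"]
            for i in range(len(ds.sample_order)):
                cols.append(f"{gt_str[int(s.dosage[i])]}:{int(s.gq[i])}:{int(s.dp[i])}")
            fh.write("\t".join(cols) + "\n")


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus the ground truth; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = outdir / "cohort.vcf"
    write_vcf(ds, paths["vcf"])

    paths["ped"] = outdir / "cohort.ped"
    write_ped(ds.pedigrees, paths["ped"])

    paths["annotations"] = outdir / "annotations.tsv"
    import pandas as pd

    from .prioritization import ANNOTATION_COLUMNS

    pd.DataFrame(ds.annotation_rows, columns=ANNOTATION_COLUMNS).to_csv(
        paths["annotations"], sep="\t", index=False
    )

    paths["gene_model"] = outdir / "gene_model.bed"
    with open(paths["gene_model"], "w") as fh:
        for g in ds.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")

    for caller in CALLERS:
        p = outdir / f"cnv_{caller}.tsv"
        with open(p, "w") as fh:
            for c in ds.cnv_calls:
                if c.caller != caller:
                    continue
                sf = "." if c.support_fraction is None else f"{c.support_fraction}"
                fh.write(
                    f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.svtype}\t{sf}\n"
                )
        paths[f"cnv_{caller}"] = p

    paths["repeat_track"] = outdir / "repeats.bed"
    with open(paths["repeat_track"], "w") as fh:
        for chrom in sorted(ds.repeat_track):
            for s, e in ds.repeat_track[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")

    paths["risk_loci"] = outdir / "risk_loci.bed"
    with open(paths["risk_loci"], "w") as fh:
        for l in ds.risk_loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.name}\t{l.svtype}\n")

    paths["ground_truth"] = outdir / "ground_truth.json"
    ds.truth.to_json(paths["ground_truth"])
    return paths
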