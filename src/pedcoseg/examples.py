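"""Worked-example inputs bundled with the package.

``CANDIDATE_VARIANTS`` holds the published annotation values for the three
candidate ultrarare missense variants that the reduced-cosegregation screen
of a six-pedigree schizophrenia cohort produced (one each in *ATP2B2*,
*SLC25A28* and *GSK3A*), on GRCh38 coordinates: the gnomAD exome minor
allele count (MAC), MPC and CADD deleteriousness scores, SIFT/PolyPhen2
categories, and gene-level constraint (pLI, missense Z, LOEUF).  They are
the canonical worked example for the prioritization conjunction: all three
satisfy MAC <= 5, MPC > 2 and pLI > 0.9.

``build_roster_38`` reconstructs that cohort's sequencing roster: 38
samples sent for sequencing across 6 pedigrees, of which 2 failed
sequencing on DNA quality and 1 was removed as unrelated to its siblings,
leaving 35 for analysis.
"""

from __future__ import annotations

from .pedigree import Affection, Pedigree, Sample, Sex

CANDIDATE_VARIANTS = [
    {
        "family": "K1546",
        "chrom": "3",
        "pos": 1_036_002,
        "ref": "G",
        "alt": "A",
        "gene": "ATP2B2",
        "hgvsp": "R588C",
        "MAC": 1,
        "MPC": 2.23,
        "CADD": 31.0,
        "SIFT": "damaging",
        "PolyPhen2": "deleterious",
        "pLI": 1.00,
        "mis_Z": 4.55,
        "LOEUF": 0.15,
    },
    {
        "family": "K1524",
        "chrom": "10",
        "pos": 99_610_923,
        "ref": "T",
        "alt": "C",
        "gene": "SLC25A28",
        "hgvsp": "I341V",
        "MAC": 0,
        "MPC": 2.11,
        "CADD": 25.6,
        "SIFT": "damaging",
        "PolyPhen2": "deleterious",
        "pLI": 0.93,
        "mis_Z": 2.92,
        "LOEUF": 0.37,
    },
    {
        "family": "K1494",
        "chrom": "19",
        "pos": 42_232_651,
        "ref": "A",
        "alt": "G",
        "gene": "GSK3A",
        "hgvsp": "I377T",
        "MAC": 0,
        "MPC": 2.39,
        "CADD": 26.9,
        "SIFT": "damaging",
        "PolyPhen2": "deleterious",
        "pLI": 1.00,
        "mis_Z": 3.22,
        "LOEUF": 0.13,
    },
]

# Retained sample counts per pedigree (totalling 35) plus the three
# excluded samples, assigned to their named families.
_RETAINED_PER_FAMILY = {
    "K1480": 5,
    "K1494": 5,
    "K1501": 7,
    "K1524": 4,
    "K1527": 6,
    "K1546": 8,
}

SAMPLE_EXCLUSIONS = {
    "K1501_9": "failed sequencing (low-quality DNA)",
    "K1527_33": "failed sequencing (low-quality DNA)",
    "K1524_3": "unrelated to siblings",
}


def build_roster_38() -> list[Pedigree]:
    """The 38-sample sequencing roster as per-family pedigrees (sample ids
    only; pedigree structure is irrelevant for the exclusion count)."""
    pedigrees = []
    for fam, n_retained in sorted(_RETAINED_PER_FAMILY.items()):
        ped = Pedigree(fam, {}, set())
        for i in range(1, n_retained + 1):
            sid = f"{fam}_{i}"
            if sid in SAMPLE_EXCLUSIONS:  # keep ids distinct from excluded ones
                sid = f"{fam}_{i}r"
            ped.add(Sample(sid, fam, None, None, Sex.UNKNOWN, Affection.UNKNOWN))
        pedigrees.append(ped)
    by_fam = {p.family_id: p for p in pedigrees}
    for sid in sorted(SAMPLE_EXCLUSIONS):
        fam = sid.rsplit("_", 1)[0]
        by_fam[fam].add(Sample(sid, fam, None, None, Sex.UNKNOWN, Affection.UNKNOWN))
    assert sum(len(p.samples) for p in pedigrees) == 38
    return pedigrees


def candidate_annotation_records():
    """The worked-example rows as AnnotationRecord objects."""
    from .prioritization import AnnotationRecord

    return [
        AnnotationRecord(
            chrom=row["chrom"],
            pos=row["pos"],
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            transcript=None,
            consequence=frozenset({"missense_variant"}),
            mpc=row["MPC"],
            cadd=row["CADD"],
            sift=row["SIFT"],
            polyphen2=row["PolyPhen2"],
            gnomad_mac=row["MAC"],
            pli=row["pLI"],
            mis_z=row["mis_Z"],
            loeuf=row["LOEUF"],
        )
        for row in CANDIDATE_VARIANTS
    ]
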