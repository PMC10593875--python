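# Methods

This note documents the models, rules and numerical choices behind
`pedcoseg`, and what the synthetic-data generator does and does not
emulate.

## The cosegregation model

The pipeline assumes a dominant, high-penetrance model within each
pedigree: a risk variant inherited from a common ancestor should be
carried by the affected in-family members and absent from unaffected
in-family members and from individuals who married into the family.
Heterozygous and homozygous-alternate genotypes count equally as
"carrying".

Two pattern classes are recognized per family-private variant:

* **full** — every sequenced in-family case carries the variant; no
  sequenced in-family control and no marry-in sample carries it;
* **reduced** — exactly one sequenced in-family case does not carry it
  (a phenocopy allowance), everything else as in *full*.

The two classes are disjoint: a fully cosegregating variant is reported as
*full* only. *Reduced* additionally requires at least
`min_cases_reduced = 3` sequenced cases, because with two cases "all but
one" degenerates to a single carrier and the pattern loses meaning.

**Missing genotypes.** Under the default `strict` policy, a required
carrier must be affirmatively genotyped as a carrier and a required
non-carrier affirmatively genotyped as homozygous reference; a masked or
missing genotype in a constrained role voids the pattern (a masked case
degrades *full* to *none*, never to *reduced*). The `lenient` policy
treats missing genotypes as compatible with any requirement, constraining
only the affirmatively genotyped samples. Strict is the default because
genotype masking runs before cosegregation and an unverifiable genotype
should not certify a pattern.

**Unknown affection.** Samples with unknown affection are ignored by
default (they are neither required carriers nor disqualifying
non-carriers); `unknown_policy="treat_as_control"` makes them obligate
non-carriers. Marry-in samples are obligate non-carriers regardless of
their affection status — they did not inherit from the lineage founders,
so their carriage would indicate an independent origin. In the degenerate
case of a sample annotated both as a case and as a marry-in, the marry-in
constraint governs.

**Roles.** Explicit role annotation (7th PED column, `IN`/`MARRY`) is the
primary mechanism. The inference fallback classifies a founder (no listed
parents) as marry-in when it co-parents with a non-founder; everything
else, including the founder couple at the top of the pedigree, is
in-family. This is a heuristic that matches typical multiplex rosters but
cannot resolve, e.g., two unrelated founder couples in one family record.

## Mendelian screen

For every trio with all three members sequenced and unmasked, the child's
genotype must be composable from one transmitted allele per parent.
Dosage coding (0/1/2) is used throughout. On chrX a male is hemizygous:
his dosage must be 0 or 2 and his single allele must come from the mother;
a het-coded male X (dosage 1) is itself counted as a violation rather than
skipped, since it cannot arise from a consistent hemizygous call. On chrY
the single allele passes father to son, and any non-reference female Y
call is a violation. Trios with a masked or missing member are skipped,
not failed.

## Quality control

Thresholds follow GATK-style post-genotyping practice and are all strict
inequalities at their boundaries:

| parameter | default | action |
|---|---|---|
| `gq_min` | 20.0 | genotype masked when GQ < 20 |
| `dp_min` | 10 | genotype masked when DP < 10 |
| `missingness_max` | 0.20 | site dropped when missing+masked fraction > 20% |
| `depth_sd_mult` | 5.0 | site dropped when depth > mean + 5 SD |
| `qd_min` / `rprs_min` / `fs_max` / `sor_max` | 2.0 / −20.0 / 200.0 / 10.0 | hard filters, non-SNV/indel sites only |

Choices where upstream conventions leave room:

* A genotype with *absent* GQ or DP is masked — quality cannot be
  certified, so the conservative action is taken.
* The depth-outlier mean/SD use the population (n) denominator and are
  computed once over the declared input set; site depth comes from
  INFO/DP, falling back to summed FORMAT/DP.
* After a multiallelic split, a sample carrying a *different* alternate
  allele is coded 0 for the current alternate (the `bcftools norm`
  convention); `other_alt_policy="missing"` switches this to missing.
  Split alleles are parsimony-trimmed (shared suffix, then prefix).
* "Standard chromosomes" are 1–22, X and Y — not MT — in either `chr`-
  prefixed or bare naming.
* Upstream recalibration (VQSR) is not re-implemented; the VCF FILTER
  column is honored instead: any non-PASS flag drops the site.

## Prioritization

Per (variant, gene) annotation record, evaluated on the gene's canonical
transcript, the conjunction is:

1. gnomAD exome minor allele count ≤ `mac_max` (5); absence from gnomAD
   counts as 0;
2. protein-truncating consequence (frameshift, stop gained, splice
   acceptor/donor — splice *region* and in-frame indels deliberately do
   not qualify) **or** missense with MPC > `mpc_min` (2, exclusive); a
   missense lacking an MPC score never qualifies;
3. pLI > `pli_min` (0.9, exclusive).

MPC class labels (class I: MPC ≥ 3; class II: 2 ≤ MPC < 3) are reported
alongside but do not drive the filter — the filter is the strict
`MPC > 2` rule. A variant is retained if any of its gene rows is
retained; candidates with no annotation are reported as unannotatable
rather than silently dropped. Coding-sequence restriction intersects the
variant's reference span (1-based VCF position converted to a 0-based
half-open interval) with CDS intervals from a 4-column BED.

## CNV consensus

Coordinates are 0-based half-open throughout. Reciprocal overlap is
`min(overlap/len(a), overlap/len(b))`; the merge criterion is ≥ 0.5
(inclusive), reused for within-caller collapsing, the two-stage
consensus, and cross-sample matching in the pedigree-support rule, since
no separate cross-sample threshold is established practice.

* **Collapse/merge semantics.** Merged spans are the union of member
  spans — a conservative locus definition for downstream screening.
  Merging iterates to a fixpoint; because a union span can dilute its
  overlap with a further call, a chain of pairwise-mergeable calls may
  legitimately resolve to more than one cluster (a pinned test documents
  this).
* **Two-stage consensus.** Read-depth callers (CNVnator, ERDS) merge with
  each other first, paired-end/split-read callers (LUMPY, Manta)
  likewise, then the two class-level sets merge. Clusters never span
  samples; family support is established by cross-sample matching, which
  requires identical svtype.
* **Filters.** Repeat filter: drop when strictly more than 50% of the
  cluster span lies in the pre-unioned repeat/low-complexity track
  (exactly 50% is kept). Pedigree support: keep when ≥ 2 callers agree or
  the event matches in ≥ 2 individuals of the pedigree. Breakpoint
  support: applies only to clusters kept solely by the multi-individual
  route with a single caller; dropped when all member support fractions
  fall below `min_support = 0.2` — "low support" has no established
  value, so the default is exposed in configuration and recorded in
  output; clusters without support data pass with a warning. Read
  counting from alignments is out of scope: the support fraction is an
  input column.
* **Risk-locus screen.** A cluster is reported when it covers ≥ 50% of a
  locus with matching svtype (locus coverage, not reciprocal overlap,
  because risk loci are typically much larger than any one call's
  uncertainty).

## The synthetic-data generator

The generator emulates the target study design — a handful of
multi-generation multiplex pedigrees, jointly genotyped — on a miniature
genome of three autosomal 1 Mb contigs with 30 single-exon genes (1.5 kb
CDS) per contig, small enough for base-by-base oracles.

**Affection from a latent gene-drop.** Each pedigree (default: 3
generations, 2–4 children per couple, each intermediate generation
contributing at least one marry-in spouse) receives a latent heterozygous
haplotype dropped from a top founder; generation is retried until the
carrier count lands in `cases_per_family` (default 4–6). In-family
carriers become cases, everyone else unaffected. Planted variants reuse
this haplotype, making full/reduced patterns Mendelian-consistent by
construction: *reduced* removes a transmission-leaf case (one with no
carrying children), *none*-pattern decoys add one heterozygous marry-in
founder. The default planted panel is one pass-all signal per pattern
(missense and PTV) plus one decoy per eliminating clause (MAC 12,
MPC 1.5, pLI 0.5, non-coding placement, non-cosegregating pattern), so
clause-level attribution is testable.

**Background variation.** Per-site allele frequencies follow
Beta(0.2, 2) — a rare-skewed site-frequency spectrum — with founder
haplotypes drawn Bernoulli(p) and children inheriting one allele per
parent by fair meiosis (no linkage or recombination map; sites are
independent). Defaults: 2,000 background sites for routine runs; the
signal-recovery check in the test suite runs 6 families at 50,000 sites.
Baseline call quality is high (GQ 60–99, DP 20–60); `masking_rate` and
`missing_rate` inject low-GQ/low-DP and uncalled genotypes, never on
genotypes a planted pattern constrains unless `stress_planted` is set.
Cohort site depth is Normal(30·n, 3·n) with optional planted outliers far
beyond the 5-SD cut.

**CNV call sets.** Per family: 2 true events (5–50 kb, ≥ 2 carriers, all
four callers, support 0.5–0.95), 2 single-caller/single-sample artifacts,
1 low-support (0.05) single-caller event shared by two relatives, and 1
event confined to the repeat region; plus one cohort-level duplication
fully covering a planted risk locus, called by both read-depth callers in
one sample. Breakpoint jitter and per-caller dropout are configurable and
default to zero. Repeats occupy a designated 750–990 kb block per contig
at ~50% density, and event placement rejects within-family overlaps so
each event's expected filter fate is unambiguous.

**Determinism.** All randomness flows from one seed through named
substreams (pedigree, genotypes, artifacts, annotations, site_info, cnv),
spawned in a fixed order, so adding one component's draws never perturbs
another's; identical configurations produce byte-identical files.

**What passing tests do not show.** The generator has no linkage
disequilibrium, recombination, sequencing-read level error structure,
population stratification, batch effects, annotation errors, or caller-
specific breakpoint biases; pedigrees are fully sequenced. Passing the
recovery tests demonstrates the correctness of the decision rules under
the stated model, not robustness to real-data artifacts beyond the
injected masking/missingness and CNV jitter/dropout.

## Known limitations

* Cosegregation classification treats each variant independently; no
  haplotype sharing or identity-by-descent inference.
* The Mendelian screen ignores de novo mutation as a legitimate
  explanation — any violation fails the variant, which is the intended
  behavior for inherited-variant discovery but discards true de novos.
* Multiallelic split alleles are parsimony-trimmed but not left-aligned
  against a reference sequence.
* The within-sample collapse fixpoint is order-canonicalized (inputs are
  sorted) but, as noted, chains of marginal overlaps are resolved
  greedily left to right.
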