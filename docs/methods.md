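# Methods

This note documents the models, rules, defaults, and design choices behind
`exofam`, and what the synthetic cohorts do and do not establish about real
data.

## Data model and coordinates

VCF positions are kept 1-based; CNV intervals are 0-based half-open
(CNVkit convention). Each source format keeps its native convention and is
converted once at the boundary. Contig names are normalized to the
`chr`-prefixed dialect. Multiallelic VCF records are split into biallelic
records before any filtering, with per-allele allele depths, and alleles are
normalized by trimming shared trailing then leading bases (reference-free).
A missing genotype (`./.`) is *unknown*, never homozygous reference: absence
of evidence must not create segregation calls. Individuals affected with
conditions other than the ascertained one (e.g. grandmothers) are treated as
unaffected controls.

## Filtration

Quality retention is per genotype: DP ≥ 10 and GQ ≥ 30, both inclusive.
Genotypes with an absent DP or GQ are dropped conservatively and counted
under a reason code. Rarity uses a strict < 0.01 cutoff on every reported
frequency, overall and sub-population alike; absent frequencies do not veto
rarity (a variant with no database entry is novel, hence rare). "Private"
is person-level, not family-level: a variant shared by a proband and a
parent is not private. Per-exome count summaries are computed over post-split
biallelic records; whether published per-exome counts include split records
is generally not stated, so this is documented as the package's convention.

## Segregation

The stage order is fixed: quality → rare → novel → private → segregation.
De novo calling runs over private variants; the inherited modes run over
rare variants.

Decisions made where the rules leave room:

- **De novo auxiliary criteria** (GQ ≥ 99, AD-Alt ≥ 10, AD-Ref ≥ 10,
  0.3 ≤ AD-Alt/DP ≤ 0.7) are evaluated on the proband's genotype only;
  relatives are constrained separately through the absence requirement.
  "Absent from the exome" means a quality-retained 0/0; a missing genotype
  in a recorded relative makes the call not-evaluable rather than de novo,
  which prevents dropout-driven false positives. With one parent missing
  from the pedigree the call is still made, flagged `one_parent_only`.
- **Compound heterozygosity** requires both parents; the AD/allele-balance
  filter is applied to the proband's genotype at each member variant (whose
  genotype the filter applies to is not specified upstream; the proband's is
  the conservative reading since parental hets are already constrained).
  Pairs are not pruned by unaffected-sibling trans-carriage by default; a
  strict mode (`strict_sibling_comp_het`) adds that pruning.
- **Inherited homozygous** calling excludes only *unaffected* siblings that
  are homozygous-alt; affected siblings are allowed to share the genotype.
  Male probands are excluded on non-PAR chrX, where a diploid-encoded 1/1
  is hemizygosity, not recessive homozygosity — that case belongs to the
  X-linked caller.
- **X-linked** calls accept haploid (`1`) and diploid-style (`1/1`)
  hemizygous encodings, since pVCF conventions vary. PAR1/PAR2 (GRCh38
  coordinates) are treated as autosomal and excluded. Female probands are
  rejected by default; `allow_female_x` admits homozygous affected females
  as a documented deviation.

## Prioritization

Only steps 1, 6, 7 and the oversized-gene rate screen remove variants;
steps 3–5 are soft rank components. This reproduces published candidate
tables in which survivors include genes with pLI ≈ 0 — constraint
prioritizes, it does not filter. "Unrelated person" in step 1 means a
different family ID; identical variants within a family (affected sibling
pairs) are kept.

The step-4 deleteriousness composite counts VEST ≥ 0.5, CADD ≥ 20 and
phyloP ≥ 2.0 (the tools are standard; these numeric cutoffs are this
package's configurable defaults — upstream sources name the tools without
cutoffs). ClinVar matching is case-insensitive on labels asserting only
benign/likely-benign, including composite labels. The homozygous-carrier
filter applies to all inheritance modes with a strict ≥ 1 threshold.
AlphaMissense is a ranking signal only; an absent score sorts last among
missense variants.

The oversized-gene screen divides the total base pairs carrying missense
variants in the gene for one proband by the gene's coding length and drops
the gene's candidates for that proband iff the quotient exceeds the
population reference rate (default gene list: TTN, coding length 108,000 bp,
reference 1.23 × 10⁻⁵ per bp). With 1 missense bp the rate (9.26 × 10⁻⁶)
is below the reference and the variant is kept; with 2 it already exceeds it.

Step order is audited: every ladder input carries a full step trace with
exactly one terminal state, inputs always equal survivors plus per-step
drops, and re-running the ladder is idempotent.

## CNV screening

Order: outlier-sample exclusion → per-segment filters → exact cross-family
dedup → locus annotation → common-SV containment. The outlier policy is
explicit (raw per-sample segment count > median + 3·MAD, unscaled MAD)
because published removals of this kind are typically manual judgments.
Known-locus "overlap" is ≥ 1 bp of intersection, with overlap bp reported so
stricter reciprocal-overlap policies can be layered on; overlap annotates
and never drops. "Complete overlap" with a common SV means containment of
the call within the SV interval, with the SV type required to match the call
direction (DEL for deletions, DUP for duplications) — the type requirement is
this package's choice and can be disabled. Dedup is exact interval identity
by default with an optional tolerance knob. The mean CNV size statistic is
`end − start` over kept calls.

## Cohort statistics

The burden and parental-age comparisons default to two-sided Mann–Whitney U —
robust for overdispersed counts — with an exact or Monte-Carlo
label-permutation alternative (statistic: absolute difference in group
means; add-one estimator for the Monte-Carlo p). Correlations default to
Spearman; Pearson is available by flag. Phenotype prevalence excludes
unknowns from the denominator and reports percentages to two decimals; with
nobody tested the value is undefined rather than zero. Gene-set enrichment
consumes pre-thresholded membership lists (e.g. pSI < 0.05 sets); computing
specificity indices from expression data is out of scope. The BH family is
all sets tested in one run, and q < 0.05 is the significance level.

## Synthetic cohorts

The generator emulates the study conditions: a configurable number of
trio/quad families (default 50% quads, 6% single-parent), proband sex ratio
matching the observed 2.7:1, and per-proband Poisson planting of candidate
classes — 2 coding plus 2 non-coding de novo candidates (matching the
observed average of 4 de novo variants per proband, 2 of them coding), one
compound-het pair, one inherited homozygous and (for male probands) one
X-linked candidate per proband in expectation. Each decoy class — quality
failure, common frequency, each de novo auxiliary-criterion failure,
cis-configured pairs, homozygous unaffected siblings, homozygous mothers on
chrX, synonymous effects, ClinVar-benign, population homozygous carriers,
cross-family identical variants, and TTN missense excess — is planted at a
configurable rate with its expected drop stage recorded in the truth set.
Non-planted background variants are Mendelian-consistent by construction
(founder genotypes binomial in an allele frequency drawn per site; children
inherit one allele per parent), which also reproduces the qualitative
observation that parents carry more private variants than offspring.

CNV planting is deterministic per proband (one segment of each survivor and
decoy class) so that raw per-sample counts stay tightly clustered and only
the designated outlier sample (174 segments, echoing the scale of the
outlier observed in real data) exceeds the MAD bound. Each sample owns a
disjoint coordinate band, so the only identical cross-proband intervals are
the deliberately planted duplicate pairs.

The noise model (Poisson depth with mean 46, matching the study's average
coverage; Beta-distributed allele balance; jittered GQ) is off by default:
truth-recovery checks run noise-free so they test logic, not luck, while
stochastic properties use the noisy mode. The noise defaults are engineering
choices — the empirical DP/GQ distributions of the original data are not
published beyond means.

What passing truth-recovery shows: every filtering rule fires exactly where
specified on inputs that isolate that rule. What it does not show: behaviour
under real error processes (batch effects, segmental duplications, allele
dropout correlated with GC content), realistic site-frequency spectra, or
linkage beyond within-gene compound-het pairs — none of which the generator
attempts to model.

## Problem sizes and determinism

Acceptance-scale runs use 50 families (≈ 175 samples, ≈ 900 variant sites,
≈ 660 CNV segments), completing in a few seconds; the burden calibration
uses 100 replicates of 1,000 permutations. Identical configuration and seed
give byte-identical output files. All randomness flows from
`numpy.random.default_rng` seeded from the configuration.

## Known limitations

- No statistical de novo caller (no joint likelihoods, no mosaicism); the
  rule-based criteria are deliberately those of the published pipeline.
- Compound-het phasing is parental-origin-based only; no read-backed phasing.
- The gene tier table, constraint metrics and ClinVar labels are inputs;
  the package performs no lookups.
- Storage is in-memory tables; cohorts far beyond exome scale would need a
  backing store.
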