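# exofam

Family-based rare-variant discovery for whole-exome cohorts ascertained
through a child with autism spectrum disorder (or any condition studied
through trio/quad pedigrees). The package implements, as a tested and
reusable library plus CLI, the full post-annotation analysis: genotype
quality filtering, frequency-based classification, pedigree segregation,
a candidate-prioritization ladder, CNV segment screening, and cohort
statistics. A synthetic-cohort generator with planted, labeled truth stands
in for restricted patient-level data, so every filtering decision in the
pipeline is verifiable end to end.

It is aimed at statistical-genetics practitioners who have a joint-genotyped
multi-sample VCF, a PED file, and per-variant / per-gene annotation tables
(ANNOVAR-style), and who want auditable candidate lists per proband.

## The analysis

**Stage 1 — filtration.** A genotype is retained iff DP ≥ 10 and GQ ≥ 30
(per sample, per site). A variant is *rare* iff every reported population
frequency (overall and per sub-population, across 1000G/gnomAD/GME/ExAC-style
columns) is < 1%; *novel* iff absent from all databases; *private* iff novel
and carried by exactly one individual in the cohort.

**Stage 2 — segregation.** Per proband, four inheritance modes:

- *de novo*: a private heterozygous variant absent (0/0, quality-retained)
  from both parents and all siblings, additionally requiring GQ ≥ 99,
  AD-Alt ≥ 10, AD-Ref ≥ 10, 0.3 ≤ AD-Alt/DP ≤ 0.7, site QUAL ≥ 999 and
  allele length ≤ 50 bp;
- *compound heterozygous*: two rare heterozygous variants in one gene, one
  het in the father only and the other het in the mother only, each passing
  the AD/allele-balance filter (requires both parents);
- *inherited homozygous*: proband homozygous-alt, both available parents
  heterozygous, no unaffected sibling homozygous-alt (full penetrance);
- *X-linked*: chrX (non-PAR) variant hemizygous in a male proband with a
  heterozygous mother.

A relative missing from the pedigree degrades the call (`one_parent_only`);
a missing or quality-failed genotype in a recorded relative makes a call
not-evaluable — dropout never creates a de novo call.

**Stage 3 — prioritization.** Calls are *possibly damaging* if splice-site;
or a frameshift/nonframeshift indel, stopgain/stoploss or unknown exonic
effect; or a nonsynonymous SNV flagged by ≥ 1 of SIFT / PolyPhen-2 HumVar.
The ladder then applies: (1) drop variants shared identically across
unrelated families; (2) tier genes as *known* (SFARI score 1, 2 or S, or an
OMIM neurological phenotype) vs *novel*; (3)–(5) soft priorities (recurrent
genes, deleteriousness scores from VEST/CADD/phyloP, constraint pLI > 0.5 and
LOEUF < 0.5); (6) drop ClinVar benign/likely-benign; (7) drop variants with
≥ 1 homozygous carrier in the population database. For oversized genes
(default: *TTN*, 108 kb coding), a per-proband missense rate
`missense_bp / coding_length` above the population reference rate
(1.23 × 10⁻⁵ per bp) removes that gene's candidates for that proband.
Surviving variants are ranked per proband: known genes before novel,
truncating before missense, de novo before inherited, then descending
AlphaMissense score.

**Stage 4 — CNV screening.** Samples with outlying raw segment counts
(median + 3·MAD policy) are excluded; segments are kept iff p < 0.05, copy
number ∈ {0, 1, 3, 4}, and log2 ratio ≤ −0.5 (deletions) or ≥ 0.5
(duplications); identical intervals in probands of different families are
dropped; calls are annotated (never dropped) by ≥ 1 bp overlap with known
ASD / syndromic loci; a call completely contained in a same-type structural
variant of frequency > 1% is removed.

**Stage 5 — statistics.** Rare-variant burden between affected and
unaffected samples per category (total-coding, nondisrupting,
missense-damaging, LoF) via Mann–Whitney U with an optional label-permutation
p-value; phenotype prevalences over tested individuals; pedigree
demographics; parental-age comparisons and Spearman correlation of de novo
counts with parental age; gene-set enrichment (one-sided hypergeometric
Fisher p, Benjamini–Hochberg q across all sets, significance at q < 0.05).

## Worked example

Generate a 50-family synthetic cohort and run every stage:

```bash
exofam simulate --seed 5 --outdir demo
exofam segregate  --vcf demo/cohort.vcf --ped demo/cohort.ped \
    --annotation demo/annotation.tsv --genes demo/genes.tsv --outdir demo/out
exofam prioritize --vcf demo/cohort.vcf --ped demo/cohort.ped \
    --annotation demo/annotation.tsv --genes demo/genes.tsv --outdir demo/out
exofam cnv --segments demo/cnv_segments.tsv --ped demo/cohort.ped \
    --asd-loci demo/asd_loci.tsv --syndromic-loci demo/syndromic_loci.tsv \
    --sv-table demo/sv_frequencies.tsv --outdir demo/out
```

which prints

```
wrote 11 files to demo
530 inheritance calls
299 candidates survive
kept 196 CNVs; excluded samples: ['FAM0000-P1']
```

530 inheritance calls are made across the 50 probands (planted candidates
plus Mendelian background that genuinely segregates); 299 variants survive
the damaging classification and the seven-step ladder; the CNV stage keeps
196 segments after excluding the one sample planted with an outlying segment
count. `demo/out/ranked_candidates.tsv` then lists each proband's surviving
variants in priority order, e.g.

```
proband_id   rank  gene     variant              tier
FAM0000-P1   1     ATP1A3   chr19:10000001:A>G   known
FAM0000-P1   2     SYNGAP1  chr6:10000001:A>G    known
```

— known-tier genes outrank novel ones, per the ranking rules above.

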