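"""Stage 3: damaging classification, gene tiering, the seven-step
prioritization ladder, the oversized-gene missense-rate filter, and final
within-proband ranking.

Ladder semantics: step 1 (cross-family identical variant) and steps 6–7
(ClinVar benign, gnomAD homozygous carriers) are hard filters; step 2 assigns
the known/novel tier; steps 3–5 (recurrent gene, deleteriousness scores,
constraint) are soft priorities recorded on each survivor, never filters.
Every input keeps a full step trace for auditability.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .models import (
    CohortVariant,
    EFFECT_NONSYN,
    GeneMetadata,
    LOF_EFFECTS,
    VariantAnnotation,
    VariantKey,
)
from .segregation import MODE_DE_NOVO, InheritanceCall

TIER_KNOWN = "known"
TIER_NOVEL = "novel"

KEPT, DROPPED, NOT_APPLICABLE = "kept", "dropped", "not-applicable"

STEPS = ["step1", "step2", "step3", "step4", "step5", "step6", "step7", "gene_rate"]

# Conventional score cutoffs for the step-4 deleteriousness composite; the
# tools are fixed, the thresholds are configurable engineering defaults.
VEST_DAMAGING = 0.5
CADD_DAMAGING = 20.0
PHYLOP_DAMAGING = 2.0

#: Genes large enough that raw missense counts are uninformative; their
#: prioritized variants are screened by the per-proband missense rate.
DEFAULT_OVERSIZED_GENES = ("TTN",)

#: Effects ranked as protein-truncating for the final within-proband ranking.
_TRUNCATING = LOF_EFFECTS


@dataclass(frozen=True)
class DamagingClass:
    is_possibly_damaging: bool
    basis: Optional[str] = None  # splice-site | protein-truncating-or-indel-or-unknown | missense-predicted


def classify_damaging(variant: CohortVariant) -> DamagingClass:
    """Possibly damaging iff splice-site; or frameshift/nonframeshift indel,
    stopgain/stoploss, or unknown exonic effect; or a nonsynonymous SNV called
    damaging by at least one of SIFT and PolyPhen-2 HumVar."""
    ann = variant.annotation
    if ann is None:
        return DamagingClass(False)
    if ann.effect == "splice-site":
        return DamagingClass(True, "splice-site")
    if ann.effect in (
        "frameshift-insertion",
        "frameshift-deletion",
        "nonframeshift-insertion",
        "nonframeshift-deletion",
        "stopgain",
        "stoploss",
        "unknown",
    ):
        return DamagingClass(True, "protein-truncating-or-indel-or-unknown")
    if ann.effect == EFFECT_NONSYN and (
        ann.sift_damaging is True or ann.polyphen_humvar_damaging is True
    ):
        return DamagingClass(True, "missense-predicted")
    return DamagingClass(False)


def tier_gene(meta: Optional[GeneMetadata]) -> str:
    """Known: SFARI score 1, 2 or S, or an OMIM neurological phenotype;
    everything else (including genes without a metadata row) is novel."""
    if meta is None:
        return TIER_NOVEL
    if meta.sfari_score in ("1", "2", "S") or meta.omim_neuro:
        return TIER_KNOWN
    return TIER_NOVEL


def _clinvar_benign_only(label: Optional[str]) -> bool:
    """Case-insensitive match on labels asserting only benign/likely benign."""
    if label is None:
        return False
    parts = [p.strip().lower() for p in label.replace("/", ";").split(";") if p.strip()]
    return bool(parts) and all(p in ("benign", "likely benign", "likely_benign") for p in parts)


def deleteriousness_score(ann: VariantAnnotation) -> int:
    """Step-4 composite: count of VEST/CADD/phyloP exceeding their cutoffs."""
    n = 0
    if ann.vest is not None and ann.vest >= VEST_DAMAGING:
        n += 1
    if ann.cadd is not None and ann.cadd >= CADD_DAMAGING:
        n += 1
    if ann.phylop is not None and ann.phylop >= PHYLOP_DAMAGING:
        n += 1
    return n


def constraint_score(meta: Optional[GeneMetadata]) -> int:
    """Step-5 composite: (pLI > 0.5) + (LOEUF < 0.5)."""
    if meta is None:
        return 0
    n = 0
    if meta.pli is not None and meta.pli > 0.5:
        n += 1
    if meta.loeuf is not None and meta.loeuf < 0.5:
        n += 1
    return n


@dataclass
class PrioritizedVariant:
    call: InheritanceCall
    variant: CohortVariant
    tier: str
    step_trace: dict[str, str] = field(default_factory=dict)
    recurrent_gene: bool = False
    deleteriousness: int = 0
    constraint: int = 0
    dropped_at: Optional[str] = None
    gene_rate: Optional["GeneMissenseRate"] = None  # set by the oversized-gene screen

    @property
    def survived(self) -> bool:
        return self.dropped_at is None

    @property
    def gene(self) -> Optional[str]:
        return self.variant.annotation.gene if self.variant.annotation else None

    @property
    def rank_key(self) -> tuple:
        ann = self.variant.annotation
        effect_rank = 0 if (ann is not None and ann.effect in _TRUNCATING) else 1
        inh_rank = 0 if self.call.mode == MODE_DE_NOVO else 1
        am = ann.alphamissense if ann is not None else None
        am_rank = -am if am is not None else float("inf")  # absent sorts last
        return (
            0 if self.tier == TIER_KNOWN else 1,
            effect_rank,
            inh_rank,
            am_rank,
            self.variant.key,
        )


@dataclass
class GeneMissenseRate:
    proband_id: str
    gene: str
    missense_bp: int
    coding_length_bp: int
    reference_rate: float

    @property
    def rate(self) -> float:
        return self.missense_bp / self.coding_length_bp

    @property
    def exceeds_reference(self) -> bool:
        return self.rate > self.reference_rate


def gene_missense_rate(
    proband_id: str,
    gene: str,
    proband_variants: list[CohortVariant],
    meta: GeneMetadata,
) -> GeneMissenseRate:
    """Per-proband missense rate in one gene: base pairs carrying missense
    variants divided by the gene's coding length, compared to the population
    reference rate (e.g. gnomAD)."""
    if meta.coding_length_bp is None or meta.gnomad_missense_rate is None:
        raise ValueError(f"gene {gene} lacks coding length or reference rate")
    bp = sum(
        len(v.ref)
        for v in proband_variants
        if v.annotation is not None and v.annotation.effect == EFFECT_NONSYN
    )
    return GeneMissenseRate(
        proband_id=proband_id,
        gene=gene,
        missense_bp=bp,
        coding_length_bp=meta.coding_length_bp,
        reference_rate=meta.gnomad_missense_rate,
    )


def prioritize_candidates(
    calls: list[tuple[InheritanceCall, CohortVariant]],
    gene_metadata: dict[str, GeneMetadata],
    oversized_genes: tuple[str, ...] = DEFAULT_OVERSIZED_GENES,
) -> list[PrioritizedVariant]:
    """Run the seven-step ladder plus the oversized-gene missense-rate filter.

    ``calls`` pairs each inheritance call with its (annotated, possibly
    damaging) variant; compound-het calls contribute one entry per member
    variant.  Within-family sharing of a variant never triggers step 1 —
    "unrelated" means different family IDs.
    """
    items = [
        PrioritizedVariant(
            call=c,
            variant=v,
            tier=tier_gene(gene_metadata.get(v.annotation.gene) if v.annotation and v.annotation.gene else None),
        )
        for c, v in calls
    ]

    # step 1: exact same variant in probands of more than one family
    families_by_key: dict[VariantKey, set[str]] = {}
    for it in items:
        families_by_key.setdefault(it.variant.key, set()).add(it.call.family_id)
    for it in items:
        shared = len(families_by_key[it.variant.key]) > 1
        it.step_trace["step1"] = DROPPED if shared else KEPT
        if shared and it.dropped_at is None:
            it.dropped_at = "step1"

    # step 2: known/novel tier (classification, never a filter)
    for it in items:
        it.step_trace["step2"] = KEPT

    # step 3: recurrent genes — multiple different variants in different people
    live = [it for it in items if it.dropped_at is None]
    gene_people: dict[tuple[str, str], set[str]] = {}
    gene_vars: dict[tuple[str, str], set[VariantKey]] = {}
    for it in live:
        if it.gene is None:
            continue
        k = (it.tier, it.gene)
        gene_people.setdefault(k, set()).add(it.call.proband_id)
        gene_vars.setdefault(k, set()).add(it.variant.key)
    for it in items:
        if it.dropped_at is not None:
            it.step_trace["step3"] = NOT_APPLICABLE
            continue
        k = (it.tier, it.gene)
        it.recurrent_gene = (
            it.gene is not None
            and len(gene_people.get(k, ())) > 1
            and len(gene_vars.get(k, ())) > 1
        )
        it.step_trace["step3"] = KEPT

    # steps 4-5: soft priority components
    for it in items:
        if it.dropped_at is not None:
            it.step_trace["step4"] = it.step_trace["step5"] = NOT_APPLICABLE
            continue
        ann = it.variant.annotation
        it.deleteriousness = deleteriousness_score(ann) if ann else 0
        meta = gene_metadata.get(it.gene) if it.gene else None
        it.constraint = constraint_score(meta)
        it.step_trace["step4"] = KEPT
        it.step_trace["step5"] = KEPT

    # step 6: ClinVar benign / likely benign (hard filter)
    for it in items:
        if it.dropped_at is not None:
            it.step_trace["step6"] = NOT_APPLICABLE
            continue
        ann = it.variant.annotation
        benign = ann is not None and _clinvar_benign_only(ann.clinvar_significance)
        it.step_trace["step6"] = DROPPED if benign else KEPT
        if benign:
            it.dropped_at = "step6"

    # step 7: one or more homozygous carriers in the population database
    for it in items:
        if it.dropped_at is not None:
            it.step_trace["step7"] = NOT_APPLICABLE
            continue
        ann = it.variant.annotation
        hom = ann is not None and (ann.gnomad_hom_carriers or 0) >= 1
        it.step_trace["step7"] = DROPPED if hom else KEPT
        if hom:
            it.dropped_at = "step7"

    # oversized-gene missense-rate filter (e.g. TTN)
    by_proband_gene: dict[tuple[str, str], list[PrioritizedVariant]] = {}
    for it in items:
        if it.dropped_at is None and it.gene in oversized_genes:
            by_proband_gene.setdefault((it.call.proband_id, it.gene), []).append(it)
    for (pid, gene), group in by_proband_gene.items():
        meta = gene_metadata.get(gene)
        if meta is None or meta.coding_length_bp is None or meta.gnomad_missense_rate is None:
            logging.getLogger(__name__).warning(
                "oversized gene %s lacks coding length/reference rate; filter skipped", gene
            )
            continue
        gmr = gene_missense_rate(pid, gene, [it.variant for it in group], meta)
        for it in group:
            it.gene_rate = gmr
        if gmr.exceeds_reference:
            for it in group:
                it.step_trace["gene_rate"] = DROPPED
                it.dropped_at = "gene_rate"
    for it in items:
        it.step_trace.setdefault(
            "gene_rate", KEPT if it.dropped_at is None else NOT_APPLICABLE
        )
    return items


def conservation_check(items: list[PrioritizedVariant]) -> bool:
    """Inputs must equal survivors plus the per-step drop totals."""
    drops = Counter(it.dropped_at for it in items if it.dropped_at is not None)
    survivors = sum(1 for it in items if it.survived)
    return survivors + sum(drops.values()) == len(items)


def rank_proband_variants(items: list[PrioritizedVariant]) -> list[PrioritizedVariant]:
    """Total order over one proband's surviving variants: known genes before
    novel, truncating effects before missense, de novo before inherited, then
    descending AlphaMissense, then the variant key as a deterministic
    tie-break."""
    return sorted((it for it in items if it.survived), key=lambda it: it.rank_key)
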