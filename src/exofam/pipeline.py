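"""End-to-end orchestration of the variant pipeline stages, plus truth-set
scoring for simulated cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .cnv import CnvCall
from .filtration import (
    FrequencyClass,
    QualityFilterResult,
    apply_quality_filter,
    classify_all,
)
from .models import CohortVariant, GeneMetadata, PedigreeFamily, VariantAnnotation, VariantKey
from .prioritization import (
    PrioritizedVariant,
    classify_damaging,
    prioritize_candidates,
)
from .segregation import InheritanceCall, segregate_all
from .simulate import TruthRecord


def attach_annotations(
    variants: list[CohortVariant], annotations: dict[VariantKey, VariantAnnotation]
) -> None:
    """Join the annotation table onto variants in place; unmatched keys keep
    annotation=None."""
    for v in variants:
        v.annotation = annotations.get(v.key)


@dataclass
class PipelineResult:
    variants: list[CohortVariant]
    quality: QualityFilterResult
    freq: dict[VariantKey, FrequencyClass]
    calls: list[InheritanceCall]
    prioritized: list[PrioritizedVariant]

    @property
    def survivors(self) -> list[PrioritizedVariant]:
        return [p for p in self.prioritized if p.survived]


def run_variant_pipeline(
    variants: list[CohortVariant],
    families: list[PedigreeFamily],
    gene_metadata: dict[str, GeneMetadata],
    annotations: Optional[dict[VariantKey, VariantAnnotation]] = None,
    strict_sibling_comp_het: bool = False,
    allow_female_x: bool = False,
) -> PipelineResult:
    """Quality filter -> frequency classes -> segregation -> damaging
    classification -> prioritization ladder (with the oversized-gene
    missense-rate screen)."""
    if annotations is not None:
        attach_annotations(variants, annotations)
    quality = apply_quality_filter(variants)
    freq = classify_all(variants, quality)
    calls = segregate_all(
        variants,
        families,
        freq,
        quality,
        strict_sibling_comp_het=strict_sibling_comp_het,
        allow_female_x=allow_female_x,
    )
    by_key = {v.key: v for v in variants}
    ladder_input: list[tuple[InheritanceCall, CohortVariant]] = []
    for call in calls:
        for key in call.variants:
            v = by_key[key]
            if classify_damaging(v).is_possibly_damaging:
                ladder_input.append((call, v))
    prioritized = prioritize_candidates(ladder_input, gene_metadata)
    return PipelineResult(
        variants=variants,
        quality=quality,
        freq=freq,
        calls=calls,
        prioritized=prioritized,
    )


# ---------------------------------------------------------------------------
# Truth scoring
# ---------------------------------------------------------------------------


def _variant_record_recovered(rec: TruthRecord, result: PipelineResult) -> bool:
    """Did the pipeline treat one planted record exactly as intended?"""
    calls_for = [
        c
        for c in result.calls
        if c.proband_id == rec.sample_id
    ]
    pr_for = {
        (p.variant.key, p.call.mode): p
        for p in result.prioritized
        if p.call.proband_id == rec.sample_id
    }

    def has_call(mode: str, keys: tuple) -> bool:
        for c in calls_for:
            if c.mode == mode and set(keys) <= set(c.variants):
                return True
        return False

    stage = rec.drop_stage
    if stage is None:  # expected survivor at every stage
        assert rec.expected_mode is not None
        if not has_call(rec.expected_mode, rec.keys):
            return False
        return all(
            (k, rec.expected_mode) in pr_for and pr_for[(k, rec.expected_mode)].survived
            for k in rec.keys
        )
    if stage == "quality":
        return not result.quality.is_retained(rec.sample_id, rec.keys[0])
    if stage == "rare":
        return not result.freq[rec.keys[0]].is_rare
    if stage == "de_novo":
        return not has_call("de_novo", rec.keys)
    if stage == "segregation":
        return not has_call(rec.expected_mode, rec.keys)
    if stage == "damaging":
        # the call exists but the variant never enters the ladder
        return has_call(rec.expected_mode, rec.keys) and all(
            (k, rec.expected_mode) not in pr_for for k in rec.keys
        )
    if stage in ("step1", "step6", "step7", "gene_rate"):
        return all(
            (k, rec.expected_mode) in pr_for
            and pr_for[(k, rec.expected_mode)].dropped_at == stage
            for k in rec.keys
        )
    raise ValueError(f"unknown truth stage {stage!r}")


def score_variant_truth(
    truth: list[TruthRecord], result: PipelineResult
) -> pd.DataFrame:
    """One row per planted variant record with its recovery outcome."""
    rows = [
        {
            "label": rec.label,
            "family_id": rec.family_id,
            "sample_id": rec.sample_id,
            "expected_mode": rec.expected_mode,
            "drop_stage": rec.drop_stage or "",
            "is_survivor": rec.is_survivor,
            "recovered": _variant_record_recovered(rec, result),
        }
        for rec in truth
        if rec.kind == "variant"
    ]
    return pd.DataFrame(rows)


def score_cnv_truth(truth: list[TruthRecord], calls: list[CnvCall]) -> pd.DataFrame:
    """One row per planted CNV record; 'recovered' means the call was kept
    (survivors) or dropped with exactly the expected reason (decoys)."""
    by_key = {
        (c.segment.sample_id, c.segment.chrom, c.segment.start, c.segment.end): c
        for c in calls
    }
    rows = []
    for rec in truth:
        if rec.kind != "cnv":
            continue
        if rec.label == "outlier-sample":
            sample_calls = [c for c in calls if c.segment.sample_id == rec.sample_id]
            ok = bool(sample_calls) and all(
                c.dropped_reason == "outlier-sample" for c in sample_calls
            )
        else:
            chrom, start, end = rec.keys
            call = by_key.get((rec.sample_id, chrom, start, end))
            if call is None:
                ok = False
            elif rec.is_survivor:
                ok = call.kept
            else:
                ok = call.dropped_reason == rec.drop_stage
        rows.append(
            {
                "label": rec.label,
                "sample_id": rec.sample_id,
                "is_survivor": rec.is_survivor,
                "recovered": ok,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TruthSummary:
    survivor_recall: float
    decoy_rejection: float
    n_survivors: int
    n_decoys: int


def summarize_truth(scores: pd.DataFrame) -> TruthSummary:
    """Fraction of expected survivors recovered and of decoys handled at
    their designated stage."""
    surv = scores[scores["is_survivor"]]
    decoy = scores[~scores["is_survivor"]]
    return TruthSummary(
        survivor_recall=float(surv["recovered"].mean()) if len(surv) else float("nan"),
        decoy_rejection=float(decoy["recovered"].mean()) if len(decoy) else float("nan"),
        n_survivors=int(len(surv)),
        n_decoys=int(len(decoy)),
    )
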