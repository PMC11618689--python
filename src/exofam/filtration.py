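"""Stage 1: genotype quality filtering and frequency classification.

A genotype is retained when DP >= 10 and GQ >= 30 (retention is per sample
per site, not per site).  Variants are then classified as rare (every reported
population frequency, overall and sub-population, below 1%), novel (absent
from all reference databases), and private (novel and carried by exactly one
individual in the cohort, counted over quality-retained genotypes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .models import CohortVariant, VariantKey

MIN_DP = 10
MIN_GQ = 30
RARE_MAF = 0.01


@dataclass(frozen=True)
class FrequencyClass:
    is_rare: bool
    is_novel: bool
    is_private: bool

    def __post_init__(self) -> None:
        if self.is_private and not self.is_novel:
            raise ValueError("private implies novel")
        if self.is_novel and not self.is_rare:
            raise ValueError("novel implies rare")


@dataclass
class QualityFilterResult:
    """Per-sample sets of quality-retained variant keys plus drop bookkeeping."""

    retained: dict[str, set[VariantKey]]
    drop_reasons: Counter = field(default_factory=Counter)

    def is_retained(self, sample_id: str, key: VariantKey) -> bool:
        return key in self.retained.get(sample_id, set())


def apply_quality_filter(variants: list[CohortVariant]) -> QualityFilterResult:
    """Retain a sample's genotype at a site iff DP >= 10 and GQ >= 30.

    Genotypes with an absent DP or GQ are dropped conservatively, with the
    reason counted ("missing-dp" / "missing-gq"); called (non-missing)
    genotypes failing a threshold count as "fail-dp" / "fail-gq".
    """
    retained: dict[str, set[VariantKey]] = {}
    reasons: Counter = Counter()
    for v in variants:
        for sample_id, call in v.genotypes.items():
            retained.setdefault(sample_id, set())
            if call.is_missing:
                reasons["missing-genotype"] += 1
                continue
            if call.dp is None:
                reasons["missing-dp"] += 1
                continue
            if call.gq is None:
                reasons["missing-gq"] += 1
                continue
            if call.dp < MIN_DP:
                reasons["fail-dp"] += 1
                continue
            if call.gq < MIN_GQ:
                reasons["fail-gq"] += 1
                continue
            retained[sample_id].add(v.key)
    return QualityFilterResult(retained=retained, drop_reasons=reasons)


def carrier_count(variant: CohortVariant, quality: QualityFilterResult) -> int:
    """Number of cohort individuals carrying the alternate allele, counted
    over quality-retained genotypes only."""
    n = 0
    for sample_id, call in variant.genotypes.items():
        if call.carries_alt and quality.is_retained(sample_id, variant.key):
            n += 1
    return n


def classify_frequency(
    variant: CohortVariant, quality: QualityFilterResult
) -> FrequencyClass:
    """Classify one variant as rare / novel / private.

    Rare: every available database frequency (overall and sub-population)
    is strictly below 1%; absent frequencies do not veto rarity.  Novel:
    absent from all databases (empty MAF mapping).  Private: novel and
    carried by exactly one individual.
    """
    maf = variant.annotation.maf if variant.annotation is not None else {}
    is_rare = all(f < RARE_MAF for f in maf.values())
    is_novel = is_rare and len(maf) == 0
    is_private = is_novel and carrier_count(variant, quality) == 1
    return FrequencyClass(is_rare=is_rare, is_novel=is_novel, is_private=is_private)


def classify_all(
    variants: list[CohortVariant], quality: QualityFilterResult
) -> dict[VariantKey, FrequencyClass]:
    return {v.key: classify_frequency(v, quality) for v in variants}


# Stage order for the per-exome count summary.
SUMMARY_STAGES = [
    "raw",
    "quality",
    "rare_het",
    "rare_hom",
    "novel",
    "private",
    "private_coding",
    "private_damaging",
]


def summarize_exome_counts(
    variants: list[CohortVariant],
    quality: QualityFilterResult,
    freq: dict[VariantKey, FrequencyClass],
) -> pd.DataFrame:
    """Per-sample variant counts at each pipeline stage, split SNV/indel.

    "rare" counts are over quality-retained carried genotypes; a site counts
    for a sample only when that sample carries the alternate allele.
    """
    from .prioritization import classify_damaging  # local import avoids cycle

    samples = sorted({s for v in variants for s in v.genotypes})
    rows = {
        s: {f"{stage}_{kind}": 0 for stage in SUMMARY_STAGES for kind in ("total", "snv", "indel")}
        for s in samples
    }
    for v in variants:
        kind = "snv" if v.is_snv else "indel"
        fc = freq[v.key]
        ann = v.annotation
        damaging = ann is not None and classify_damaging(v).is_possibly_damaging
        coding = ann is not None and ann.is_coding
        for s, call in v.genotypes.items():
            if not call.carries_alt:
                continue
            r = rows[s]

            def bump(stage: str) -> None:
                r[f"{stage}_total"] += 1
                r[f"{stage}_{kind}"] += 1

            bump("raw")
            if not quality.is_retained(s, v.key):
                continue
            bump("quality")
            if not fc.is_rare:
                continue
            if call.is_het:
                bump("rare_het")
            elif call.is_hom_alt:
                bump("rare_hom")
            if not fc.is_novel:
                continue
            bump("novel")
            if not fc.is_private:
                continue
            bump("private")
            if coding:
                bump("private_coding")
                if damaging:
                    bump("private_damaging")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df.sort_index()
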