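"""Stage 5: cohort-level statistics.

Burden comparison of per-sample rare-variant counts between affected and
unaffected individuals (Mann–Whitney U by default, with an exact/Monte-Carlo
label-permutation alternative), phenotype prevalences over tested individuals,
pedigree demographics, parental-age analyses, and Fisher+Benjamini–Hochberg
specific-expression enrichment over pre-thresholded (pSI < 0.05) gene sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .models import (
    CohortVariant,
    EFFECT_NFS_DEL,
    EFFECT_NFS_INS,
    EFFECT_NONSYN,
    EFFECT_SYN,
    LOF_EFFECTS,
    PedigreeFamily,
    PHENO_ABSENT,
    PHENO_PRESENT,
    PhenotypeTable,
    ROLE_PROBAND,
)

CATEGORY_TOTAL_CODING = "total-coding"
CATEGORY_NONDISRUPTING = "nondisrupting"
CATEGORY_MISSENSE_DAMAGING = "missense-damaging"
CATEGORY_LOF = "LoF"
BURDEN_CATEGORIES = (
    CATEGORY_TOTAL_CODING,
    CATEGORY_NONDISRUPTING,
    CATEGORY_MISSENSE_DAMAGING,
    CATEGORY_LOF,
)


def variant_in_category(variant: CohortVariant, category: str) -> bool:
    """Membership rules for the burden categories.

    Nondisrupting: exonic synonymous SNV or nonframeshift indel.  LoF:
    frameshift indel, stopgain/stoploss, or splice error.  Missense-damaging:
    nonsynonymous SNV with at least one of SIFT / PolyPhen-2 HumVar damaging.
    Total-coding: any coding (exonic or splice-site) variant.
    """
    ann = variant.annotation
    if ann is None:
        return False
    if category == CATEGORY_TOTAL_CODING:
        return ann.is_coding
    if category == CATEGORY_NONDISRUPTING:
        return ann.effect in (EFFECT_SYN, EFFECT_NFS_INS, EFFECT_NFS_DEL)
    if category == CATEGORY_LOF:
        return ann.effect in LOF_EFFECTS
    if category == CATEGORY_MISSENSE_DAMAGING:
        return ann.effect == EFFECT_NONSYN and (
            ann.sift_damaging is True or ann.polyphen_humvar_damaging is True
        )
    raise ValueError(f"unknown burden category {category!r}")


def permutation_pvalue(
    affected: Sequence[float],
    unaffected: Sequence[float],
    n_permutations: int = 1000,
    rng: Optional[np.random.Generator] = None,
    exact: bool = False,
) -> float:
    """Two-sided label-permutation p for the difference in group means.

    p = (1 + #{|perm stat| >= |observed|}) / (B + 1); with ``exact`` every
    label assignment is enumerated instead (p = #{...} / n_assignments).
    """
    a = np.asarray(affected, dtype=float)
    u = np.asarray(unaffected, dtype=float)
    if a.size == 0 or u.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, u])
    observed = abs(a.mean() - u.mean())
    n_a = a.size
    if exact:
        hits = total = 0
        for idx in itertools.combinations(range(pooled.size), n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            hits += stat >= observed - 1e-12
            total += 1
        return hits / total
    if rng is None:
        rng = np.random.default_rng()
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if stat >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


@dataclass
class BurdenResult:
    category: str
    mean_affected: float
    mean_unaffected: float
    mannwhitney_u: float
    mannwhitney_p: float
    permutation_p: Optional[float]
    significant: bool  # at alpha = 0.05 on the Mann-Whitney p


def burden_test(
    counts: dict[str, dict[str, int]],
    affected: dict[str, bool],
    n_permutations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list[BurdenResult]:
    """Compare per-sample counts between affected and unaffected samples for
    each category.  ``counts`` maps category -> sample -> count."""
    results = []
    for category, per_sample in counts.items():
        a = [n for s, n in per_sample.items() if affected.get(s)]
        u = [n for s, n in per_sample.items() if s in affected and not affected[s]]
        if not a or not u:
            raise ValueError(f"empty group for category {category}")
        stat, p = sps.mannwhitneyu(a, u, alternative="two-sided")
        perm_p = (
            permutation_pvalue(a, u, n_permutations=n_permutations, rng=rng)
            if n_permutations > 0
            else None
        )
        results.append(
            BurdenResult(
                category=category,
                mean_affected=float(np.mean(a)),
                mean_unaffected=float(np.mean(u)),
                mannwhitney_u=float(stat),
                mannwhitney_p=float(p),
                permutation_p=perm_p,
                significant=p < 0.05,
            )
        )
    return results


def burden_counts(
    variants: list[CohortVariant],
    rare_keys: set,
    retained: dict[str, set],
    samples: Iterable[str],
) -> dict[str, dict[str, int]]:
    """Per-sample rare-variant counts for every burden category, over
    quality-retained carried genotypes."""
    samples = list(samples)
    counts = {cat: {s: 0 for s in samples} for cat in BURDEN_CATEGORIES}
    for v in variants:
        if v.key not in rare_keys:
            continue
        cats = [c for c in BURDEN_CATEGORIES if variant_in_category(v, c)]
        if not cats:
            continue
        for s in samples:
            call = v.genotype(s)
            if call.carries_alt and v.key in retained.get(s, set()):
                for c in cats:
                    counts[c][s] += 1
    return counts


def phenotype_prevalence(
    table: PhenotypeTable, condition: str, individuals: Optional[Iterable[str]] = None
) -> tuple[int, int, Optional[float]]:
    """(n_tested, n_with, percent to 2 decimals) for one condition.

    Individuals with an unknown state are excluded from the denominator;
    with nobody tested the percentage is undefined (None).
    """
    ids = list(individuals) if individuals is not None else list(table.states)
    n_tested = n_with = 0
    for ind in ids:
        state = table.state(ind, condition)
        if state == PHENO_PRESENT:
            n_tested += 1
            n_with += 1
        elif state == PHENO_ABSENT:
            n_tested += 1
    if n_tested == 0:
        return 0, 0, None
    return n_tested, n_with, round(100.0 * n_with / n_tested, 2)


def cohort_demographics(families: list[PedigreeFamily]) -> dict:
    """Role counts, proband sex counts, and the affected male:female ratio
    (one decimal)."""
    role_counts: dict[str, int] = {}
    male = female = 0
    for fam in families:
        for m in fam.members:
            role_counts[m.role] = role_counts.get(m.role, 0) + 1
            if m.role == ROLE_PROBAND:
                if m.sex == "male":
                    male += 1
                else:
                    female += 1
    total = sum(role_counts.values())
    n_probands = role_counts.get(ROLE_PROBAND, 0)
    ratio = round(male / female, 1) if female else None
    return {
        "role_counts": role_counts,
        "total_individuals": total,
        "n_probands": n_probands,
        "n_unaffected": total - n_probands,
        "probands_male": male,
        "probands_female": female,
        "male_female_ratio": ratio,
    }


@dataclass
class ParentalAgeResult:
    paternal_comparison_p: Optional[float]
    maternal_comparison_p: Optional[float]
    spearman_paternal: Optional[tuple[float, float]]  # (rho, p)
    spearman_maternal: Optional[tuple[float, float]]


def parental_age_analyses(
    ages: pd.DataFrame,
    de_novo_counts: Optional[dict[str, int]] = None,
    method: str = "spearman",
) -> ParentalAgeResult:
    """Affected-vs-unaffected parental-age comparison (Mann–Whitney) and the
    correlation of per-proband de novo count with each parent's age at birth.

    ``ages`` columns: individual_id, affected (bool), paternal_age,
    maternal_age.  Correlations require at least 3 paired observations.
    """

    def compare(col: str) -> Optional[float]:
        a = ages.loc[ages["affected"].astype(bool), col].dropna()
        u = ages.loc[~ages["affected"].astype(bool), col].dropna()
        if a.empty or u.empty:
            return None
        if a.nunique() == 1 and u.nunique() == 1 and a.iloc[0] == u.iloc[0]:
            return 1.0  # identical constant groups: no evidence of difference
        return float(sps.mannwhitneyu(a, u, alternative="two-sided").pvalue)

    def correlate(col: str) -> Optional[tuple[float, float]]:
        if de_novo_counts is None:
            return None
        sub = ages[ages["individual_id"].isin(de_novo_counts)].dropna(subset=[col])
        if len(sub) < 3:
            return None
        x = sub[col].to_numpy(dtype=float)
        y = np.array([de_novo_counts[i] for i in sub["individual_id"]], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return None  # correlation undefined for a constant input
        if method == "pearson":
            r, p = sps.pearsonr(x, y)
        else:
            r, p = sps.spearmanr(x, y)
        return float(r), float(p)

    return ParentalAgeResult(
        paternal_comparison_p=compare("paternal_age"),
        maternal_comparison_p=compare("maternal_age"),
        spearman_paternal=correlate("paternal_age"),
        spearman_maternal=correlate("maternal_age"),
    )


@dataclass
class EnrichmentResult:
    gene_set: str
    n_candidate_in_set: int
    n_candidate: int
    n_background_in_set: int
    n_background: int
    p_value: float
    q_value: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.q_value < 0.05


def sea_enrichment(
    candidates: Iterable[str],
    gene_sets: dict[str, set[str]],
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Enrichment of candidate genes in each region x developmental-window
    gene set: one-sided hypergeometric (Fisher) p with BH correction across
    the whole family of sets.  Candidates absent from the background universe
    are dropped with a warning."""
    bg = set(background)
    cand = set(candidates)
    missing = cand - bg
    if missing:
        logging.getLogger(__name__).warning(
            "%d candidate genes absent from background dropped", len(missing)
        )
        cand &= bg
    results = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & bg
        k = len(cand & members)
        # hypergeometric upper tail: P(X >= k)
        p = float(sps.hypergeom.sf(k - 1, len(bg), len(members), len(cand)))
        results.append(
            EnrichmentResult(
                gene_set=set_id,
                n_candidate_in_set=k,
                n_candidate=len(cand),
                n_background_in_set=len(members),
                n_background=len(bg),
                p_value=min(p, 1.0),
            )
        )
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results
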