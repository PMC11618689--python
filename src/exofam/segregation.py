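"""Stage 2: pedigree-based inheritance-mode calling.

Four modes are called per proband against the quality-retained genotypes:

* de novo — heterozygous private variant absent from both parents and all
  siblings, passing six auxiliary criteria (GQ >= 99, AD-Alt >= 10,
  AD-Ref >= 10, 0.3 <= AD-Alt/DP <= 0.7, site QUAL >= 999, allele
  length <= 50);
* compound heterozygous — two rare heterozygous variants in one gene, one
  inherited from each parent, each passing the AD/allele-balance filter;
* inherited homozygous — proband homozygous-alt with both parents
  heterozygous and no unaffected sibling homozygous-alt;
* X-linked — chrX (non-PAR) variant hemizygous in a male proband with a
  heterozygous mother.

A relative missing from the pedigree degrades the call (one_parent_only);
a relative present but with a missing or quality-failed genotype makes the
call not-evaluable — absence of evidence never creates a call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .filtration import FrequencyClass, QualityFilterResult
from .models import (
    CohortVariant,
    GenotypeCall,
    PedigreeFamily,
    ROLE_PROBAND,
    ROLE_SIBLING,
    VariantKey,
    in_par,
    normalize_chrom,
)

MODE_DE_NOVO = "de_novo"
MODE_COMP_HET = "compound_het"
MODE_INHERITED_HOM = "inherited_hom"
MODE_X_LINKED = "x_linked"
MODES = (MODE_DE_NOVO, MODE_COMP_HET, MODE_INHERITED_HOM, MODE_X_LINKED)

PASS, FAIL, NOT_EVALUABLE = "pass", "fail", "not-evaluable"

DE_NOVO_MIN_GQ = 99
MIN_AD = 10
AB_LOW, AB_HIGH = 0.3, 0.7
MIN_SITE_QUAL = 999
MAX_ALLELE_LEN = 50


@dataclass
class InheritanceCall:
    proband_id: str
    family_id: str
    mode: str
    variants: tuple[VariantKey, ...]
    evidence: dict[str, str] = field(default_factory=dict)
    one_parent_only: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        expected = 2 if self.mode == MODE_COMP_HET else 1
        if len(self.variants) != expected:
            raise ValueError(f"{self.mode} call must carry {expected} variant key(s)")


def _retained_genotype(
    variant: CohortVariant, sample_id: str, quality: QualityFilterResult
) -> Optional[GenotypeCall]:
    """The genotype if called and quality-retained, else None (= unknown)."""
    call = variant.genotype(sample_id)
    if call.is_missing or not quality.is_retained(sample_id, variant.key):
        return None
    return call


def _ad_balance_evidence(g: GenotypeCall, evidence: dict[str, str]) -> None:
    evidence["ad_alt_ge_10"] = (
        NOT_EVALUABLE if g.ad_alt is None else (PASS if g.ad_alt >= MIN_AD else FAIL)
    )
    evidence["ad_ref_ge_10"] = (
        NOT_EVALUABLE if g.ad_ref is None else (PASS if g.ad_ref >= MIN_AD else FAIL)
    )
    ab = g.allele_balance
    evidence["allele_balance_0.3_0.7"] = (
        NOT_EVALUABLE if ab is None else (PASS if AB_LOW <= ab <= AB_HIGH else FAIL)
    )


def _proband_ad_filter_ok(g: GenotypeCall) -> bool:
    ab = g.allele_balance
    return (
        g.ad_alt is not None
        and g.ad_alt >= MIN_AD
        and g.ad_ref is not None
        and g.ad_ref >= MIN_AD
        and ab is not None
        and AB_LOW <= ab <= AB_HIGH
    )


def evaluate_de_novo(
    variant: CohortVariant,
    family: PedigreeFamily,
    proband_id: str,
    quality: QualityFilterResult,
) -> tuple[bool, dict[str, str], bool]:
    """Evaluate the de novo criteria; returns (ok, evidence, one_parent_only)."""
    ev: dict[str, str] = {}
    g = _retained_genotype(variant, proband_id, quality)
    if g is None:
        ev["proband_het"] = NOT_EVALUABLE
        return False, ev, False
    ev["proband_het"] = PASS if g.is_het else FAIL
    ev["gq_ge_99"] = (
        NOT_EVALUABLE if g.gq is None else (PASS if g.gq >= DE_NOVO_MIN_GQ else FAIL)
    )
    _ad_balance_evidence(g, ev)
    ev["site_qual_ge_999"] = (
        NOT_EVALUABLE
        if variant.site_qual is None
        else (PASS if variant.site_qual >= MIN_SITE_QUAL else FAIL)
    )
    ev["allele_length_le_50"] = (
        PASS if len(variant.ref) <= MAX_ALLELE_LEN and len(variant.alt) <= MAX_ALLELE_LEN else FAIL
    )

    father_id, mother_id = family.parents_of(proband_id)
    if father_id is None and mother_id is None:
        ev["parents"] = NOT_EVALUABLE
        return False, ev, False
    one_parent_only = father_id is None or mother_id is None
    for label, pid in (("absent_father", father_id), ("absent_mother", mother_id)):
        if pid is None:
            ev[label] = NOT_EVALUABLE
            continue
        pg = _retained_genotype(variant, pid, quality)
        if pg is None:
            ev[label] = NOT_EVALUABLE
            return False, ev, one_parent_only
        ev[label] = FAIL if pg.carries_alt else PASS
    for sib in family.siblings_of(proband_id):
        label = f"absent_sibling:{sib.individual_id}"
        sg = _retained_genotype(variant, sib.individual_id, quality)
        if sg is None:
            ev[label] = NOT_EVALUABLE
            return False, ev, one_parent_only
        ev[label] = FAIL if sg.carries_alt else PASS
    ok = all(v != FAIL for v in ev.values()) and ev["proband_het"] == PASS
    # criteria with missing inputs (e.g. absent GQ) do not license a call
    strict = ("gq_ge_99", "ad_alt_ge_10", "ad_ref_ge_10", "allele_balance_0.3_0.7", "site_qual_ge_999")
    ok = ok and all(ev[c] == PASS for c in strict)
    return ok, ev, one_parent_only


def call_de_novo(
    variant: CohortVariant,
    family: PedigreeFamily,
    proband_id: str,
    quality: QualityFilterResult,
) -> Optional[InheritanceCall]:
    ok, ev, one_parent = evaluate_de_novo(variant, family, proband_id, quality)
    if not ok:
        return None
    return InheritanceCall(
        proband_id=proband_id,
        family_id=family.family_id,
        mode=MODE_DE_NOVO,
        variants=(variant.key,),
        evidence=ev,
        one_parent_only=one_parent,
    )


def _parental_origin(
    variant: CohortVariant,
    father_id: str,
    mother_id: str,
    quality: QualityFilterResult,
) -> Optional[str]:
    """'paternal'/'maternal' if het in exactly that parent and hom-ref in the
    other; None otherwise (including unknown parental genotypes)."""
    fg = _retained_genotype(variant, father_id, quality)
    mg = _retained_genotype(variant, mother_id, quality)
    if fg is None or mg is None:
        return None
    if fg.is_het and mg.is_hom_ref:
        return "paternal"
    if mg.is_het and fg.is_hom_ref:
        return "maternal"
    return None


def call_compound_het(
    gene: str,
    variants: list[CohortVariant],
    family: PedigreeFamily,
    proband_id: str,
    quality: QualityFilterResult,
    strict_sibling: bool = False,
) -> list[InheritanceCall]:
    """Enumerate trans pairs within one gene: proband het at both, one variant
    het in the father only and the other het in the mother only, each passing
    AD-Alt >= 10, AD-Ref >= 10 and 0.3 <= AD-Alt/DP <= 0.7 on the proband.

    Requires both parents; with a parent missing the result is empty
    (compound heterozygous calling is not possible).
    """
    father_id, mother_id = family.parents_of(proband_id)
    if father_id is None or mother_id is None:
        return []
    paternal, maternal = [], []
    for v in variants:
        g = _retained_genotype(v, proband_id, quality)
        if g is None or not g.is_het or not _proband_ad_filter_ok(g):
            continue
        origin = _parental_origin(v, father_id, mother_id, quality)
        if origin == "paternal":
            paternal.append(v)
        elif origin == "maternal":
            maternal.append(v)
    calls = []
    for vp, vm in itertools.product(paternal, maternal):
        if strict_sibling and _sibling_carries_both(vp, vm, family, proband_id, quality):
            continue
        pair = tuple(sorted((vp.key, vm.key)))
        calls.append(
            InheritanceCall(
                proband_id=proband_id,
                family_id=family.family_id,
                mode=MODE_COMP_HET,
                variants=pair,
                evidence={"gene": gene, "trans_configuration": PASS},
            )
        )
    return calls


def _sibling_carries_both(vp, vm, family, proband_id, quality) -> bool:
    for sib in family.siblings_of(proband_id):
        if sib.affected:
            continue
        g1 = _retained_genotype(vp, sib.individual_id, quality)
        g2 = _retained_genotype(vm, sib.individual_id, quality)
        if g1 is not None and g2 is not None and g1.is_het and g2.is_het:
            return True
    return False


def call_inherited_homozygous(
    variant: CohortVariant,
    family: PedigreeFamily,
    proband_id: str,
    quality: QualityFilterResult,
) -> Optional[InheritanceCall]:
    """Proband homozygous-alt, both available parents heterozygous, and no
    unaffected sibling homozygous-alt (full-penetrance assumption).

    Male probands are excluded on chrX: a diploid-encoded hemizygous call is
    not a recessive homozygote (the X-linked caller owns that case)."""
    ev: dict[str, str] = {}
    proband = family.member(proband_id)
    if (
        proband is not None
        and proband.sex == "male"
        and normalize_chrom(variant.chrom) == "chrX"
        and not in_par(variant.chrom, variant.pos)
    ):
        return None
    g = _retained_genotype(variant, proband_id, quality)
    if g is None or not g.is_hom_alt:
        return None
    ev["proband_hom_alt"] = PASS
    father_id, mother_id = family.parents_of(proband_id)
    if father_id is None and mother_id is None:
        return None
    one_parent_only = father_id is None or mother_id is None
    for label, pid in (("father_het", father_id), ("mother_het", mother_id)):
        if pid is None:
            ev[label] = NOT_EVALUABLE
            continue
        pg = _retained_genotype(variant, pid, quality)
        if pg is None:
            return None
        if not pg.is_het:
            return None
        ev[label] = PASS
    for sib in family.siblings_of(proband_id):
        if sib.affected:
            continue
        sg = _retained_genotype(variant, sib.individual_id, quality)
        label = f"unaffected_sib_not_hom:{sib.individual_id}"
        if sg is None:
            ev[label] = NOT_EVALUABLE  # "when available"
            continue
        if sg.is_hom_alt:
            return None
        ev[label] = PASS
    return InheritanceCall(
        proband_id=proband_id,
        family_id=family.family_id,
        mode=MODE_INHERITED_HOM,
        variants=(variant.key,),
        evidence=ev,
        one_parent_only=one_parent_only,
    )


def _is_hemizygous_alt(g: GenotypeCall) -> bool:
    # haploid "1" or diploid homozygous-style "1/1" encodings both accepted
    return (g.ploidy == 1 and g.allele_count_alt == 1) or (
        g.ploidy == 2 and g.allele_count_alt == 2
    )


def call_x_linked(
    variant: CohortVariant,
    family: PedigreeFamily,
    proband_id: str,
    quality: QualityFilterResult,
    allow_female: bool = False,
) -> Optional[InheritanceCall]:
    """chrX (non-PAR) variant hemizygous in a male proband, heterozygous in
    the mother.  ``allow_female`` optionally admits affected female probands
    homozygous for the variant (a documented deviation from the default)."""
    if normalize_chrom(variant.chrom) != "chrX" or in_par(variant.chrom, variant.pos):
        return None
    proband = family.member(proband_id)
    if proband is None:
        return None
    g = _retained_genotype(variant, proband_id, quality)
    if g is None:
        return None
    if proband.sex == "male":
        if not _is_hemizygous_alt(g):
            return None
    elif allow_female:
        if not g.is_hom_alt:
            return None
    else:
        return None
    _, mother_id = family.parents_of(proband_id)
    if mother_id is None:
        return None
    mg = _retained_genotype(variant, mother_id, quality)
    if mg is None or not mg.is_het:
        return None
    father_id, _ = family.parents_of(proband_id)
    return InheritanceCall(
        proband_id=proband_id,
        family_id=family.family_id,
        mode=MODE_X_LINKED,
        variants=(variant.key,),
        evidence={"proband_hemizygous": PASS, "mother_het": PASS},
        one_parent_only=father_id is None,
    )


def segregate_all(
    variants: list[CohortVariant],
    families: list[PedigreeFamily],
    freq: dict[VariantKey, FrequencyClass],
    quality: QualityFilterResult,
    strict_sibling_comp_het: bool = False,
    allow_female_x: bool = False,
) -> list[InheritanceCall]:
    """Run all four callers for every proband in every family.

    De novo calling is restricted to private variants; the inherited modes
    run over rare variants, per the pipeline's stage order.
    """
    calls: list[InheritanceCall] = []
    for family in families:
        member_ids = {m.individual_id for m in family.members}
        for proband in family.probands:
            pid = proband.individual_id
            if pid not in member_ids:
                continue
            rare_by_gene: dict[str, list[CohortVariant]] = {}
            for v in variants:
                fc = freq.get(v.key)
                if fc is None:
                    continue
                if fc.is_private:
                    dn = call_de_novo(v, family, pid, quality)
                    if dn is not None:
                        calls.append(dn)
                if not fc.is_rare:
                    continue
                hom = call_inherited_homozygous(v, family, pid, quality)
                if hom is not None:
                    calls.append(hom)
                xl = call_x_linked(v, family, pid, quality, allow_female=allow_female_x)
                if xl is not None:
                    calls.append(xl)
                gene = v.annotation.gene if v.annotation is not None else None
                if gene is not None:
                    rare_by_gene.setdefault(gene, []).append(v)
            for gene, gene_variants in rare_by_gene.items():
                calls.extend(
                    call_compound_het(
                        gene,
                        gene_variants,
                        family,
                        pid,
                        quality,
                        strict_sibling=strict_sibling_comp_het,
                    )
                )
    return calls


def mode_counts(calls: list[InheritanceCall]) -> pd.DataFrame:
    """Per-proband counts for each inheritance mode."""
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for c in calls:
        row = rows.setdefault((c.family_id, c.proband_id), {m: 0 for m in MODES})
        row[c.mode] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if not df.empty:
        df.index = pd.MultiIndex.from_tuples(df.index, names=["family_id", "proband_id"])
    return df.sort_index()
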