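"""Inheritance-mode calling: worked examples per mode, missing-parent
degradation, and equivalence with a brute-force evaluator on random small
families."""

import numpy as np
import pytest

from exofam.filtration import apply_quality_filter, classify_all
from exofam.models import CohortVariant, GenotypeCall, VariantAnnotation
from exofam.pipeline import attach_annotations
from exofam.segregation import (
    call_compound_het,
    call_de_novo,
    call_inherited_homozygous,
    call_x_linked,
    evaluate_de_novo,
    mode_counts,
    segregate_all,
)

from conftest import het, homalt, homref, make_trio, make_variant
from oracles import brute_force_segregation, mendelian_consistent


def _quality(variants):
    return apply_quality_filter(variants)


# ---------------------------------------------------------------------------
# de novo
# ---------------------------------------------------------------------------


def test_de_novo_all_criteria_pass():
    fam = make_trio()
    v = make_variant(
        genotypes={
            "FAM1-P1": GenotypeCall(1, 27, 99, 15, 12),  # ratio 12/27 = 0.444
            "FAM1-FA": homref(),
            "FAM1-MO": homref(),
        },
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    call = call_de_novo(v, fam, "FAM1-P1", _quality([v]))
    assert call is not None and call.mode == "de_novo"
    assert not call.one_parent_only


def test_de_novo_parental_carrier_blocks():
    fam = make_trio()
    v = make_variant(
        genotypes={"FAM1-P1": het(), "FAM1-FA": het(), "FAM1-MO": homref()},
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    assert call_de_novo(v, fam, "FAM1-P1", _quality([v])) is None


def test_de_novo_allele_balance_failure_recorded():
    fam = make_trio()
    v = make_variant(
        genotypes={
            "FAM1-P1": GenotypeCall(1, 50, 99, 40, 10),  # 10/50 = 0.2 < 0.3
            "FAM1-FA": homref(),
            "FAM1-MO": homref(),
        },
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    ok, evidence, _ = evaluate_de_novo(v, fam, "FAM1-P1", _quality([v]))
    assert not ok
    assert evidence["allele_balance_0.3_0.7"] == "fail"


@pytest.mark.parametrize(
    "field,value",
    [("gq", 98), ("qual", 998), ("alt", "A" * 51)],
)
def test_de_novo_boundary_failures(field, value):
    fam = make_trio()
    kwargs = dict(
        genotypes={
            "FAM1-P1": GenotypeCall(1, 50, 99 if field != "gq" else value, 25, 25),
            "FAM1-FA": homref(),
            "FAM1-MO": homref(),
        },
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    if field == "qual":
        kwargs["qual"] = value
    if field == "alt":
        kwargs["alt"] = value
    v = make_variant(**kwargs)
    assert call_de_novo(v, fam, "FAM1-P1", _quality([v])) is None


def test_de_novo_one_parent_only_flag():
    fam = make_trio(missing_father=True)
    v = make_variant(
        genotypes={"FAM1-P1": het(), "FAM1-MO": homref()},
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    call = call_de_novo(v, fam, "FAM1-P1", _quality([v]))
    assert call is not None and call.one_parent_only


def test_de_novo_missing_relative_genotype_not_evaluable():
    """A dropout in a parent must not create a de novo call."""
    fam = make_trio()
    v = make_variant(
        genotypes={"FAM1-P1": het(), "FAM1-FA": GenotypeCall(), "FAM1-MO": homref()},
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    assert call_de_novo(v, fam, "FAM1-P1", _quality([v])) is None


def test_de_novo_sibling_carrier_blocks():
    fam = make_trio(with_sib=True)
    v = make_variant(
        genotypes={
            "FAM1-P1": het(),
            "FAM1-FA": homref(),
            "FAM1-MO": homref(),
            "FAM1-S1": het(),
        },
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    assert call_de_novo(v, fam, "FAM1-P1", _quality([v])) is None


# ---------------------------------------------------------------------------
# compound heterozygous
# ---------------------------------------------------------------------------


def _ch_variant(pos, proband, father, mother):
    return make_variant(
        pos=pos,
        genotypes={"FAM1-P1": proband, "FAM1-FA": father, "FAM1-MO": mother},
        gene="NVL01",
        effect="nonsynonymous-SNV",
        maf={"gnomad": 0.001},
    )


def test_comp_het_trans_pair():
    fam = make_trio()
    v1 = _ch_variant(100, het(), het(), homref())
    v2 = _ch_variant(200, het(), homref(), het())
    calls = call_compound_het("NVL01", [v1, v2], fam, "FAM1-P1", _quality([v1, v2]))
    assert len(calls) == 1
    assert set(calls[0].variants) == {v1.key, v2.key}


def test_comp_het_cis_configuration_rejected():
    fam = make_trio()
    v1 = _ch_variant(100, het(), homref(), het())
    v2 = _ch_variant(200, het(), homref(), het())
    assert call_compound_het("NVL01", [v1, v2], fam, "FAM1-P1", _quality([v1, v2])) == []


def test_comp_het_pair_count_is_product():
    fam = make_trio()
    paternal = [_ch_variant(100 + i * 10, het(), het(), homref()) for i in range(3)]
    maternal = [_ch_variant(500 + i * 10, het(), homref(), het()) for i in range(2)]
    vs = paternal + maternal
    calls = call_compound_het("NVL01", vs, fam, "FAM1-P1", _quality(vs))
    assert len(calls) == 6  # 3 paternal x 2 maternal


def test_comp_het_not_possible_with_missing_parent():
    fam = make_trio(missing_father=True)
    v1 = make_variant(pos=100, genotypes={"FAM1-P1": het(), "FAM1-MO": het()}, gene="NVL01", effect="nonsynonymous-SNV")
    v2 = make_variant(pos=200, genotypes={"FAM1-P1": het(), "FAM1-MO": homref()}, gene="NVL01", effect="nonsynonymous-SNV")
    assert call_compound_het("NVL01", [v1, v2], fam, "FAM1-P1", _quality([v1, v2])) == []


def test_comp_het_member_ad_filter():
    fam = make_trio()
    v1 = _ch_variant(100, GenotypeCall(1, 50, 99, 41, 9), het(), homref())  # AD-Alt < 10
    v2 = _ch_variant(200, het(), homref(), het())
    assert call_compound_het("NVL01", [v1, v2], fam, "FAM1-P1", _quality([v1, v2])) == []


# ---------------------------------------------------------------------------
# inherited homozygous
# ---------------------------------------------------------------------------


def test_inherited_hom_called():
    fam = make_trio(with_sib=True)
    v = make_variant(
        genotypes={
            "FAM1-P1": homalt(),
            "FAM1-FA": het(),
            "FAM1-MO": het(),
            "FAM1-S1": het(),
        },
        gene="NVL01",
        effect="nonsynonymous-SNV",
        maf={"gnomad": 0.001},
    )
    call = call_inherited_homozygous(v, fam, "FAM1-P1", _quality([v]))
    assert call is not None and call.mode == "inherited_hom"


@pytest.mark.parametrize("blocker", ["parent_hom", "sib_hom"])
def test_inherited_hom_exclusions(blocker):
    fam = make_trio(with_sib=True)
    genotypes = {
        "FAM1-P1": homalt(),
        "FAM1-FA": het(),
        "FAM1-MO": homalt() if blocker == "parent_hom" else het(),
        "FAM1-S1": homalt() if blocker == "sib_hom" else het(),
    }
    v = make_variant(genotypes=genotypes, gene="NVL01", effect="nonsynonymous-SNV", maf={"gnomad": 0.001})
    assert call_inherited_homozygous(v, fam, "FAM1-P1", _quality([v])) is None


def test_inherited_hom_one_parent():
    fam = make_trio(missing_father=True)
    v = make_variant(
        genotypes={"FAM1-P1": homalt(), "FAM1-MO": het()},
        gene="NVL01",
        effect="nonsynonymous-SNV",
    )
    call = call_inherited_homozygous(v, fam, "FAM1-P1", _quality([v]))
    assert call is not None and call.one_parent_only


# ---------------------------------------------------------------------------
# X-linked
# ---------------------------------------------------------------------------


def _x_variant(proband, mother, pos=20_000_000, father=None):
    genotypes = {"FAM1-P1": proband, "FAM1-MO": mother}
    if father is not None:
        genotypes["FAM1-FA"] = father
    return make_variant(
        chrom="chrX", pos=pos, genotypes=genotypes, gene="NVLX1", effect="nonsynonymous-SNV"
    )


def test_x_linked_called_for_hemizygous_male():
    fam = make_trio()
    v = _x_variant(homalt(), het(), father=homref())
    call = call_x_linked(v, fam, "FAM1-P1", _quality([v]))
    assert call is not None and call.mode == "x_linked"


def test_x_linked_haploid_encoding_accepted():
    fam = make_trio()
    v = _x_variant(GenotypeCall(1, 50, 99, 0, 50, ploidy=1), het(), father=homref())
    assert call_x_linked(v, fam, "FAM1-P1", _quality([v])) is not None


def test_x_linked_female_proband_rejected_by_default():
    fam = make_trio(proband_sex="female")
    v = _x_variant(homalt(), het(), father=homref())
    assert call_x_linked(v, fam, "FAM1-P1", _quality([v])) is None
    assert call_x_linked(v, fam, "FAM1-P1", _quality([v]), allow_female=True) is not None


def test_x_linked_mother_hom_rejected():
    fam = make_trio()
    v = _x_variant(homalt(), homalt(), father=homref())
    assert call_x_linked(v, fam, "FAM1-P1", _quality([v])) is None


def test_x_linked_par_region_excluded():
    fam = make_trio()
    v = _x_variant(homalt(), het(), pos=1_000_000, father=homref())  # inside PAR1
    assert call_x_linked(v, fam, "FAM1-P1", _quality([v])) is None


# ---------------------------------------------------------------------------
# orchestration & properties
# ---------------------------------------------------------------------------


def test_segregate_all_matches_truth(small_cohort):
    attach_annotations(small_cohort.variants, small_cohort.annotations)
    quality = apply_quality_filter(small_cohort.variants)
    freq = classify_all(small_cohort.variants, quality)
    calls = segregate_all(small_cohort.variants, small_cohort.families, freq, quality)
    called = {(c.proband_id, c.mode, frozenset(c.variants)) for c in calls}
    for rec in small_cohort.truth:
        if rec.kind != "variant" or rec.expected_mode is None:
            continue
        should_be_called = rec.drop_stage in (None, "damaging", "step1", "step6", "step7", "gene_rate")
        if rec.expected_mode == "compound_het":
            expectations = [(rec.sample_id, rec.expected_mode, frozenset(rec.keys))]
        else:  # single-variant modes: one call per planted key
            expectations = [
                (rec.sample_id, rec.expected_mode, frozenset([k])) for k in rec.keys
            ]
        for expected in expectations:
            assert (expected in called) == should_be_called, rec.label


def test_mode_disjointness(small_cohort):
    """No variant is both de novo and inherited for the same proband."""
    attach_annotations(small_cohort.variants, small_cohort.annotations)
    quality = apply_quality_filter(small_cohort.variants)
    freq = classify_all(small_cohort.variants, quality)
    calls = segregate_all(small_cohort.variants, small_cohort.families, freq, quality)
    de_novo = {(c.proband_id, k) for c in calls if c.mode == "de_novo" for k in c.variants}
    inherited = {(c.proband_id, k) for c in calls if c.mode != "de_novo" for k in c.variants}
    assert not (de_novo & inherited)


def test_zero_false_de_novo_on_mendelian_background(small_cohort):
    """Every de novo call must be a planted one: Mendelian-consistent
    background can never produce a de novo call."""
    attach_annotations(small_cohort.variants, small_cohort.annotations)
    quality = apply_quality_filter(small_cohort.variants)
    freq = classify_all(small_cohort.variants, quality)
    calls = segregate_all(small_cohort.variants, small_cohort.families, freq, quality)
    planted_dn = {
        (rec.sample_id, k)
        for rec in small_cohort.truth
        for k in rec.keys
        if rec.expected_mode == "de_novo"
    }
    for c in calls:
        if c.mode == "de_novo":
            assert (c.proband_id, c.variants[0]) in planted_dn


def test_mode_counts_shape(small_cohort):
    attach_annotations(small_cohort.variants, small_cohort.annotations)
    quality = apply_quality_filter(small_cohort.variants)
    freq = classify_all(small_cohort.variants, quality)
    calls = segregate_all(small_cohort.variants, small_cohort.families, freq, quality)
    df = mode_counts(calls)
    assert set(df.columns) == {"de_novo", "compound_het", "inherited_hom", "x_linked"}
    assert (df >= 0).all().all()


# ---------------------------------------------------------------------------
# brute-force equivalence on random small families
# ---------------------------------------------------------------------------


def _random_family_and_variants(rng):
    from exofam.models import PedigreeFamily, PedigreeMember

    fid = "F1"
    with_sib = rng.random() < 0.5
    missing_father = rng.random() < 0.2
    proband_sex = "male" if rng.random() < 0.7 else "female"
    members = []
    father_id = None if missing_father else f"{fid}-FA"
    if not missing_father:
        members.append(PedigreeMember(f"{fid}-FA", None, None, "male", False, "father"))
    members.append(PedigreeMember(f"{fid}-MO", None, None, "female", False, "mother"))
    members.append(PedigreeMember(f"{fid}-P1", father_id, f"{fid}-MO", proband_sex, True, "proband"))
    if with_sib:
        members.append(PedigreeMember(f"{fid}-S1", father_id, f"{fid}-MO", "female", False, "sibling"))
    fam = PedigreeFamily(fid, members)
    sample_ids = [m.individual_id for m in members]

    n_variants = int(rng.integers(1, 7))
    variants = []
    genes = ["NVL01", "NVL02"]
    for i in range(n_variants):
        on_x = rng.random() < 0.3
        chrom = "chrX" if on_x else "chr1"
        pos = int(20_000_000 + i * 13)
        genotypes = {}
        for s in sample_ids:
            roll = rng.random()
            if roll < 0.05:
                genotypes[s] = GenotypeCall()
            else:
                ac = int(rng.integers(0, 3))
                dp = int(rng.choice([5, 15, 30, 50]))
                gq = int(rng.choice([20, 50, 99]))
                if ac == 1:
                    ad_alt = int(rng.integers(0, dp + 1))
                else:
                    ad_alt = 0 if ac == 0 else dp
                genotypes[s] = GenotypeCall(ac, dp, gq, dp - ad_alt, ad_alt)
        maf_roll = rng.random()
        if maf_roll < 0.3:
            maf = {}
        elif maf_roll < 0.8:
            maf = {"gnomad": float(rng.uniform(1e-5, 0.009))}
        else:
            maf = {"gnomad": float(rng.uniform(0.011, 0.2))}
        ann = VariantAnnotation(gene=str(rng.choice(genes)), effect="nonsynonymous-SNV", maf=maf, sift_damaging=True)
        qual = float(rng.choice([500, 999, 1500]))
        variants.append(
            CohortVariant(chrom=chrom, pos=pos, ref="A", alt="G", site_qual=qual, genotypes=genotypes, annotation=ann)
        )
    return fam, variants


def test_rule_engine_matches_brute_force_on_random_families():
    rng = np.random.default_rng(20240917)
    for trial in range(300):
        fam, variants = _random_family_and_variants(rng)
        quality = apply_quality_filter(variants)
        freq = classify_all(variants, quality)
        calls = segregate_all(variants, [fam], freq, quality)
        engine = {(c.proband_id, c.mode, frozenset(c.variants)) for c in calls}
        brute = brute_force_segregation(variants, [fam], quality)
        assert engine == brute, f"trial {trial}: {engine ^ brute}"


def test_background_variants_are_mendelian(small_cohort):
    planted = {k for rec in small_cohort.truth for k in rec.keys if rec.kind == "variant"}
    fam_by_id = {f.family_id: f for f in small_cohort.families}
    checked = 0
    for v in small_cohort.variants:
        if v.key in planted:
            continue
        for fam in fam_by_id.values():
            assert mendelian_consistent(v, fam), (v.key, fam.family_id)
        checked += 1
    assert checked > 50
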