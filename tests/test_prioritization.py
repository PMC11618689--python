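"""Damaging classification, gene tiering, the prioritization ladder, the
oversized-gene missense-rate screen, and within-proband ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exofam.models import GeneMetadata, VariantAnnotation
from exofam.prioritization import (
    DamagingClass,
    classify_damaging,
    conservation_check,
    gene_missense_rate,
    prioritize_candidates,
    rank_proband_variants,
    tier_gene,
)
from exofam.segregation import InheritanceCall

from conftest import het, make_variant
from oracles import ladder_reference

TTN_META = GeneMetadata(
    symbol="TTN", sfari_score="2", coding_length_bp=108_000, gnomad_missense_rate=1.23e-5
)


# ---------------------------------------------------------------------------
# damaging classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "effect,sift,polyphen,expected_basis",
    [
        ("stopgain", None, None, "protein-truncating-or-indel-or-unknown"),
        ("splice-site", None, None, "splice-site"),
        ("frameshift-deletion", None, None, "protein-truncating-or-indel-or-unknown"),
        ("nonframeshift-insertion", None, None, "protein-truncating-or-indel-or-unknown"),
        ("unknown", None, None, "protein-truncating-or-indel-or-unknown"),
        ("nonsynonymous-SNV", False, True, "missense-predicted"),  # >= 1 of 2
        ("nonsynonymous-SNV", True, None, "missense-predicted"),
        ("nonsynonymous-SNV", False, False, None),
        ("nonsynonymous-SNV", None, None, None),  # absent predictions: not damaging
        ("synonymous-SNV", None, None, None),
    ],
)
def test_classify_damaging(effect, sift, polyphen, expected_basis):
    v = make_variant(
        genotypes={"S": het()},
        gene="G",
        effect=effect,
        sift_damaging=sift,
        polyphen_humvar_damaging=polyphen,
    )
    dc = classify_damaging(v)
    assert dc == DamagingClass(expected_basis is not None, expected_basis)


# ---------------------------------------------------------------------------
# gene tiering
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sfari,omim,tier",
    [
        ("1", False, "known"),
        ("2", False, "known"),
        ("S", False, "known"),
        ("3", False, "novel"),  # SFARI 3 does not qualify
        (None, True, "known"),
        (None, False, "novel"),
    ],
)
def test_tier_gene(sfari, omim, tier):
    assert tier_gene(GeneMetadata(symbol="G", sfari_score=sfari, omim_neuro=omim)) == tier


def test_tier_gene_absent_metadata_is_novel():
    assert tier_gene(None) == "novel"


# ---------------------------------------------------------------------------
# ladder
# ---------------------------------------------------------------------------


def _entry(pid, fam, pos=100, gene="G", mode="de_novo", chrom="chr1", **ann):
    ann.setdefault("effect", "nonsynonymous-SNV")
    ann.setdefault("sift_damaging", True)
    v = make_variant(chrom=chrom, pos=pos, genotypes={pid: het()}, gene=gene, **ann)
    call = InheritanceCall(proband_id=pid, family_id=fam, mode=mode, variants=(v.key,))
    return call, v


def test_step1_drops_cross_family_identical_variant():
    e1 = _entry("P1", "F1", pos=100)
    e2 = _entry("P2", "F2", pos=100)
    items = prioritize_candidates([e1, e2], {})
    assert all(it.dropped_at == "step1" for it in items)


def test_step1_keeps_within_family_sharing():
    e1 = _entry("P1", "F1", pos=100)
    e2 = _entry("P1b", "F1", pos=100)  # affected sibling in the same family
    items = prioritize_candidates([e1, e2], {})
    assert all(it.survived for it in items)


@pytest.mark.parametrize(
    "label,dropped",
    [
        ("Benign", True),
        ("Likely benign", True),
        ("benign/likely benign", True),
        ("Pathogenic", False),
        ("Conflicting; Benign", False),  # not a benign-only assertion
        (None, False),
    ],
)
def test_step6_clinvar_filter(label, dropped):
    items = prioritize_candidates([_entry("P1", "F1", clinvar_significance=label)], {})
    assert (items[0].dropped_at == "step6") is dropped


def test_step7_gnomad_homozygote_filter():
    items = prioritize_candidates([_entry("P1", "F1", gnomad_hom_carriers=1)], {})
    assert items[0].dropped_at == "step7"
    items = prioritize_candidates([_entry("P1", "F1", gnomad_hom_carriers=0)], {})
    assert items[0].survived


def test_recurrent_gene_flag():
    entries = [
        _entry("P1", "F1", pos=100, gene="G1"),
        _entry("P2", "F2", pos=200, gene="G1"),
        _entry("P3", "F3", pos=300, gene="G2"),
    ]
    items = prioritize_candidates(entries, {})
    by_gene = {it.variant.key[1]: it for it in items}
    assert by_gene[100].recurrent_gene and by_gene[200].recurrent_gene
    assert not by_gene[300].recurrent_gene


def test_step_trace_complete_and_conserved(small_cohort):
    from exofam.pipeline import run_variant_pipeline

    result = run_variant_pipeline(
        small_cohort.variants, small_cohort.families, small_cohort.gene_metadata, small_cohort.annotations
    )
    assert conservation_check(result.prioritized)
    for it in result.prioritized:
        assert set(it.step_trace) == {"step1", "step2", "step3", "step4", "step5", "step6", "step7", "gene_rate"}
        if it.dropped_at is not None:
            assert it.step_trace[it.dropped_at] == "dropped"


def test_ladder_is_idempotent():
    entries = [
        _entry("P1", "F1", pos=100),
        _entry("P2", "F2", pos=100),
        _entry("P3", "F3", pos=300, clinvar_significance="Benign"),
    ]
    first = prioritize_candidates(entries, {})
    second = prioritize_candidates(entries, {})
    assert [(it.dropped_at, it.step_trace) for it in first] == [
        (it.dropped_at, it.step_trace) for it in second
    ]


# ---------------------------------------------------------------------------
# oversized-gene missense rate (TTN-style)
# ---------------------------------------------------------------------------


def test_gene_missense_rate_quotient():
    v = make_variant(genotypes={"P1": het()}, gene="TTN", effect="nonsynonymous-SNV", sift_damaging=True)
    v2 = make_variant(pos=200, genotypes={"P1": het()}, gene="TTN", effect="nonsynonymous-SNV", sift_damaging=True)
    gmr = gene_missense_rate("P1", "TTN", [v, v2], TTN_META)
    assert gmr.missense_bp == 2
    assert gmr.rate == pytest.approx(2 / 108_000)
    assert gmr.exceeds_reference  # 1.85e-5 > 1.23e-5


def test_gene_missense_rate_zero_kept():
    gmr = gene_missense_rate("P1", "TTN", [], TTN_META)
    assert gmr.rate == 0.0 and not gmr.exceeds_reference


def test_ttn_variants_dropped_by_rate_filter():
    entries = [
        _entry("P1", "F1", pos=100, gene="TTN", chrom="chr2"),
        _entry("P1", "F1", pos=200, gene="TTN", chrom="chr2"),
    ]
    items = prioritize_candidates(entries, {"TTN": TTN_META})
    assert all(it.dropped_at == "gene_rate" for it in items)


def test_single_ttn_missense_below_reference_kept():
    # 1 / 108000 = 9.26e-6 < 1.23e-5
    items = prioritize_candidates([_entry("P1", "F1", pos=100, gene="TTN", chrom="chr2")], {"TTN": TTN_META})
    assert items[0].survived


def test_rate_filter_skipped_without_coding_length():
    meta = {"TTN": GeneMetadata(symbol="TTN", sfari_score="2")}
    entries = [_entry("P1", "F1", pos=p, gene="TTN", chrom="chr2") for p in (100, 200, 300)]
    items = prioritize_candidates(entries, meta)
    assert all(it.survived for it in items)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _ranked_item(pid, fam, pos, gene, mode, effect, am, meta):
    call, v = _entry(pid, fam, pos=pos, gene=gene, mode=mode, effect=effect, alphamissense=am,
                     sift_damaging=True if effect == "nonsynonymous-SNV" else None)
    (item,) = prioritize_candidates([(call, v)], meta)
    return item


def test_ranking_known_over_novel_truncating_over_missense():
    meta = {
        "SCN1A": GeneMetadata(symbol="SCN1A", sfari_score="1"),
        "RBMX2": GeneMetadata(symbol="RBMX2"),
    }
    known_mis = _ranked_item("P", "F", 100, "SCN1A", "de_novo", "nonsynonymous-SNV", 0.5, meta)
    novel_stop = _ranked_item("P", "F", 200, "RBMX2", "de_novo", "stopgain", None, meta)
    ranked = rank_proband_variants([novel_stop, known_mis])
    assert [it.gene for it in ranked] == ["SCN1A", "RBMX2"]

    stop = _ranked_item("P", "F", 300, "RBMX2", "de_novo", "stopgain", None, meta)
    mis = _ranked_item("P", "F", 400, "RBMX2", "de_novo", "nonsynonymous-SNV", 0.99, meta)
    assert [it.variant.pos for it in rank_proband_variants([mis, stop])] == [300, 400]


def test_ranking_de_novo_over_inherited_and_alphamissense():
    dn = _ranked_item("P", "F", 100, "G", "de_novo", "nonsynonymous-SNV", 0.4, {})
    inh = _ranked_item("P", "F", 200, "G", "inherited_hom", "nonsynonymous-SNV", 0.9, {})
    assert [it.variant.pos for it in rank_proband_variants([inh, dn])] == [100, 200]

    hi = _ranked_item("P", "F", 300, "G", "de_novo", "nonsynonymous-SNV", 0.9, {})
    lo = _ranked_item("P", "F", 400, "G", "de_novo", "nonsynonymous-SNV", 0.4, {})
    absent = _ranked_item("P", "F", 500, "G", "de_novo", "nonsynonymous-SNV", None, {})
    assert [it.variant.pos for it in rank_proband_variants([absent, lo, hi])] == [300, 400, 500]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from(["known_gene", "novel_gene"]),
                          st.sampled_from(["stopgain", "nonsynonymous-SNV"]),
                          st.sampled_from(["de_novo", "inherited_hom", "x_linked"]),
                          st.one_of(st.none(), st.floats(0, 1))),
                min_size=0, max_size=12))
def test_ranking_is_total_order(specs):
    meta = {"known_gene": GeneMetadata(symbol="known_gene", sfari_score="1")}
    items = []
    for i, (gene, effect, mode, am) in enumerate(specs):
        items.append(
            _ranked_item("P", "F", 100 + 10 * i, gene, mode, effect, am, meta)
        )
    ranked = rank_proband_variants(items)
    # deterministic: re-sorting a shuffled copy gives the same order
    ranked2 = rank_proband_variants(list(reversed(items)))
    assert [it.variant.key for it in ranked] == [it.variant.key for it in ranked2]
    # antisymmetry/transitivity via strict ordering of distinct rank keys
    keys = [it.rank_key for it in ranked]
    assert all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))


# ---------------------------------------------------------------------------
# straight-line oracle equivalence
# ---------------------------------------------------------------------------


def test_ladder_matches_straight_line_reference_on_random_cohorts():
    rng = np.random.default_rng(777)
    meta = {
        "TTN": TTN_META,
        "G1": GeneMetadata(symbol="G1", sfari_score="1", pli=0.99, loeuf=0.1),
        "G2": GeneMetadata(symbol="G2", pli=0.01, loeuf=1.2),
    }
    genes = ["TTN", "G1", "G2", "G3"]
    for trial in range(100):
        n = int(rng.integers(1, 51))
        entries = []
        for i in range(n):
            pid = f"P{rng.integers(1, 6)}"
            fam = f"F{pid[-1]}"
            gene = str(rng.choice(genes))
            pos = int(rng.choice([100, 150, 200, 250, 300, 350])) if rng.random() < 0.3 else 1000 + i
            clinvar = str(rng.choice(["Benign", "Pathogenic"])) if rng.random() < 0.25 else None
            hom = int(rng.integers(0, 3)) if rng.random() < 0.3 else None
            chrom = "chr2" if gene == "TTN" else "chr1"
            entries.append(
                _entry(pid, fam, pos=pos, gene=gene, chrom=chrom,
                       clinvar_significance=clinvar, gnomad_hom_carriers=hom,
                       mode=str(rng.choice(["de_novo", "inherited_hom"])))
            )
        items = prioritize_candidates(entries, meta)
        engine = {(it.call.proband_id, it.call.mode, it.variant.key) for it in items if it.survived}
        reference = ladder_reference(entries, meta)
        assert engine == reference, f"trial {trial}"
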