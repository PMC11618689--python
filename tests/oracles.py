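"""Independent brute-force reference implementations used only as test
oracles.  Each one re-derives its answer directly from the stated rule,
structured differently from the package code (straight-line, per-candidate
enumeration), so agreement is meaningful."""

from __future__ import annotations

import itertools
import math

from exofam.models import CohortVariant, PedigreeFamily, in_par, normalize_chrom


def _gt(variant: CohortVariant, sample: str, quality):
    g = variant.genotype(sample)
    if g.is_missing or not quality.is_retained(sample, variant.key):
        return None
    return g


def _carriers(variant, quality):
    return {
        s
        for s, g in variant.genotypes.items()
        if g.carries_alt and quality.is_retained(s, variant.key)
    }


def _is_rare(variant):
    maf = variant.annotation.maf if variant.annotation else {}
    return all(f < 0.01 for f in maf.values())


def _is_private(variant, quality):
    maf = variant.annotation.maf if variant.annotation else {}
    return len(maf) == 0 and len(_carriers(variant, quality)) == 1


def brute_force_segregation(variants, families, quality) -> set:
    """Enumerate every (proband, mode, variant-key-set) directly against the
    mode definitions."""
    out = set()
    for fam in families:
        for proband in fam.probands:
            pid = proband.individual_id
            father_id, mother_id = fam.parents_of(pid)
            sibs = fam.siblings_of(pid)
            for v in variants:
                g = _gt(v, pid, quality)
                if g is None:
                    continue
                # --- de novo ---
                if (
                    _is_private(v, quality)
                    and g.is_het
                    and g.gq is not None
                    and g.gq >= 99
                    and g.ad_alt is not None
                    and g.ad_alt >= 10
                    and g.ad_ref is not None
                    and g.ad_ref >= 10
                    and g.dp
                    and 0.3 <= g.ad_alt / g.dp <= 0.7
                    and v.site_qual is not None
                    and v.site_qual >= 999
                    and len(v.ref) <= 50
                    and len(v.alt) <= 50
                    and (father_id is not None or mother_id is not None)
                ):
                    ok = True
                    for rel in [father_id, mother_id] + [s.individual_id for s in sibs]:
                        if rel is None:
                            continue
                        rg = _gt(v, rel, quality)
                        if rg is None or rg.carries_alt:
                            ok = False
                            break
                    if ok:
                        out.add((pid, "de_novo", frozenset([v.key])))
                # --- inherited homozygous ---
                on_male_x = (
                    proband.sex == "male"
                    and normalize_chrom(v.chrom) == "chrX"
                    and not in_par(v.chrom, v.pos)
                )
                if (
                    _is_rare(v)
                    and g.is_hom_alt
                    and g.ploidy == 2
                    and not on_male_x
                    and (father_id is not None or mother_id is not None)
                ):
                    ok = True
                    for parent in (father_id, mother_id):
                        if parent is None:
                            continue
                        pg = _gt(v, parent, quality)
                        if pg is None or not pg.is_het:
                            ok = False
                            break
                    if ok:
                        for sib in sibs:
                            if sib.affected:
                                continue
                            sg = _gt(v, sib.individual_id, quality)
                            if sg is not None and sg.is_hom_alt:
                                ok = False
                                break
                    if ok:
                        out.add((pid, "inherited_hom", frozenset([v.key])))
                # --- X-linked ---
                if (
                    _is_rare(v)
                    and normalize_chrom(v.chrom) == "chrX"
                    and not in_par(v.chrom, v.pos)
                    and proband.sex == "male"
                    and g.allele_count_alt == g.ploidy
                    and mother_id is not None
                ):
                    mg = _gt(v, mother_id, quality)
                    if mg is not None and mg.is_het:
                        out.add((pid, "x_linked", frozenset([v.key])))
            # --- compound heterozygous ---
            if father_id is None or mother_id is None:
                continue
            by_gene = {}
            for v in variants:
                gene = v.annotation.gene if v.annotation else None
                if gene is not None and _is_rare(v):
                    by_gene.setdefault(gene, []).append(v)
            for gene, vs in by_gene.items():
                for v1, v2 in itertools.combinations(vs, 2):
                    sides = []
                    for v in (v1, v2):
                        g = _gt(v, pid, quality)
                        fg = _gt(v, father_id, quality)
                        mg = _gt(v, mother_id, quality)
                        if (
                            g is None
                            or not g.is_het
                            or g.ad_alt is None
                            or g.ad_alt < 10
                            or g.ad_ref is None
                            or g.ad_ref < 10
                            or not g.dp
                            or not (0.3 <= g.ad_alt / g.dp <= 0.7)
                            or fg is None
                            or mg is None
                        ):
                            sides.append(None)
                        elif fg.is_het and mg.is_hom_ref:
                            sides.append("P")
                        elif mg.is_het and fg.is_hom_ref:
                            sides.append("M")
                        else:
                            sides.append(None)
                    if set(sides) == {"P", "M"}:
                        out.add((pid, "compound_het", frozenset([v1.key, v2.key])))
    return out


def ladder_reference(entries, metadata, oversized=("TTN",)) -> set:
    """Straight-line re-statement of the prioritization rules; returns the
    surviving (proband, mode, key) triples."""
    families_per_key = {}
    for call, v in entries:
        families_per_key.setdefault(v.key, set()).add(call.family_id)
    survivors = []
    for call, v in entries:
        if len(families_per_key[v.key]) > 1:
            continue
        ann = v.annotation
        label = (ann.clinvar_significance or "").lower() if ann else ""
        parts = [p.strip() for p in label.replace("/", ";").split(";") if p.strip()]
        if parts and all(p in ("benign", "likely benign", "likely_benign") for p in parts):
            continue
        if ann and (ann.gnomad_hom_carriers or 0) >= 1:
            continue
        survivors.append((call, v))
    # oversized-gene missense rate per proband
    out = set()
    dropped_pg = set()
    for gene in oversized:
        meta = metadata.get(gene)
        if meta is None or not meta.coding_length_bp or meta.gnomad_missense_rate is None:
            continue
        per_proband = {}
        for call, v in survivors:
            if v.annotation and v.annotation.gene == gene and v.annotation.effect == "nonsynonymous-SNV":
                per_proband.setdefault(call.proband_id, 0)
                per_proband[call.proband_id] += len(v.ref)
        for pid, bp in per_proband.items():
            if bp / meta.coding_length_bp > meta.gnomad_missense_rate:
                dropped_pg.add((pid, gene))
    for call, v in survivors:
        gene = v.annotation.gene if v.annotation else None
        if (call.proband_id, gene) in dropped_pg:
            continue
        out.add((call.proband_id, call.mode, v.key))
    return out


def hypergeom_tail_sum(k, M, K, n) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n) by direct pmf summation."""
    total = 0.0
    denom = math.comb(M, n)
    for x in range(k, min(K, n) + 1):
        if n - x > M - K:
            continue
        total += math.comb(K, x) * math.comb(M - K, n - x) / denom
    return total


def bh_reference(pvalues):
    """Step-up BH adjusted values via explicit sort and cumulative minimum."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running = min(running, pvalues[i] * m / rank_from_end)
        adjusted[i] = running
    return adjusted


def mendelian_consistent(variant, family) -> bool:
    """Child alleles must be drawable from the recorded parental genotypes."""
    geno = {m.individual_id: variant.genotype(m.individual_id) for m in family.members}
    for m in family.members:
        if m.role not in ("proband", "sibling"):
            continue
        if m.father_id is None or m.mother_id is None:
            continue
        child = geno.get(m.individual_id)
        f = geno.get(m.father_id)
        mo = geno.get(m.mother_id)
        if any(g is None or g.is_missing for g in (child, f, mo)):
            continue

        def gametes(g):
            return {0: {0}, 1: {0, 1}, 2: {1}}[g.allele_count_alt]

        possible = {a + b for a in gametes(f) for b in gametes(mo)}
        if child.allele_count_alt not in possible:
            return False
    return True
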