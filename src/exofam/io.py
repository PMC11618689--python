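"""Readers and writers for the pipeline's file formats.

VCF 4.2 (GT/DP/GQ/AD) is read through pysam with multiallelic records split
into biallelic, normalized variants.  Pedigrees use the 6-column PED
convention.  Annotation, gene-metadata, CNV-segment, locus, SV-frequency,
phenotype, and age tables are tab-separated with documented headers.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .models import (
    CnvSegment,
    CohortVariant,
    GeneMetadata,
    GenotypeCall,
    PedigreeFamily,
    PedigreeMember,
    PhenotypeTable,
    ROLE_FATHER,
    ROLE_GRANDMOTHER,
    ROLE_MOTHER,
    ROLE_PROBAND,
    ROLE_SIBLING,
    VariantAnnotation,
    VariantKey,
)

logger = logging.getLogger(__name__)

_SEX_CODES = {"1": "male", "2": "female"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _trim_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared trailing then leading bases (reference-free normalization)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _parse_genotype(sample, alt_index: int) -> GenotypeCall:
    gt = sample.get("GT", None)
    ac: Optional[int]
    ploidy = 2
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        ac = None
        ploidy = len(gt) if gt else 2
    else:
        ploidy = len(gt)
        ac = sum(1 for a in gt if a == alt_index)

    def _int(value) -> Optional[int]:
        return None if value is None else int(value)

    dp = _int(sample.get("DP", None))
    gq = _int(sample.get("GQ", None))
    ad = sample.get("AD", None)
    ad_ref = ad_alt = None
    if ad is not None and len(ad) > alt_index and ad[0] is not None:
        ad_ref = _int(ad[0])
        ad_alt = _int(ad[alt_index]) if ad[alt_index] is not None else None
    return GenotypeCall(
        allele_count_alt=ac, dp=dp, gq=gq, ad_ref=ad_ref, ad_alt=ad_alt, ploidy=ploidy
    )


def read_multisample_vcf(path: str | Path) -> list[CohortVariant]:
    """Read a multi-sample VCF into biallelic :class:`CohortVariant` records.

    Multiallelic records are split per alternate allele with per-allele AD;
    missing FORMAT fields yield absent (None) fields, never zeros.
    """
    variants: list[CohortVariant] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcf = pysam.VariantFile(str(path))
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            for alt_i, alt in enumerate(alts, start=1):
                if alt is None:
                    continue
                genotypes = {
                    s: _parse_genotype(rec.samples[s], alt_i) for s in samples
                }
                pos, ref, alt_trim = _trim_allele(rec.pos, rec.ref, str(alt))
                variants.append(
                    CohortVariant(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_trim,
                        site_qual=rec.qual,
                        genotypes=genotypes,
                    )
                )
        vcf.close()
    return variants


def _format_genotype(call: GenotypeCall) -> str:
    if call.allele_count_alt is None:
        gt = "./." if call.ploidy == 2 else "."
    elif call.ploidy == 1:
        gt = str(call.allele_count_alt)
    else:
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}[call.allele_count_alt]
    dp = "." if call.dp is None else str(call.dp)
    gq = "." if call.gq is None else str(call.gq)
    if call.ad_ref is None and call.ad_alt is None:
        ad = "."
    else:
        ad = f"{'.' if call.ad_ref is None else call.ad_ref},{'.' if call.ad_alt is None else call.ad_alt}"
    return f"{gt}:{dp}:{gq}:{ad}"


def write_vcf(
    variants: Iterable[CohortVariant], samples: list[str], path: str | Path
) -> None:
    """Write biallelic variants as a plain-text VCF 4.2 with GT:DP:GQ:AD."""
    variants = list(variants)
    def _contig_order(chrom: str) -> tuple:
        bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
        return (0, int(bare)) if bare.isdigit() else (1, bare)

    contigs = sorted({v.chrom for v in variants}, key=_contig_order)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
        qual = "." if v.site_qual is None else f"{v.site_qual:g}"
        fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, qual, "PASS", ".", "GT:DP:GQ:AD"]
        fields += [_format_genotype(v.genotype(s)) for s in samples]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def _infer_roles(rows: list[dict]) -> dict[str, str]:
    ids = {r["iid"] for r in rows}
    fathers = {r["fid_"] for r in rows if r["fid_"]}
    mothers = {r["mid_"] for r in rows if r["mid_"]}
    parent_ids = fathers | mothers
    roles: dict[str, str] = {}
    for r in rows:
        iid = r["iid"]
        if iid in parent_ids:
            # a parent whose own child is itself a parent is a grandparent
            children = [x for x in rows if x["fid_"] == iid or x["mid_"] == iid]
            if any(c["iid"] in parent_ids for c in children):
                roles[iid] = ROLE_GRANDMOTHER if r["sex"] == "female" else ROLE_FATHER
            else:
                roles[iid] = ROLE_FATHER if r["sex"] == "male" else ROLE_MOTHER
        elif r["affected"]:
            roles[iid] = ROLE_PROBAND
        else:
            roles[iid] = ROLE_SIBLING
    # sanity: parent ids referencing people absent from the file are external
    del ids
    return roles


def _check_acyclic(rows: list[dict]) -> None:
    parent = {r["iid"]: [p for p in (r["fid_"], r["mid_"]) if p] for r in rows}
    for start in parent:
        seen = {start}
        frontier = list(parent[start])
        while frontier:
            node = frontier.pop()
            if node == start:
                raise ValueError(f"cyclic parentage involving {start}")
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(parent.get(node, []))


def read_pedigree(path: str | Path) -> list[PedigreeFamily]:
    """Read a 6-column PED file (affected coded 2/1, sex coded 1/2)."""
    fam_rows: dict[str, list[dict]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"PED line {lineno}: expected 6 columns")
        fid, iid, father, mother, sex_code, pheno = parts[:6]
        if sex_code not in _SEX_CODES:
            raise ValueError(f"PED line {lineno}: unknown sex code {sex_code!r}")
        fam_rows.setdefault(fid, []).append(
            {
                "iid": iid,
                "fid_": None if father in ("0", ".", "") else father,
                "mid_": None if mother in ("0", ".", "") else mother,
                "sex": _SEX_CODES[sex_code],
                "affected": pheno == "2",
            }
        )
    families = []
    for fid, rows in fam_rows.items():
        _check_acyclic(rows)
        roles = _infer_roles(rows)
        members = [
            PedigreeMember(
                individual_id=r["iid"],
                father_id=r["fid_"],
                mother_id=r["mid_"],
                sex=r["sex"],
                affected=r["affected"],
                role=roles[r["iid"]],
            )
            for r in rows
        ]
        families.append(PedigreeFamily(family_id=fid, members=members))
    return families


def write_pedigree(families: Iterable[PedigreeFamily], path: str | Path) -> None:
    lines = []
    for fam in families:
        for m in fam.members:
            lines.append(
                "\t".join(
                    [
                        fam.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        "1" if m.sex == "male" else "2",
                        "2" if m.affected else "1",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

_ANNOT_FIXED = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "sift_damaging",
    "polyphen_humvar_damaging",
    "vest",
    "cadd",
    "phylop",
    "alphamissense",
    "clinvar_significance",
    "gnomad_hom_carriers",
]


def _opt_bool(x) -> Optional[bool]:
    if x is None or (isinstance(x, float) and pd.isna(x)) or x == "":
        return None
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in ("true", "1", "yes", "d")


def _opt_float(x) -> Optional[float]:
    if x is None or x == "" or (isinstance(x, float) and pd.isna(x)):
        return None
    return float(x)


def _opt_int(x) -> Optional[int]:
    f = _opt_float(x)
    return None if f is None else int(f)


def _opt_str(x) -> Optional[str]:
    if x is None or (isinstance(x, float) and pd.isna(x)) or str(x) == "":
        return None
    return str(x)


def read_annotation_table(path: str | Path) -> dict[VariantKey, VariantAnnotation]:
    """Read the per-variant annotation TSV keyed by (chrom, pos, ref, alt).

    Columns named ``maf_<database>`` become entries of the MAF mapping; empty
    cells mean "absent from that database".  Duplicate keys: last row wins,
    with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    out: dict[VariantKey, VariantAnnotation] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        if int(d["pos"]) < 0:
            raise ValueError("negative variant position")
        key = (d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        maf = {}
        for c in maf_cols:
            f = _opt_float(d[c])
            if f is not None:
                maf[c[4:]] = f
        ann = VariantAnnotation(
            gene=_opt_str(d.get("gene")),
            effect=d["effect"],
            maf=maf,
            sift_damaging=_opt_bool(d.get("sift_damaging")),
            polyphen_humvar_damaging=_opt_bool(d.get("polyphen_humvar_damaging")),
            vest=_opt_float(d.get("vest")),
            cadd=_opt_float(d.get("cadd")),
            phylop=_opt_float(d.get("phylop")),
            alphamissense=_opt_float(d.get("alphamissense")),
            clinvar_significance=_opt_str(d.get("clinvar_significance")),
            gnomad_hom_carriers=_opt_int(d.get("gnomad_hom_carriers")),
        )
        if key in out:
            logger.warning("duplicate annotation key %s: last row wins", key)
        out[key] = ann
    return out


def write_annotation_table(
    annotations: dict[VariantKey, VariantAnnotation], path: str | Path
) -> None:
    dbs: dict[str, None] = {}
    for ann in annotations.values():
        for db in ann.maf:
            dbs.setdefault(db)
    maf_cols = [f"maf_{db}" for db in sorted(dbs)]
    rows = []
    for key in sorted(annotations):
        ann = annotations[key]
        row = {
            "chrom": key[0],
            "pos": key[1],
            "ref": key[2],
            "alt": key[3],
            "gene": ann.gene or "",
            "effect": ann.effect,
            "sift_damaging": "" if ann.sift_damaging is None else str(ann.sift_damaging),
            "polyphen_humvar_damaging": ""
            if ann.polyphen_humvar_damaging is None
            else str(ann.polyphen_humvar_damaging),
            "vest": "" if ann.vest is None else repr(ann.vest),
            "cadd": "" if ann.cadd is None else repr(ann.cadd),
            "phylop": "" if ann.phylop is None else repr(ann.phylop),
            "alphamissense": "" if ann.alphamissense is None else repr(ann.alphamissense),
            "clinvar_significance": ann.clinvar_significance or "",
            "gnomad_hom_carriers": ""
            if ann.gnomad_hom_carriers is None
            else str(ann.gnomad_hom_carriers),
        }
        for col in maf_cols:
            f = ann.maf.get(col[4:])
            row[col] = "" if f is None else repr(f)
        rows.append(row)
    cols = _ANNOT_FIXED[:6] + maf_cols + _ANNOT_FIXED[6:]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene metadata
# ---------------------------------------------------------------------------

def read_gene_metadata(path: str | Path) -> dict[str, GeneMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, GeneMetadata] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        meta = GeneMetadata(
            symbol=d["symbol"],
            sfari_score=_opt_str(d.get("sfari_score")),
            omim_neuro=bool(_opt_bool(d.get("omim_neuro"))),
            pli=_opt_float(d.get("pli")),
            loeuf=_opt_float(d.get("loeuf")),
            z_score=_opt_float(d.get("z_score")),
            coding_length_bp=_opt_int(d.get("coding_length_bp")),
            gnomad_missense_rate=_opt_float(d.get("gnomad_missense_rate")),
        )
        if meta.symbol in out:
            logger.warning("duplicate gene metadata for %s: last row wins", meta.symbol)
        out[meta.symbol] = meta
    return out


def write_gene_metadata(metadata: dict[str, GeneMetadata], path: str | Path) -> None:
    rows = []
    for symbol in sorted(metadata):
        m = metadata[symbol]
        rows.append(
            {
                "symbol": m.symbol,
                "sfari_score": m.sfari_score or "",
                "omim_neuro": str(m.omim_neuro),
                "pli": "" if m.pli is None else repr(m.pli),
                "loeuf": "" if m.loeuf is None else repr(m.loeuf),
                "z_score": "" if m.z_score is None else repr(m.z_score),
                "coding_length_bp": "" if m.coding_length_bp is None else str(m.coding_length_bp),
                "gnomad_missense_rate": ""
                if m.gnomad_missense_rate is None
                else repr(m.gnomad_missense_rate),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNV segments, known-CNV loci, SV frequencies
# ---------------------------------------------------------------------------

def read_cnv_segments(path: str | Path) -> list[CnvSegment]:
    """Read a CNVkit-style segment TSV (half-open 0-based intervals)."""
    df = pd.read_csv(path, sep="\t")
    return [
        CnvSegment(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            log2_ratio=float(r.log2),
            copy_number=int(r.cn),
            p_value=float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]


def write_cnv_segments(segments: Iterable[CnvSegment], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "log2": repr(s.log2_ratio),
            "cn": s.copy_number,
            "p_value": repr(s.p_value),
        }
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "log2", "cn", "p_value"]
    ).to_csv(path, sep="\t", index=False)


def read_locus_table(path: str | Path) -> list[dict]:
    """Read a BED-like known-CNV locus table: chrom, start, end, locus_id."""
    df = pd.read_csv(path, sep="\t")
    loci = []
    for r in df.itertuples(index=False):
        if int(r.start) < 0:
            raise ValueError("negative locus coordinate")
        loci.append(
            {
                "chrom": str(r.chrom),
                "start": int(r.start),
                "end": int(r.end),
                "locus_id": str(r.locus_id),
            }
        )
    return loci


def write_locus_table(loci: Iterable[dict], path: str | Path) -> None:
    pd.DataFrame(list(loci), columns=["chrom", "start", "end", "locus_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_sv_table(path: str | Path) -> list[dict]:
    """Read an SV frequency table: chrom, start, end, svtype (DEL/DUP), frequency."""
    df = pd.read_csv(path, sep="\t")
    svs = []
    for r in df.itertuples(index=False):
        freq = float(r.frequency)
        if not (0.0 <= freq <= 1.0):
            raise ValueError(f"SV frequency out of [0,1]: {freq}")
        svs.append(
            {
                "chrom": str(r.chrom),
                "start": int(r.start),
                "end": int(r.end),
                "svtype": str(r.svtype),
                "frequency": freq,
            }
        )
    return svs


def write_sv_table(svs: Iterable[dict], path: str | Path) -> None:
    rows = [
        {**sv, "frequency": repr(sv["frequency"])} for sv in svs
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Phenotypes and ages
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    conditions = [c for c in df.columns if c != "individual_id"]
    states = {
        str(r.individual_id): {c: getattr(r, c) for c in conditions}
        for r in df.itertuples(index=False)
    }
    return PhenotypeTable(states=states)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    conditions = table.conditions
    rows = [
        {"individual_id": ind, **{c: table.state(ind, c) for c in conditions}}
        for ind in sorted(table.states)
    ]
    pd.DataFrame(rows, columns=["individual_id"] + conditions).to_csv(
        path, sep="\t", index=False
    )


def read_ages(path: str | Path) -> pd.DataFrame:
    """Read per-offspring parental ages at birth: individual_id, affected,
    paternal_age, maternal_age."""
    return pd.read_csv(path, sep="\t")


def write_ages(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_run_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
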