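"""Synthetic family-exome cohorts with planted, labeled truth.

The generator emits exactly the formats the readers consume (multi-sample
VCF, PED, annotation/gene-metadata/phenotype/age TSVs, CNV segment and locus
tables) for a cohort of trio/quad families.  Non-planted background variants
are Mendelian-consistent; planted records carry a truth label stating the
inheritance class they should be called as, or the exact pipeline stage at
which they must be removed (quality, rarity, a de novo auxiliary criterion,
segregation logic, damaging classification, a prioritization step, the
oversized-gene missense-rate screen, or a CNV filter).

Sequencing noise is off by default: noise-free cohorts exercise the logic;
the optional noise model (Poisson depth, binomial allele depths, jittered GQ)
exercises the statistical behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as xio
from .models import (
    CnvSegment,
    CohortVariant,
    EFFECT_FS_INS,
    EFFECT_NONSYN,
    EFFECT_OTHER,
    EFFECT_STOPGAIN,
    EFFECT_SYN,
    GeneMetadata,
    GenotypeCall,
    PedigreeFamily,
    PedigreeMember,
    PHENO_ABSENT,
    PHENO_PRESENT,
    PHENO_UNKNOWN,
    PhenotypeTable,
    ROLE_FATHER,
    ROLE_MOTHER,
    ROLE_PROBAND,
    ROLE_SIBLING,
    VariantAnnotation,
    VariantKey,
)

# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

# symbol, chrom, sfari, omim_neuro, pli, loeuf, coding length (bp)
_PANEL = [
    ("SCN1A", "chr2", "1", True, 1.00, 0.11, 6030),
    ("SHANK3", "chr22", "1", True, 0.98, 0.21, 5166),
    ("CHD8", "chr14", "1", True, 1.00, 0.08, 7746),
    ("SYNGAP1", "chr6", "1", True, 1.00, 0.06, 4035),
    ("ADNP", "chr20", "1", True, 0.99, 0.17, 3309),
    ("ATP1A3", "chr19", None, True, 1.00, 0.10, 3042),
    ("TTN", "chr2", "2", False, 0.00, 1.06, 108000),
    ("MECP2", "chrX", "1", True, 0.92, 0.34, 1461),
    ("SLC7A3", "chrX", "2", False, 0.02, 0.95, 1848),
    ("NVLX1", "chrX", None, False, 0.10, 0.90, 2400),
    ("NVLX2", "chrX", None, False, 0.75, 0.40, 2100),
    ("NVL01", "chr1", None, False, 0.99, 0.20, 3600),
    ("NVL02", "chr3", None, False, 0.01, 1.10, 2700),
    ("NVL03", "chr4", None, False, 0.65, 0.45, 4200),
    ("NVL04", "chr5", None, False, 0.30, 0.80, 3000),
    ("NVL05", "chr7", None, False, 0.95, 0.25, 5100),
    ("NVL06", "chr8", None, False, 0.05, 1.00, 2400),
    ("NVL07", "chr9", None, False, 0.88, 0.33, 3900),
    ("NVL08", "chr10", None, False, 0.15, 0.92, 2850),
    ("NVL09", "chr11", None, False, 0.72, 0.41, 3300),
    ("NVL10", "chr12", None, False, 0.44, 0.66, 4500),
    ("NVL11", "chr13", None, False, 0.91, 0.28, 2550),
    ("NVL12", "chr15", None, False, 0.08, 1.20, 3150),
    ("NVL13", "chr16", None, False, 0.83, 0.37, 2700),
    ("NVL14", "chr17", None, False, 0.22, 0.85, 3450),
    ("NVL15", "chr18", None, False, 0.60, 0.52, 2400),
    ("NVL16", "chr21", None, False, 0.35, 0.71, 3600),
    # SFARI score 3 does not qualify as "known"
    ("NVL17", "chr1", "3", False, 0.50, 0.60, 3000),
]

_SITE_SPACING = 3  # bp between allocated variant sites within a gene


def default_gene_panel() -> tuple[list[dict], dict[str, GeneMetadata]]:
    """Fixed panel of genes with coordinates and metadata.

    Genes are laid out along their chromosomes with generous spacing; chrX
    genes sit between the pseudoautosomal regions.
    """
    cursors: dict[str, int] = {}
    genes: list[dict] = []
    metadata: dict[str, GeneMetadata] = {}
    for symbol, chrom, sfari, omim, pli, loeuf, length in _PANEL:
        start = cursors.get(chrom, 10_000_000)
        cursors[chrom] = start + length + 1_000_000
        genes.append({"symbol": symbol, "chrom": chrom, "start": start, "length": length})
        metadata[symbol] = GeneMetadata(
            symbol=symbol,
            sfari_score=sfari,
            omim_neuro=omim,
            pli=pli,
            loeuf=loeuf,
            z_score=round(3.0 * pli - 0.5, 2),
            coding_length_bp=length,
            gnomad_missense_rate=1.23e-5 if symbol == "TTN" else 8.0e-6,
        )
    return genes, metadata


# ---------------------------------------------------------------------------
# Configuration / truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    n_families: int = 50
    quad_fraction: float = 0.5
    one_parent_fraction: float = 0.06
    seed: int = 0
    male_proband_fraction: float = 162 / 222  # observed cohort sex ratio 2.7:1
    # planted per-proband means (coding/non-coding split mirrors the observed
    # average of 4 de novo candidates per proband, 2 of them coding)
    de_novo_coding_per_proband: float = 2.0
    de_novo_noncoding_per_proband: float = 2.0
    comp_het_pairs_per_proband: float = 1.0
    inherited_hom_per_proband: float = 1.0
    x_linked_per_male_proband: float = 1.0
    decoy_rate: float = 0.5
    ttn_decoy_rate: float = 0.2
    background_variants: int = 200
    frac_background_common: float = 0.25
    frac_background_rare_known: float = 0.35  # remainder is novel
    # noise model (off by default; logic tests run noise-free)
    noise: bool = False
    depth_mean: float = 46.0
    gq_mean: float = 90.0
    allele_balance_beta: tuple[float, float] = (20.0, 20.0)
    haploid_male_x: bool = False
    # phenotype simulation
    phenotype_prevalences: dict = field(
        default_factory=lambda: {
            "language_impairment": 0.9172,
            "developmental_delay": 0.8321,
            "learning_disability": 0.7131,
            "behavioral_problems": 0.6581,
            "ADHD": 0.4955,
            "intellectual_disability": 0.4954,
            "seizures": 0.2745,
            "OCD": 0.25,
        }
    )
    phenotype_tested_fraction: float = 0.6
    # CNV planting (deterministic per proband so per-sample segment counts
    # stay tightly clustered for the outlier policy)
    cnv_size_range: tuple[int, int] = (50_000, 450_000)
    n_outlier_segments: int = 174

    def __post_init__(self) -> None:
        rates = [
            self.de_novo_coding_per_proband,
            self.de_novo_noncoding_per_proband,
            self.comp_het_pairs_per_proband,
            self.inherited_hom_per_proband,
            self.x_linked_per_male_proband,
            self.decoy_rate,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("planting rates must be >= 0")


@dataclass
class TruthRecord:
    kind: str  # "variant" | "cnv"
    label: str
    family_id: str
    sample_id: str
    keys: tuple
    expected_mode: Optional[str] = None
    drop_stage: Optional[str] = None  # None => expected final survivor

    @property
    def is_survivor(self) -> bool:
        return self.drop_stage is None


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    families: list[PedigreeFamily]
    samples: list[str]
    variants: list[CohortVariant]
    annotations: dict[VariantKey, VariantAnnotation]
    gene_metadata: dict[str, GeneMetadata]
    phenotypes: PhenotypeTable
    ages: pd.DataFrame
    truth: list[TruthRecord]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "ped": outdir / "cohort.ped",
            "annotation": outdir / "annotation.tsv",
            "genes": outdir / "genes.tsv",
            "phenotypes": outdir / "phenotypes.tsv",
            "ages": outdir / "ages.tsv",
            "truth": outdir / "truth.json",
        }
        xio.write_vcf(self.variants, self.samples, paths["vcf"])
        xio.write_pedigree(self.families, paths["ped"])
        xio.write_annotation_table(self.annotations, paths["annotation"])
        xio.write_gene_metadata(self.gene_metadata, paths["genes"])
        xio.write_phenotypes(self.phenotypes, paths["phenotypes"])
        xio.write_ages(self.ages, paths["ages"])
        paths["truth"].write_text(
            json.dumps([asdict(t) for t in self.truth], indent=1, sort_keys=True) + "\n"
        )
        return paths


@dataclass
class SimulatedCnv:
    segments: list[CnvSegment]
    asd_loci: list[dict]
    syndromic_loci: list[dict]
    sv_table: list[dict]
    truth: list[TruthRecord]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "segments": outdir / "cnv_segments.tsv",
            "asd_loci": outdir / "asd_loci.tsv",
            "syndromic_loci": outdir / "syndromic_loci.tsv",
            "sv_table": outdir / "sv_frequencies.tsv",
            "truth": outdir / "cnv_truth.json",
        }
        xio.write_cnv_segments(self.segments, paths["segments"])
        xio.write_locus_table(self.asd_loci, paths["asd_loci"])
        xio.write_locus_table(self.syndromic_loci, paths["syndromic_loci"])
        xio.write_sv_table(self.sv_table, paths["sv_table"])
        paths["truth"].write_text(
            json.dumps([asdict(t) for t in self.truth], indent=1, sort_keys=True) + "\n"
        )
        return paths


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

HOMREF = GenotypeCall(0, 50, 99, 50, 0)


class _SiteAllocator:
    """Hands out unique positions inside gene intervals."""

    def __init__(self, genes: list[dict]):
        self.genes = {g["symbol"]: g for g in genes}
        self.offsets = {g["symbol"]: 0 for g in genes}

    def allocate(self, symbol: str) -> tuple[str, int]:
        g = self.genes[symbol]
        off = self.offsets[symbol]
        if off + _SITE_SPACING >= g["length"]:
            raise ValueError(
                "planting rates and background imply more variant sites than "
                f"available slots in gene {symbol}"
            )
        self.offsets[symbol] = off + _SITE_SPACING
        return g["chrom"], g["start"] + off + 1


def _noisefree_call(ac: Optional[int], ploidy: int = 2, dp: int = 50, gq: int = 99) -> GenotypeCall:
    if ac is None:
        return GenotypeCall(ploidy=ploidy)
    if ac == 0:
        return GenotypeCall(0, dp, gq, dp, 0, ploidy)
    if ac == ploidy:
        return GenotypeCall(ac, dp, gq, 0, dp, ploidy)
    return GenotypeCall(ac, dp, gq, dp - dp // 2, dp // 2, ploidy)


def _noisy_call(ac: Optional[int], rng: np.random.Generator, cfg: SimulationConfig, ploidy: int = 2) -> GenotypeCall:
    if ac is None:
        return GenotypeCall(ploidy=ploidy)
    dp = max(1, int(rng.poisson(cfg.depth_mean)))
    gq = int(np.clip(rng.normal(cfg.gq_mean, 10), 0, 99))
    if ac == 0:
        ad_alt = 0
    elif ac == ploidy:
        ad_alt = dp
    else:
        ab = rng.beta(*cfg.allele_balance_beta)
        ad_alt = int(rng.binomial(dp, ab))
    return GenotypeCall(ac, dp, gq, dp - ad_alt, ad_alt, ploidy)


class _Cohort:
    """Mutable build state for one simulation run."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.genes, self.metadata = default_gene_panel()
        self.alloc = _SiteAllocator(self.genes)
        self.autosomal = [g["symbol"] for g in self.genes if g["chrom"] != "chrX" and g["symbol"] != "TTN"]
        self.x_genes = [g["symbol"] for g in self.genes if g["chrom"] == "chrX"]
        self.comp_het_genes = [s for s in self.autosomal]
        self.variants: list[CohortVariant] = []
        self.annotations: dict[VariantKey, VariantAnnotation] = {}
        self.truth: list[TruthRecord] = []
        self.families: list[PedigreeFamily] = []
        self.samples: list[str] = []

    # -- family construction -------------------------------------------------

    def build_families(self) -> None:
        cfg = self.cfg
        for i in range(cfg.n_families):
            fid = f"FAM{i:04d}"
            one_parent = self.rng.random() < cfg.one_parent_fraction
            quad = self.rng.random() < cfg.quad_fraction
            proband_sex = "male" if self.rng.random() < cfg.male_proband_fraction else "female"
            father = f"{fid}-FA"
            mother = f"{fid}-MO"
            members = []
            father_id: Optional[str] = father
            if one_parent:
                father_id = None  # father unsequenced and absent from the pedigree
            else:
                members.append(PedigreeMember(father, None, None, "male", False, ROLE_FATHER))
            members.append(PedigreeMember(mother, None, None, "female", False, ROLE_MOTHER))
            members.append(
                PedigreeMember(f"{fid}-P1", father_id, mother, proband_sex, True, ROLE_PROBAND)
            )
            if quad:
                sib_sex = "male" if self.rng.random() < 0.5 else "female"
                members.append(
                    PedigreeMember(f"{fid}-S1", father_id, mother, sib_sex, False, ROLE_SIBLING)
                )
            self.families.append(PedigreeFamily(family_id=fid, members=members))
        self.samples = [m.individual_id for f in self.families for m in f.members]
        self.sample_sex = {
            m.individual_id: m.sex for f in self.families for m in f.members
        }

    # -- variant helpers ------------------------------------------------------

    def _call(self, ac: Optional[int], ploidy: int = 2, **kw) -> GenotypeCall:
        if self.cfg.noise:
            return _noisy_call(ac, self.rng, self.cfg, ploidy=ploidy)
        return _noisefree_call(ac, ploidy=ploidy, **kw)

    def add_site(
        self,
        gene: str,
        genotypes: dict[str, GenotypeCall],
        annotation: VariantAnnotation,
        qual: float = 1000.0,
        ref: str = "A",
        alt: str = "G",
    ) -> VariantKey:
        chrom, pos = self.alloc.allocate(gene)
        full = {}
        for s in self.samples:
            if s in genotypes:
                full[s] = genotypes[s]
            elif chrom == "chrX" and self.cfg.haploid_male_x and self.sample_sex[s] == "male":
                full[s] = self._call(0, ploidy=1)
            else:
                full[s] = HOMREF if not self.cfg.noise else self._call(0)
        v = CohortVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, site_qual=qual, genotypes=full)
        self.variants.append(v)
        self.annotations[v.key] = annotation
        return v.key

    def _damaging_missense(self, gene: str, rare_maf: Optional[float] = None, **kw) -> VariantAnnotation:
        maf = {} if rare_maf is None else {"gnomad": rare_maf}
        return VariantAnnotation(
            gene=gene,
            effect=EFFECT_NONSYN,
            maf=maf,
            sift_damaging=True,
            polyphen_humvar_damaging=bool(self.rng.random() < 0.7),
            vest=float(np.round(self.rng.uniform(0.5, 1.0), 3)),
            cadd=float(np.round(self.rng.uniform(20, 40), 2)),
            phylop=float(np.round(self.rng.uniform(2, 8), 2)),
            alphamissense=float(np.round(self.rng.uniform(0.3, 1.0), 3)),
            **kw,
        )

    # -- planting -------------------------------------------------------------

    def plant_all(self) -> None:
        cfg = self.cfg
        rng = self.rng
        dup_candidates: list[tuple[PedigreeFamily, str]] = []
        for fam in self.families:
            proband = fam.probands[0]
            pid = proband.individual_id
            father_id, mother_id = fam.parents_of(pid)
            two_parents = father_id is not None and mother_id is not None
            sib = next((m for m in fam.siblings if not m.affected), None)

            # --- expected survivors ---
            for _ in range(rng.poisson(cfg.de_novo_coding_per_proband)):
                self._plant_de_novo(fam, pid, coding=True)
            for _ in range(rng.poisson(cfg.de_novo_noncoding_per_proband)):
                self._plant_de_novo(fam, pid, coding=False)
            if two_parents:
                for _ in range(rng.poisson(cfg.comp_het_pairs_per_proband)):
                    self._plant_comp_het(fam, pid, cis=False)
            for _ in range(rng.poisson(cfg.inherited_hom_per_proband)):
                self._plant_inherited_hom(fam, pid, sib_hom=False)
            if proband.sex == "male":
                for _ in range(rng.poisson(cfg.x_linked_per_male_proband)):
                    self._plant_x_linked(fam, pid, mother_hom=False)

            # --- decoys, one stage each ---
            p = cfg.decoy_rate
            if rng.random() < p:
                self._plant_quality_decoy(fam, pid)
            if rng.random() < p:
                self._plant_not_rare_decoy(fam, pid)
            if rng.random() < p:
                self._plant_dn_decoy(fam, pid, flavor="allele-balance")
            if rng.random() < p:
                self._plant_dn_decoy(fam, pid, flavor="low-gq")
            if rng.random() < p:
                self._plant_dn_decoy(fam, pid, flavor="low-qual")
            if rng.random() < p:
                self._plant_dn_decoy(fam, pid, flavor="long-allele")
            if two_parents and rng.random() < p:
                self._plant_comp_het(fam, pid, cis=True)
            if sib is not None and two_parents and rng.random() < p:
                self._plant_inherited_hom(fam, pid, sib_hom=True)
            if proband.sex == "male" and rng.random() < p:
                self._plant_x_linked(fam, pid, mother_hom=True)
            if rng.random() < p:
                self._plant_de_novo(fam, pid, coding=True, synonymous=True)
            if rng.random() < p:
                self._plant_de_novo(fam, pid, coding=True, clinvar="Benign")
            if rng.random() < p:
                self._plant_inherited_hom(fam, pid, sib_hom=False, gnomad_hom=int(rng.integers(1, 6)))
            if rng.random() < cfg.ttn_decoy_rate:
                self._plant_ttn_excess(fam, pid)
            if rng.random() < p:
                dup_candidates.append((fam, pid))

        # cross-family identical de novo pairs (prioritization step 1 decoys)
        for (fam_a, pid_a), (fam_b, pid_b) in zip(dup_candidates[::2], dup_candidates[1::2]):
            self._plant_cross_family_dup(fam_a, pid_a, fam_b, pid_b)

    def _pick_gene(self) -> str:
        return self.autosomal[int(self.rng.integers(len(self.autosomal)))]

    def _plant_de_novo(
        self,
        fam: PedigreeFamily,
        pid: str,
        coding: bool,
        synonymous: bool = False,
        clinvar: Optional[str] = None,
        gene: Optional[str] = None,
    ) -> VariantKey:
        gene = gene or self._pick_gene()
        if synonymous:
            ann = VariantAnnotation(gene=gene, effect=EFFECT_SYN)
            label, drop = "de-novo-synonymous", "damaging"
        elif not coding:
            ann = VariantAnnotation(gene=gene, effect=EFFECT_OTHER)
            label, drop = "de-novo-noncoding", "damaging"
        elif clinvar is not None:
            ann = self._damaging_missense(gene, clinvar_significance=clinvar)
            label, drop = "de-novo-clinvar-benign", "step6"
        else:
            if self.rng.random() < 0.25:
                ann = VariantAnnotation(
                    gene=gene,
                    effect=EFFECT_STOPGAIN,
                    alphamissense=None,
                )
            else:
                ann = self._damaging_missense(gene)
            label, drop = "de-novo-survivor", None
        genos = {pid: _noisefree_call(1)}  # de novo criteria need clean AD/GQ
        key = self.add_site(gene, genos, ann)
        self.truth.append(
            TruthRecord("variant", label, fam.family_id, pid, (key,), "de_novo", drop)
        )
        return key

    def _plant_dn_decoy(self, fam: PedigreeFamily, pid: str, flavor: str) -> None:
        gene = self._pick_gene()
        ann = self._damaging_missense(gene)
        qual = 1000.0
        ref, alt = "A", "G"
        if flavor == "allele-balance":
            genos = {pid: GenotypeCall(1, 50, 99, 40, 10)}
        elif flavor == "low-gq":
            genos = {pid: GenotypeCall(1, 50, 50, 25, 25)}
        elif flavor == "low-qual":
            genos = {pid: _noisefree_call(1)}
            qual = 500.0
        elif flavor == "long-allele":
            genos = {pid: _noisefree_call(1)}
            alt = "A" + "T" * 59
            ann = VariantAnnotation(gene=gene, effect=EFFECT_FS_INS)
        else:
            raise ValueError(flavor)
        key = self.add_site(gene, genos, ann, qual=qual, ref=ref, alt=alt)
        self.truth.append(
            TruthRecord(
                "variant", f"de-novo-fails-{flavor}", fam.family_id, pid, (key,), "de_novo", "de_novo"
            )
        )

    def _plant_quality_decoy(self, fam: PedigreeFamily, pid: str) -> None:
        gene = self._pick_gene()
        key = self.add_site(gene, {pid: GenotypeCall(1, 5, 99, 3, 2)}, self._damaging_missense(gene))
        self.truth.append(
            TruthRecord("variant", "fails-quality", fam.family_id, pid, (key,), None, "quality")
        )

    def _plant_not_rare_decoy(self, fam: PedigreeFamily, pid: str) -> None:
        gene = self._pick_gene()
        _, mother_id = fam.parents_of(pid)
        genos = {pid: self._call(1)}
        if mother_id is not None:
            genos[mother_id] = self._call(1)
        ann = self._damaging_missense(gene, rare_maf=None)
        ann.maf = {"gnomad": float(np.round(self.rng.uniform(0.011, 0.2), 4))}
        key = self.add_site(gene, genos, ann)
        self.truth.append(
            TruthRecord("variant", "common-frequency", fam.family_id, pid, (key,), None, "rare")
        )

    def _plant_comp_het(self, fam: PedigreeFamily, pid: str, cis: bool) -> None:
        gene = self.comp_het_genes[int(self.rng.integers(len(self.comp_het_genes)))]
        father_id, mother_id = fam.parents_of(pid)
        assert father_id is not None and mother_id is not None
        maf = float(np.round(self.rng.uniform(1e-4, 0.009), 6))
        keys = []
        for origin in ("paternal", "maternal"):
            genos = {pid: _noisefree_call(1)}
            if cis:
                genos[mother_id] = self._call(1)
                genos[father_id] = self._call(0)
            elif origin == "paternal":
                genos[father_id] = self._call(1)
                genos[mother_id] = self._call(0)
            else:
                genos[mother_id] = self._call(1)
                genos[father_id] = self._call(0)
            keys.append(self.add_site(gene, genos, self._damaging_missense(gene, rare_maf=maf)))
        self.truth.append(
            TruthRecord(
                "variant",
                "comp-het-cis" if cis else "comp-het-survivor",
                fam.family_id,
                pid,
                tuple(sorted(keys)),
                "compound_het",
                "segregation" if cis else None,
            )
        )

    def _plant_inherited_hom(
        self, fam: PedigreeFamily, pid: str, sib_hom: bool, gnomad_hom: Optional[int] = None
    ) -> None:
        gene = self._pick_gene()
        father_id, mother_id = fam.parents_of(pid)
        genos = {pid: self._call(2)}
        for parent in (father_id, mother_id):
            if parent is not None:
                genos[parent] = self._call(1)
        for sib in fam.siblings:
            genos[sib.individual_id] = self._call(2 if sib_hom else 1)
        maf = float(np.round(self.rng.uniform(1e-4, 0.009), 6))
        ann = self._damaging_missense(gene, rare_maf=maf, gnomad_hom_carriers=gnomad_hom)
        key = self.add_site(gene, genos, ann)
        if sib_hom:
            label, drop = "hom-unaffected-sib-hom", "segregation"
        elif gnomad_hom:
            label, drop = "hom-gnomad-hom-carrier", "step7"
        else:
            label, drop = "inherited-hom-survivor", None
        self.truth.append(
            TruthRecord("variant", label, fam.family_id, pid, (key,), "inherited_hom", drop)
        )

    def _plant_x_linked(self, fam: PedigreeFamily, pid: str, mother_hom: bool) -> None:
        gene = self.x_genes[int(self.rng.integers(len(self.x_genes)))]
        father_id, mother_id = fam.parents_of(pid)
        assert mother_id is not None
        male_ploidy = 1 if self.cfg.haploid_male_x else 2
        genos = {
            pid: self._call(male_ploidy, ploidy=male_ploidy),  # hemizygous alt
            mother_id: self._call(2 if mother_hom else 1),
        }
        if father_id is not None:
            fploidy = 1 if self.cfg.haploid_male_x else 2
            genos[father_id] = self._call(0, ploidy=fploidy)
        for sib in fam.siblings:
            ploidy = 1 if (self.cfg.haploid_male_x and sib.sex == "male") else 2
            # a homozygous mother transmits the allele to every child
            ac = (1 if ploidy == 2 else 1) if mother_hom else 0
            genos[sib.individual_id] = self._call(ac, ploidy=ploidy)
        maf = float(np.round(self.rng.uniform(1e-4, 0.009), 6))
        key = self.add_site(gene, genos, self._damaging_missense(gene, rare_maf=maf))
        self.truth.append(
            TruthRecord(
                "variant",
                "x-mother-hom" if mother_hom else "x-linked-survivor",
                fam.family_id,
                pid,
                (key,),
                "x_linked",
                "segregation" if mother_hom else None,
            )
        )

    def _plant_ttn_excess(self, fam: PedigreeFamily, pid: str) -> None:
        keys = tuple(
            sorted(
                self._plant_de_novo_raw(fam, pid, gene="TTN")
                for _ in range(2)
            )
        )
        self.truth.append(
            TruthRecord("variant", "ttn-missense-excess", fam.family_id, pid, keys, "de_novo", "gene_rate")
        )

    def _plant_de_novo_raw(self, fam: PedigreeFamily, pid: str, gene: str) -> VariantKey:
        ann = self._damaging_missense(gene)
        return self.add_site(gene, {pid: _noisefree_call(1)}, ann)

    def _plant_cross_family_dup(self, fam_a, pid_a, fam_b, pid_b) -> None:
        """The exact same (inherited homozygous) variant in probands of two
        unrelated families: both calls must drop at prioritization step 1."""
        gene = self._pick_gene()
        maf = float(np.round(self.rng.uniform(1e-4, 0.009), 6))
        ann = self._damaging_missense(gene, rare_maf=maf)
        genos: dict[str, GenotypeCall] = {}
        for fam, pid in ((fam_a, pid_a), (fam_b, pid_b)):
            genos[pid] = self._call(2)
            for parent in fam.parents_of(pid):
                if parent is not None:
                    genos[parent] = self._call(1)
            for sib in fam.siblings:
                genos[sib.individual_id] = self._call(1)
        key = self.add_site(gene, genos, ann)
        for fam, pid in ((fam_a, pid_a), (fam_b, pid_b)):
            self.truth.append(
                TruthRecord(
                    "variant", "cross-family-duplicate", fam.family_id, pid, (key,), "inherited_hom", "step1"
                )
            )

    # -- Mendelian background --------------------------------------------------

    def plant_background(self) -> None:
        cfg = self.cfg
        rng = self.rng
        for _ in range(cfg.background_variants):
            gene = self._pick_gene()
            f = float(rng.beta(0.5, 8.0))
            genos: dict[str, GenotypeCall] = {}
            for fam in self.families:
                father_id, mother_id = None, None
                for m in fam.members:
                    if m.role == ROLE_FATHER:
                        father_id = m.individual_id
                    elif m.role == ROLE_MOTHER:
                        mother_id = m.individual_id
                father_ac = int(rng.binomial(2, f))
                mother_ac = int(rng.binomial(2, f))
                if father_id is not None:
                    genos[father_id] = self._call(father_ac)
                if mother_id is not None:
                    genos[mother_id] = self._call(mother_ac)
                for m in fam.members:
                    if m.role not in (ROLE_PROBAND, ROLE_SIBLING):
                        continue
                    pat = 1 if rng.random() < father_ac / 2 else 0
                    mat = 1 if rng.random() < mother_ac / 2 else 0
                    genos[m.individual_id] = self._call(pat + mat)
            roll = rng.random()
            if roll < cfg.frac_background_common:
                maf = {"gnomad": float(np.round(rng.uniform(0.011, 0.3), 4))}
            elif roll < cfg.frac_background_common + cfg.frac_background_rare_known:
                maf = {"gnomad": float(np.round(rng.uniform(1e-5, 0.009), 6)), "thousandg": float(np.round(rng.uniform(1e-5, 0.009), 6))}
            else:
                maf = {}
            effect_roll = rng.random()
            if effect_roll < 0.35:
                effect = EFFECT_SYN
            elif effect_roll < 0.8:
                effect = EFFECT_NONSYN
            else:
                effect = EFFECT_OTHER
            ann = VariantAnnotation(
                gene=gene,
                effect=effect,
                maf=maf,
                sift_damaging=bool(rng.random() < 0.4) if effect == EFFECT_NONSYN else None,
                polyphen_humvar_damaging=bool(rng.random() < 0.4) if effect == EFFECT_NONSYN else None,
                alphamissense=float(np.round(rng.uniform(0, 1), 3)) if effect == EFFECT_NONSYN else None,
            )
            self.add_site(gene, genos, ann)

    # -- phenotypes / ages ------------------------------------------------------

    def build_phenotypes(self) -> tuple[PhenotypeTable, pd.DataFrame]:
        cfg = self.cfg
        rng = self.rng
        states: dict[str, dict[str, str]] = {}
        age_rows = []
        for fam in self.families:
            for m in fam.members:
                conds = {"ASD": PHENO_PRESENT if m.affected else PHENO_ABSENT}
                for cond, prev in cfg.phenotype_prevalences.items():
                    if m.role != ROLE_PROBAND or rng.random() > cfg.phenotype_tested_fraction:
                        conds[cond] = PHENO_UNKNOWN
                    else:
                        conds[cond] = PHENO_PRESENT if rng.random() < prev else PHENO_ABSENT
                states[m.individual_id] = conds
                if m.role in (ROLE_PROBAND, ROLE_SIBLING):
                    age_rows.append(
                        {
                            "individual_id": m.individual_id,
                            "affected": m.affected,
                            "paternal_age": float(np.round(rng.normal(32.0, 5.0), 1)),
                            "maternal_age": float(np.round(rng.normal(30.0, 5.0), 1)),
                        }
                    )
        return PhenotypeTable(states=states), pd.DataFrame(age_rows)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with planted truth.

    Identical configs (including the seed) produce byte-identical outputs.
    """
    state = _Cohort(config)
    state.build_families()
    state.plant_all()
    state.plant_background()
    phenotypes, ages = state.build_phenotypes()
    return SimulatedCohort(
        config=config,
        families=state.families,
        samples=state.samples,
        variants=state.variants,
        annotations=state.annotations,
        gene_metadata=state.metadata,
        phenotypes=phenotypes,
        ages=ages,
        truth=state.truth,
    )


# ---------------------------------------------------------------------------
# CNV simulation
# ---------------------------------------------------------------------------


def simulate_cnv_segments(
    config: SimulationConfig, families: list[PedigreeFamily]
) -> SimulatedCnv:
    """Plant one CNV of every survivor/decoy class per proband.

    Planting is deterministic per proband so per-sample raw segment counts
    stay tightly clustered and only the designated outlier sample exceeds the
    median + 3*MAD bound.  Segments within one sample never overlap.
    """
    rng = np.random.default_rng(config.seed + 1)
    segments: list[CnvSegment] = []
    truth: list[TruthRecord] = []
    asd_loci: list[dict] = []
    syndromic_loci: list[dict] = []
    sv_table: list[dict] = []

    cursors: dict[tuple[str, str], int] = {}
    sample_base: dict[str, int] = {}

    def alloc(sample: str, chrom: str, size: int) -> tuple[int, int]:
        # each sample owns a disjoint coordinate band so planted intervals are
        # never accidentally identical across probands (exact dedup is itself
        # exercised by the explicit duplicate pair)
        base = 1_000_000 + sample_base.setdefault(sample, len(sample_base)) * 2_000_000
        start = cursors.get((sample, chrom), base)
        cursors[(sample, chrom)] = start + size + 100_000
        return start, start + size

    def size() -> int:
        return int(rng.integers(*config.cnv_size_range))

    probands = [
        (fam, fam.probands[0].individual_id) for fam in families if fam.probands
    ]
    outlier_idx = 0 if probands else None

    def add(fam, pid, chrom, start, end, log2, cn, p, label, drop) -> CnvSegment:
        seg = CnvSegment(pid, chrom, start, end, log2, cn, p)
        segments.append(seg)
        truth.append(
            TruthRecord("cnv", label, fam.family_id, pid, (chrom, start, end), None, drop)
        )
        return seg

    n_non_outlier = len(probands) - (1 if outlier_idx is not None else 0)
    # the duplicate decoy needs a partner: with an odd count the last
    # non-outlier proband simply skips it
    n_dup_planted = n_non_outlier - (n_non_outlier % 2)
    dup_seen = 0
    dup_pair_interval: Optional[tuple[str, int, int]] = None
    for i, (fam, pid) in enumerate(probands):
        if i == outlier_idx:
            # the outlier sample: an unusually high raw segment count, all of
            # which leave the analysis when the sample is excluded
            for j in range(config.n_outlier_segments):
                chrom = f"chr{(j % 22) + 1}"
                s, e = alloc(pid, chrom, size())
                seg = CnvSegment(pid, chrom, s, e, float(np.round(rng.uniform(-1.5, 1.5), 3)), int(rng.integers(0, 5)), float(np.round(rng.uniform(0, 1), 4)), )
                segments.append(seg)
            truth.append(
                TruthRecord("cnv", "outlier-sample", fam.family_id, pid, (pid,), None, "outlier-sample")
            )
            continue

        # survivors
        s, e = alloc(pid, "chr3", size())
        add(fam, pid, "chr3", s, e, -1.0, 1, 0.01, "deletion-survivor", None)
        asd_loci.append({"chrom": "chr3", "start": s + (e - s) // 2, "end": e + 200_000, "locus_id": f"ASD-{i}"})
        s, e = alloc(pid, "chr7", size())
        add(fam, pid, "chr7", s, e, 0.8, 3, 0.01, "duplication-survivor", None)
        syndromic_loci.append({"chrom": "chr7", "start": max(0, s - 50_000), "end": s + 10_000, "locus_id": f"SYN-{i}"})
        # a deletion fully inside a *duplication* SV of high frequency: the
        # type mismatch means it must be kept
        s, e = alloc(pid, "chr11", size())
        add(fam, pid, "chr11", s, e, -0.9, 1, 0.01, "deletion-in-common-dup-sv", None)
        sv_table.append({"chrom": "chr11", "start": s - 10_000, "end": e + 10_000, "svtype": "DUP", "frequency": 0.02})
        # a deletion inside a low-frequency DEL SV: kept (frequency <= 1%)
        s, e = alloc(pid, "chr12", size())
        add(fam, pid, "chr12", s, e, -0.8, 1, 0.02, "deletion-in-rare-del-sv", None)
        sv_table.append({"chrom": "chr12", "start": s - 5_000, "end": e + 5_000, "svtype": "DEL", "frequency": 0.005})

        # decoys
        s, e = alloc(pid, "chr4", size())
        add(fam, pid, "chr4", s, e, -1.0, 1, 0.2, "low-significance", "low-significance")
        s, e = alloc(pid, "chr5", size())
        add(fam, pid, "chr5", s, e, -0.6, 2, 0.01, "neutral-copy", "neutral-copy")
        s, e = alloc(pid, "chr6", size())
        add(fam, pid, "chr6", s, e, -0.3, 1, 0.01, "sub-threshold-log2", "sub-threshold-log2")
        s, e = alloc(pid, "chr8", size())
        add(fam, pid, "chr8", s, e, 0.9, 1, 0.01, "copy-direction-contradiction", "sub-threshold-log2")
        s, e = alloc(pid, "chr10", size())
        add(fam, pid, "chr10", s, e, -0.9, 0, 0.01, "common-sv-contained", "common-sv")
        sv_table.append({"chrom": "chr10", "start": s - 20_000, "end": e + 20_000, "svtype": "DEL", "frequency": 0.03})
        # exact duplicate interval across unrelated probands
        if dup_seen < n_dup_planted:
            dup_seen += 1
            if dup_pair_interval is None:
                s, e = alloc(pid, "chr9", size())
                dup_pair_interval = ("chr9", s, e)
                add(fam, pid, "chr9", s, e, -1.1, 1, 0.01, "duplicate-cross-family", "duplicate-cross-family")
            else:
                chrom, s, e = dup_pair_interval
                dup_pair_interval = None
                add(fam, pid, chrom, s, e, -1.1, 1, 0.01, "duplicate-cross-family", "duplicate-cross-family")

    # overlap sanity: planted segments within one sample must be disjoint
    by_sample: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for seg in segments:
        by_sample.setdefault((seg.sample_id, seg.chrom), []).append((seg.start, seg.end))
    for ivs in by_sample.values():
        ivs.sort()
        for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("overlapping planted CNV segments within one sample")

    return SimulatedCnv(
        segments=segments,
        asd_loci=asd_loci,
        syndromic_loci=syndromic_loci,
        sv_table=sv_table,
        truth=truth,
    )
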