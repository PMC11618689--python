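"""Shared data model for the familial exome rare-variant pipeline.

The objects here mirror the columns of the standard input formats (multi-sample
VCF, 6-column PED, annotation/gene-metadata TSVs, CNVkit-style segment tables)
after parsing; every downstream stage operates on these containers, never on
raw files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Canonical functional-effect vocabulary (ANNOVAR-style categories).
EFFECT_NONSYN = "nonsynonymous-SNV"
EFFECT_SYN = "synonymous-SNV"
EFFECT_STOPGAIN = "stopgain"
EFFECT_STOPLOSS = "stoploss"
EFFECT_FS_INS = "frameshift-insertion"
EFFECT_FS_DEL = "frameshift-deletion"
EFFECT_NFS_INS = "nonframeshift-insertion"
EFFECT_NFS_DEL = "nonframeshift-deletion"
EFFECT_SPLICE = "splice-site"
EFFECT_UNKNOWN = "unknown"
EFFECT_OTHER = "other"

EFFECTS = frozenset(
    {
        EFFECT_NONSYN,
        EFFECT_SYN,
        EFFECT_STOPGAIN,
        EFFECT_STOPLOSS,
        EFFECT_FS_INS,
        EFFECT_FS_DEL,
        EFFECT_NFS_INS,
        EFFECT_NFS_DEL,
        EFFECT_SPLICE,
        EFFECT_UNKNOWN,
        EFFECT_OTHER,
    }
)

#: Protein-truncating / loss-of-function effect classes.
LOF_EFFECTS = frozenset(
    {EFFECT_STOPGAIN, EFFECT_STOPLOSS, EFFECT_FS_INS, EFFECT_FS_DEL, EFFECT_SPLICE}
)

#: Effect classes counted as coding (exonic or splice-site).
CODING_EFFECTS = frozenset(EFFECTS - {EFFECT_OTHER})

#: GRCh38 X-chromosome pseudoautosomal regions, 0-based half-open.
PAR_REGIONS = ((10000, 2781479), (155701382, 156030895))

VariantKey = tuple[str, int, str, str]


def normalize_chrom(chrom: str, use_prefix: bool = True) -> str:
    """Normalize contig names to a single dialect ('chr1' style by default)."""
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if use_prefix else bare


def in_par(chrom: str, pos: int) -> bool:
    """True if a 1-based X-chromosome position falls in PAR1/PAR2."""
    if normalize_chrom(chrom) != "chrX":
        return False
    return any(start < pos <= end for start, end in PAR_REGIONS)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``allele_count_alt`` is the number of alternate alleles carried (0/1/2 for
    diploid, 0/1 for haploid) or None when the genotype is missing.  Missing
    FORMAT fields stay None — the reader never fabricates values.
    """

    allele_count_alt: Optional[int] = None
    dp: Optional[int] = None
    gq: Optional[int] = None
    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError("dp must be >= 0")
        if self.gq is not None and self.gq < 0:
            raise ValueError("gq must be >= 0")
        if (
            self.dp is not None
            and self.ad_ref is not None
            and self.ad_alt is not None
            and self.ad_ref + self.ad_alt > self.dp
        ):
            raise ValueError("ad_ref + ad_alt must be <= dp")

    @property
    def is_missing(self) -> bool:
        return self.allele_count_alt is None

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and self.allele_count_alt == 1

    @property
    def is_hom_alt(self) -> bool:
        return self.allele_count_alt == self.ploidy and self.ploidy >= 1

    @property
    def is_hom_ref(self) -> bool:
        return self.allele_count_alt == 0

    @property
    def carries_alt(self) -> bool:
        return self.allele_count_alt is not None and self.allele_count_alt > 0

    @property
    def allele_balance(self) -> Optional[float]:
        """AD-Alt / DP, or None when either is unavailable or DP == 0."""
        if self.ad_alt is None or self.dp is None or self.dp == 0:
            return None
        return self.ad_alt / self.dp


MISSING_GENOTYPE = GenotypeCall()


@dataclass
class VariantAnnotation:
    """Per-variant functional annotation (ANNOVAR-style table row)."""

    gene: Optional[str] = None
    effect: str = EFFECT_UNKNOWN
    maf: dict[str, float] = field(default_factory=dict)
    sift_damaging: Optional[bool] = None
    polyphen_humvar_damaging: Optional[bool] = None
    vest: Optional[float] = None
    cadd: Optional[float] = None
    phylop: Optional[float] = None
    alphamissense: Optional[float] = None
    clinvar_significance: Optional[str] = None
    gnomad_hom_carriers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect category: {self.effect!r}")
        for db, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"allele frequency out of [0,1] for {db}: {f}")

    @property
    def is_coding(self) -> bool:
        return self.effect in CODING_EFFECTS

    @property
    def is_lof(self) -> bool:
        return self.effect in LOF_EFFECTS


@dataclass
class CohortVariant:
    """One biallelic site (multiallelic records are split upstream)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    site_qual: Optional[float]
    genotypes: dict[str, GenotypeCall]
    annotation: Optional[VariantAnnotation] = None

    def __post_init__(self) -> None:
        if len(self.ref) < 1 or len(self.alt) < 1:
            raise ValueError("ref and alt must be non-empty")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def genotype(self, sample_id: str) -> GenotypeCall:
        return self.genotypes.get(sample_id, MISSING_GENOTYPE)


@dataclass
class GeneMetadata:
    """Gene-level annotation: autism-gene curation and constraint metrics."""

    symbol: str
    sfari_score: Optional[str] = None  # "1", "2", "3" or "S"
    omim_neuro: bool = False
    pli: Optional[float] = None
    loeuf: Optional[float] = None
    z_score: Optional[float] = None
    coding_length_bp: Optional[int] = None
    gnomad_missense_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sfari_score is not None and self.sfari_score not in {"1", "2", "3", "S"}:
            raise ValueError(f"invalid SFARI score: {self.sfari_score!r}")
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError("pLI must lie in [0,1]")
        if self.coding_length_bp is not None and self.coding_length_bp <= 0:
            raise ValueError("coding_length_bp must be > 0")


ROLE_PROBAND = "proband"
ROLE_FATHER = "father"
ROLE_MOTHER = "mother"
ROLE_SIBLING = "sibling"
ROLE_GRANDMOTHER = "grandmother"


@dataclass
class PedigreeMember:
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female"
    affected: bool
    role: str

    def __post_init__(self) -> None:
        if self.sex not in {"male", "female"}:
            raise ValueError(f"sex must be male/female, got {self.sex!r}")


@dataclass
class PedigreeFamily:
    family_id: str
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        if not any(m.affected for m in self.members):
            raise ValueError(f"family {self.family_id} has no affected member")

    def member(self, individual_id: str) -> Optional[PedigreeMember]:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        return None

    @property
    def probands(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.role == ROLE_PROBAND]

    @property
    def siblings(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.role == ROLE_SIBLING]

    def parents_of(self, individual_id: str) -> tuple[Optional[str], Optional[str]]:
        m = self.member(individual_id)
        if m is None:
            return (None, None)
        return (m.father_id, m.mother_id)

    def siblings_of(self, individual_id: str) -> list[PedigreeMember]:
        """Children sharing at least one recorded parent with ``individual_id``."""
        m = self.member(individual_id)
        if m is None:
            return []
        out = []
        for other in self.members:
            if other.individual_id == m.individual_id:
                continue
            shared = (
                (m.father_id is not None and other.father_id == m.father_id)
                or (m.mother_id is not None and other.mother_id == m.mother_id)
            )
            if shared:
                out.append(other)
        return out

    @property
    def one_parent_missing(self) -> bool:
        return any(
            (m.father_id is None) != (m.mother_id is None)
            for m in self.members
            if m.role in (ROLE_PROBAND, ROLE_SIBLING)
        )


@dataclass
class CnvSegment:
    """One read-depth segment (CNVkit .cns-style row), 0-based half-open."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    copy_number: int
    p_value: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("negative start coordinate")
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0,1]")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def interval_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


PHENO_PRESENT = "present"
PHENO_ABSENT = "absent"
PHENO_UNKNOWN = "unknown"
PHENO_STATES = (PHENO_PRESENT, PHENO_ABSENT, PHENO_UNKNOWN)


@dataclass
class PhenotypeTable:
    """Per-individual condition states: present / absent / unknown."""

    states: dict[str, dict[str, str]]  # individual -> condition -> state

    def __post_init__(self) -> None:
        for ind, conds in self.states.items():
            for cond, state in conds.items():
                if state not in PHENO_STATES:
                    raise ValueError(f"invalid state {state!r} for {ind}/{cond}")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for conds in self.states.values():
            for c in conds:
                seen.setdefault(c)
        return list(seen)

    def state(self, individual_id: str, condition: str) -> str:
        return self.states.get(individual_id, {}).get(condition, PHENO_UNKNOWN)
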