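import pytest

from exofam.models import (
    CohortVariant,
    GenotypeCall,
    PedigreeFamily,
    PedigreeMember,
    VariantAnnotation,
)
from exofam.simulate import SimulationConfig, simulate_cohort


def het(dp=50, gq=99, ad=(25, 25)):
    return GenotypeCall(1, dp, gq, ad[0], ad[1])


def homref(dp=50, gq=99):
    return GenotypeCall(0, dp, gq, dp, 0)


def homalt(dp=50, gq=99):
    return GenotypeCall(2, dp, gq, 0, dp)


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    qual=1000.0,
    genotypes=None,
    annotation=None,
    **ann_kwargs,
):
    if annotation is None and ann_kwargs:
        annotation = VariantAnnotation(**ann_kwargs)
    return CohortVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        site_qual=qual,
        genotypes=genotypes or {},
        annotation=annotation,
    )


def make_trio(family_id="FAM1", proband_sex="male", with_sib=False, missing_father=False):
    father_id = None if missing_father else f"{family_id}-FA"
    members = []
    if not missing_father:
        members.append(PedigreeMember(f"{family_id}-FA", None, None, "male", False, "father"))
    members.append(PedigreeMember(f"{family_id}-MO", None, None, "female", False, "mother"))
    members.append(
        PedigreeMember(f"{family_id}-P1", father_id, f"{family_id}-MO", proband_sex, True, "proband")
    )
    if with_sib:
        members.append(
            PedigreeMember(f"{family_id}-S1", father_id, f"{family_id}-MO", "female", False, "sibling")
        )
    return PedigreeFamily(family_id=family_id, members=members)


@pytest.fixture(scope="session")
def small_cohort():
    """A 15-family noise-free simulated cohort shared across tests."""
    return simulate_cohort(SimulationConfig(n_families=15, seed=42))
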