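import pytest

from kmt2pop.variant_model import (
    AnnotationBundle,
    ClinVarSignificance,
    Cohort,
    CohortRecord,
    PopulationCounts,
    VariantRecord,
)


def make_record(
    gene="KMT2A",
    chrom="chr11",
    pos=118_436_500,
    ref="A",
    alt="G",
    consequence="missense_variant",
    protein_pos=None,
    ac=1,
    an=148_050,
    per_ancestry=None,
    per_sex=None,
    **ann_kwargs,
) -> CohortRecord:
    """Build one cohort record with sensible defaults for tests."""
    if protein_pos is None and consequence in {
        "missense_variant",
        "frameshift_variant",
        "stop_gained",
        "stop_lost",
        "inframe_deletion",
        "inframe_insertion",
    }:
        protein_pos = 100
    clinvar = ann_kwargs.pop("clinvar", ClinVarSignificance.NONE)
    if isinstance(clinvar, str):
        clinvar = ClinVarSignificance.parse(clinvar)
    variant = VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        transcript=f"{gene}_tx",
        hgvs_c=f"c.{pos}{ref}>{alt}",
        hgvs_p=f"p.Ala{protein_pos}Thr" if protein_pos else "",
        protein_pos=protein_pos,
        consequence=consequence,
        multiallelic=ann_kwargs.pop("multiallelic", False),
    )
    annotations = AnnotationBundle(clinvar=clinvar, **ann_kwargs)
    popcounts = PopulationCounts(
        ac_total=ac,
        an_total=an,
        per_ancestry=per_ancestry or {},
        per_sex=per_sex or {},
    )
    return CohortRecord(variant, annotations, popcounts)


def make_cohort(records, n_individuals=74_025) -> Cohort:
    genes = {rec.variant.gene for rec in records}
    return Cohort(
        records=list(records),
        n_individuals={g: n_individuals for g in genes},
    )


@pytest.fixture
def tiny_cohort():
    """Four variants spanning the main consequence routes."""
    return make_cohort(
        [
            make_record(pos=1000, consequence="frameshift_variant", ref="AT", alt="A"),
            make_record(pos=2000, consequence="missense_variant", cadd_phred=35.0),
            make_record(pos=3000, consequence="synonymous_variant"),
            make_record(pos=4000, consequence="intron_variant"),
        ]
    )
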