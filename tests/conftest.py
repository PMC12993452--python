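import numpy as np
import pytest

from beaconrip import Cohort, Dataset, Variant


def make_variant(vid, start=100, ref="A", alt="G", f=0.01, chrom="1", **kw):
    return Variant(
        variant_id=vid,
        reference_name=chrom,
        start=start,
        end=kw.pop("end", start + 1),
        reference_bases=ref,
        alternate_bases=alt,
        population_frequency=f,
        **kw,
    )


def make_dataset(n_subjects, variant_specs, dataset_id="ds", access_level="registered"):
    """Build a dataset from (Variant, carrier-index-list) pairs."""
    subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    variants = [v for v, _ in variant_specs]
    carriers = {
        v.variant_id: np.asarray(idx, dtype=np.int32) for v, idx in variant_specs
    }
    return Dataset(
        dataset_id=dataset_id,
        access_level=access_level,
        cohort=Cohort(subject_ids=subject_ids, carriers=carriers),
        variants=variants,
    )


@pytest.fixture
def small_dataset():
    """Five annotated variants over a 10-subject cohort."""
    specs = [
        (
            make_variant(
                "v1", start=99, ref="A", alt="G", f=0.25, variant_type="SNP",
                gene_id="BRAF", aminoacid_change="V600E",
                genomic_allele_short_form="NC_000001.11:g.100A>G",
            ),
            [0, 1],
        ),
        (make_variant("v2", start=200, ref="C", alt="T", f=0.5, variant_type="SNP", gene_id="BRAF"), [2]),
        (
            make_variant("v3", start=300, end=301, ref="T", alt="TAG", f=0.01,
                         variant_type="INS", gene_id="TP53"),
            [3, 4, 5],
        ),
        (make_variant("v4", start=400, ref="G", alt="A", f=0.001, variant_type="SNP", gene_id="TP53"), [6]),
        (make_variant("v5", start=500, ref="G", alt="C", f=0.1, variant_type="SNP", gene_id="EGFR"), []),
    ]
    return make_dataset(10, specs)
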