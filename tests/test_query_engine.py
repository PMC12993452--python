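import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beaconrip import (
    Dataset,
    Query,
    QueryValidationError,
    RIPConfig,
    RIPState,
    UserContext,
    canonicalize,
    match_variants,
    resolve_access,
    respond,
    generate_cohort,
)

from conftest import make_dataset, make_variant


def _user(status, authorized=()):
    uid = None if status == "unauthenticated" else "u"
    return UserContext(user_id=uid, status=status, authorized_dataset_ids=frozenset(authorized))


class TestAccessMatrix:
    """The full user-status x dataset-tier access matrix."""

    @pytest.mark.parametrize(
        "status,level,authorized,expected",
        [
            ("unauthenticated", "public", False, "full"),
            ("unauthenticated", "registered", False, "none"),
            ("unauthenticated", "controlled", False, "none"),
            ("authenticated", "public", False, "full"),
            ("authenticated", "registered", False, "rip"),
            ("authenticated", "controlled", False, "rip"),
            ("researcher", "public", False, "full"),
            ("researcher", "registered", False, "full"),
            ("researcher", "controlled", False, "rip"),
            ("researcher", "public", True, "full"),
            ("researcher", "registered", True, "full"),
            ("researcher", "controlled", True, "full"),
        ],
    )
    def test_tier_resolution(self, status, level, authorized, expected):
        ds = make_dataset(3, [(make_variant("v"), [0])], dataset_id="d", access_level=level)
        user = _user(status, ["d"] if authorized else ())
        assert resolve_access(user, ds) == expected

    def test_matrix_is_total(self, small_dataset):
        for status in ("unauthenticated", "authenticated", "researcher"):
            for level in ("public", "registered", "controlled"):
                ds = make_dataset(2, [(make_variant("v"), [0])], access_level=level)
                assert resolve_access(_user(status), ds) in {"full", "rip", "none"}


class TestValidation:
    def test_unknown_subtype(self):
        with pytest.raises(QueryValidationError):
            Query(subtype="phenotype").validate()

    def test_missing_mandatory_parameter(self):
        with pytest.raises(QueryValidationError, match="referenceBases"):
            Query(subtype="sequence", referenceName="1", start=5, alternateBases="G").validate()

    def test_mutually_exclusive_filters(self):
        with pytest.raises(QueryValidationError, match="mutually exclusive"):
            Query(
                subtype="range", referenceName="1", start=0, end=10,
                variantType="SNP", alternateBases="G",
            ).validate()

    def test_bracket_needs_two_coordinates(self):
        with pytest.raises(QueryValidationError):
            Query(subtype="bracket", referenceName="1", start=5, end=[1, 2]).validate()

    def test_disallowed_parameter_for_subtype(self):
        with pytest.raises(QueryValidationError):
            Query(subtype="genomicAllele", genomicAlleleShortForm="x", geneId="BRAF").validate()


class TestMatching:
    def test_sequence_exact_match_singleton(self, small_dataset):
        q = Query(subtype="sequence", referenceName="1", start=99,
                  referenceBases="A", alternateBases="G")
        assert [v.variant_id for v in match_variants(q, small_dataset)] == ["v1"]

    def test_sequence_is_case_insensitive_on_bases(self, small_dataset):
        q = Query(subtype="sequence", referenceName="1", start=99,
                  referenceBases="a", alternateBases="g")
        assert [v.variant_id for v in match_variants(q, small_dataset)] == ["v1"]

    def test_range_empty_region(self, small_dataset):
        q = Query(subtype="range", referenceName="1", start=1000, end=2000)
        assert match_variants(q, small_dataset) == []

    def test_range_half_open_overlap(self, small_dataset):
        # v1 occupies [99, 100); a range ending at 99 must not include it
        q = Query(subtype="range", referenceName="1", start=0, end=99)
        assert match_variants(q, small_dataset) == []
        q = Query(subtype="range", referenceName="1", start=99, end=100)
        assert [v.variant_id for v in match_variants(q, small_dataset)] == ["v1"]

    def test_gene_match_with_min_length_filters_snps(self, small_dataset):
        q = Query(subtype="gene", geneId="TP53", variantMinLength=2)
        assert [v.variant_id for v in match_variants(q, small_dataset)] == ["v3"]
        q = Query(subtype="gene", geneId="BRAF", variantMinLength=2)
        assert match_variants(q, small_dataset) == []

    def test_bracket_inclusive_bounds(self, small_dataset):
        q = Query(subtype="bracket", referenceName="1", start=[99, 200], end=[100, 201])
        assert {v.variant_id for v in match_variants(q, small_dataset)} == {"v1", "v2"}

    def test_genomic_allele_short_form(self, small_dataset):
        q = Query(subtype="genomicAllele", genomicAlleleShortForm="NC_000001.11:g.100A>G")
        assert [v.variant_id for v in match_variants(q, small_dataset)] == ["v1"]

    def test_aminoacid_change_needs_matching_gene(self, small_dataset):
        q = Query(subtype="aminoacidChange", geneId="BRAF", aminoacidChange="V600E")
        assert [v.variant_id for v in match_variants(q, small_dataset)] == ["v1"]
        q = Query(subtype="aminoacidChange", geneId="TP53", aminoacidChange="V600E")
        assert match_variants(q, small_dataset) == []


def _oracle_match(query, dataset):
    """Independent linear-scan matcher used as the reference semantics."""
    out = []
    for v in dataset.variants:
        if query.subtype == "sequence":
            ok = (
                v.reference_name == query.referenceName
                and v.start == query.start
                and v.reference_bases == query.referenceBases.upper()
                and v.alternate_bases == query.alternateBases.upper()
            )
        elif query.subtype == "range":
            ok = (
                v.reference_name == query.referenceName
                and v.start < query.end
                and v.end > query.start
            )
            if ok and query.variantType is not None:
                ok = v.variant_type == query.variantType
        elif query.subtype == "gene":
            ok = v.gene_id == query.geneId
        else:
            ok = False
        if ok:
            out.append(v.variant_id)
    return out


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_match_agrees_with_linear_scan_oracle(data):
    seed = data.draw(st.integers(0, 10_000))
    ds = generate_cohort(5, 30, seed=seed, gene_block=7)
    subtype = data.draw(st.sampled_from(["sequence", "range", "gene"]))
    if subtype == "sequence":
        v = ds.variants[data.draw(st.integers(0, 29))]
        q = Query(subtype="sequence", referenceName="1", start=v.start,
                  referenceBases=v.reference_bases, alternateBases=v.alternate_bases)
    elif subtype == "range":
        lo = data.draw(st.integers(0, 250))
        hi = lo + data.draw(st.integers(1, 120))
        vt = data.draw(st.sampled_from([None, "SNP", "INS"]))
        q = Query(subtype="range", referenceName="1", start=lo, end=hi, variantType=vt)
    else:
        q = Query(subtype="gene", geneId=f"GENE{data.draw(st.integers(0, 5))}")
    assert sorted(v.variant_id for v in match_variants(q, ds)) == sorted(_oracle_match(q, ds))


class TestCanonicalize:
    def test_parameter_order_insensitive(self):
        a = Query.from_json({"subtype": "sequence", "referenceName": "1", "start": 99,
                             "referenceBases": "A", "alternateBases": "G"})
        b = Query.from_json({"alternateBases": "G", "start": 99, "subtype": "sequence",
                             "referenceBases": "A", "referenceName": "1"})
        assert canonicalize(a) == canonicalize(b)

    def test_base_case_folded(self):
        a = Query(subtype="sequence", referenceName="1", start=99,
                  referenceBases="A", alternateBases="g")
        b = Query(subtype="sequence", referenceName="1", start=99,
                  referenceBases="a", alternateBases="G")
        assert canonicalize(a) == canonicalize(b)

    def test_granularity_excluded_from_key(self):
        a = Query(subtype="gene", geneId="BRAF", granularity="boolean")
        b = Query(subtype="gene", geneId="BRAF", granularity="count")
        assert canonicalize(a) == canonicalize(b)

    def test_different_queries_have_different_keys(self):
        a = Query(subtype="gene", geneId="BRAF")
        b = Query(subtype="gene", geneId="TP53")
        assert canonicalize(a) != canonicalize(b)


class TestRespond:
    def test_tier_routing_splits_full_and_rip(self, small_dataset):
        public = make_dataset(4, [(make_variant("pv", start=99, f=0.25), [0])],
                              dataset_id="pub", access_level="public")
        controlled = make_dataset(
            4, [(make_variant("cv", start=99, f=0.25), [0])],
            dataset_id="ctl", access_level="controlled",
        )
        user = UserContext(user_id="u", status="authenticated")
        state = RIPState(RIPConfig(p=0.1))
        q = Query(subtype="sequence", referenceName="1", start=99,
                  referenceBases="A", alternateBases="G", granularity="count")
        responses = {r.dataset_id: r for r in respond(q, user, [public, controlled], state)}
        assert responses["pub"].count == 1 and not responses["pub"].rip_applied
        assert responses["ctl"].rip_applied and responses["ctl"].exists
        assert responses["ctl"].count is None and responses["ctl"].records is None

    def test_inaccessible_datasets_are_omitted(self):
        controlled = make_dataset(2, [(make_variant("v", start=99), [0])],
                                  dataset_id="ctl", access_level="controlled")
        q = Query(subtype="sequence", referenceName="1", start=99,
                  referenceBases="A", alternateBases="G")
        assert respond(q, UserContext(status="unauthenticated"), [controlled]) == []

    def test_record_granularity_served_in_full_access(self, small_dataset):
        ds = make_dataset(2, [(make_variant("v", start=99), [0])],
                          dataset_id="pub", access_level="public")
        q = Query(subtype="sequence", referenceName="1", start=99,
                  referenceBases="A", alternateBases="G", granularity="record")
        (r,) = respond(q, UserContext(status="unauthenticated"), [ds])
        assert r.records and r.records[0]["variantId"] == "v"

    def test_rip_response_never_carries_counts_or_records(self, small_dataset):
        user = UserContext(user_id="u", status="authenticated")
        state = RIPState(RIPConfig(p=0.1))
        for granularity in ("boolean", "count", "record"):
            q = Query(subtype="gene", geneId="BRAF", granularity=granularity)
            (r,) = respond(q, user, [small_dataset], state)
            assert r.rip_applied and r.count is None and r.records is None
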