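"""Variant parsing, catalog classification, and hotspot-input filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhf import (
    AnalysisRegion,
    VariantCatalog,
    VariantClass,
    VariantRecord,
    Severity,
    classify_counts,
    format_variant,
    parse_variant,
    select_mhf_input,
)
from mhf.errors import ParseError, ReferenceMismatchError

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestParseVariant:
    @pytest.mark.parametrize(
        "token,pos,ref,alt,vclass",
        [
            ("L203P", 203, "L", "P", VariantClass.MISSENSE),
            ("p.Leu203Pro", 203, "L", "P", VariantClass.MISSENSE),
            ("p.(Leu203Pro)", 203, "L", "P", VariantClass.MISSENSE),
            ("Leu203Pro", 203, "L", "P", VariantClass.MISSENSE),
            ("p.Leu203Leu", 203, "L", "L", VariantClass.SILENT),
            ("K552del", 552, "K", "del", VariantClass.SINGLE_AA_DELETION),
            ("p.Lys552del", 552, "K", "del", VariantClass.SINGLE_AA_DELETION),
            ("R213*", 213, "R", "*", VariantClass.NONSENSE),
            ("p.Arg213Ter", 213, "R", "*", VariantClass.NONSENSE),
        ],
    )
    def test_grammars_and_inferred_class(self, token, pos, ref, alt, vclass):
        rec = parse_variant(token)
        assert (rec.position, rec.ref_aa, rec.alt_aa) == (pos, ref, alt)
        assert rec.variant_class is vclass

    @pytest.mark.parametrize("token", ["", "foo", "L203", "203P", "p.Xyz203Pro", "L-3P"])
    def test_unrecognized_syntax(self, token):
        with pytest.raises(ParseError):
            parse_variant(token)

    def test_reference_validation(self, demo_sequence):
        rec = parse_variant("L203P", demo_sequence)
        assert rec.ref_aa == "L"
        with pytest.raises(ReferenceMismatchError, match="L"):
            parse_variant("A203P", demo_sequence)

    @settings(derandomize=True, max_examples=60)
    @given(
        pos=st.integers(1, 9999),
        ref=st.sampled_from(AA),
        alt=st.sampled_from(AA + "*") | st.just("del"),
    )
    def test_format_parse_round_trip(self, pos, ref, alt):
        token = f"{ref}{pos}{alt if alt != 'del' else 'del'}"
        rec = parse_variant(token)
        assert format_variant(rec) == token


class TestClassifyCounts:
    def test_demo_catalog_composition(self, demo_catalog):
        summary = classify_counts(demo_catalog)
        assert summary.total == 194
        bc = summary.by_class
        assert bc["missense"] == 126
        assert bc["frameshift"] == 25
        assert bc["splice_site"] == 17
        assert bc["nonsense"] == 10
        assert bc["gene_deletion"] == 10
        assert bc["non_initiation"] == 2
        assert bc["single_aa_deletion"] == 4
        assert bc.sum() == summary.total
        assert summary.by_severity.sum() == summary.total

    def test_empty_catalog_is_all_zero(self):
        summary = classify_counts(VariantCatalog(records=[]))
        assert summary.total == 0
        assert (summary.by_class == 0).all()

    def test_small_synthetic_tally(self):
        recs = [parse_variant(f"A{i}G") for i in range(2, 9)] + [
            parse_variant(f"A{i}*") for i in range(20, 23)
        ]
        recs = [r for r in recs]
        summary = classify_counts(VariantCatalog(records=recs))
        assert summary.by_class["missense"] == 7
        assert summary.by_class["nonsense"] == 3


def _rec(token, severity=Severity.UNCERTAIN):
    import dataclasses

    return dataclasses.replace(parse_variant(token), severity=severity)


class TestSelectMhfInput:
    def test_demo_all_pathogenic_has_130(self, demo_catalog, demo_full_map):
        S = select_mhf_input(demo_catalog, demo_full_map.region)
        assert S.size == 130

    def test_disjoint_severity_filter_empties_the_set(self, demo_catalog, demo_full_map):
        with pytest.warns(UserWarning, match="empty"):
            S = select_mhf_input(
                demo_catalog, demo_full_map.region, {Severity.NONPATHOGENIC}
            )
        assert S.size == 0

    def test_class_filter_and_per_substitution_counting(self):
        catalog = VariantCatalog(
            records=[_rec("A10G"), _rec("A10V"), _rec("K20*")]
        )
        S = select_mhf_input(catalog, AnalysisRegion(1, 100))
        assert S.size == 2
        assert list(S.positions) == [10, 10]

    def test_identical_duplicates_collapse(self):
        catalog = VariantCatalog(records=[_rec("A10G"), _rec("A10G")])
        assert len(catalog) == 1

    def test_primary_start_codon_and_non_initiation_excluded(self):
        noninit = VariantRecord(
            raw_label="M1V",
            variant_class=VariantClass.NON_INITIATION,
            severity=Severity.UNCERTAIN,
        )
        catalog = VariantCatalog(records=[_rec("M1L"), noninit, _rec("A10G")])
        S = select_mhf_input(catalog, AnalysisRegion(1, 100))
        assert list(S.positions) == [10]

    def test_region_restriction(self):
        catalog = VariantCatalog(records=[_rec("A10G"), _rec("C300W")])
        S = select_mhf_input(catalog, AnalysisRegion(200, 400))
        assert list(S.positions) == [300]

    def test_idempotent_and_order_independent(self, demo_catalog, demo_full_map):
        region = demo_full_map.region
        S1 = select_mhf_input(demo_catalog, region)
        shuffled = VariantCatalog(records=list(reversed(demo_catalog.records)))
        S2 = select_mhf_input(shuffled, region)
        assert np.array_equal(S1.positions, S2.positions)

    def test_size_invariant_under_alt_relabeling(self):
        a = VariantCatalog(records=[_rec("A10G"), _rec("A10V")])
        b = VariantCatalog(records=[_rec("A10W"), _rec("A10Y")])
        region = AnalysisRegion(1, 50)
        assert select_mhf_input(a, region).size == select_mhf_input(b, region).size


class TestCatalogIO:
    def test_tsv_round_trip(self, tmp_path, demo_catalog, demo_sequence):
        out = tmp_path / "cat.tsv"
        demo_catalog.to_tsv(out)
        again = VariantCatalog.from_tsv(out, sequence=demo_sequence)
        assert len(again) == len(demo_catalog)
        assert classify_counts(again).by_class.equals(
            classify_counts(demo_catalog).by_class
        )

    def test_class_token_conflict_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "variant\tclass\tseverity\tallele_freq_pct\tsource\n"
            "L203P\tnonsense\tuncertain\t\t\n"
        )
        with pytest.raises(ParseError, match="parses as"):
            VariantCatalog.from_tsv(path)
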