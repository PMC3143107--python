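import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stemsrna.io_formats import AnnotationFeature
from stemsrna.mapping import AlignedRead, AlignmentHit
from stemsrna.mirna_quant import (
    ExpressionFilter,
    abundance,
    count_families,
    expressed_families,
    fold_change_analysis,
    is_expressed,
    star_ratio_analysis,
)


def _read(start, length, lib, rid, strand="+"):
    return AlignedRead(
        rid, lib, "A" * length, length, [AlignmentHit("c", start, start + length, strand)]
    )


@pytest.fixture
def mir_features():
    return [
        AnnotationFeature("c", 100, 120, "+", "MIR_mature", "MIR172-m", "miR172"),
        AnnotationFeature("c", 150, 171, "+", "MIR_star", "MIR172-s", "miR172"),
    ]


class TestCountFamilies:
    def test_longer_read_counts_via_shift_tolerance(self, mir_features):
        # a 22-nt read over a 20-nt annotation, same 5' end
        aligned = {"bc02": [_read(100, 22, "bc02", "r1")]}
        m = count_families(aligned, mir_features)
        assert m.loc[("miR172", "mature"), "bc02"] == 1

    def test_shifted_read_not_counted(self, mir_features):
        aligned = {"bc02": [_read(105, 21, "bc02", "r1")]}
        m = count_families(aligned, mir_features)
        assert m.loc[("miR172", "mature"), "bc02"] == 0

    def test_wrong_strand_not_counted(self, mir_features):
        aligned = {"bc02": [_read(100, 20, "bc02", "r1", strand="-")]}
        m = count_families(aligned, mir_features)
        assert m.loc[("miR172", "mature"), "bc02"] == 0

    def test_multi_hit_read_counts_once_per_family(self):
        feats = [
            AnnotationFeature("c", 100, 121, "+", "MIR_mature", "MIR395a", "miR395"),
            AnnotationFeature("c", 500, 521, "+", "MIR_mature", "MIR395b", "miR395"),
        ]
        read = AlignedRead(
            "r1",
            "bc02",
            "A" * 21,
            21,
            [AlignmentHit("c", 100, 121, "+"), AlignmentHit("c", 500, 521, "+")],
        )
        m = count_families({"bc02": [read]}, feats)
        assert m.loc[("miR395", "mature"), "bc02"] == 1

    def test_missing_family_label_rejected(self):
        feats = [AnnotationFeature("c", 100, 120, "+", "MIR_mature", "m1")]
        with pytest.raises(ValueError, match="family"):
            count_families({"bc02": []}, feats)

    def test_planted_counts_recovered_on_synthetic(self, pipeline_bundle):
        _, bundle, data = pipeline_bundle
        truth = data["truth"]
        m = bundle["family_matrix"]
        # brute-force recount of miR169 mature reads in the BTx library
        locus = truth.mir["miR169"]
        expect = 0
        for a in bundle["aligned"]["bc02"]:
            if a.mapped and any(
                h.strand == "+" and abs(h.start - locus.mature_start) <= 2
                and h.start < locus.mature_end and locus.mature_start < h.end
                for h in a.hits
            ):
                expect += 1
        assert m.loc[("miR169", "mature"), "bc02"] == expect


class TestExpressionFilter:
    @pytest.mark.parametrize(
        "counts,expected",
        [((4, 3, 2, 1, 0), True), ((10, 0, 0, 0, 0), False), ((3, 3, 3, 0, 0), False)],
    )
    def test_boundary_cases(self, counts, expected):
        assert is_expressed(counts, ExpressionFilter()) is expected

    @given(st.lists(st.integers(0, 50), min_size=5, max_size=5), st.integers(0, 4), st.integers(1, 20))
    def test_monotone_under_added_reads(self, counts, idx, extra):
        f = ExpressionFilter()
        if is_expressed(counts, f):
            more = list(counts)
            more[idx] += extra
            assert is_expressed(more, f)

    def test_invalid_filter_rejected(self):
        with pytest.raises(ValueError):
            ExpressionFilter(min_libraries=6, n_libraries=5)

    def test_synthetic_silent_families_not_expressed(self, pipeline_bundle):
        _, bundle, _ = pipeline_bundle
        assert bundle["expressed"] == [
            "miR160", "miR164", "miR169", "miR172", "miR319", "miR395",
        ]


class TestAbundance:
    def test_fraction_of_library_total(self):
        idx = pd.MultiIndex.from_product([["miR1"], ["mature", "star"]], names=["family", "strand"])
        m = pd.DataFrame({"bc02": [600, 0]}, index=idx)
        ab = abundance(m, {"bc02": 10000})
        assert ab.loc[("miR1", "mature"), "bc02"] == 0.06
        assert ab.loc[("miR1", "star"), "bc02"] == 0.0

    def test_dominant_family_share_on_synthetic(self, pipeline_bundle):
        _, bundle, _ = pipeline_bundle
        m = bundle["family_matrix"]
        share = m.loc[("miR172", "mature"), "bc02"] / bundle["library_totals"]["bc02"]
        # planted at 6% of the grain-type library (mature+star+noise); the
        # mature strand alone is ~5% with binomial noise
        assert 0.04 < share < 0.07


def _matrix(rows: dict) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["family", "strand"])
    return pd.DataFrame(list(rows.values()), index=idx, columns=["bc02", "bc03", "bc04", "bc05"])


TOTALS = {"bc02": 10000, "bc03": 10000, "bc04": 10000, "bc05": 10000}


class TestFoldChange:
    def test_inherited_high_p1(self):
        m = _matrix({("miR169", "mature"): [400, 100, 300, 100], ("miR169", "star"): [0, 0, 0, 0]})
        (r,) = fold_change_analysis(m, TOTALS, "bc02", "bc03", "bc04", "bc05")
        assert r.call == "inherited_high_P1" and r.parental_ratio == 4.0

    def test_inherited_high_p2(self):
        m = _matrix({("miR395", "mature"): [30, 100, 40, 100], ("miR395", "star"): [0, 0, 0, 0]})
        (r,) = fold_change_analysis(m, TOTALS, "bc02", "bc03", "bc04", "bc05")
        assert r.call == "inherited_high_P2"

    def test_undetected_in_one_parent(self):
        m = _matrix({("miR5383", "mature"): [50, 0, 40, 10], ("miR5383", "star"): [0, 0, 0, 0]})
        (r,) = fold_change_analysis(m, TOTALS, "bc02", "bc03", "bc04", "bc05")
        assert r.call == "undetected_in_one"
        assert r.parental_ratio is None

    @given(
        st.lists(st.integers(1, 500), min_size=4, max_size=4),
    )
    def test_antisymmetric_under_parent_swap(self, counts):
        m = _matrix({("f", "mature"): counts, ("f", "star"): [0, 0, 0, 0]})
        (fwd,) = fold_change_analysis(m, TOTALS, "bc02", "bc03", "bc04", "bc05")
        (rev,) = fold_change_analysis(m, TOTALS, "bc03", "bc02", "bc05", "bc04")
        swap = {
            "inherited_high_P1": "inherited_high_P2",
            "inherited_high_P2": "inherited_high_P1",
            "not_inherited": "not_inherited",
            "undetected_in_one": "undetected_in_one",
        }
        assert rev.call == swap[fwd.call]


class TestStarRatios:
    def test_six_to_one(self):
        m = _matrix({("miR395", "mature"): [600, 0, 0, 0], ("miR395", "star"): [100, 0, 0, 0]})
        recs = {r.library: r for r in star_ratio_analysis(m)}
        assert recs["bc02"].ratio == 6.0 and not recs["bc02"].arm_switch

    def test_equal_counts_flag_arm_switch(self):
        m = _matrix({("miR395", "mature"): [50, 0, 0, 0], ("miR395", "star"): [50, 0, 0, 0]})
        recs = {r.library: r for r in star_ratio_analysis(m)}
        assert recs["bc02"].ratio == 1.0 and recs["bc02"].arm_switch

    def test_zero_star_undefined_ratio(self):
        m = _matrix({("miR1", "mature"): [10, 0, 0, 0], ("miR1", "star"): [0, 0, 0, 0]})
        recs = {r.library: r for r in star_ratio_analysis(m)}
        assert recs["bc02"].ratio is None
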