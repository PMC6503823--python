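"""Clonality rules, copy-number calls, driver selection and matrix IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmaland.core_data import (
    AlterationMatrix,
    CnSegment,
    DriverCatalog,
    GeneAnnotation,
    MutationRecord,
    build_cohort_matrix,
    call_clonal_by_ccf,
    call_clonal_by_maf,
    call_cna_vs_normal,
    call_cna_vs_ploidy,
    multi_region_clonality,
    select_drivers,
    weighted_ploidy,
)

from conftest import random_binary_matrix


def rec(ccf=None, lo=None, hi=None, maf=None):
    return MutationRecord("s1", "TP53", ccf=ccf, ccf_ci_low=lo, ccf_ci_high=hi, maf=maf)


class TestClonality:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.9, 1.05, True),   # CI includes 1
            (0.7, 0.95, False),  # CI entirely below 1
            (1.0, 1.0, True),    # boundary inclusion
        ],
    )
    def test_ccf_ci_rule(self, lo, hi, expected):
        r = rec(ccf=min(hi, 1.0), lo=lo, hi=hi)
        assert call_clonal_by_ccf([r]) == [expected]

    def test_missing_ci_is_an_error_not_a_silent_false(self):
        with pytest.raises(ValueError, match="confidence interval"):
            call_clonal_by_ccf([rec(maf=0.9)])

    @pytest.mark.parametrize(
        "maf,expected", [(0.85, True), (0.80, False), (0.0, False)]
    )
    def test_maf_rule_is_strict(self, maf, expected):
        assert call_clonal_by_maf([rec(maf=maf)]) == [expected]

    def test_maf_outside_unit_interval_rejected_at_construction(self):
        with pytest.raises(ValueError):
            rec(maf=1.2)

    def test_ccf_outside_its_ci_rejected(self):
        with pytest.raises(ValueError):
            rec(ccf=0.5, lo=0.8, hi=1.0)

    @pytest.mark.parametrize(
        "flags,expected",
        [([True, True, True, False], True), ([True, True, False, False], False),
         ([True, True, True], True)],
    )
    def test_multi_region_three_quarters_rule(self, flags, expected):
        assert multi_region_clonality(flags) is expected

    def test_multi_region_empty_errors(self):
        with pytest.raises(ValueError):
            multi_region_clonality([])


GENE = GeneAnnotation("PTEN", "10", 1000, 2000, length_bp=1001)


class TestCnaCalls:
    def seg(self, cn, n_probes=50, start=500, end=2500, sample="s1", chrom="10"):
        return CnSegment(sample, chrom, start, end, cn, n_probes)

    @pytest.mark.parametrize(
        "cn,expected", [(3.0, "gain"), (2.5, "none"), (1.4, "loss"), (0.9, "loss")]
    )
    def test_deviation_threshold(self, cn, expected):
        calls = call_cna_vs_ploidy([self.seg(cn)], 2.0, [GENE])
        assert calls["PTEN"] == expected

    def test_low_probe_segments_filtered(self):
        calls = call_cna_vs_ploidy([self.seg(0.9, n_probes=9)], 2.0, [GENE])
        assert calls["PTEN"] == "none"

    def test_gene_without_covering_segment_is_none(self):
        far = self.seg(4.0, start=100000, end=200000)
        assert call_cna_vs_ploidy([far], 2.0, [GENE])["PTEN"] == "none"

    def test_midpoint_rule_for_spanning_gene(self):
        # gene midpoint 1500 is inside the second segment -> its call wins
        left = self.seg(4.0, start=500, end=1200)
        right = self.seg(0.5, start=1201, end=2500)
        calls = call_cna_vs_ploidy([left, right], 2.0, [GENE])
        assert calls["PTEN"] == "loss"

    def test_invariant_to_segment_order(self):
        segs = [self.seg(3.5, start=500, end=1200), self.seg(0.5, start=1201, end=2500),
                self.seg(2.0, start=2501, end=9000)]
        forward = call_cna_vs_ploidy(segs, 2.0, [GENE])
        backward = call_cna_vs_ploidy(segs[::-1], 2.0, [GENE])
        assert forward == backward

    def test_normal_reference_one_tailed(self):
        normals = [-0.1, -0.05, 0.0, 0.05, 0.1]  # mean 0, sd 0.079
        assert call_cna_vs_normal(0.5, normals, "gain") is True
        assert call_cna_vs_normal(0.5, normals, "loss") is False
        assert call_cna_vs_normal(0.0, normals, "gain") is False
        assert call_cna_vs_normal(0.0, normals, "loss") is False

    def test_zero_sd_normals_error(self):
        with pytest.raises(ValueError):
            call_cna_vs_normal(0.5, [0.0, 0.0, 0.0], "gain")


class TestWeightedPloidy:
    def test_exon_weighted_mean(self):
        segs = [
            CnSegment("s", "1", 1, 10, 2.0, 10, n_exons=100),
            CnSegment("s", "1", 11, 20, 4.0, 10, n_exons=50),
        ]
        assert weighted_ploidy(segs) == pytest.approx(8 / 3)

    def test_single_and_uniform(self):
        one = [CnSegment("s", "1", 1, 10, 3.0, 10, n_exons=5)]
        assert weighted_ploidy(one) == 3.0
        flat = [CnSegment("s", "1", i, i + 1, 2.0, 10, n_exons=7) for i in range(1, 9, 2)]
        assert weighted_ploidy(flat) == 2.0

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_ploidy([])
        with pytest.raises(ValueError):
            weighted_ploidy([CnSegment("s", "1", 1, 2, 2.0, 10, n_exons=0)])


class TestMatrix:
    def test_derived_counts_are_consistent(self):
        mat = random_binary_matrix(12, 7, seed=1)
        assert mat.sample_loads.sum() == mat.total_events
        assert mat.alteration_counts.sum() == mat.total_events

    def test_non_binary_rejected(self):
        df = pd.DataFrame([[0, 2]], index=["s"], columns=["a_mut", "b_mut"])
        with pytest.raises(ValueError):
            AlterationMatrix(df)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12), d=st.integers(2, 10))
    def test_tsv_round_trip_exact(self, tmp_path_factory, seed, n, d):
        mat = random_binary_matrix(n, d, seed=seed)
        path = tmp_path_factory.mktemp("mat") / "m.tsv"
        mat.to_tsv(path)
        back = AlterationMatrix.from_tsv(path)
        assert back == mat
        assert list(back.sample_loads) == list(mat.sample_loads)
        assert list(back.alteration_counts) == list(mat.alteration_counts)


class TestSelectDrivers:
    def build(self, freqs: dict[str, float], n=1000):
        # one column per candidate with the requested exact frequency
        sets = {f"S{i:04d}": set() for i in range(n)}
        for aid, f in freqs.items():
            for i in range(int(round(f * n))):
                sets[f"S{i:04d}"].add(aid)
        return AlterationMatrix.from_sets(sets, alteration_ids=sorted(freqs))

    def test_top_50_of_60_candidates(self):
        freqs = {f"G{i:02d}_mut": 0.01 + 0.001 * i for i in range(60)}
        mat = self.build(freqs)
        catalog = DriverCatalog([(f"G{i:02d}", "mut") for i in range(60)])
        retained, _ = select_drivers(mat, catalog)
        assert len(retained) == 50
        # the 10 least frequent candidates were dropped
        assert "G00_mut" not in retained.alteration_ids
        assert "G59_mut" in retained.alteration_ids

    def test_min_frequency_is_strict(self):
        mat = self.build({"A_mut": 0.004, "B_mut": 0.005, "C_mut": 0.006})
        catalog = DriverCatalog([("A", "mut"), ("B", "mut"), ("C", "mut")])
        retained, _ = select_drivers(mat, catalog)
        assert retained.alteration_ids == ["C_mut"]  # 0.5% itself is excluded

    def test_cdkn2a_b_losses_merged_before_ranking(self):
        sets = {
            "s1": {"CDKN2A_loss"},
            "s2": {"CDKN2B_loss"},
            "s3": {"CDKN2A_loss", "CDKN2B_loss"},
            "s4": {"TP53_mut"},
        }
        mat = AlterationMatrix.from_sets(sets)
        catalog = DriverCatalog([("CDKN2A", "loss"), ("CDKN2B", "loss"), ("TP53", "mut")])
        retained, merged = select_drivers(mat, catalog, min_freq=0.0)
        assert "CDKN2A/B_loss" in retained.alteration_ids
        assert "CDKN2A_loss" not in merged.alteration_ids
        # union of the two original columns: present in s1, s2, s3
        assert merged.alteration_counts["CDKN2A/B_loss"] == 3

    def test_output_frequencies_non_increasing_and_above_floor(self):
        rng = np.random.default_rng(7)
        freqs = {f"G{i:02d}_mut": float(rng.uniform(0.001, 0.4)) for i in range(30)}
        mat = self.build(freqs)
        catalog = DriverCatalog([(f"G{i:02d}", "mut") for i in range(30)])
        retained, merged = select_drivers(mat, catalog, max_n=10)
        got = [merged.frequencies[a] for a in retained.alteration_ids]
        assert all(a >= b for a, b in zip(got, got[1:]))
        assert len(retained) <= 10
        assert all(f > 0.005 for f in got)

    def test_empty_catalog_errors(self):
        mat = self.build({"A_mut": 0.1})
        with pytest.raises(ValueError):
            select_drivers(mat, DriverCatalog([]))


def test_build_cohort_matrix_pipeline():
    genes = [GeneAnnotation("MYC", "8", 1000, 2000, 1001)]
    muts = [
        MutationRecord("s1", "TP53", ccf=1.0, ccf_ci_low=0.9, ccf_ci_high=1.0),
        MutationRecord("s1", "KRAS", ccf=0.4, ccf_ci_low=0.3, ccf_ci_high=0.5),
        MutationRecord("s2", "TP53", ccf=0.95, ccf_ci_low=0.85, ccf_ci_high=1.0),
        MutationRecord("s2", "TP53", ccf=1.0, ccf_ci_low=0.95, ccf_ci_high=1.0),
    ]
    segs = [
        CnSegment("s1", "8", 500, 2500, 3.4, 50, n_exons=10),
        CnSegment("s1", "8", 2501, 99999, 2.0, 500, n_exons=500),
        CnSegment("s2", "8", 500, 99999, 2.0, 500, n_exons=510),
    ]
    mat = build_cohort_matrix(muts, segs, genes)
    assert mat.sample_set("s1") == {"TP53_mut", "MYC_gain"}
    # multiple clonal TP53 mutations in s2 collapse to a single 1
    assert mat.sample_set("s2") == {"TP53_mut"}
    assert mat.values.loc["s2", "TP53_mut"] == 1
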