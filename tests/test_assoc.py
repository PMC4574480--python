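"""Allelic association statistics, QC filters, and the printed-table rebuild."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bagwas.assoc import (
    AlleleTable2x2,
    QcParams,
    allelic_test,
    association_scan,
    genomic_inflation,
    qc_filter,
    reconstruct_counts,
    reproduce_table1,
)
from bagwas.core import GenotypeMatrix, SampleRecord, SnpRecord

cells = st.integers(min_value=1, max_value=1000)


def _matrix(dosage, statuses):
    n_snps = dosage.shape[1]
    snps = [SnpRecord(f"s{j}", "1", j + 1, "A", "G") for j in range(n_snps)]
    samples = [SampleRecord(f"i{i}", status) for i, status in enumerate(statuses)]
    return GenotypeMatrix(samples, snps, dosage)


class TestQcFilter:
    def test_low_call_rate_snp_excluded(self):
        dos = np.ones((10, 2))
        dos[:2, 0] = np.nan  # call rate 0.8 < 0.9
        dos[:, 1] = [0, 0, 0, 1, 1, 0, 0, 1, 0, 1]
        m = _matrix(dos, ["case"] * 5 + ["control"] * 5)
        filtered, report = qc_filter(m, QcParams())
        assert [s.snp_id for s in filtered.snps] == ["s1"]
        assert report.iloc[0]["reason"] == "low_call_rate"

    def test_boundary_maf_retained(self):
        # 50 individuals, one minor allele in 100: MAF exactly 0.01
        dos = np.zeros((50, 1))
        dos[0, 0] = 1
        m = _matrix(dos, ["case"] * 25 + ["control"] * 25)
        filtered, report = qc_filter(m, QcParams())
        assert filtered.n_snps == 1 and report.empty

    def test_clean_panel_untouched(self, small_panel):
        filtered, _ = qc_filter(small_panel.matrix, QcParams(min_call_rate=0.5, min_maf=0.0))
        assert filtered.n_snps == small_panel.matrix.n_snps

    def test_empty_matrix_rejected(self):
        m = _matrix(np.zeros((2, 1)), ["case", "control"])
        with pytest.raises(ValueError):
            qc_filter(m.subset_snps(np.array([], dtype=int)), QcParams())


class TestAllelicTest:
    def test_combined_cohort_statistics(self):
        chi2, p, odds = allelic_test(AlleleTable2x2(36, 90, 499, 3315))
        assert round(odds, 2) == 2.66
        assert f"{p:.2e}" == "5.94e-07"

    def test_identical_rows_null(self):
        chi2, p, odds = allelic_test(AlleleTable2x2(10, 90, 10, 90))
        assert chi2 == 0 and p == 1 and odds == 1

    def test_hand_worked_table(self):
        chi2, p, odds = allelic_test(AlleleTable2x2(10, 10, 5, 15))
        assert odds == pytest.approx(3.0)
        assert chi2 == pytest.approx(8 / 3, abs=1e-12)
        assert p == pytest.approx(0.1025, abs=5e-5)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            allelic_test(AlleleTable2x2(0, 0, 5, 15))
        with pytest.raises(ValueError):
            allelic_test(AlleleTable2x2(0, 10, 0, 15))

    def test_zero_cell_or_extremes(self):
        chi2, _, odds = allelic_test(AlleleTable2x2(0, 10, 5, 15))
        assert odds == 0.0 and np.isfinite(chi2)
        chi2, _, odds = allelic_test(AlleleTable2x2(5, 0, 5, 15))
        assert odds == np.inf and np.isfinite(chi2)

    @settings(deadline=None, max_examples=100)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_matches_expected_count_oracle(self, a, b, c, d):
        """Pearson chi-square from the expected-count formulation is identical."""
        chi2, p, _ = allelic_test(AlleleTable2x2(a, b, c, d))
        oracle = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        assert chi2 == pytest.approx(oracle.statistic, abs=1e-10)
        assert p == pytest.approx(oracle.pvalue, abs=1e-10)

    @settings(deadline=None, max_examples=60)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_or_inversion_and_chi2_symmetry(self, a, b, c, d):
        chi2, _, odds = allelic_test(AlleleTable2x2(a, b, c, d))
        chi2_sw, _, odds_sw = allelic_test(AlleleTable2x2(c, d, a, b))
        assert odds_sw == pytest.approx(1.0 / odds)
        assert chi2_sw == pytest.approx(chi2, rel=1e-12)
        chi2_col, _, _ = allelic_test(AlleleTable2x2(b, a, d, c))
        assert chi2_col == pytest.approx(chi2, rel=1e-12)


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "maf, n, expected",
        [
            (0.2857, 63, (36, 90)),
            (0.1308, 1907, (499, 3315)),
            (0.0, 10, (0, 20)),
            (0.2821, 39, (22, 56)),
        ],
    )
    def test_examples(self, maf, n, expected):
        assert reconstruct_counts(maf, n) == expected

    def test_half_rounds_away_from_zero(self):
        assert reconstruct_counts(0.25, 2) == (1, 3)  # 2*2*0.25 = 1 exactly
        assert reconstruct_counts(0.125, 2) == (1, 3)  # 0.5 -> 1


class TestGenomicInflation:
    def test_at_null_median(self):
        assert genomic_inflation([0.4549364231195724] * 5) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert genomic_inflation([1, 2, 3]) == pytest.approx(2 / 0.4549364, rel=1e-6)

    def test_null_chi_squares_calibrated(self, rng):
        values = rng.chisquare(1, size=50_000)
        assert 0.95 <= genomic_inflation(values) <= 1.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


class TestAssociationScan:
    def test_agrees_with_single_snp_test(self, small_panel):
        m = small_panel.matrix
        df = association_scan(m)
        j = m.snp_index("risk_a")
        row = df.iloc[j]
        table = AlleleTable2x2(
            int(row.case_minor), int(row.case_major),
            int(row.control_minor), int(row.control_major),
        )
        chi2, p, odds = allelic_test(table)
        assert row.chi2 == pytest.approx(chi2, rel=1e-12)
        assert row.p == pytest.approx(p, rel=1e-12)
        assert row.odds_ratio == pytest.approx(odds, rel=1e-12)

    def test_planted_pair_among_top_associations(self, small_panel):
        df = association_scan(small_panel.matrix).set_index("snp_id")
        assert df.loc["risk_a", "p_rank"] <= 10
        assert df.loc["risk_b", "p_rank"] <= 10

    def test_requires_both_phenotypes(self, small_panel):
        m = small_panel.matrix
        cases = m.subset_samples(np.flatnonzero(m.case_mask))
        with pytest.raises(ValueError):
            association_scan(cases)


class TestReproduceTable1:
    def test_all_odds_ratios_match_printed(self):
        df = reproduce_table1()
        assert df["or_pass"].all()

    def test_pvalues_match_printed_except_inconsistent_cell(self):
        df = reproduce_table1()
        failed = df[~df["p_pass"]]
        # the one cell whose printed p does not follow from its own MAFs
        assert list(zip(failed["cohort"], failed["snp_id"])) == [
            ("CAG BA (n=24)", "rs10140366")
        ]
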