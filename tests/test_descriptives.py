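import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency, kruskal

import underdx as u
from underdx.descriptives import kruskal_wallis, pearson_chi_square, summarize_table1

# Admission and demographic counts by SMI group (schizophrenia, bipolar,
# PTSD, MDD, non-SMI) in the reference cohort of 87,806 patients.
ADMISSION = np.array([[16, 98], [53, 359], [10, 72], [668, 5125], [6522, 74883]])
FEMALE = np.array([[63, 51], [256, 156], [47, 35], [4300, 1493], [45693, 35712]])


class TestPearsonChiSquare:
    def test_reference_admission_table(self):
        stat, df, p = pearson_chi_square(ADMISSION)
        assert stat == pytest.approx(106.4, abs=0.05)
        assert df == 4
        assert p < 0.01

    def test_reference_female_table(self):
        stat, df, _ = pearson_chi_square(FEMALE)
        assert stat == pytest.approx(728.2, abs=0.05)
        assert df == 4

    def test_homogeneous_proportions_give_zero(self):
        stat, df, p = pearson_chi_square([[10, 10], [20, 20]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    def test_2x2_closed_form(self, cells):
        """For 2x2 tables the statistic equals N(ad-bc)^2 / product of margins."""
        a, b, c, d = cells
        stat, df, _ = pearson_chi_square([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed, rel=1e-12)
        assert df == 1

    @settings(max_examples=100)
    @given(st.lists(st.lists(st.integers(1, 50), min_size=3, max_size=3),
                    min_size=2, max_size=5), st.randoms(use_true_random=False))
    def test_scipy_oracle_and_permutation_invariance(self, rows, rnd):
        table = np.array(rows)
        stat, df, p = pearson_chi_square(table)
        ref_stat, ref_p, ref_df, _ = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref_stat, rel=1e-10)
        assert df == ref_df and p == pytest.approx(ref_p, rel=1e-8)
        rp = rnd.sample(range(table.shape[0]), table.shape[0])
        cp = rnd.sample(range(table.shape[1]), table.shape[1])
        stat_perm, _, _ = pearson_chi_square(table[np.ix_(rp, cp)])
        assert stat_perm == pytest.approx(stat, rel=1e-12)

    def test_squared_pearson_residuals_identity(self):
        table = np.array([[5, 9, 2], [11, 3, 8]])
        stat, _, _ = pearson_chi_square(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        resid = (table - expected) / np.sqrt(expected)
        assert stat == pytest.approx((resid ** 2).sum())

    @pytest.mark.parametrize("bad", [
        [[1, 2]],                       # one row
        [[0, 0], [1, 2]],               # zero row margin
        [[1, 0], [2, 0]],               # zero column margin
        [[-1, 2], [3, 4]],              # negative count
    ])
    def test_degenerate_tables_rejected(self, bad):
        with pytest.raises(ValueError):
            pearson_chi_square(bad)


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        """Groups {1,2,3} vs {4,5,6}: rank sums 6 and 15, H = 27/7."""
        h, df, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7)
        assert df == 1

    def test_label_symmetry(self):
        a, b = [1.0, 3.0, 5.0, 5.0], [2.0, 2.0, 4.0]
        assert kruskal_wallis([a, b])[0] == pytest.approx(kruskal_wallis([b, a])[0])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_scipy_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 6, size=rng.integers(2, 12)).astype(float)
                  for _ in range(rng.integers(2, 5))]
        if min(np.concatenate(groups)) == max(np.concatenate(groups)):
            return
        h, df, p = kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert h == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_all_identical_observations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])

    def test_too_few_groups_or_observations(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestTable1Summary:
    def test_structure_and_group_order(self, default_cohort):
        s = summarize_table1(default_cohort)
        assert [c.split(" (")[0] for c in s.table.columns[1:]] == [
            "Schizophrenia", "Bipolar", "PTSD", "MDD", "Non-SMI"]
        assert not s.tests.skipped.any()
        assert set(s.tests.test) == {"chi-square", "kruskal-wallis"}
        # generated at beta0 = -3 with the reference odds ratios: admission
        # in the realistic single-digit range
        overall = default_cohort.admission.mean() * 100
        assert 5.0 < overall < 13.0

    def test_admission_percent_formatting(self):
        """16 admissions of 114 schizophrenia patients print as '16 (14.0)'."""
        n = 114
        coh = pd.DataFrame({
            "admission": [1] * 16 + [0] * (n - 16),
            "reported_smi": ["schizophrenia"] * n,
            "age_years": np.linspace(20, 80, n),
            "female": [0, 1] * 57,
            "race": ["white"] * n,
            "hispanic": [0] * n,
            "selim": [1] * n,
        })
        s = summarize_table1(coh)
        cell = s.table.loc["Admission (%)", s.table.columns[1]]
        assert cell == "16 (14.0)"

    def test_single_group_flags_tests_not_applicable(self):
        coh = pd.DataFrame({
            "admission": [0, 1, 0, 1], "reported_smi": ["mdd"] * 4,
            "age_years": [30.0, 40, 50, 60], "female": [0, 1, 0, 1],
            "race": ["white", "black", "other", "white"],
            "hispanic": [0, 0, 1, 0], "selim": [0, 1, 2, 3]})
        s = summarize_table1(coh)
        assert s.tests.skipped.all()
        assert s.group_sizes["schizophrenia"] == 0
        assert "-" in s.table.iloc[0].values  # empty group columns flagged

    def test_csv_and_text_outputs(self, tmp_path, default_cohort):
        s = summarize_table1(default_cohort)
        s.to_csv(tmp_path / "t1.csv")
        assert (tmp_path / "t1.csv").exists()
        assert (tmp_path / "t1.tests.csv").exists()
        text = s.to_text()
        assert "Admission (%)" in text and "Test statistic" in text
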