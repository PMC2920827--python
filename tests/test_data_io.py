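"""Harvest-table I/O and the pre-model data corrections."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import harvestipm as hi
from harvestipm.data_io import SEXES, misclassification_matrix

MIS = hi.MisclassificationSample(
    n_true_female=159, n_female_recorded_male=17,
    n_true_male=183, n_male_recorded_female=1,
)


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text)


class TestReadWrite:
    def test_toy_file_parses_to_dense_array(self):
        # one year of a file cannot satisfy T >= 2, so give two years
        arr = hi.read_harvest_table(_csv(
            "year,age,sex,count\n2000,1,M,5\n2000,2,M,7\n2000,3,M,1\n2001,1,M,2\n"))
        assert arr.counts.shape == (2, 3, 2)
        assert arr.counts[0, 0, SEXES.index("M")] == 5
        assert arr.counts[0, 1, SEXES.index("M")] == 7
        assert arr.counts[:, :, SEXES.index("F")].sum() == 0
        assert not arr.plus_group

    def test_plus_group_label_sets_flag_and_age_count(self):
        arr = hi.read_harvest_table(_csv(
            "year,age,sex,count\n2000,1,F,3\n2000,10+,F,4\n2001,2,M,1\n"))
        assert arr.plus_group
        assert arr.n_ages == 10
        assert arr.counts[0, 9, SEXES.index("F")] == 4

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            hi.read_harvest_table(_csv("year,age,sex,count\n2000,1,M,-1\n2001,1,M,2\n"))

    def test_duplicate_key_rejected_with_key_named(self):
        with pytest.raises(ValueError, match="2000"):
            hi.read_harvest_table(_csv(
                "year,age,sex,count\n2000,1,M,1\n2000,1,M,2\n2001,1,M,2\n"))

    def test_round_trip_is_exact(self, toy_harvest, tmp_path):
        path = tmp_path / "h.csv"
        hi.write_harvest_table(toy_harvest, path)
        back = hi.read_harvest_table(path)
        np.testing.assert_array_equal(back.counts, toy_harvest.counts)
        np.testing.assert_array_equal(back.year_labels, toy_harvest.year_labels)
        assert back.plus_group == toy_harvest.plus_group


class TestSexMisclassification:
    def test_telemetry_rates_match_linear_solve_oracle(self):
        counts = np.zeros((2, 3, 2))
        counts[0, 0] = (100.0, 100.0)  # (F, M) observed
        arr = hi.HarvestArray(counts, [2000, 2001])
        out = hi.correct_sex_misclassification(arr, MIS)
        # independent oracle: solve the 2x2 forward system directly
        p_fm, p_mf = 17 / 159, 1 / 183
        M = np.array([[1 - p_fm, p_mf], [p_fm, 1 - p_mf]])
        expected = np.linalg.solve(M, np.array([100.0, 100.0]))
        np.testing.assert_allclose(out.counts[0, 0], expected, rtol=1e-12)

    def test_zero_rates_are_identity(self, toy_harvest):
        mis = hi.MisclassificationSample(100, 0, 100, 0)
        out = hi.correct_sex_misclassification(toy_harvest, mis)
        np.testing.assert_array_equal(out.counts, toy_harvest.counts)

    def test_cell_totals_conserved(self, toy_harvest):
        out = hi.correct_sex_misclassification(toy_harvest, MIS)
        np.testing.assert_allclose(out.counts.sum(axis=2),
                                   toy_harvest.counts.sum(axis=2), rtol=1e-12)

    def test_singular_rates_rejected(self):
        mis = hi.MisclassificationSample(10, 4, 10, 6)  # rates sum to 1
        with pytest.raises(ValueError, match="singular"):
            hi.correct_sex_misclassification(
                hi.HarvestArray(np.ones((2, 3, 2)), [0, 1]), mis)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_forward_map_round_trip(self, seed):
        """Observed counts generated by the forward misclassification map
        are corrected back to the underlying true counts, and pushing the
        corrected counts forward again recovers the observed counts."""
        rng = np.random.default_rng(seed)
        true = rng.uniform(0, 50, (3, 4, 2))
        observed = np.einsum("ij,taj->tai", misclassification_matrix(MIS), true)
        arr = hi.HarvestArray(observed, [0, 1, 2])
        corrected = hi.correct_sex_misclassification(arr, MIS)
        np.testing.assert_allclose(corrected.counts, true, atol=1e-9)
        forward = np.einsum("ij,taj->tai", misclassification_matrix(MIS),
                            corrected.counts)
        np.testing.assert_allclose(forward, arr.counts, atol=1e-9)


class TestAgedFractionInflation:
    def test_seventy_one_percent_inflates_to_total(self):
        counts = np.zeros((2, 3, 2))
        counts[0, :, 1] = (30, 30, 11)  # year total 71 aged
        arr = hi.HarvestArray(counts, [2000, 2001])
        frac = hi.AgedFractionSeries([2000, 2001], [0.71, 1.0])
        out = hi.inflate_for_unaged(arr, frac)
        assert out.counts[0].sum() == pytest.approx(100.0)

    def test_fraction_one_is_identity(self, toy_harvest):
        frac = hi.AgedFractionSeries(toy_harvest.year_labels,
                                     np.ones(toy_harvest.n_years))
        out = hi.inflate_for_unaged(toy_harvest, frac)
        np.testing.assert_array_equal(out.counts, toy_harvest.counts)

    def test_within_year_proportions_preserved(self, toy_harvest):
        frac = hi.AgedFractionSeries(toy_harvest.year_labels,
                                     [0.5, 0.71, 0.9, 0.61])
        out = hi.inflate_for_unaged(toy_harvest, frac)
        for t in range(toy_harvest.n_years):
            tot_in, tot_out = toy_harvest.counts[t].sum(), out.counts[t].sum()
            np.testing.assert_allclose(out.counts[t] / tot_out,
                                       toy_harvest.counts[t] / tot_in, atol=1e-12)

    def test_ratio_preserved_on_two_ages(self):
        counts = np.zeros((2, 3, 2))
        counts[0, 0, 1], counts[0, 1, 1] = 10, 20
        arr = hi.HarvestArray(counts, [2000, 2001])
        out = hi.inflate_for_unaged(
            arr, hi.AgedFractionSeries([2000, 2001], [0.5, 1.0]))
        assert out.counts[0, 0, 1] == 20 and out.counts[0, 1, 1] == 40


class TestPlusGroupPooling:
    def test_old_ages_summed_into_terminal_class(self):
        df = pd.DataFrame({
            "year": [2000] * 4 + [2001],
            "age": [9, 10, 11, 12, 1],
            "sex": ["M"] * 5,
            "count": [1.0, 1.0, 1.0, 1.0, 1.0],
        })
        arr = hi.pool_plus_group(df, cutoff=10)
        assert arr.n_ages == 10 and arr.plus_group
        assert arr.counts[0, 8, SEXES.index("M")] == 1
        assert arr.counts[0, 9, SEXES.index("M")] == 3

    def test_cub_rows_dropped(self, caplog):
        df = pd.DataFrame({
            "year": [2000, 2000, 2001], "age": [0, 1, 2],
            "sex": ["F", "F", "F"], "count": [5.0, 3.0, 2.0],
        })
        with caplog.at_level("INFO", logger="harvestipm.data_io"):
            arr = hi.pool_plus_group(df, cutoff=3)
        assert arr.counts.sum() == 5.0  # cubs excluded
        assert any("cub" in r.message for r in caplog.records)

    def test_low_cutoff_rejected(self):
        df = pd.DataFrame({"year": [0], "age": [1], "sex": ["M"], "count": [1.0]})
        with pytest.raises(ValueError):
            hi.pool_plus_group(df, cutoff=1)
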