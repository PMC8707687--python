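import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmacv.datatypes import ReporterMatrix
from plasmacv.synthetic import SimulationConfig, simulate_dataset
from plasmacv.variation import (
    cv_analytical,
    cv_biological,
    cv_total,
    duplicate_sd_bias_factor,
    filter_by_completeness,
    summarize,
    variation_table,
)

from conftest import make_matrix, make_toy_map


def _matrix_with_presence(sample_map, counts):
    """One protein per requested presence count over the designed columns."""
    cols = sample_map.sample_columns
    data = {}
    for i, count in enumerate(counts):
        row = np.full(len(cols), np.nan)
        row[:count] = 1.0
        data[f"PR{i:02d}"] = row
    values = pd.DataFrame(data, index=cols).T
    values.index.name = "accession"
    return ReporterMatrix(values)


@pytest.fixture(scope="module")
def full_map():
    _, sm, _ = simulate_dataset(SimulationConfig(n_proteins=1, seed=0))
    return sm


class TestCompletenessFilter:
    def test_inclusive_boundary_42_of_84(self, full_map):
        m = _matrix_with_presence(full_map, [42])
        assert len(filter_by_completeness(m, full_map).proteins) == 1

    def test_41_of_84_removed(self, full_map):
        m = _matrix_with_presence(full_map, [41])
        assert len(filter_by_completeness(m, full_map).proteins) == 0

    def test_toy_grid_counts(self, full_map):
        counts = [0, 10, 20, 30, 40, 50, 60, 70, 80, 84]
        m = _matrix_with_presence(full_map, counts)
        kept = filter_by_completeness(m, full_map)
        expected = [f"PR{i:02d}" for i, c in enumerate(counts) if c >= 42]
        assert kept.proteins == expected

    def test_order_preserved(self, full_map):
        m = _matrix_with_presence(full_map, [84, 50, 42, 60])
        kept = filter_by_completeness(m, full_map)
        assert kept.proteins == ["PR00", "PR01", "PR02", "PR03"]

    def test_threshold_validation(self, full_map):
        m = _matrix_with_presence(full_map, [84])
        with pytest.raises(ValueError):
            filter_by_completeness(m, full_map, threshold=0.0)
        with pytest.raises(ValueError):
            filter_by_completeness(m, full_map, threshold=1.5)


class TestCVAnalytical:
    def test_identical_pair_zero(self):
        sm = make_toy_map(n_plexes=1, n_subjects=1)
        m = make_matrix(sm, fill=1.0)
        out = cv_analytical(m, sm)
        assert (out["cv_analytical"] == 0.0).all()
        assert (out["n_pairs_used"] == 1).all()

    def test_two_point_pair_hand_value(self):
        # pair (0.9, 1.1): SD (ddof=1) = 0.1414, mean = 1.0 -> 14.14%
        sm = make_toy_map(n_plexes=1, n_subjects=1)
        m = make_matrix(sm, fill=1.0)
        c1, c2 = sm.replicate_columns("S01")
        m.values[c1] = 0.9
        m.values[c2] = 1.1
        out = cv_analytical(m, sm)
        expected = np.std([0.9, 1.1], ddof=1) / 1.0 * 100
        assert out["cv_analytical"].iloc[0] == pytest.approx(expected)
        assert out["cv_analytical"].iloc[0] == pytest.approx(14.142135, abs=1e-4)

    def test_incomplete_pair_excluded(self):
        sm = make_toy_map(n_plexes=1, n_subjects=2)
        m = make_matrix(sm, fill=1.0)
        c1, _ = sm.replicate_columns("S02")
        m.values.loc["PR0", c1] = np.nan
        out = cv_analytical(m, sm)
        assert out.loc["PR0", "n_pairs_used"] == 1
        assert out.loc["PR1", "n_pairs_used"] == 2

    def test_no_pairs_flagged_missing(self):
        sm = make_toy_map(n_plexes=1, n_subjects=1)
        m = make_matrix(sm, fill=1.0)
        c1, _ = sm.replicate_columns("S01")
        m.values[c1] = np.nan
        out = cv_analytical(m, sm)
        assert out["n_pairs_used"].eq(0).all()
        assert out["cv_analytical"].isna().all()

    def test_duplicate_sd_bias_monte_carlo(self):
        # oracle: E[pair CV] = sqrt(2/pi) * true CV for duplicate pairs
        cfg = SimulationConfig(
            n_proteins=1000, cv_biological=20.0, cv_analytical=5.0, missing_rate=0.0, seed=21
        )
        matrix, sm, _ = simulate_dataset(cfg)
        out = cv_analytical(matrix, sm)
        expected = duplicate_sd_bias_factor() * 5.0
        assert np.median(out["cv_analytical"]) == pytest.approx(expected, abs=0.3)


class TestCVTotal:
    def test_constant_values_zero_cv(self):
        sm = make_toy_map(n_plexes=1, n_subjects=2)
        m = make_matrix(sm, fill=1.0)
        out = cv_total(m, sm)
        assert (out["cv_total"] == 0.0).all()

    def test_two_point_hand_value(self):
        sm = make_toy_map(n_plexes=1, n_subjects=1)
        m = make_matrix(sm, fill=1.0)
        c1, c2 = sm.replicate_columns("S01")
        m.values[c1] = 0.8
        m.values[c2] = 1.2
        out = cv_total(m, sm)
        assert out["mean_total"].iloc[0] == pytest.approx(1.0)
        assert out["sd_total"].iloc[0] == pytest.approx(0.2828427, abs=1e-6)
        assert out["cv_total"].iloc[0] == pytest.approx(28.28427, abs=1e-4)

    def test_zero_analytical_noise_recovers_bio_cv(self):
        cfg = SimulationConfig(
            n_proteins=800, cv_biological=20.0, cv_analytical=0.0, missing_rate=0.0, seed=31
        )
        matrix, sm, _ = simulate_dataset(cfg)
        out = cv_total(matrix, sm)
        assert np.median(out["cv_total"]) == pytest.approx(20.0, abs=1.5)

    def test_single_value_flagged(self, full_map):
        m = _matrix_with_presence(full_map, [1])
        out = cv_total(m, full_map)
        assert np.isnan(out["sd_total"].iloc[0])
        assert np.isnan(out["cv_total"].iloc[0])

    def test_subject_means_mode(self):
        sm = make_toy_map(n_plexes=1, n_subjects=2)
        m = make_matrix(sm, fill=1.0)
        (a1, a2), (b1, b2) = sm.replicate_columns("S01"), sm.replicate_columns("S02")
        m.values[a1], m.values[a2] = 0.8, 1.2  # subject mean 1.0
        m.values[b1], m.values[b2] = 1.9, 2.1  # subject mean 2.0
        out = cv_total(m, sm, over="subject-means")
        assert out["mean_total"].iloc[0] == pytest.approx(1.5)
        assert out["sd_total"].iloc[0] == pytest.approx(np.std([1.0, 2.0], ddof=1))


class TestCVBiological:
    @pytest.mark.parametrize(
        "cvt,cva,expected",
        [
            (92.3, 7.6, 92.0),   # C-reactive protein
            (38.3, 2.7, 38.2),   # haptoglobin
            (7.1, 1.9, 6.8),     # serum albumin
        ],
    )
    def test_reference_rows_one_decimal(self, cvt, cva, expected):
        assert round(cv_biological(cvt, cva), 1) == expected

    def test_zero_analytical_identity(self):
        assert cv_biological(25.0, 0.0) == pytest.approx(25.0)

    def test_clipped_to_zero_when_analytical_exceeds_total(self):
        assert cv_biological(5.0, 7.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv_biological(-1.0, 2.0)
        with pytest.raises(ValueError):
            cv_biological(1.0, -2.0)

    def test_nan_propagates(self):
        out = cv_biological(np.array([10.0, np.nan]), np.array([3.0, 3.0]))
        assert not np.isnan(out[0])
        assert np.isnan(out[1])

    @given(
        cvt=st.floats(min_value=0.0, max_value=200.0),
        cva=st.floats(min_value=0.0, max_value=200.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_pythagorean_closure(self, cvt, cva):
        bio = cv_biological(cvt, cva)
        assert bio >= 0.0
        if cvt >= cva:
            assert math.sqrt(bio**2 + cva**2) == pytest.approx(cvt, abs=1e-9)


class TestVariationTable:
    def test_fields_and_closure(self, default_sim):
        _, matrix, sm, _ = default_sim
        table = variation_table(matrix, sm)
        for col in ("n_present", "completeness", "mean_total", "sd_total", "cv_total",
                    "cv_analytical", "n_pairs_used", "cv_biological", "cv_bio_clipped"):
            assert col in table.columns
        ok = table["cv_total"] >= table["cv_analytical"]
        recomposed = np.sqrt(table.loc[ok, "cv_biological"] ** 2 + table.loc[ok, "cv_analytical"] ** 2)
        np.testing.assert_allclose(recomposed, table.loc[ok, "cv_total"], atol=1e-9)
        defined = table["cv_total"].notna()
        np.testing.assert_allclose(
            table.loc[defined, "cv_total"],
            table.loc[defined, "sd_total"] / table.loc[defined, "mean_total"] * 100,
            rtol=1e-12,
        )

    def test_scale_invariance_per_protein(self, default_sim):
        _, matrix, sm, _ = default_sim
        base = variation_table(matrix, sm)
        scaled = matrix.copy()
        scaled.values.iloc[0] *= 37.5
        out = variation_table(scaled, sm)
        for col in ("cv_total", "cv_analytical", "cv_biological"):
            assert out[col].iloc[0] == pytest.approx(base[col].iloc[0], rel=1e-12)

    def test_median_ordering(self):
        cfg = SimulationConfig(
            n_proteins=400, cv_biological=20.0, cv_analytical=5.0, missing_rate=0.0, seed=41
        )
        matrix, sm, _ = simulate_dataset(cfg)
        table = variation_table(matrix, sm)
        med = table[["cv_total", "cv_analytical", "cv_biological"]].median()
        assert med["cv_analytical"] < med["cv_biological"] <= med["cv_total"]

    def test_parameter_recovery(self):
        cfg = SimulationConfig(
            n_proteins=1000, cv_biological=20.0, cv_analytical=5.0, missing_rate=0.0, seed=51
        )
        matrix, sm, _ = simulate_dataset(cfg)
        table = variation_table(matrix, sm)
        assert np.median(table["cv_total"]) == pytest.approx(math.sqrt(425), abs=1.5)
        # biological CV recovered within 2 points after the documented
        # (uncorrected) duplicate-SD bias in the analytical component
        assert np.median(table["cv_biological"]) == pytest.approx(20.0, abs=2.0)


class TestSummarize:
    def test_single_protein(self):
        table = pd.DataFrame(
            {"cv_total": [12.0], "cv_analytical": [3.0], "cv_biological": [11.6]}
        )
        s = summarize(table)
        assert s["medians"]["cv_total"] == 12.0
        assert s["n_proteins"] == 1

    def test_three_protein_median(self):
        table = pd.DataFrame(
            {
                "cv_total": [10.0, 20.0, 30.0],
                "cv_analytical": [1.0, 2.0, 3.0],
                "cv_biological": [9.9, 19.9, 29.8],
            }
        )
        assert summarize(table)["medians"]["cv_total"] == 20.0

    def test_histogram_counts_conserve_proteins(self, default_sim):
        _, matrix, sm, _ = default_sim
        table = variation_table(matrix, sm)
        s = summarize(table)
        hist = s["histogram"]
        n_defined = table["cv_total"].notna().sum()
        assert hist["count_cv_total"].sum() == n_defined
        assert hist["cumulative_cv_total"].iloc[-1] == n_defined

    def test_variance_addition_closed_form(self):
        cfg = SimulationConfig(
            n_proteins=600, cv_biological=19.2, cv_analytical=5.3, missing_rate=0.0, seed=61
        )
        matrix, sm, _ = simulate_dataset(cfg)
        table = variation_table(matrix, sm)
        expected = math.sqrt(19.2**2 + 5.3**2)  # ~19.9
        assert summarize(table)["medians"]["cv_total"] == pytest.approx(expected, abs=1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["cv_total", "cv_analytical", "cv_biological"]))
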