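"""MA statistics, self-calibrated cutoff and regulation classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresseq.de_calling import (
    CutoffCalibration,
    DEConfig,
    calibrate_cutoff,
    call_differential,
    classify,
    compute_ma_table,
    fold_change,
    ma_plot_table,
    ma_statistics,
)


class TestMaStatistics:
    @pytest.mark.parametrize(
        "ref,trt,m,a",
        [
            ([4, 4], [32, 32], 3.0, 3.5),
            ([8, 8], [8, 8], 0.0, 3.0),
            ([3, 5], [24, 40], 3.0, math.log2(4 * 32) / 2),  # means 4 and 32
        ],
    )
    def test_mean_then_log(self, ref, trt, m, a):
        M, A = ma_statistics(ref, trt)
        assert M == pytest.approx(m)
        assert A == pytest.approx(a)

    def test_nonpositive_rpkm_is_hard_error(self):
        with pytest.raises(ValueError):
            ma_statistics([0.0, 1.0], [2.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1e6), min_size=1, max_size=4),
        st.lists(st.floats(0.01, 1e6), min_size=1, max_size=4),
    )
    def test_swapping_conditions_negates_m_keeps_a(self, ref, trt):
        m1, a1 = ma_statistics(ref, trt)
        m2, a2 = ma_statistics(trt, ref)
        assert m1 == pytest.approx(-m2, abs=1e-9)
        assert a1 == pytest.approx(a2, abs=1e-9)


class TestFoldChange:
    def test_identity_at_zero(self):
        assert fold_change(0.0) == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-20, 20))
    def test_reciprocal_symmetry(self, m):
        assert fold_change(m) * fold_change(-m) == pytest.approx(1.0)


class TestCalibration:
    def test_three_point_example(self):
        cal = calibrate_cutoff([-0.5, 0.0, 0.5])
        assert cal.stdev_m == pytest.approx(0.5)
        assert cal.m_min == pytest.approx(1.29)
        assert cal.m_effective == pytest.approx(1.5)  # floor dominates

    def test_degenerate_identical_values_fall_back_to_floor(self):
        cal = calibrate_cutoff([1.0, 1.0, 1.0])
        assert cal.stdev_m == 0.0
        assert cal.m_effective == 1.5

    def test_fewer_than_two_values_is_error(self):
        with pytest.raises(ValueError):
            calibrate_cutoff([0.0])

    def test_standard_normal_null_yields_one_percent_tail(self):
        rng = np.random.default_rng(7)
        m = rng.standard_normal(10_000)
        cal = calibrate_cutoff(m)
        assert cal.m_min == pytest.approx(2.58, abs=0.1)
        frac_outside = np.mean(np.abs(m) > cal.m_min)
        assert 0.005 <= frac_outside <= 0.02


def _table(rows):
    df = pd.DataFrame(rows)
    df["fold_change"] = 2.0 ** df["M"]
    return df.set_index("gene_id", drop=False)


class TestClassification:
    CAL = CutoffCalibration(stdev_m=0.4, m_min=1.032, m_effective=1.5)

    def test_rule_application(self):
        table = _table(
            [
                {"gene_id": "up", "mean_rpkm_ref": 40, "mean_rpkm_trt": 120,
                 "A": 5.8, "M": 1.58},
                {"gene_id": "weak", "mean_rpkm_ref": 25, "mean_rpkm_trt": 28,
                 "A": 4.7, "M": 3.0},
                {"gene_id": "near", "mean_rpkm_ref": 100, "mean_rpkm_trt": 280,
                 "A": 7.0, "M": 1.49},
                {"gene_id": "down", "mean_rpkm_ref": 300, "mean_rpkm_trt": 30,
                 "A": 6.0, "M": -3.3},
            ]
        )
        out = classify(table, self.CAL)
        cats = out.set_index("gene_id")["category"]
        assert cats["up"] == "up"
        assert cats["weak"] == "filtered"  # both condition means below 30
        assert cats["near"] == "non"  # strictly below the cutoff
        assert cats["down"] == "down"  # one condition mean at 30 passes

    def test_low_a_is_filtered(self):
        table = _table(
            [{"gene_id": "dim", "mean_rpkm_ref": 50, "mean_rpkm_trt": 50,
              "A": 1.9, "M": 0.0}]
        )
        assert classify(table, self.CAL)["category"].iloc[0] == "filtered"

    def test_categories_partition_gene_set(self):
        rng = np.random.default_rng(1)
        n = 300
        table = _table(
            [
                {"gene_id": f"g{i}", "mean_rpkm_ref": r, "mean_rpkm_trt": t,
                 "A": (math.log2(r) + math.log2(t)) / 2,
                 "M": math.log2(t) - math.log2(r)}
                for i, (r, t) in enumerate(
                    zip(rng.lognormal(4, 2, n), rng.lognormal(4, 2, n))
                )
            ]
        )
        out = classify(table, self.CAL)
        counts = out["category"].value_counts()
        assert counts.sum() == n
        assert set(counts.index) <= {"up", "down", "non", "filtered"}


class TestMaPlotTable:
    def test_colour_tags_and_filtered_exclusion(self):
        table = _table(
            [
                {"gene_id": "a", "mean_rpkm_ref": 40, "mean_rpkm_trt": 400,
                 "A": 7.0, "M": 3.3},
                {"gene_id": "b", "mean_rpkm_ref": 400, "mean_rpkm_trt": 40,
                 "A": 7.0, "M": -3.3},
                {"gene_id": "c", "mean_rpkm_ref": 100, "mean_rpkm_trt": 100,
                 "A": 6.6, "M": 0.0},
                {"gene_id": "d", "mean_rpkm_ref": 1, "mean_rpkm_trt": 1,
                 "A": 0.0, "M": 0.0},
            ]
        )
        out = ma_plot_table(classify(table, TestClassification.CAL))
        assert list(out["color"]) == ["green", "red", "grey"]

    def test_empty_input_gives_empty_table(self):
        empty = _table(
            [{"gene_id": "x", "mean_rpkm_ref": 1, "mean_rpkm_trt": 1,
              "A": 0.0, "M": 0.0}]
        )
        out = ma_plot_table(classify(empty, TestClassification.CAL))
        assert len(out) == 0


class TestFullContrast:
    def test_call_differential_calibrates_on_filter_passing_genes(self):
        rng = np.random.default_rng(3)
        n = 500
        base = rng.lognormal(6, 1, n)
        rpkm_df = pd.DataFrame(
            {
                "ref1": base * rng.lognormal(0, 0.05, n),
                "ref2": base * rng.lognormal(0, 0.05, n),
                "trt1": base * rng.lognormal(0, 0.05, n),
                "trt2": base * rng.lognormal(0, 0.05, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        rpkm_df.iloc[:5] *= 0.001  # push a few genes below the filters
        results, cal = call_differential(rpkm_df, ["ref1", "ref2"], ["trt1", "trt2"])
        assert cal.m_effective == 1.5  # tight replicates: floor dominates
        assert (results["category"] == "filtered").sum() >= 1
        passing = results[results["category"] != "filtered"]
        assert (passing["category"] == "non").mean() > 0.99
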