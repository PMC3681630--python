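"""Scale-factor normalization and trimmed-mean summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trimfold import preprocess
from trimfold.preprocess import (DegenerateInputError, ScaleFactor,
                                 apply_scale_factor, array_mean_signal,
                                 compute_scale_factor, trimmed_mean,
                                 trimmed_mean_summarize)

from conftest import probe_frame


def two_array_table(control_values, treatment_values):
    return probe_frame({
        "ctrl": ("control", control_values),
        "treat": ("treatment", treatment_values),
    })


class TestArrayMean:
    @pytest.mark.parametrize("values, expected", [
        ([100, 200, 300], 200.0),
        ([7], 7.0),
        ([5, 5, 5, 5], 5.0),
    ])
    def test_arithmetic_mean_of_spot_signals(self, values, expected):
        table = probe_frame({"a1": ("control", values)})
        assert array_mean_signal(table, "a1") == expected

    def test_unknown_array_raises(self):
        table = probe_frame({"a1": ("control", [1.0])})
        with pytest.raises(KeyError):
            array_mean_signal(table, "nope")

    def test_exclusion_list_removes_named_genes_from_mean(self):
        table = pd.concat([
            probe_frame({"a1": ("control", [10, 10])}, gene_id="gA"),
            probe_frame({"a1": ("control", [1000, 1000])}, gene_id="spike"),
        ], ignore_index=True)
        assert array_mean_signal(table, "a1") == 505.0
        assert array_mean_signal(table, "a1", exclude_genes=["spike"]) == 10.0


class TestScaleFactor:
    def test_direct_ratio_of_means(self):
        table = two_array_table([1000, 1000], [500, 500])
        sf = compute_scale_factor(table, "ctrl", "treat")
        assert sf.value == 2.0
        assert sf.control_mean == 1000.0 and sf.treatment_mean == 500.0

    def test_identical_arrays_give_unit_factor(self):
        table = two_array_table([10, 20, 30], [10, 20, 30])
        assert compute_scale_factor(table, "ctrl", "treat").value == 1.0

    def test_swapping_arrays_gives_reciprocal(self):
        table = two_array_table([120, 180, 60], [40, 55, 85])
        fwd = compute_scale_factor(table, "ctrl", "treat").value
        rev = compute_scale_factor(table, "treat", "ctrl").value
        assert fwd * rev == pytest.approx(1.0, rel=1e-14)

    def test_zero_treatment_mean_is_degenerate(self):
        table = two_array_table([10.0], [0.0])
        with pytest.raises(DegenerateInputError):
            compute_scale_factor(table, "ctrl", "treat")

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(DegenerateInputError):
            ScaleFactor(value=-1.0, control_mean=1.0, treatment_mean=-1.0)


class TestApplyScaleFactor:
    def test_treatment_spots_multiplied_control_untouched(self):
        table = two_array_table([10, 20], [10, 20])
        sf = ScaleFactor(value=2.0, control_mean=1.0, treatment_mean=0.5)
        out = apply_scale_factor(table, "treat", sf)
        assert out.loc[out["array_id"] == "treat", "signal"].tolist() == [20, 40]
        assert out.loc[out["array_id"] == "ctrl", "signal"].tolist() == [10, 20]

    def test_unit_factor_is_identity(self):
        table = two_array_table([1.5, 2.5], [3.5, 4.5])
        sf = ScaleFactor(value=1.0, control_mean=1.0, treatment_mean=1.0)
        out = apply_scale_factor(table, "treat", sf)
        pd.testing.assert_frame_equal(out, table)

    @given(st.lists(st.floats(1.0, 1e6), min_size=2, max_size=20),
           st.lists(st.floats(1.0, 1e6), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_means_agree(self, ctrl, treat):
        """Algebraic post-condition: adjusted treatment mean = control mean."""
        table = two_array_table(ctrl, treat)
        sf = compute_scale_factor(table, "ctrl", "treat")
        out = apply_scale_factor(table, "treat", sf)
        mu_c = array_mean_signal(out, "ctrl")
        mu_t = array_mean_signal(out, "treat")
        assert mu_t == pytest.approx(mu_c, rel=1e-12)


class TestTrimmedMean:
    @pytest.mark.parametrize("values, expected, used, discarded", [
        ([10, 2, 8, 100, 6], 8.0, 3, 2),       # drop 100 and 2
        ([5, 5, 5, 5, 5], 5.0, 3, 2),          # ties: still one per extreme
        ([1, 1, 1, 1, 10], 1.0, 3, 2),         # duplicated minimum
        ([4, 8, 6, 2], 5.0, 2, 2),             # 4 values: average middle two
        ([3, 9, 6], 6.0, 3, 0),                # 3 values: untrimmed mean
    ])
    def test_examples(self, values, expected, used, discarded):
        mean, n_used, n_discarded = trimmed_mean(np.array(values))
        assert mean == expected
        assert (n_used, n_discarded) == (used, discarded)

    def test_fewer_than_three_values_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean(np.array([1.0, 2.0]))

    @given(st.lists(st.floats(0.0, 1e9), min_size=5, max_size=5))
    @settings(max_examples=200, deadline=None)
    def test_oracle_sort_and_average_middle_three(self, values):
        mean, _, _ = trimmed_mean(np.array(values))
        assert mean == np.mean(np.sort(values)[1:4])

    @given(st.lists(st.floats(1.0, 1e6), min_size=5, max_size=9, unique=True),
           st.floats(1.0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_inflating_the_unique_maximum_changes_nothing(self, values, bump):
        base, _, _ = trimmed_mean(np.array(values))
        inflated = sorted(values)
        inflated[-1] += bump
        assert trimmed_mean(np.array(inflated))[0] == base

    @given(st.lists(st.floats(0.1, 1e6), min_size=5, max_size=5),
           st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, values, c):
        base, _, _ = trimmed_mean(np.array(values))
        scaled, _, _ = trimmed_mean(c * np.array(values))
        assert scaled == pytest.approx(c * base, rel=1e-12)


class TestSummarizeTable:
    def test_groups_summarized_per_gene_and_array(self):
        table = pd.concat([
            probe_frame({"ctrl": ("control", [10, 2, 8, 100, 6])}, gene_id="gA"),
            probe_frame({"ctrl": ("control", [5, 5, 5, 5, 5])}, gene_id="gB"),
        ], ignore_index=True)
        out = trimmed_mean_summarize(table)
        by_gene = out.set_index("gene_id")["signal"]
        assert by_gene["gA"] == 8.0
        assert by_gene["gB"] == 5.0
        assert (out["n_used"] == 3).all() and (out["n_discarded"] == 2).all()

    def test_summary_lies_between_group_min_and_max(self, small_result):
        phase = small_result.config.phases[0]
        table = small_result.probe_tables[phase]
        out = trimmed_mean_summarize(table)
        bounds = table.groupby(["array_id", "gene_id"])["signal"].agg(["min", "max"])
        merged = out.merge(bounds, left_on=["array_id", "gene_id"],
                           right_index=True)
        assert (merged["signal"] >= merged["min"]).all()
        assert (merged["signal"] <= merged["max"]).all()

    def test_mixed_replicate_counts_follow_stated_rules(self):
        # gA keeps 5 spots, gB has 4, gC has 3: trim/trim/untrimmed
        table = pd.concat([
            probe_frame({"a": ("control", [10, 2, 8, 100, 6])}, gene_id="gA"),
            probe_frame({"a": ("control", [4, 8, 6, 2])}, gene_id="gB"),
            probe_frame({"a": ("control", [3, 9, 6])}, gene_id="gC"),
        ], ignore_index=True)
        out = trimmed_mean_summarize(table).set_index("gene_id")
        assert out.loc["gA", "signal"] == 8.0
        assert out.loc["gB", "signal"] == 5.0
        assert out.loc["gC", "signal"] == 6.0
        assert out.loc["gC", "n_discarded"] == 0

    def test_undersized_group_excluded_and_logged(self, caplog):
        table = pd.concat([
            probe_frame({"a": ("control", [1, 2, 3, 4, 5])}, gene_id="gA"),
            probe_frame({"a": ("control", [7, 9])}, gene_id="gB"),
        ], ignore_index=True)
        with caplog.at_level("WARNING", logger="trimfold"):
            out = trimmed_mean_summarize(table)
        assert set(out["gene_id"]) == {"gA"}
        assert any("<3 replicates" in r.message for r in caplog.records)


def test_normalize_then_summarize_uses_adjusted_signals():
    """Scaling runs before trimming, so the trim sees adjusted values."""
    table = two_array_table([100, 100, 100, 100, 100], [40, 50, 60, 10, 90])
    summarized, sf = preprocess.normalize_and_summarize(table, "ctrl", "treat")
    assert sf.value == pytest.approx(2.0)
    treat = summarized.set_index("array_id").loc["treat", "signal"]
    assert treat == pytest.approx(100.0)  # trimmed mean of 2x{40,50,60}
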