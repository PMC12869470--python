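"""Pseudobulk aggregation, size factors, and the two-mode differential test."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regshift.core import CountMatrix
from regshift.diffacc import (
    PseudobulkTable,
    compartment_shift,
    diff_test,
    pseudobulk,
    size_factors_median_of_ratios,
)
from regshift.synthetic import cell_groups


def _matrix(dense, groups=None):
    n_peaks, n_cells = dense.shape
    barcodes = [f"c{i}" for i in range(n_cells)]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if groups is not None:
        obs["subset"] = [g.split(":")[0] for g in groups]
    return CountMatrix(sp.csr_matrix(dense), [f"p{i}" for i in range(n_peaks)], barcodes, obs)


def _table(dense_by_group, subset_of):
    counts = pd.DataFrame(dense_by_group)
    counts.index = [f"p{i}" for i in range(len(counts))]
    return PseudobulkTable(counts, subset_of)


class TestPseudobulk:
    def test_single_group_equals_row_sums(self):
        dense = np.arange(12).reshape(3, 4)
        cm = _matrix(dense)
        table = pseudobulk(cm, {bc: "g" for bc in cm.barcodes})
        assert np.array_equal(table.counts["g"].to_numpy(), dense.sum(axis=1))

    def test_identical_cells_give_identical_columns(self):
        dense = np.tile([[2], [5]], (1, 6))
        cm = _matrix(dense)
        groups = {f"c{i}": ("a" if i < 3 else "b") for i in range(6)}
        table = pseudobulk(cm, groups)
        assert table.counts["a"].equals(table.counts["b"])

    def test_matches_brute_force_and_conserves_mass(self):
        rng = np.random.default_rng(2)
        dense = rng.integers(0, 10, size=(100, 60))
        cm = _matrix(dense)
        groups = {f"c{i}": f"g{rng.integers(0, 3)}" for i in range(60)}
        table = pseudobulk(cm, groups)
        for g in table.counts.columns:
            members = [i for i in range(60) if groups[f"c{i}"] == g]
            assert np.array_equal(
                table.counts[g].to_numpy(), dense[:, members].sum(axis=1)
            )
        assert table.counts.to_numpy().sum() == dense.sum()

    def test_unassigned_barcode_is_an_error(self):
        cm = _matrix(np.ones((2, 3), dtype=int))
        with pytest.raises(ValueError, match="c2"):
            pseudobulk(cm, {"c0": "a", "c1": "a"})


class TestSizeFactors:
    def test_identical_groups_give_unit_factors(self):
        table = _table({"a": [10, 20, 5], "b": [10, 20, 5]}, {"a": "x", "b": "y"})
        factors = size_factors_median_of_ratios(table)
        assert np.allclose(factors, 1.0)

    def test_doubled_group_ratio_is_two(self):
        table = _table({"a": [10, 20, 5], "b": [20, 40, 10]}, {"a": "x", "b": "y"})
        factors = size_factors_median_of_ratios(table)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        assert np.prod(factors) == pytest.approx(1.0)  # geometric mean 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.integers(0, 50, size=(200, 4)).astype(float)
        counts = pd.DataFrame(values, columns=list("abcd"))
        got = size_factors_median_of_ratios(
            PseudobulkTable(counts, {c: c for c in "abcd"})
        )
        # oracle: literal median-of-ratios with python loops
        usable = [i for i in range(200) if all(values[i] > 0)]
        geo = {i: float(np.exp(np.mean(np.log(values[i])))) for i in usable}
        raw = [float(np.median([values[i, j] / geo[i] for i in usable])) for j in range(4)]
        rescale = float(np.exp(np.mean(np.log(raw))))
        oracle = np.array(raw) / rescale
        assert np.allclose(got.to_numpy(), oracle)

    def test_no_common_nonzero_peak_is_an_error(self):
        table = _table({"a": [0, 3], "b": [4, 0]}, {"a": "x", "b": "y"})
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(table)


class TestDiffTest:
    def _paired_table(self, col_a, col_b, reps=2):
        data = {}
        subset_of = {}
        for r in range(reps):
            data[f"a{r}"] = col_a
            subset_of[f"a{r}"] = "A"
            data[f"b{r}"] = col_b
            subset_of[f"b{r}"] = "B"
        return _table(data, subset_of)

    def test_identical_columns_give_null_results(self):
        table = self._paired_table([10, 30, 50], [10, 30, 50])
        res = diff_test(table, "A", "B")
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_closed_form_fold_change(self):
        # counts 16,16 vs 4,4: log2fc -> -2 as pseudocount -> 0
        table = self._paired_table([16, 100], [4, 100])
        res = diff_test(table, "A", "B", pseudocount=1e-9, min_mean=0)
        assert res.loc["p0", "log2fc"] == pytest.approx(-2.0, abs=1e-6)

    def test_min_mean_excludes_low_peaks(self):
        table = self._paired_table([2, 100], [3, 100])
        res = diff_test(table, "A", "B", min_mean=5)
        assert list(res.index) == ["p1"]

    def test_fewer_than_two_replicates_is_an_error(self):
        table = _table({"a0": [5], "b0": [5]}, {"a0": "A", "b0": "B"})
        with pytest.raises(ValueError, match="replicates"):
            diff_test(table, "A", "B")

    def test_bh_qvalues_dominate_pvalues(self, small_config, small_genome, small_counts):
        table = pseudobulk(small_counts, cell_groups(small_counts))
        res = diff_test(table, "bright", "dim57neg")
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
        ordered = res.sort_values("p_value")
        assert ordered["q_value"].is_monotonic_increasing


@pytest.fixture(scope="module")
def modes(small_counts):
    table = pseudobulk(small_counts, cell_groups(small_counts))
    raw = diff_test(table, "bright", "dim57neg", mode="raw")
    centered = diff_test(table, "bright", "dim57neg", mode="centered")
    return raw, centered


class TestShiftRecoveryAndMasking:
    def test_raw_mode_recovers_planted_dre_shift(self, small_genome, modes):
        raw, _ = modes
        shifted = small_genome.ground_truth.shifted_dre_ids
        mean_fc = raw.loc[raw.index.isin(shifted), "log2fc"].mean()
        assert mean_fc == pytest.approx(-1.0, abs=0.1)

    def test_raw_mode_recovers_planted_promoter_shift(self, small_genome, modes):
        raw, _ = modes
        truth = small_genome.ground_truth.peak_class_by_id
        shifts = compartment_shift(raw, truth)
        assert shifts.loc["promoter", "mean_log2fc"] == pytest.approx(0.2, abs=0.1)

    def test_centered_mode_masks_dre_loss_and_biases_promoters(self, small_genome, modes):
        raw, centered = modes
        truth = small_genome.ground_truth.peak_class_by_id
        sh_raw = compartment_shift(raw, truth)
        sh_cen = compartment_shift(centered, truth)
        # attenuation of the DRE loss and spurious positive promoter bias
        assert sh_cen.loc["dre", "mean_log2fc"] > sh_raw.loc["dre", "mean_log2fc"]
        assert sh_cen.loc["promoter", "mean_log2fc"] > sh_raw.loc["promoter", "mean_log2fc"]


class TestCompartmentShift:
    def test_all_zero_fold_changes(self):
        res = pd.DataFrame(
            {"log2fc": [0.0, 0.0, 0.0], "t_stat": 0.0, "p_value": 1.0, "q_value": 1.0, "mode": "raw"},
            index=pd.Index(["p0", "p1", "p2"], name="peak_id"),
        )
        shifts = compartment_shift(res, {"p0": "dre", "p1": "dre", "p2": "promoter"})
        assert np.allclose(shifts["mean_log2fc"], 0.0)
        assert np.allclose(shifts["one_sample_p"], 1.0)

    def test_empty_compartment_omitted(self):
        res = pd.DataFrame(
            {"log2fc": [1.0], "t_stat": 1.0, "p_value": 0.5, "q_value": 0.5, "mode": "raw"},
            index=pd.Index(["p0"], name="peak_id"),
        )
        shifts = compartment_shift(res, {"p0": "dre"})
        assert list(shifts.index) == ["dre"]
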