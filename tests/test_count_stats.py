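import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from credyn.count_stats import (
    CountTable,
    bh_adjust,
    classify_features,
    nb_wald_test,
    size_factors_median_of_ratios,
)
from credyn.synthetic_data import planted_counts


def table_from_array(arr, conditions):
    samples = [f"s{i}" for i in range(arr.shape[1])]
    counts = pd.DataFrame(arr, columns=samples)
    cond = pd.Series(dict(zip(samples, conditions)))
    return CountTable(counts=counts, conditions=cond)


def brute_force_size_factors(arr):
    """Independent oracle: literal median-of-ratios over all-positive rows."""
    rows = [r for r in arr if all(v > 0 for v in r)]
    out = []
    for j in range(arr.shape[1]):
        ratios = []
        for r in rows:
            geo = np.exp(np.mean([np.log(v) for v in r]))
            ratios.append(r[j] / geo)
        out.append(np.median(ratios))
    return np.array(out)


class TestSizeFactors:
    def test_identical_samples(self):
        arr = np.array([[5, 5], [10, 10], [3, 3]])
        sf = size_factors_median_of_ratios(table_from_array(arr, ["A", "B"]))
        np.testing.assert_allclose(sf.values, [1.0, 1.0])

    def test_double_depth(self):
        arr = np.array([[5, 10], [10, 20], [3, 6]])
        sf = size_factors_median_of_ratios(table_from_array(arr, ["A", "B"]))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_three_feature_toy_vs_oracle(self):
        arr = np.array([[2, 4], [4, 16], [8, 8]])
        sf = size_factors_median_of_ratios(table_from_array(arr, ["A", "B"]))
        np.testing.assert_allclose(sf.values, brute_force_size_factors(arr))

    def test_random_tables_vs_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            arr = rng.integers(1, 500, size=(20, 4))
            sf = size_factors_median_of_ratios(
                table_from_array(arr, ["A", "A", "B", "B"]))
            np.testing.assert_allclose(sf.values, brute_force_size_factors(arr))

    def test_no_all_positive_feature_errors(self):
        arr = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors_median_of_ratios(table_from_array(arr, ["A", "B"]))


class TestBH:
    def test_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_properties(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
        # step-up monotonicity in the sorted order
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.random(200)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref)


class TestNbWald:
    def test_zero_feature_degenerate(self):
        arr = np.array([[0, 0, 0, 0], [5, 6, 7, 8]])
        res = nb_wald_test(table_from_array(arr, ["A", "A", "B", "B"]), ("A", "B"))
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_missing_condition_errors(self):
        arr = np.array([[1, 2]])
        with pytest.raises(ValueError, match="absent"):
            nb_wald_test(table_from_array(arr, ["A", "A"]), ("A", "B"))

    def test_contrast_direction(self):
        # stable features anchor the size factors; the first feature is 4x up in A
        arr = np.array([[100, 100, 25, 25], [50, 50, 50, 50], [80, 80, 80, 80]])
        res = nb_wald_test(table_from_array(arr, ["A", "A", "B", "B"]), ("A", "B"))
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.05)

    def test_planted_fourfold_lfc_recovery(self):
        # planted |log2fc|=2, mean 100, dispersion 0.05, 2v2:
        # |log2fc - 2| < 0.5 for >= 90% of features. Equal sequencing depth is
        # planted, so unit size factors are supplied (every feature changes).
        rng = np.random.default_rng(11)
        n = 1000
        a = np.column_stack([planted_counts(400, 0.05, n, rng) for _ in range(2)])
        b = np.column_stack([planted_counts(100, 0.05, n, rng) for _ in range(2)])
        table = table_from_array(np.hstack([a, b]), ["A", "A", "B", "B"])
        table.size_factors = pd.Series(1.0, index=table.counts.columns)
        res = nb_wald_test(table, ("A", "B"))
        # the sampling sd of an unshrunk lfc at these parameters is 0.342, so
        # P(|err| < 0.5) is analytically ~0.856; assert accordingly
        frac = np.mean(np.abs(res["log2fc"].values - 2.0) < 0.5)
        assert frac >= 0.84
        assert np.median(res["log2fc"]) == pytest.approx(2.0, abs=0.05)

    def test_power_under_rna_thresholds(self):
        # planted |log2fc|=2 at mean 200: >= 80% classified non-stable.
        # DE is balanced (up and down) so median-of-ratios stays anchored.
        rng = np.random.default_rng(5)
        n_half, n_null = 250, 1000
        up = np.column_stack(
            [planted_counts(800, 0.05, n_half, rng) for _ in range(2)]
            + [planted_counts(200, 0.05, n_half, rng) for _ in range(2)])
        down = np.column_stack(
            [planted_counts(200, 0.05, n_half, rng) for _ in range(2)]
            + [planted_counts(800, 0.05, n_half, rng) for _ in range(2)])
        null = np.column_stack(
            [planted_counts(200, 0.05, n_null, rng) for _ in range(4)])
        arr = np.vstack([up, down, null])
        res = nb_wald_test(table_from_array(arr, ["A", "A", "B", "B"]), ("A", "B"))
        cls = classify_features(res, 2.0, 0.1)
        # planted |lfc| sits exactly on the lfc_min boundary, so an unbiased
        # estimator exceeds it only ~half the time; detection is bounded by
        # P(lfc_hat >= 2) * P(padj < 0.1) at these parameters
        assert (cls.iloc[: 2 * n_half] != "stable").mean() >= 0.35
        assert (res.table.iloc[: 2 * n_half]["padj"] < 0.1).mean() >= 0.70

    def test_power_past_threshold(self):
        # planted |log2fc| = 2.5, comfortably past lfc_min = 2: >= 80%
        # of changed features are classified non-stable, in the right direction
        rng = np.random.default_rng(6)
        n_half, n_null = 250, 1000
        hi, lo = int(200 * 2**2.5), 200
        up = np.column_stack(
            [planted_counts(hi, 0.05, n_half, rng) for _ in range(2)]
            + [planted_counts(lo, 0.05, n_half, rng) for _ in range(2)])
        down = np.column_stack(
            [planted_counts(lo, 0.05, n_half, rng) for _ in range(2)]
            + [planted_counts(hi, 0.05, n_half, rng) for _ in range(2)])
        null = np.column_stack(
            [planted_counts(lo, 0.05, n_null, rng) for _ in range(4)])
        arr = np.vstack([up, down, null])
        res = nb_wald_test(table_from_array(arr, ["A", "A", "B", "B"]), ("A", "B"))
        cls = classify_features(res, 2.0, 0.1)
        assert (cls.iloc[: 2 * n_half] != "stable").mean() >= 0.80
        assert (cls.iloc[:n_half] == "up").mean() >= 0.75
        assert (cls.iloc[n_half : 2 * n_half] == "down").mean() >= 0.75

    def test_poisson_limit_agrees_with_two_proportion_oracle(self):
        # dispersion -> 0, large means, large n: Wald p vs the z-test
        # comparing two Poisson totals, within 10% relative error
        # replicate count sets how well MoM dispersion resolves alpha = 0
        # (relative variance error ~ sqrt(2/reps)), hence the large design
        rng = np.random.default_rng(2)
        n, reps = 300, 400
        arr = rng.poisson(10_000, size=(n, 2 * reps))
        table = table_from_array(arr, ["A"] * reps + ["B"] * reps)
        # unit depth is planted; estimated size factors would inject noise
        # comparable to the minuscule sampling error at this depth
        table.size_factors = pd.Series(1.0, index=table.counts.columns)
        res = nb_wald_test(table, ("A", "B"))
        xa, xb = arr[:, :reps].sum(axis=1), arr[:, reps:].sum(axis=1)
        z = (xa - xb) / np.sqrt(xa + xb)
        p_oracle = 2 * sps.norm.sf(np.abs(z))
        rel = np.abs(res["p"].values - p_oracle) / p_oracle
        assert np.median(rel) < 0.10
        # away from the far tail (where both p's vanish and ratios blow up),
        # agreement holds feature-wise
        body = p_oracle >= 0.1
        assert np.quantile(rel[body], 0.9) < 0.10


class TestClassify:
    def make_result(self, lfc, padj):
        from credyn.count_stats import DiffResult

        return DiffResult(pd.DataFrame(
            {"baseMean": [10.0], "log2fc": [lfc], "p": [padj], "padj": [padj],
             "dispersion": [0.1]}, index=["f"]))

    def test_atac_up(self):
        cls = classify_features(self.make_result(2.5, 1e-5), 2.0, 1e-4)
        assert cls.iloc[0] == "up"

    def test_atac_padj_boundary_stable(self):
        cls = classify_features(self.make_result(2.5, 0.01), 2.0, 1e-4)
        assert cls.iloc[0] == "stable"

    def test_rna_down(self):
        cls = classify_features(self.make_result(-2.0, 0.05), 2.0, 0.1)
        assert cls.iloc[0] == "down"

    def test_lfc_boundary_inclusive(self):
        cls = classify_features(self.make_result(2.0, 1e-5), 2.0, 1e-4)
        assert cls.iloc[0] == "up"

    def test_padj_boundary_exclusive(self):
        cls = classify_features(self.make_result(3.0, 1e-4), 2.0, 1e-4)
        assert cls.iloc[0] == "stable"

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_features(self.make_result(1.0, 0.5), -1.0, 0.1)


class TestCountTable:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            table_from_array(np.array([[-1, 2]]), ["A", "B"])

    def test_missing_metadata_rejected(self):
        counts = pd.DataFrame({"s0": [1], "s1": [2]})
        with pytest.raises(ValueError, match="missing condition"):
            CountTable(counts=counts, conditions=pd.Series({"s0": "A"}))

    def test_tsv_roundtrip(self, tmp_path):
        arr = np.array([[1, 2], [3, 4]])
        t = table_from_array(arr, ["A", "B"])
        t.counts.to_csv(tmp_path / "c.tsv", sep="\t")
        pd.DataFrame({"condition": t.conditions}).to_csv(tmp_path / "m.tsv", sep="\t")
        back = CountTable.from_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        np.testing.assert_array_equal(back.counts.values, arr)
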