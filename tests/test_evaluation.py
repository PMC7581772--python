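"""Evaluation statistics against brute-force rank and quantile oracles."""

import numpy as np
import pandas as pd
import pytest

from mridensity.density_cnn import DatasetSplit
from mridensity.evaluation import (
    bland_altman_nonparametric,
    spearman,
    split_balance,
    subgroup_correlation,
)


def rank_midrank(x):
    """Midrank assignment, written directly from the definition."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x)
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    """Pearson correlation of midranks — independent of scipy."""
    ra, rb = rank_midrank(a), rank_midrank(b)
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


def quantile_oracle(values, q):
    x = np.sort(np.asarray(values, dtype=float))
    pos = q / 100.0 * (len(x) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(x) - 1)
    return x[lo] + (pos - lo) * (x[hi] - x[lo])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_five_point_permutation_example(self):
        """(1,2,3,4,5) vs (1,3,2,5,4): sum d^2 = 4, so the classic formula
        1 - 6*4/(5*24) and the midrank oracle both give rho = 0.8."""
        a, b = [1, 2, 3, 4, 5], [1, 3, 2, 5, 4]
        d2 = sum((x - y) ** 2 for x, y in zip(a, b))
        assert 1 - 6 * d2 / (5 * 24) == pytest.approx(0.8)
        assert spearman_oracle(a, b) == pytest.approx(0.8)
        rho, p = spearman(a, b)
        assert rho == pytest.approx(0.8)
        assert 0 < p < 1

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, 50).astype(float)
        b = a + rng.normal(0, 1, 50)
        rho, _ = spearman(a, b)
        assert rho == pytest.approx(spearman_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: 2 * x + 7])
    def test_invariant_under_strictly_monotone_transforms(self, transform):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(size=30)
        rho1, _ = spearman(a, b)
        rho2, _ = spearman(transform(a), b)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_perfect_agreement(self):
        x = np.array([1.0, 5.0, 9.0])
        stats = bland_altman_nonparametric(x, x)
        assert (stats.median_bias, stats.loa_low, stats.loa_high) == (0.0, 0.0, 0.0)

    def test_differences_one_to_hundred(self):
        """Median 50.5, LoA (3.475, 97.525) from the quantile oracle."""
        diff = np.arange(1, 101, dtype=float)
        truth = np.zeros(100)
        stats = bland_altman_nonparametric(diff, truth)
        assert stats.median_bias == pytest.approx(50.5)
        assert stats.loa_low == pytest.approx(quantile_oracle(diff, 2.5))
        assert stats.loa_high == pytest.approx(quantile_oracle(diff, 97.5))
        assert stats.loa_low == pytest.approx(3.475)
        assert stats.loa_high == pytest.approx(97.525)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        est, truth = rng.normal(10, 3, 40), rng.normal(10, 3, 40)
        base = bland_altman_nonparametric(est, truth)
        shifted = bland_altman_nonparametric(est + 2.5, truth)
        assert shifted.median_bias == pytest.approx(base.median_bias + 2.5)
        assert shifted.loa_low == pytest.approx(base.loa_low + 2.5)
        assert shifted.loa_high == pytest.approx(base.loa_high + 2.5)

    def test_ordering_invariant_and_n(self):
        est, truth = np.array([1.0, 2.0]), np.array([2.0, 1.0])
        stats = bland_altman_nonparametric(est, truth)
        assert stats.loa_low <= stats.median_bias <= stats.loa_high
        assert stats.n == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_nonparametric([1.0], [1.0])


class TestSubgroups:
    def test_all_below_threshold_is_error(self):
        truths = np.full(10, 5.0) + np.arange(10) * 0.1
        with pytest.raises(ValueError, match="dense"):
            subgroup_correlation(truths, truths, threshold=15.5)

    def test_threshold_outside_range_is_degenerate(self):
        """A threshold at or below every ground-truth density empties the
        non-dense group: the split is degenerate in either direction."""
        rng = np.random.default_rng(3)
        truths = rng.uniform(2, 40, 30)
        est = truths + rng.normal(0, 2, 30)
        with pytest.raises(ValueError, match="non-dense"):
            subgroup_correlation(est, truths, threshold=0.0)

    def test_subgroup_rhos_match_independent_recomputation(self):
        rng = np.random.default_rng(7)
        truths = rng.uniform(2, 40, 200)
        est = truths + rng.normal(0, 3, 200)
        result = subgroup_correlation(est, truths, threshold=15.5)
        nd = truths < 15.5
        assert result.rho_nondense == pytest.approx(spearman_oracle(est[nd], truths[nd]), abs=0.1)
        assert result.rho_dense == pytest.approx(spearman_oracle(est[~nd], truths[~nd]), abs=0.1)
        assert result.n_nondense + result.n_dense == 200


class TestSplitBalance:
    @staticmethod
    def _split(n=60):
        ids = [f"s{i:03d}" for i in range(n)]
        return ids, DatasetSplit(tuple(ids[:40]), tuple(ids[40:50]), tuple(ids[50:]))

    def test_partition_index_covariate_is_flagged(self):
        ids, split = self._split()
        cov = pd.DataFrame(
            {"leak": [0.0] * 40 + [1.0] * 10 + [2.0] * 10}, index=ids
        )
        table = split_balance(cov, split)
        assert table["p_value"].iloc[0] < 1e-6 and bool(table["flagged"].iloc[0])

    def test_categorical_covariate_uses_chi_square(self):
        ids, split = self._split()
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"subtype": rng.choice(list("ABC"), 60)}, index=ids)
        table = split_balance(cov, split)
        assert table["test"].iloc[0] == "chi-square"

    def test_null_calibration(self):
        """A covariate shuffled independently of the split should rarely be
        flagged: p > 0.05 in at least 90% of 100 replicates."""
        ids, split = self._split()
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            cov = pd.DataFrame({"x": rng.normal(size=60)}, index=ids)
            table = split_balance(cov, split)
            hits += table["p_value"].iloc[0] > 0.05
        assert hits >= 90

    def test_single_partition_rejected(self):
        ids = [f"s{i}" for i in range(6)]
        split = DatasetSplit(tuple(ids), (), ())
        cov = pd.DataFrame({"x": np.arange(6.0)}, index=ids)
        with pytest.raises(ValueError):
            split_balance(cov, split)

    def test_missing_covariate_lists_ids(self):
        ids, split = self._split()
        cov = pd.DataFrame({"x": np.arange(58.0)}, index=ids[:58])
        with pytest.raises(ValueError, match="s058"):
            split_balance(cov, split)
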