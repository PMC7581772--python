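"""Statistical evaluation: Spearman correlation, nonparametric Bland-Altman
agreement, dense/non-dense subgroup analysis and split-balance checks.

The agreement analysis is nonparametric throughout: the bias is the median
of the paired differences (estimate - ground truth) and the 95% limits of
agreement are the 2.5th and 97.5th percentiles of those differences, under
the same linear-interpolation quantile convention used by the preprocessing
module.  The dense/non-dense subgroup threshold defaults to a volumetric
density of 15.5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .density_cnn import DatasetSplit

__all__ = [
    "AgreementStats",
    "SubgroupResult",
    "spearman",
    "bland_altman_nonparametric",
    "subgroup_correlation",
    "split_balance",
]

DENSE_THRESHOLD_PERCENT = 15.5


@dataclass
class AgreementStats:
    spearman_rho: float
    p_value: float
    median_bias: float
    loa_low: float
    loa_high: float
    n: int
    # (mean of pair, estimate - truth) points for the Bland-Altman plot
    means: np.ndarray | None = None
    differences: np.ndarray | None = None


@dataclass
class SubgroupResult:
    threshold: float
    rho_nondense: float
    p_nondense: float
    rho_dense: float
    p_dense: float
    n_nondense: int
    n_dense: int


def _paired(estimates, ground_truths, min_n: int):
    e = np.asarray(estimates, dtype=float)
    g = np.asarray(ground_truths, dtype=float)
    if e.shape != g.shape or e.ndim != 1:
        raise ValueError("estimates and ground truths must be 1D and equal length")
    if len(e) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(e)}")
    return e, g


def spearman(estimates, ground_truths) -> tuple[float, float]:
    """Rank correlation with midrank ties; p from the large-sample
    approximation.  Constant inputs leave the rank correlation undefined."""
    e, g = _paired(estimates, ground_truths, 3)
    if np.all(e == e[0]) or np.all(g == g[0]):
        raise ValueError("rank correlation undefined for a constant input vector")
    res = stats.spearmanr(e, g)
    return float(res.statistic), float(res.pvalue)


def bland_altman_nonparametric(estimates, ground_truths) -> AgreementStats:
    """Median bias and percentile (2.5/97.5) limits of agreement.

    Differences are taken as estimate - ground truth; the Spearman rho of
    the pairs is reported alongside when computable.
    """
    e, g = _paired(estimates, ground_truths, 2)
    diff = e - g
    median_bias = float(np.median(diff))
    loa_low, loa_high = (float(v) for v in np.percentile(diff, [2.5, 97.5]))
    try:
        rho, p = spearman(e, g)
    except ValueError:
        rho, p = float("nan"), float("nan")
    return AgreementStats(
        spearman_rho=rho,
        p_value=p,
        median_bias=median_bias,
        loa_low=loa_low,
        loa_high=loa_high,
        n=len(e),
        means=(e + g) / 2.0,
        differences=diff,
    )


def subgroup_correlation(estimates, ground_truths, threshold: float = DENSE_THRESHOLD_PERCENT) -> SubgroupResult:
    """Spearman correlation separately for non-dense (< threshold) and dense
    (>= threshold) breasts, grouped on the ground-truth density."""
    e, g = _paired(estimates, ground_truths, 3)
    nondense = g < threshold
    dense = ~nondense
    for name, mask in (("non-dense", nondense), ("dense", dense)):
        if mask.sum() < 3:
            raise ValueError(f"{name} subgroup has {int(mask.sum())} samples, need >= 3")
    rho_nd, p_nd = spearman(e[nondense], g[nondense])
    rho_d, p_d = spearman(e[dense], g[dense])
    return SubgroupResult(
        threshold=threshold,
        rho_nondense=rho_nd,
        p_nondense=p_nd,
        rho_dense=rho_d,
        p_dense=p_d,
        n_nondense=int(nondense.sum()),
        n_dense=int(dense.sum()),
    )


def split_balance(covariates: pd.DataFrame, split: DatasetSplit, alpha: float = 0.05) -> pd.DataFrame:
    """Check that train/validation/test sets are exchangeable on covariates.

    One Kruskal-Wallis p-value per numeric covariate across the partitions,
    one chi-square (contingency) p-value per categorical covariate; a
    covariate is flagged when p < alpha.  ``covariates`` is indexed by
    sample id.
    """
    partitions = {
        "train": list(split.train_ids),
        "val": list(split.val_ids),
        "test": list(split.test_ids),
    }
    partitions = {k: v for k, v in partitions.items() if v}
    if len(partitions) < 2:
        raise ValueError("balance test needs at least 2 nonempty partitions")
    all_ids = [i for ids in partitions.values() for i in ids]
    missing = sorted(set(all_ids) - set(covariates.index))
    if missing:
        raise ValueError(f"covariates missing for ids: {missing}")
    rows = []
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            groups = [series.loc[ids].to_numpy() for ids in partitions.values()]
            stat, p = stats.kruskal(*groups)
            kind = "kruskal-wallis"
        else:
            membership = pd.Series(
                {i: name for name, ids in partitions.items() for i in ids}, name="partition"
            )
            table = pd.crosstab(series.loc[all_ids], membership.loc[all_ids])
            stat, p, _, _ = stats.chi2_contingency(table)
            kind = "chi-square"
        rows.append({"covariate": col, "test": kind, "statistic": float(stat),
                     "p_value": float(p), "flagged": bool(p < alpha)})
    return pd.DataFrame(rows)
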