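"""Thin statistical wrappers used across the DMR and enrichment modules."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def fisher_exact_2x2(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided exact test p-value on a pooled 2x2 (meth/unmeth x group)."""
    _, p = sps.fisher_exact(
        [[meth_a, unmeth_a], [meth_b, unmeth_b]], alternative="two-sided"
    )
    return float(p)


def rank_sum_test(x, y, exact_max_n: int = 50) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    Exact null enumeration for small samples without ties; normal
    approximation with tie and continuity correction otherwise. NaNs are
    dropped; returns NaN when either side is empty.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def empirical_p(observed: float, null_values: np.ndarray) -> float:
    """Permutation p-value with add-one correction: never exactly zero."""
    null_values = np.asarray(null_values)
    return float((1 + int((null_values >= observed).sum())) / (1 + null_values.size))
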