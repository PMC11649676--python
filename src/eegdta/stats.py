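"""Rank-based comparison of classifier accuracy distributions.

Accuracy samples are small and not normal, so families are compared with the
two-sided Mann-Whitney U test: under the null, a draw from one group is as
likely to exceed a draw from the other as vice versa. The exact null
distribution is used for small tie-free samples (n_a * n_b <= 400); larger
or tied samples fall back to the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

__all__ = ["ComparisonResult", "mann_whitney_u"]


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool


def mann_whitney_u(a, b, group_a: str = "a", group_b: str = "b",
                   alpha: float = 0.05) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    ``u_statistic`` is the U of the first sample (midrank ties), so swapping
    the samples maps U to ``n_a * n_b - U`` with the same p-value.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) \
        else "asymptotic"
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(group_a, group_b, float(res.statistic), p,
                            len(a), len(b), p < alpha)
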