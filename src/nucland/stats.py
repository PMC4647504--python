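"""Rank-based two-sample tests shared by the analysis modules.

Both the marker-vs-DAPI comparison and the radial-profile comparison use the
two-sided Wilcoxon rank-sum / Mann-Whitney U test with continuity correction
(normal approximation with tie correction), one exchangeable value per
nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RankTestResult", "rank_sum_test"]


@dataclass
class RankTestResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    n_x: int
    n_y: int
    median_difference: float


def rank_sum_test(x, y) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test with continuity correction.

    Uses the normal approximation with tie correction (the asymptotic,
    continuity-corrected form), matching R's ``wilcox.test(..., correct=TRUE,
    exact=FALSE)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True, method="asymptotic")
    return RankTestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_x=int(x.size),
        n_y=int(y.size),
        median_difference=float(np.median(x) - np.median(y)),
    )
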