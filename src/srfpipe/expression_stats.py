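"""Convenience statistics for replicate expression measurements.

The two-sample t-test here is a utility for flagging knockdown effects on
replicate values; the dependency filter itself is a plain fold-change rule
and does not use it.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["fold_change_ttest"]


def fold_change_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test on two replicate groups.

    Returns (t statistic, two-sided p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two replicates")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
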