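"""Two-sample Kolmogorov-Smirnov screening of features between groups.

The KS statistic is the supremum gap between the two empirical CDFs; it is
distribution-free and invariant under monotone transforms, which suits
features whose scales differ wildly (counts vs. seconds).  P-values use the
two-sided asymptotic KS distribution, appropriate at cohort sizes of a few
dozen per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedMetricError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float


def ks_two_sample(x, y) -> KSResult:
    """Exact sup-difference of the two ECDFs with an asymptotic p-value.

    NaNs are dropped; each sample must retain at least 2 values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise UndefinedMetricError(
            f"KS test needs >=2 present values per sample "
            f"(got {x.size} and {y.size})")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return KSResult(statistic=float(res.statistic),
                    p_value=float(min(res.pvalue, 1.0)))


def screen_features(matrix) -> pd.DataFrame:
    """KS-screen every feature column of a FeatureMatrix between groups.

    Returns a DataFrame with columns feature, statistic, p_value, sorted by
    p_value.  Features with too few present values in a group are skipped
    with a warning.
    """
    mci = matrix.labels == "MCI"
    rows = []
    for col in matrix.data.columns:
        x = matrix.data.loc[mci, col].to_numpy()
        y = matrix.data.loc[~mci, col].to_numpy()
        try:
            res = ks_two_sample(x, y)
        except UndefinedMetricError as exc:
            logger.warning("skipping feature %s: %s", col, exc)
            continue
        rows.append((col, res.statistic, res.p_value))
    return (pd.DataFrame(rows, columns=["feature", "statistic", "p_value"])
            .sort_values("p_value", kind="stable")
            .reset_index(drop=True))
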