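"""Two-group comparison statistics for per-nucleus measurements.

Per-cell metrics from two treatment groups are compared with the
independent-samples Wilcoxon rank-sum (Mann-Whitney U) test, two-sided;
group variability is summarized by mean ± sample SD and by the coefficient
of variation (CV = SD / mean × 100).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

#: minimum per-group cell count below which a warning is issued
MIN_GROUP_SIZE = 255


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of x, p-value).

    ``mode="exact"`` enumerates the exact null distribution of U (valid for
    tie-free samples); ``"normal"`` uses the normal approximation with tie
    and continuity corrections; ``"auto"`` picks exact when n1 + n2 <= 20
    and the pooled sample is tie-free.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 20 and not has_ties) else "normal"
    if mode == "exact":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def coefficient_of_variation(values) -> float:
    """CV in percent: sample SD (n−1 denominator) / mean × 100.

    NaN when the mean is non-positive (undefined for this convention).
    Requires n >= 2.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("CV requires at least two values")
    mean = v.mean()
    if mean <= 0:
        return math.nan
    return float(v.std(ddof=1) / mean * 100.0)


def format_p(p: float) -> str:
    """Human-readable p: full precision is kept internally, reports never
    print an impossible ``0.000``."""
    if math.isnan(p):
        return "nan"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class GroupComparison:
    """Two-group summary of one per-nucleus metric."""

    metric_name: str
    group_labels: Tuple[str, str]
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    u_stat: float
    p_value: float
    cv1_pct: float
    cv2_pct: float
    n_excluded1: int = 0
    n_excluded2: int = 0

    def summary_row(self) -> dict:
        return {
            "metric": self.metric_name,
            "group1": self.group_labels[0],
            "group2": self.group_labels[1],
            "n1": self.n1,
            "n2": self.n2,
            "mean1": self.mean1,
            "mean2": self.mean2,
            "sd1": self.sd1,
            "sd2": self.sd2,
            "cv1_pct": self.cv1_pct,
            "cv2_pct": self.cv2_pct,
            "u_stat": self.u_stat,
            "p_value": self.p_value,
            "p_formatted": format_p(self.p_value),
            "n_excluded1": self.n_excluded1,
            "n_excluded2": self.n_excluded2,
        }


def _extract(measurements: Sequence, metric: str):
    values, n_excluded = [], 0
    for rec in measurements:
        v = rec[metric] if isinstance(rec, dict) else getattr(rec, metric)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_excluded += 1
        else:
            values.append(float(v))
    return np.asarray(values), n_excluded


def compare_groups(
    measurements_a: Sequence,
    measurements_b: Sequence,
    metric: str,
    group_labels: Tuple[str, str] = ("group1", "group2"),
    mode: str = "auto",
    min_group_size: Optional[int] = MIN_GROUP_SIZE,
) -> GroupComparison:
    """Compare one metric between two groups of nucleus measurements.

    Undefined (NaN) values are excluded and counted.  Groups smaller than
    ``min_group_size`` cells trigger a warning, not an error, so desk-scale
    analyses still run.
    """
    a, excl_a = _extract(measurements_a, metric)
    b, excl_b = _extract(measurements_b, metric)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"all values of {metric!r} are undefined in one group")
    if min_group_size and (a.size < min_group_size or b.size < min_group_size):
        warnings.warn(
            f"group sizes {a.size}/{b.size} below the recommended minimum of "
            f"{min_group_size} cells",
            stacklevel=2,
        )
    u, p = wilcoxon_rank_sum(a, b, mode=mode)
    return GroupComparison(
        metric_name=metric,
        group_labels=tuple(group_labels),
        n1=int(a.size),
        n2=int(b.size),
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        sd1=float(a.std(ddof=1)) if a.size > 1 else math.nan,
        sd2=float(b.std(ddof=1)) if b.size > 1 else math.nan,
        u_stat=u,
        p_value=p,
        cv1_pct=coefficient_of_variation(a) if a.size > 1 else math.nan,
        cv2_pct=coefficient_of_variation(b) if b.size > 1 else math.nan,
        n_excluded1=excl_a,
        n_excluded2=excl_b,
    )
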