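"""Statistical comparisons for the porosity and connection analyses.

Two tests mirror the quantitative analysis: (1) projected canalicular
porosity of the youngest-ranked regions against all older-ranked regions
(two-sample Student's t-test, equal variance by default, with a Pearson
correlation of porosity against rank reported alongside, and group medians
recorded since a t-test formally compares means); (2) Pearson correlation
between per-lacuna connection counts N.Conn and the neighboring older
region's normalized mean GV, with the p-value from the t-transform
``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.
All p-values are two-sided; the significance level is 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    alpha: float = ALPHA
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def porosity_group_test(
    records,
    equal_var: bool = True,
    alpha: float = ALPHA,
) -> TestResult:
    """Youngest-region porosities vs older-region porosities.

    ``records`` is an iterable of (rank, pcan_p) pairs pooled over samples;
    group A holds rank-1 values, group B all older ranks.  Degenerate
    zero-variance inputs are handled explicitly: identical groups give
    statistic 0, p = 1; exactly separated constant groups give an infinite
    statistic with p = 0 and a flag.
    """
    pairs = [(int(r), float(p)) for r, p in records if np.isfinite(p)]
    young = np.array([p for r, p in pairs if r == 1])
    older = np.array([p for r, p in pairs if r > 1])
    if len(young) == 0 or len(older) == 0:
        raise ValueError("both rank groups must be non-empty")
    extra = {
        "median_young": float(np.median(young)),
        "median_older": float(np.median(older)),
    }
    ranks = np.array([r for r, _ in pairs], dtype=float)
    vals = np.array([p for _, p in pairs])
    if len(pairs) >= 3 and np.ptp(ranks) > 0 and np.ptp(vals) > 0:
        r_corr, p_corr = sps.pearsonr(ranks, vals)
        extra["pearson_r_vs_rank"] = float(r_corr)
        extra["pearson_p_vs_rank"] = float(p_corr)
    flags = []
    if np.ptp(young) == 0 and np.ptp(older) == 0:  # constant groups
        if young[0] == older[0]:
            stat, p = 0.0, 1.0
        else:
            stat, p = float("inf"), 0.0
            flags.append("zero within-group variance: exact separation")
    else:
        stat, p = sps.ttest_ind(young, older, equal_var=equal_var)
        stat, p = float(stat), float(p)
    return TestResult(
        name="porosity_young_vs_older_ttest",
        statistic=stat,
        p_value=p,
        n=(len(young), len(older)),
        alpha=alpha,
        flags=flags,
        extra=extra,
    )


def connection_correlation(records, alpha: float = ALPHA) -> TestResult:
    """Pearson correlation of N.Conn against the older neighbor's norm. mean GV.

    ``records`` is an iterable of (n_conn, neighbor_norm_gv) pairs; at
    least three are required and both variables must vary.
    """
    pairs = [(float(a), float(b)) for a, b in records]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 lacuna records, got {len(pairs)}")
    x = np.array([a for a, _ in pairs])
    y = np.array([b for _, b in pairs])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the correlated variables")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        name="n_conn_vs_neighbor_norm_gv_pearson",
        statistic=float(r),
        p_value=float(p),
        n=(len(pairs),),
        alpha=alpha,
        extra={"r": float(r)},
    )
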