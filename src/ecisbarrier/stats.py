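"""Group-comparison statistics and the LDH background correction.

Two-tailed unpaired t-tests (pooled variance) for two-group comparisons,
one-way ANOVA with Tukey's HSD post-test for three or more groups, the
conventional significance-star mapping, and the spectrophotometric LDH
signal computation (A490 minus the instrument's A680 background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "STAR_THRESHOLDS",
    "ComparisonResult",
    "AnovaTukeyResult",
    "t_test_two_tailed",
    "anova_tukey",
    "p_to_stars",
    "ldh_signal",
    "ldh_group_summary",
]

#: inclusive p-value thresholds for the star annotation
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    """Map a p-value to its star annotation.

    Thresholds are inclusive: * p <= 0.05, ** p <= 0.01, *** p <= 0.001,
    **** p <= 0.0001; anything above 0.05 is "ns".
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise group comparison."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    method: str  # "t_two_tailed" or "anova_tukey"
    stars: str = field(default="")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        expected = p_to_stars(self.p_value)
        if self.stars == "":
            object.__setattr__(self, "stars", expected)
        elif self.stars != expected:
            raise ValueError("stars inconsistent with p_value")


@dataclass(frozen=True)
class AnovaTukeyResult:
    """One-way ANOVA F-test plus Tukey-HSD-adjusted pairwise comparisons."""

    f_statistic: float
    p_value: float
    pairwise: tuple  # of ComparisonResult


def _check_sample(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"sample {name!r} must be 1-D with n >= 2")
    return x


def t_test_two_tailed(x, y, group_a: str = "a", group_b: str = "b") -> ComparisonResult:
    """Unpaired, equal-variance (pooled), two-tailed t-test."""
    x = _check_sample(x, group_a)
    y = _check_sample(y, group_b)
    res = sps.ttest_ind(x, y, equal_var=True, alternative="two-sided")
    return ComparisonResult(
        group_a, group_b, float(res.statistic), float(res.pvalue), "t_two_tailed"
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's HSD post-test.

    ``groups`` maps group name to sample.  Requires at least three groups
    (use :func:`t_test_two_tailed` for two); adjusted pairwise p-values come
    from the studentized range distribution.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError(
            "anova_tukey needs >= 3 groups; use t_test_two_tailed for two groups"
        )
    samples = [_check_sample(groups[n], n) for n in names]
    f_stat, f_p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise.append(
                ComparisonResult(
                    names[i],
                    names[j],
                    float(hsd.statistic[i, j]),
                    float(min(max(hsd.pvalue[i, j], 0.0), 1.0)),
                    "anova_tukey",
                )
            )
    return AnovaTukeyResult(float(f_stat), float(f_p), tuple(pairwise))


def ldh_signal(a490, a680):
    """Background-corrected LDH absorbance: A490 − A680, per well.

    The 680 nm reading is the instrument background.  Negative corrected
    values are physically possible with noisy near-blank wells and are
    returned as-is.
    """
    a490 = np.asarray(a490, dtype=float)
    a680 = np.asarray(a680, dtype=float)
    if a490.shape != a680.shape:
        raise ValueError("A490 and A680 must have the same shape")
    out = a490 - a680
    return float(out) if out.ndim == 0 else out


def ldh_group_summary(ldh_table) -> "pd.DataFrame":
    """Mean ± SD of the background-corrected LDH signal per group × timepoint.

    ``ldh_table`` is the long DataFrame produced by
    :func:`ecisbarrier.synthetic.simulate_ldh` (columns well_id, group,
    timepoint_h, A490, A680).
    """
    import pandas as pd

    df = ldh_table.copy()
    df["signal"] = ldh_signal(df["A490"].to_numpy(), df["A680"].to_numpy())
    out = (
        df.groupby(["group", "timepoint_h"], sort=False)["signal"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out
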