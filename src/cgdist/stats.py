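"""Two-group comparison of per-oocyte measurements.

Mirrors the classical "independent samples t-test, mean ± SD, p < alpha"
reporting used for I_cgd and CG density: pooled-variance Student's t by
default (df = n_a + n_b - 2), Welch's correction available by flag,
two-sided p-values, no multiple-testing correction (one contrast per
measurement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float  # sample SD, n-1 denominator

    def __str__(self) -> str:
        return f"{self.label}: {self.mean:.3f} ± {self.sd:.3f} (n={self.n})"


@dataclass(frozen=True)
class GroupComparison:
    group_a: GroupSummary
    group_b: GroupSummary
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    alpha: float
    significant: bool
    variant: str  # {pooled, welch}

    def summary(self) -> str:
        star = "significant" if self.significant else "not significant"
        return (
            f"{self.group_a} vs {self.group_b} | t={self.t_statistic:.3f} "
            f"df={self.degrees_of_freedom:.1f} p={self.p_value:.4g} "
            f"({star} at alpha={self.alpha})"
        )


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.05,
    variant: str = "pooled",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Independent two-sample t-test with mean ± SD reporting.

    Raises
    ------
    InsufficientDataError
        If either group has fewer than 2 finite values.
    DegenerateDataError
        If both groups have zero variance and equal means (t undefined).
    """
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    for name, arr in (("a", a), ("b", b)):
        if arr.ndim != 1 or len(arr) < 2:
            raise InsufficientDataError(f"group {name} needs >= 2 values, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"group {name} contains non-finite values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0 and a.mean() == b.mean():
        raise DegenerateDataError(
            "both groups constant with equal means: t statistic undefined"
        )
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = float(res.df)
    p = float(res.pvalue)
    return GroupComparison(
        group_a=GroupSummary(labels[0], len(a), float(a.mean()), float(a.std(ddof=1))),
        group_b=GroupSummary(labels[1], len(b), float(b.mean()), float(b.std(ddof=1))),
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
        variant=variant,
    )
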