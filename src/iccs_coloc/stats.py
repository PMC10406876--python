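"""Group-comparison statistics.

One-way ANOVA across all groups, then every pairwise comparison via a
variance-gated two-sample t-test: a two-sided F-test of the variance
ratio decides between the pooled-variance (homoscedastic) and Welch
(heteroscedastic) t-test.  Pairwise significance is flagged against a
Bonferroni-corrected per-comparison alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError


@dataclass
class GroupSample:
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValidationError(f"group {self.name}: need >= 2 values")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"group {self.name}: values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    variance_F_p: float
    t_variant: str  # "homoscedastic" | "heteroscedastic"
    t_stat: float
    t_p: float
    significant: bool


@dataclass
class ComparisonReport:
    anova_F: float
    anova_p: float
    pairwise: list[PairwiseComparison]
    alpha_family: float
    alpha_bonferroni: float
    group_names: list[str] = field(default_factory=list)


def one_way_anova(groups: list[GroupSample]) -> tuple[float, float]:
    """Classical between/within mean-square F with (k-1, N-k) df."""
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    samples = [g.values for g in groups]
    grand = np.concatenate(samples)
    ss_within = sum(np.sum((s - s.mean()) ** 2) for s in samples)
    ss_between = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
    if ss_within == 0 and ss_between == 0:
        raise DegenerateInputError("all groups constant and equal: F undefined")
    k = len(samples)
    N = len(grand)
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def variance_gate_t_test(
    a: GroupSample, b: GroupSample, alpha_var: float = 0.05
) -> tuple[float, str, float, float]:
    """Two-sided variance-ratio F-test, then the matching t-test.

    Returns ``(variance_F_p, t_variant, t_stat, t_p)``.  The pooled
    t-test is used when the F-test does not reject at ``alpha_var``,
    Welch's otherwise; both t-tests are two-tailed.
    """
    va = a.values.var(ddof=1)
    vb = b.values.var(ddof=1)
    if va == 0 and vb == 0:
        if a.values.mean() == b.values.mean():
            raise DegenerateInputError("zero variance in both groups, equal means")
        var_p = 1.0
    else:
        F = va / vb if vb > 0 else np.inf
        dfa, dfb = a.n - 1, b.n - 1
        if np.isinf(F):
            var_p = 0.0
        else:
            p_one = sps.f.sf(F, dfa, dfb)
            var_p = float(2 * min(p_one, 1 - p_one))
    variant = "homoscedastic" if var_p >= alpha_var else "heteroscedastic"
    t_stat, t_p = sps.ttest_ind(
        a.values, b.values, equal_var=(variant == "homoscedastic")
    )
    return float(var_p), variant, float(t_stat), float(t_p)


def bonferroni_alpha(alpha_family: float, m: int) -> float:
    """Per-comparison threshold: family-wise alpha divided by m tests."""
    if not (0 < alpha_family < 1):
        raise ValidationError("alpha_family must be in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha_family / m


def compare_groups(
    groups: list[GroupSample],
    alpha_family: float = 0.05,
    alpha_var: float = 0.05,
) -> ComparisonReport:
    """Omnibus ANOVA plus all Bonferroni-gated pairwise t-tests.

    Pairwise flags use the Bonferroni-corrected threshold at full
    precision (e.g. 0.05/3, not the rounded 0.0167); the omnibus p is
    reported alongside and does not gate the pairwise tests.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValidationError("group names must be unique")
    F, p = one_way_anova(groups)
    pairs = list(combinations(sorted(groups, key=lambda g: g.name), 2))
    alpha_b = bonferroni_alpha(alpha_family, len(pairs))
    pairwise = []
    for ga, gb in pairs:
        var_p, variant, t_stat, t_p = variance_gate_t_test(ga, gb, alpha_var)
        pairwise.append(
            PairwiseComparison(
                pair=(ga.name, gb.name),
                variance_F_p=var_p,
                t_variant=variant,
                t_stat=t_stat,
                t_p=t_p,
                significant=bool(t_p < alpha_b),
            )
        )
    return ComparisonReport(
        anova_F=F,
        anova_p=p,
        pairwise=pairwise,
        alpha_family=alpha_family,
        alpha_bonferroni=alpha_b,
        group_names=sorted(names),
    )
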