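"""Condition-vs-control statistics: one-way ANOVA plus Dunnett's test.

Treated conditions are compared against the shared vehicle control with a
one-way fixed-effects ANOVA followed by Dunnett's many-to-one post-hoc
test (two-sided, classical pooled-variance form). The familywise-adjusted
p-values come from the multivariate-t distribution of the comparison
statistics; with a single treatment the adjustment collapses to an
ordinary two-sample pooled t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupedMeasurements:
    """Replicate values per group, with one group designated as control."""

    control: str
    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} missing")
        self.groups = {k: np.asarray(v, dtype=float).ravel() for k, v in self.groups.items()}
        for name, vals in self.groups.items():
            if vals.size < 2:
                raise ValueError(f"group {name!r} needs >= 2 replicate values")

    @property
    def treatments(self) -> list[str]:
        return [g for g in self.groups if g != self.control]


@dataclass
class DunnettResult:
    """ANOVA F/p plus per-treatment Dunnett-adjusted comparisons."""

    f_statistic: float
    p_anova: float
    comparisons: pd.DataFrame  # treatment, mean_diff, statistic, p_adjusted, significant
    alpha: float = 0.05


def anova_oneway(groups: GroupedMeasurements) -> tuple[float, float]:
    """Standard one-way fixed-effects ANOVA over all groups."""
    samples = list(groups.groups.values())
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if all(np.ptp(s) == 0 for s in samples):
        means = [s.mean() for s in samples]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance with unequal means: F undefined")
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def dunnett_test(
    groups: GroupedMeasurements, alpha: float = 0.05, seed: int | None = 0
) -> DunnettResult:
    """Dunnett many-to-one comparison of every treatment against control.

    Two-sided, pooled error variance across all groups. ``seed`` fixes the
    quasi-random evaluation of the multivariate-t probabilities so repeated
    runs agree to well below any decision threshold.
    """
    f, p_anova = anova_oneway(groups)
    control = groups.groups[groups.control]
    treatments = groups.treatments
    if not treatments:
        raise ValueError("no treatment groups to compare against control")
    samples = [groups.groups[t] for t in treatments]
    res = sps.dunnett(*samples, control=control, alternative="two-sided", rng=seed)
    comparisons = pd.DataFrame(
        {
            "treatment": treatments,
            "mean_diff": [s.mean() - control.mean() for s in samples],
            "statistic": res.statistic,
            "p_adjusted": res.pvalue,
            "significant": res.pvalue < alpha,
        }
    )
    return DunnettResult(f, p_anova, comparisons, alpha)


def compare_to_control(
    table: pd.DataFrame,
    value_col: str,
    condition_col: str = "condition",
    control: str = "vehicle",
    alpha: float = 0.05,
    seed: int | None = 0,
) -> DunnettResult:
    """ANOVA + Dunnett on a long-form replicate table (one row per replicate)."""
    groups = {
        str(cond): sub[value_col].to_numpy(float)
        for cond, sub in table.groupby(condition_col, sort=True)
    }
    return dunnett_test(GroupedMeasurements(control=control, groups=groups), alpha=alpha, seed=seed)
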