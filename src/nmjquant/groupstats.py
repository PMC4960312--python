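"""Group comparisons and reporting conventions for per-NMJ estimates.

Values are reported as mean +/- s.e.m. with n = number of NMJs. Two groups
are compared with a two-tailed Student's t-test (pooled variance by
default). Three or more groups are first screened with a variance
homogeneity test (Brown-Forsythe, i.e. median-centered Levene); if
variances are homogeneous, one-way ANOVA with Tukey's HSD post hoc follows,
otherwise a Welch omnibus with the Games-Howell post hoc.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["GroupSummary", "ComparisonResult", "summarize", "compare_pair", "compare_groups", "stars"]


def stars(p: float) -> str:
    """Figure-style significance stars at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    """mean +/- s.e.m. (n) for one genotype and measure."""

    label: str
    mean: float
    sem: float  # nan for n == 1
    n: int

    def __str__(self) -> str:
        if math.isnan(self.sem):
            return f"{self.label}: {self.mean:.4g} (n={self.n}, s.e.m. undefined)"
        return f"{self.label}: {self.mean:.4g}±{self.sem:.3g} (n={self.n})"


def summarize(values, label: str = "") -> GroupSummary:
    """mean and s.e.m. (sample s.d. with n-1 denominator over sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarize an empty group")
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
    return GroupSummary(label=label, mean=float(x.mean()), sem=sem, n=int(x.size))


@dataclass
class ComparisonResult:
    """Outcome of a group comparison, recording the branch actually taken."""

    test_used: str  # t_test | anova_tukey | anova_games_howell
    statistic: float
    p_value: float
    variance_stat: float = float("nan")
    variance_p: float = float("nan")
    pairwise: pd.DataFrame | None = None
    summaries: list = field(default_factory=list)

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def compare_pair(
    group_a,
    group_b,
    labels: tuple[str, str] = ("a", "b"),
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-tailed two-sample Student's t-test (pooled variance by default;
    ``equal_var=False`` gives Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("compare_pair needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no variance anywhere
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        test_used="t_test",
        statistic=float(t_stat),
        p_value=float(p),
        summaries=[summarize(a, labels[0]), summarize(b, labels[1])],
    )


def compare_groups(groups: dict, alpha_var: float = 0.05) -> ComparisonResult:
    """Compare >= 3 groups with the variance-screened branching procedure.

    Brown-Forsythe first: p >= ``alpha_var`` selects one-way ANOVA with
    Tukey HSD pairwise comparisons; p < ``alpha_var`` selects the Welch
    omnibus with Games-Howell pairwise comparisons (Welch-Satterthwaite
    degrees of freedom, studentized-range quantiles).
    """
    if len(groups) < 3:
        raise ValidationError("compare_groups needs >= 3 groups (use compare_pair for 2)")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} has n={v.size}; need n >= 2")
    var_stat, var_p = stats.levene(*arrays.values(), center="median")
    long = pd.DataFrame(
        [(k, x) for k, v in arrays.items() for x in v], columns=["group", "value"]
    )
    if var_p >= alpha_var:
        test_used = "anova_tukey"
        omni_stat, omni_p = stats.f_oneway(*arrays.values())
        pairwise = pg.pairwise_tukey(data=long, dv="value", between="group")
        pairwise = pairwise.rename(columns={"p_tukey": "p", "p-tukey": "p"})
    else:
        test_used = "anova_games_howell"
        welch = pg.welch_anova(data=long, dv="value", between="group")
        omni_stat = float(welch["F"].iloc[0])
        pcol = "p_unc" if "p_unc" in welch.columns else "p-unc"
        omni_p = float(welch[pcol].iloc[0])
        pairwise = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        pairwise = pairwise.rename(columns={"pval": "p"})
    pairwise = pairwise.loc[:, ["A", "B", "diff", "p"]].copy()
    pairwise["stars"] = pairwise["p"].map(stars)
    log.info(
        "variance test p=%.4g -> %s branch (omnibus p=%.4g)", var_p, test_used, omni_p
    )
    return ComparisonResult(
        test_used=test_used,
        statistic=float(omni_stat),
        p_value=float(omni_p),
        variance_stat=float(var_stat),
        variance_p=float(var_p),
        pairwise=pairwise,
        summaries=[summarize(v, k) for k, v in arrays.items()],
    )
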