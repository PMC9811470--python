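"""Shared statistics: robust outlier removal and group comparisons.

Outliers follow the median rule: a value is an outlier when it lies more
than 3 scaled median absolute deviations (MAD × 1.4826) from the group
median.  Group comparisons are one-way/two-way ANOVA followed by pairwise
(paired or Welch) t-tests with Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["GroupStats", "remove_outliers", "group_compare", "two_way_anova"]

MAD_SCALE = 1.4826
MAD_THRESHOLD = 3.0


def remove_outliers(
    values: np.ndarray,
    threshold: float = MAD_THRESHOLD,
    scale: float = MAD_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag values farther than ``threshold`` scaled MADs from the median.

    Returns ``(mask, filtered)`` where ``mask`` is True for outliers.  With
    fewer than 3 values the rule is a no-op (warned).  A constant series has
    zero MAD and flags nothing.  The rule is applied once per group, before
    any other analysis.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        logger.warning("fewer than 3 values; outlier removal skipped")
        return np.zeros(x.shape, dtype=bool), x.copy()
    med = np.median(x)
    smad = scale * np.median(np.abs(x - med))
    mask = np.abs(x - med) > threshold * smad
    return mask, x[~mask]


@dataclass
class GroupStats:
    """ANOVA result with Bonferroni-adjusted pairwise follow-ups."""

    design: str                     # one_way | two_way
    group_means: dict[str, float]
    group_sem: dict[str, float]
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame          # group_a, group_b, t, p_raw, p_bonferroni
    outlier_mask: dict[str, np.ndarray] = field(default_factory=dict)
    anova_table: pd.DataFrame | None = None


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"group_{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def group_compare(
    groups,
    paired: bool = False,
    alpha: float = 0.05,
    outlier_removal: bool = False,
) -> GroupStats:
    """One-way ANOVA across groups followed by Bonferroni pairwise t-tests.

    ``groups`` is a dict (name → values) or a sequence of arrays.  With
    ``paired=True`` the pairwise follow-ups are paired t-tests (groups must
    then have equal lengths); otherwise Welch t-tests.  Bonferroni-adjusted
    p = min(1, m · p_raw) for m pairwise comparisons.  Optional outlier
    removal applies the median rule once per group before the ANOVA.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in g.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    masks = {}
    if outlier_removal:
        for name in g:
            masks[name], g[name] = remove_outliers(g[name])
    if paired:
        lengths = {len(v) for v in g.values()}
        if len(lengths) != 1:
            raise ValueError("paired comparisons need equal group lengths")

    names = list(g)
    f, p = sps.f_oneway(*[g[n] for n in names])
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        if paired:
            res = sps.ttest_rel(g[a], g[b])
        else:
            res = sps.ttest_ind(g[a], g[b], equal_var=False)
        rows.append(dict(
            group_a=a, group_b=b, t=float(res.statistic),
            p_raw=float(res.pvalue),
            p_bonferroni=float(min(1.0, m * res.pvalue)),
        ))
    return GroupStats(
        design="one_way",
        group_means={n: float(np.mean(v)) for n, v in g.items()},
        group_sem={n: float(np.std(v, ddof=1) / np.sqrt(len(v))) for n, v in g.items()},
        f_statistic=float(f),
        p_value=float(p),
        pairwise=pd.DataFrame(rows),
        outlier_mask=masks,
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    paired: bool = False,
    interaction: bool = True,
) -> GroupStats:
    """Two-way ANOVA on a long-format table, plus Bonferroni follow-ups.

    Factors are taken explicitly as column names.  The reported F and p are
    for ``factor_a`` (the factor of interest); the full ANOVA table is kept
    on the result.  Pairwise follow-ups compare the levels of ``factor_a``
    pooled over ``factor_b``.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data[[value, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "fa", "fb"]
    formula = "y ~ C(fa) * C(fb)" if interaction else "y ~ C(fa) + C(fb)"
    table = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=2)

    levels = {str(lv): df.loc[df["fa"] == lv, "y"].to_numpy() for lv in df["fa"].unique()}
    sub = group_compare(levels, paired=paired)
    return GroupStats(
        design="two_way",
        group_means=sub.group_means,
        group_sem=sub.group_sem,
        f_statistic=float(table.loc["C(fa)", "F"]),
        p_value=float(table.loc["C(fa)", "PR(>F)"]),
        pairwise=sub.pairwise,
        anova_table=table,
    )
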