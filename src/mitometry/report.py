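"""Two-group comparison, significance stars and report assembly.

The test choice (Welch's t vs Mann–Whitney) is always an explicit flag;
it is never selected automatically.  More than two groups is out of
scope and raises, pointing users at pairwise comparisons.

Star convention (strict inequalities): p < 0.05 "*", p < 0.01 "**",
p < 0.001 "***", p < 0.0001 "****", otherwise "ns".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))
EXACT_MW_MAX_COMBINED_N = 20

WELCH_T = "welch_t"
MANN_WHITNEY = "mann_whitney"


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str
    statistic: float
    p_value: float
    stars: str
    degenerate: bool = False
    notes: str = ""


@dataclass
class ReportMetadata:
    """Blinded-workflow provenance: who fixed, imaged and quantified.

    Recorded verbatim; the tool cannot enforce blinding, only log it.
    """

    fixer_id: str = ""
    imager_id: str = ""
    quantifier_id: str = ""
    extra: dict = field(default_factory=dict)


def stars(p_value: float) -> str:
    """Map a p-value to its significance-star string."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p_value}")
    for thr, s in STAR_THRESHOLDS:
        if p_value < thr:
            return s
    return "ns"


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str,
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``mann_whitney`` uses the exact null distribution when the combined
    sample size is <= 20 (and there are no ties), otherwise the normal
    approximation with tie correction.  ``welch_t`` uses unequal-variance
    degrees of freedom; two identical constant groups are degenerate and
    reported as p = 1 with a flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if test == WELCH_T:
        if np.var(a) == 0 and np.var(b) == 0:
            degenerate_equal = np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]
            if degenerate_equal:
                return GroupComparison(
                    metric, group_a, group_b, a.size, b.size, test,
                    statistic=0.0, p_value=1.0, stars="ns", degenerate=True,
                    notes="zero variance in both groups; identical values",
                )
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):
            return GroupComparison(
                metric, group_a, group_b, a.size, b.size, test,
                statistic=0.0, p_value=1.0, stars="ns", degenerate=True,
                notes="undefined variance; p set to 1",
            )
    elif test == MANN_WHITNEY:
        method = "exact" if a.size + b.size <= EXACT_MW_MAX_COMBINED_N else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}; use {WELCH_T!r} or {MANN_WHITNEY!r}")
    p = min(p, 1.0)
    return GroupComparison(
        metric, group_a, group_b, int(a.size), int(b.size), test,
        statistic=stat, p_value=p, stars=stars(p),
    )


def mann_whitney_exact_bruteforce(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact Mann–Whitney p by full enumeration of group
    assignments.  Independent oracle for small samples (combined n <= 12).
    """
    from itertools import combinations

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    observed = u_stat(a, b)
    n_ab = len(a) * len(b)
    obs_dev = abs(observed - n_ab / 2.0)
    idx = range(len(pooled))
    count = total = 0
    for comb in combinations(idx, n_a):
        sel = set(comb)
        ga = [pooled[i] for i in idx if i in sel]
        gb = [pooled[i] for i in idx if i not in sel]
        u = u_stat(ga, gb)
        if abs(u - n_ab / 2.0) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return count / total


def compare_many_groups(*_args, **_kwargs):
    raise NotImplementedError(
        "more than two groups is not implemented (one-way ANOVA with "
        "Fisher's LSD is out of scope); run pairwise two-group comparisons"
    )


# ---------------------------------------------------------------------------
# report assembly


def compare_frame(
    df,
    metric: str,
    test: str,
    group_col: str = "group",
    value_col: str = "value",
    metric_col: str = "metric",
):
    """Run the two-group comparison on a tidy (group, metric, value) table."""
    sub = df[df[metric_col] == metric] if metric_col in df.columns else df
    groups = sorted(sub[group_col].unique())
    if len(groups) != 2:
        raise NotImplementedError(
            f"expected exactly 2 groups, found {len(groups)}: {groups}; "
            "more than two groups requires pairwise comparisons"
        )
    ga, gb = groups
    return compare_groups(
        sub.loc[sub[group_col] == ga, value_col].to_numpy(),
        sub.loc[sub[group_col] == gb, value_col].to_numpy(),
        test=test,
        metric=metric,
        group_a=str(ga),
        group_b=str(gb),
    )


def comparison_to_frame(comparisons: Sequence[GroupComparison]):
    import pandas as pd

    return pd.DataFrame([c.__dict__ for c in comparisons])


def markdown_report(
    comparisons: Sequence[GroupComparison],
    metadata: Optional[ReportMetadata] = None,
) -> str:
    lines = ["# Group comparison report", ""]
    if metadata is not None:
        lines += [
            "## Provenance (blinded workflow)",
            f"- fixation: {metadata.fixer_id or 'unrecorded'}",
            f"- imaging: {metadata.imager_id or 'unrecorded'}",
            f"- quantification: {metadata.quantifier_id or 'unrecorded'}",
            "",
        ]
    lines += [
        "| metric | groups | n | test | statistic | p | stars |",
        "|---|---|---|---|---|---|---|",
    ]
    for c in comparisons:
        lines.append(
            f"| {c.metric} | {c.group_a} vs {c.group_b} | {c.n_a}/{c.n_b} "
            f"| {c.test} | {c.statistic:.4g} | {c.p_value:.4g} | {c.stars} |"
        )
    lines.append("")
    return "\n".join(lines)
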