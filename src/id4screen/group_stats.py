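"""Group comparisons and per-probe methylation/expression correlation.

Covers the box-plot style comparisons of target-gene expression between
receptor-status groups and PAM50 subtypes (unpaired Student's t, one-way ANOVA
with Bonferroni adjustment), the Wilcoxon rank-sum test, and the per-450K-probe
Pearson correlation of beta values against target expression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix, MethylationMatrix
from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, ...]
    statistic_name: str  # student_t | F | wilcoxon_W
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    group_summaries: tuple[FiveNumberSummary, ...] = field(default_factory=tuple)


def five_number_summary(values) -> FiveNumberSummary:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return FiveNumberSummary(
        minimum=float(v.min()), q1=float(q1), median=float(med),
        q3=float(q3), maximum=float(v.max()), n=int(v.size),
    )


def _clean(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    return v[np.isfinite(v)]


def student_t_test(
    x, y, labels: tuple[str, str] = ("A", "B"), welch: bool = False
) -> GroupComparison:
    """Unpaired two-sample t-test, pooled-variance by default.

    Degenerate conventions: zero pooled variance with equal means gives
    t = 0, p = 1; unequal means with zero variance gives p = 0 with a warning.
    """
    xv, yv = _clean(x), _clean(y)
    if xv.size < 2 or yv.size < 2:
        raise DegenerateInputError("each group needs >= 2 observations")
    pooled_var = (
        ((xv.size - 1) * xv.var(ddof=1) + (yv.size - 1) * yv.var(ddof=1))
        / (xv.size + yv.size - 2)
    )
    summaries = (five_number_summary(xv), five_number_summary(yv))
    if pooled_var == 0.0:
        if xv.mean() == yv.mean():
            t, p = 0.0, 1.0
        else:
            warnings.warn("zero pooled variance with unequal means; p -> 0",
                          stacklevel=2)
            t = np.inf if xv.mean() > yv.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(xv, yv, equal_var=not welch)
    return GroupComparison(
        group_labels=labels, statistic_name="student_t",
        statistic=float(t), p_value=float(p), group_summaries=summaries,
    )


def one_way_anova(values, groups) -> GroupComparison:
    """One-way fixed-effects ANOVA over the levels of ``groups``.

    F = MS_between / MS_within on (k-1, N-k) degrees of freedom.  Identical
    group means with zero within-group variance give F = 0, p = 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(v)
    v, g = v[keep], g[keep]
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    samples = [v[g == lev] for lev in levels]
    for lev, s in zip(levels, samples):
        if s.size < 2:
            raise ValidationError(f"group {lev!r} has fewer than 2 members")
    if all(s.var() == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*samples)
    return GroupComparison(
        group_labels=tuple(str(lev) for lev in levels),
        statistic_name="F", statistic=float(f_stat), p_value=float(p),
        group_summaries=tuple(five_number_summary(s) for s in samples),
    )


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni family-wise correction: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def _rank_sum_exact_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of midranks to x.

    P(|W - E[W]| >= |w_obs - E[W]|) over the C(n, n_x) equally likely splits;
    valid under ties because the midrank multiset is fixed.
    """
    expected = n_x * ranks.mean()
    dev = abs(w_obs - expected) - 1e-9  # tolerance for float midranks
    hits = total = 0
    for combo in itertools.combinations(range(ranks.size), n_x):
        total += 1
        if abs(ranks[list(combo)].sum() - expected) >= dev:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(
    x, y, exact_below: int = 12, labels: tuple[str, str] = ("A", "B")
) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    The statistic is W, the sum of the ranks of ``x`` in the pooled sample.
    For combined n <= ``exact_below`` the two-sided p is exact by full
    enumeration of rank splits; above that a normal approximation with tie
    correction and continuity correction is used.
    """
    xv, yv = _clean(x), _clean(y)
    if xv.size < 1 or yv.size < 1:
        raise DegenerateInputError("each group needs >= 1 observation")
    pooled = np.concatenate([xv, yv])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[: xv.size].sum())
    n1, n2 = xv.size, yv.size
    n = n1 + n2
    expected = n1 * (n + 1) / 2.0
    if n <= exact_below:
        p = _rank_sum_exact_p(ranks, n1, w)
    else:
        # normal approximation with tie correction
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var == 0.0:
            p = 1.0
        else:
            z = (abs(w - expected) - 0.5) / np.sqrt(var)  # continuity corrected
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return GroupComparison(
        group_labels=labels, statistic_name="wilcoxon_W",
        statistic=w, p_value=float(p),
        group_summaries=(five_number_summary(xv), five_number_summary(yv)),
    )


# ---------------------------------------------------------------------------
# probe-level methylation vs expression correlation


def probe_correlation_panel(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    target_gene: str,
    add_bh_column: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every probe's beta values with target expression.

    Returns one row per probe: ``probe_id``, ``pearson_r``, ``p_value``,
    ``promoter_flag``, ``n_used`` and a ``note`` column explaining missing
    correlations ("degenerate" for constant betas, "insufficient_pairs" for
    fewer than 3 complete pairs).  p-values are reported raw; an optional
    Benjamini-Hochberg column can be added.
    """
    from .assoc_screen import pearson_correlation

    if target_gene not in expr.values.index:
        raise ValidationError(f"target gene {target_gene!r} absent from expression")
    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("fewer than 3 samples shared by the two matrices")
    target = expr.values.loc[target_gene, shared].to_numpy(dtype=float)
    rows = []
    for probe in meth.probe_ids:
        betas = meth.betas.loc[probe, shared].to_numpy(dtype=float)
        keep = np.isfinite(betas) & np.isfinite(target)
        note = ""
        if keep.sum() < 3:
            r = p = np.nan
            note = "insufficient_pairs"
            n = int(keep.sum())
        elif np.ptp(betas[keep]) == 0 or np.ptp(target[keep]) == 0:
            r = p = np.nan
            note = "degenerate"
            n = int(keep.sum())
        else:
            r, p, n = pearson_correlation(target, betas)
        rows.append(
            {
                "probe_id": probe, "pearson_r": r, "p_value": p,
                "promoter_flag": bool(meth.annotation.loc[probe, "promoter"]),
                "n_used": n, "note": note,
            }
        )
    panel = pd.DataFrame(rows)
    if add_bh_column:
        from statsmodels.stats.multitest import multipletests

        mask = panel["p_value"].notna()
        adjusted = np.full(len(panel), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = multipletests(
                panel.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        panel["p_bh"] = adjusted
    return panel
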