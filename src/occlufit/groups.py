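"""Significance analysis of occlusion summaries (means, SDs, n).

The bundled study reports, for every paste and day, the mean ± SD of the %
occluded area in the with-saliva (S) and without-saliva (WS) groups of n = 7
specimens each, and marks per-day condition differences with superscript
letters.  Specimen-level values are not published, so all tests here operate
on summary statistics alone:

* Welch's unequal-variance t-test (Satterthwaite degrees of freedom) for the
  per-day S vs WS comparison — per-day SDs differ by up to threefold, so the
  pooled-variance test is offered only as a sensitivity variant;
* a one-way ANOVA whose between/within sums of squares are reconstructed
  exactly from the group summaries;
* Bonferroni adjustment over the days of a paste, reported side by side with
  the unadjusted p-values, since the family over which the original
  correction was applied is not stated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import OcclusionSeries

__all__ = [
    "DailyComparison",
    "DegenerateInputError",
    "welch_t_from_summary",
    "pooled_t_from_summary",
    "anova_oneway_from_summary",
    "comparison_table",
    "comparison_frame",
    "agreement_with_pattern",
]

WITH_SALIVA = "with_saliva"
WITHOUT_SALIVA = "without_saliva"


class DegenerateInputError(ValueError):
    """Raised when summaries carry no variability but differ in mean."""


@dataclass(frozen=True)
class DailyComparison:
    """One paste × day comparison between the two saliva conditions."""

    paste: str
    day: int
    mean_ws: float
    mean_s: float
    sd_ws: float
    sd_s: float
    n: int
    t_statistic: float
    df: float
    p_value: float
    p_adjusted: float
    significant: bool


def _check_summary(mean, sd, n, label):
    if n < 2:
        raise ValueError(f"group {label}: need n >= 2, got {n}")
    if sd < 0:
        raise ValueError(f"group {label}: sd must be >= 0, got {sd}")
    if not (np.isfinite(mean) and np.isfinite(sd)):
        raise ValueError(f"group {label}: non-finite summary")


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Welch two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom

    ``df = (v1/n1 + v2/n2)^2 / [ (v1/n1)^2/(n1-1) + (v2/n2)^2/(n2-1) ]``

    and a two-sided p-value.  When both SDs are zero the test is degenerate:
    equal means give ``(0, df, 1)`` by convention, unequal means raise
    :class:`DegenerateInputError`.
    """
    _check_summary(mean1, sd1, n1, "1")
    _check_summary(mean2, sd2, n2, "2")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise DegenerateInputError(
            "both groups have zero SD but different means; "
            "the t statistic is unbounded"
        )
    se1, se2 = sd1**2 / n1, sd2**2 / n2
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(t), float(df), float(p)


def pooled_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Student (pooled-variance) variant, for sensitivity analyses."""
    _check_summary(mean1, sd1, n1, "1")
    _check_summary(mean2, sd2, n2, "2")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise DegenerateInputError(
            "both groups have zero SD but different means"
        )
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t), float(n1 + n2 - 2), float(p)


def anova_oneway_from_summary(groups: Sequence[tuple[float, float, int]]):
    """One-way ANOVA reconstructed exactly from (mean, sd, n) summaries.

    The between-group sum of squares is ``Σ n_i (m_i - m̄)²`` about the
    grand (weighted) mean and the within-group sum of squares is
    ``Σ (n_i - 1) sd_i²``; both are exact functions of the summaries for
    balanced and unbalanced designs alike.  Returns ``(F, df1, df2, p)``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    means = np.array([g[0] for g in groups], dtype=float)
    sds = np.array([g[1] for g in groups], dtype=float)
    ns = np.array([g[2] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2 (insufficient replication)")
    if np.any(sds < 0):
        raise ValueError("sds must be non-negative")
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = len(groups) - 1.0, float(N - len(groups))
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def _pair_by_paste(
    table: Iterable[OcclusionSeries],
) -> dict[str, dict[str, OcclusionSeries]]:
    by_paste: dict[str, dict[str, OcclusionSeries]] = {}
    for s in table:
        by_paste.setdefault(s.paste, {})[s.condition] = s
    return by_paste


def comparison_table(
    table: Sequence[OcclusionSeries],
    alpha: float = 0.05,
    correction: str = "bonferroni",
    test: str = "welch",
) -> list[DailyComparison]:
    """Per-day WS vs S comparisons for every paste present in both conditions.

    ``correction="bonferroni"`` multiplies each p-value by the number of days
    compared within the paste (capped at 1); ``"none"`` leaves it untouched.
    The ``significant`` flag refers to the adjusted p-value.  Pastes missing
    one condition are skipped with a warning.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    tfunc = {"welch": welch_t_from_summary, "pooled": pooled_t_from_summary}[test]
    out: list[DailyComparison] = []
    for paste, conds in _pair_by_paste(table).items():
        if WITH_SALIVA not in conds or WITHOUT_SALIVA not in conds:
            warnings.warn(
                f"paste {paste!r} lacks one saliva condition; skipped",
                stacklevel=2,
            )
            continue
        ws, s = conds[WITHOUT_SALIVA], conds[WITH_SALIVA]
        if not np.array_equal(ws.days, s.days):
            warnings.warn(
                f"paste {paste!r}: day grids differ between conditions; skipped",
                stacklevel=2,
            )
            continue
        if ws.n != s.n:
            raise ValueError(
                f"paste {paste!r}: unequal group sizes not supported here"
            )
        m = len(ws.days) if correction == "bonferroni" else 1
        for i, day in enumerate(ws.days):
            t, df, p = tfunc(
                ws.means[i], ws.sds[i], ws.n, s.means[i], s.sds[i], s.n
            )
            p_adj = min(1.0, m * p)
            out.append(
                DailyComparison(
                    paste=paste,
                    day=int(day),
                    mean_ws=float(ws.means[i]),
                    mean_s=float(s.means[i]),
                    sd_ws=float(ws.sds[i]),
                    sd_s=float(s.sds[i]),
                    n=ws.n,
                    t_statistic=t,
                    df=df,
                    p_value=p,
                    p_adjusted=p_adj,
                    significant=p_adj < alpha,
                )
            )
    return out


def comparison_frame(comparisons: Sequence[DailyComparison]) -> pd.DataFrame:
    """Comparison report with superscript-style letters per condition.

    Letters mirror the usual table notation: the two conditions share the
    letter ``a`` when not significantly different, otherwise WS gets ``a``
    and S gets ``b``.
    """
    rows = []
    for c in comparisons:
        letter_s = "b" if c.significant else "a"
        rows.append(
            {
                "paste": c.paste,
                "day": c.day,
                "mean_ws": c.mean_ws,
                "sd_ws": c.sd_ws,
                "mean_s": c.mean_s,
                "sd_s": c.sd_s,
                "n": c.n,
                "t": c.t_statistic,
                "df": c.df,
                "p": c.p_value,
                "p_adj": c.p_adjusted,
                "letters": f"a/{letter_s}",
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows)


def agreement_with_pattern(
    comparisons: Sequence[DailyComparison],
    printed: Mapping[tuple[str, int], bool],
    use_adjusted: bool = False,
    alpha: float = 0.05,
) -> tuple[int, int, list[tuple[str, int]]]:
    """Score computed significance calls against a printed letter pattern.

    ``printed`` maps ``(paste, day)`` to whether the published table marked
    the two conditions with different letters.  Returns ``(n_agree, total,
    mismatches)``.
    """
    agree, mismatches = 0, []
    for c in comparisons:
        key = (c.paste, c.day)
        if key not in printed:
            continue
        p = c.p_adjusted if use_adjusted else c.p_value
        if (p < alpha) == printed[key]:
            agree += 1
        else:
            mismatches.append(key)
    total = agree + len(mismatches)
    return agree, total, mismatches
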