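"""Cohort comparison of within-session prevalence distributions.

Bartlett's variance test, Welch's unequal-variance t test, pooled-SD
Cohen's d, and Bonferroni adjustment, combined into all-pairs comparison
reports.  The unit of analysis is the within-session (or within-timeline)
prevalence value, one per session or individual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError

__all__ = [
    "CohortComparison",
    "bartlett_test",
    "welch_t_test",
    "cohens_d",
    "bonferroni_adjust",
    "compare_cohorts",
    "comparisons_to_frame",
]


@dataclass(frozen=True)
class CohortComparison:
    pair: tuple[str, str]
    bartlett_T: float
    bartlett_p: float
    welch_t: float
    welch_df: float
    welch_p: float
    cohen_d: float
    alpha_adjusted: float
    bartlett_significant: bool
    welch_significant: bool


def _check_sample(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DegenerateSampleError(f"sample {name!r} needs at least 2 values")
    return x


def bartlett_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-group Bartlett statistic (log-pooled-variance form) and its
    p-value from the chi-square distribution with 1 df."""
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    if np.var(x, ddof=1) == 0 or np.var(y, ddof=1) == 0:
        raise DegenerateSampleError("Bartlett test requires positive variance in both groups")
    T, p = stats.bartlett(x, y)
    return float(T), float(p)


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df, and two-sided p-value."""
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateSampleError("Welch t test requires variance in at least one sample")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference with pooled SD (n-1 weighting)."""
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise DegenerateSampleError("pooled SD is zero")
    return float((np.mean(x) - np.mean(y)) / np.sqrt(pooled_var))


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Family-wise significance level alpha/m for m comparisons."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def compare_cohorts(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[CohortComparison]:
    """All pairwise comparisons between labelled samples of session-level
    prevalence values; Bonferroni m = number of pairs; output ordered by
    label pair."""
    if len(samples) < 2:
        raise ValueError("need at least 2 labelled samples")
    labels = sorted(samples)
    pairs = list(itertools.combinations(labels, 2))
    alpha_adj = bonferroni_adjust(alpha, len(pairs))
    out = []
    for a, b in pairs:
        x, y = samples[a], samples[b]
        T, bp = bartlett_test(x, y)
        t, df, wp = welch_t_test(x, y)
        d = cohens_d(x, y)
        out.append(
            CohortComparison(
                pair=(a, b),
                bartlett_T=T,
                bartlett_p=bp,
                welch_t=t,
                welch_df=df,
                welch_p=wp,
                cohen_d=d,
                alpha_adjusted=alpha_adj,
                bartlett_significant=bp < alpha_adj,
                welch_significant=wp < alpha_adj,
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[CohortComparison]) -> pd.DataFrame:
    """Tabular report: one row per cohort pair."""
    return pd.DataFrame(
        {
            "pair": [f"{c.pair[0]} vs {c.pair[1]}" for c in comparisons],
            "bartlett_T": [c.bartlett_T for c in comparisons],
            "bartlett_p": [c.bartlett_p for c in comparisons],
            "welch_t": [c.welch_t for c in comparisons],
            "welch_df": [c.welch_df for c in comparisons],
            "welch_p": [c.welch_p for c in comparisons],
            "cohen_d": [c.cohen_d for c in comparisons],
            "alpha_adjusted": [c.alpha_adjusted for c in comparisons],
            "bartlett_significant": [c.bartlett_significant for c in comparisons],
            "welch_significant": [c.welch_significant for c in comparisons],
        }
    )
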