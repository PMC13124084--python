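"""Cohort-level, within-session, and monthly CDS prevalence and ratios.

Prevalence is the fraction of messages of one role containing at least one
marker from a pattern set.  The primary statistic pools messages across all
sessions (message-weighted); session-averaged values are computed separately
for the within-session analysis, which is also the unit of the cohort
statistical tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, Role, Session
from .errors import EmptyCohortError, EmptyDistributionError, UndefinedRatioError
from .lexicon import DistortionType
from .matcher import MatchAnnotation, annotations_to_frame

__all__ = [
    "PrevalenceReport",
    "RatioReport",
    "WithinSessionPrevalence",
    "MonthlyPrevalence",
    "cohort_prevalence",
    "within_session_prevalence",
    "monthly_prevalence",
    "prevalence_ratio",
]

#: pseudo-category meaning "any pattern of the whole lexicon"
OVERALL = "any"


@dataclass(frozen=True)
class PrevalenceReport:
    scope: str  # cohort | session | month
    role: Role
    category: str  # "any" or a category code
    numerator: int
    denominator: int

    @property
    def prevalence(self) -> float:
        return self.numerator / self.denominator


@dataclass(frozen=True)
class RatioReport:
    category: str
    role_pair: tuple[Role, Role]
    ratio: float


@dataclass(frozen=True)
class WithinSessionPrevalence:
    role: Role
    category: str
    values: pd.Series  # session_id -> within-session prevalence
    mean: float
    sd: float  # sample SD (n-1)


@dataclass(frozen=True)
class MonthlyPrevalence:
    role: Role
    category: str
    series: pd.Series  # month (Period) -> pooled prevalence
    level: float  # mean of monthly values
    interval: tuple[float, float]  # empirical 2.5/97.5 percentiles


def _as_frame(annotations: Iterable[MatchAnnotation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        return annotations
    return annotations_to_frame(annotations)


def _indicator_column(category: str | DistortionType | None) -> str:
    if category is None or category == OVERALL:
        return "any_cds"
    if isinstance(category, DistortionType):
        return category.code
    if category in {c.code for c in DistortionType}:
        return category
    return DistortionType.from_label(category).code


def _role_rows(frame: pd.DataFrame, role: Role) -> pd.DataFrame:
    return frame[frame["role"] == role.value]


def cohort_prevalence(
    annotations: Iterable[MatchAnnotation] | pd.DataFrame,
    role: Role,
    category: str | DistortionType | None = None,
) -> PrevalenceReport:
    """Pooled prevalence across all sessions (message-weighted)."""
    frame = _role_rows(_as_frame(annotations), role)
    if frame.empty:
        raise EmptyCohortError(f"no messages with role {role.value!r}")
    col = _indicator_column(category)
    return PrevalenceReport(
        scope="cohort",
        role=role,
        category=col if col != "any_cds" else OVERALL,
        numerator=int(frame[col].sum()),
        denominator=int(len(frame)),
    )


def within_session_prevalence(
    annotations: Iterable[MatchAnnotation] | pd.DataFrame,
    role: Role,
    category: str | DistortionType | None = None,
) -> WithinSessionPrevalence:
    """Per-session prevalence for one role; sessions without messages of
    that role do not contribute.  Summary SD is the sample SD (n-1 weighting;
    0.0 for a single contributing session)."""
    frame = _role_rows(_as_frame(annotations), role)
    if frame.empty:
        raise EmptyDistributionError(f"no sessions contribute for role {role.value!r}")
    col = _indicator_column(category)
    values = frame.groupby("session_id", sort=False)[col].mean()
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return WithinSessionPrevalence(
        role=role,
        category=col if col != "any_cds" else OVERALL,
        values=values,
        mean=float(values.mean()),
        sd=sd,
    )


def monthly_prevalence(
    annotations: Iterable[MatchAnnotation] | pd.DataFrame,
    sessions: Corpus | Sequence[Session],
    role: Role,
    category: str | DistortionType | None = None,
) -> MonthlyPrevalence:
    """Pooled prevalence per calendar month of session start date.

    Months without messages are omitted from the series.  The summary level
    is the mean of monthly values; the interval is the empirical 2.5th/97.5th
    percentile across months (a convention — the underlying construction of
    published monthly intervals is not specified).
    """
    session_list = sessions.sessions if isinstance(sessions, Corpus) else list(sessions)
    month_of = {s.session_id: pd.Period(s.start_date, freq="M") for s in session_list}
    frame = _role_rows(_as_frame(annotations), role).copy()
    if frame.empty:
        raise EmptyCohortError(f"no messages with role {role.value!r}")
    missing = set(frame["session_id"]) - set(month_of)
    if missing:
        raise KeyError(f"annotations reference unknown sessions: {sorted(missing)[:5]}")
    col = _indicator_column(category)
    frame["month"] = frame["session_id"].map(month_of)
    series = frame.groupby("month")[col].mean().sort_index()
    lo, hi = np.percentile(series.to_numpy(), [2.5, 97.5])
    return MonthlyPrevalence(
        role=role,
        category=col if col != "any_cds" else OVERALL,
        series=series,
        level=float(series.mean()),
        interval=(float(lo), float(hi)),
    )


def prevalence_ratio(
    annotations: Iterable[MatchAnnotation] | pd.DataFrame,
    role_1: Role,
    role_2: Role,
    category: str | DistortionType | None = None,
) -> RatioReport:
    """Ratio of pooled cohort prevalences between two roles."""
    frame = _as_frame(annotations)
    p1 = cohort_prevalence(frame, role_1, category)
    p2 = cohort_prevalence(frame, role_2, category)
    if p2.prevalence == 0:
        raise UndefinedRatioError(
            f"prevalence of role {role_2.value!r} for {p2.category!r} is zero"
        )
    return RatioReport(
        category=p1.category,
        role_pair=(role_1, role_2),
        ratio=p1.prevalence / p2.prevalence,
    )
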