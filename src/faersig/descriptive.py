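"""Descriptive surfaces: baseline characteristics, time-to-onset, outcomes.

Percentages are always computed against the block's own "data available"
denominator (records with a non-missing value for that block); no
imputation is performed.  Quantiles use linear interpolation between order
statistics; the early-onset windows are fixed at <=30 and <=90 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import time_to_onset_series
from .reports import OUTCOME_CODE_TO_LEVEL, OUTCOME_LEVELS, ReportSet
from .vocabulary import DrugLexicon, SmqCategory, category_membership, match_drug_mask

#: Severity precedence for records carrying several outcome codes: each
#: record counts toward exactly one level, the most severe present.
OUTCOME_PRECEDENCE: tuple[str, ...] = OUTCOME_LEVELS


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to 2 dp."""
    if denominator <= 0:
        raise ValueError("proportion needs a positive denominator")
    return round(100.0 * numerator / denominator, 2)


@dataclass(frozen=True)
class TtoSummary:
    """Median/quartile and early-window summary of time-to-onset (days)."""

    n_available: int
    median: float | None
    q1: float | None
    q3: float | None
    prop_30d: float | None  # % of available values <= 30 days
    prop_90d: float | None  # % of available values <= 90 days


def tto_summary(tto_values) -> TtoSummary:
    """Summarize available time-to-onset values (missing excluded upstream)."""
    values = np.asarray(pd.Series(tto_values).dropna(), dtype=float)
    n = values.size
    if n == 0:
        return TtoSummary(0, None, None, None, None, None)
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return TtoSummary(
        n_available=n,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        prop_30d=proportion(int((values <= 30).sum()), n),
        prop_90d=proportion(int((values <= 90).sum()), n),
    )


@dataclass(frozen=True)
class OutcomeProfile:
    """Counts and percentages per outcome level among available records."""

    counts: dict[str, int]
    percentages: dict[str, float | None]
    n_available: int


def _primary_outcome(reports: ReportSet) -> pd.Series:
    """One outcome level per report by severity precedence; NaN if missing."""
    oc = reports.outcomes.copy()
    ids = reports.demo["report_id"]
    if oc.empty:
        return pd.Series([None] * len(ids), index=ids.to_numpy(), dtype=object)
    oc["level"] = oc["outcome_code"].map(lambda c: OUTCOME_CODE_TO_LEVEL.get(c, c))
    rank = {lvl: i for i, lvl in enumerate(OUTCOME_PRECEDENCE)}
    oc["rank"] = oc["level"].map(lambda l: rank.get(l, len(rank)))
    best = oc.sort_values(["report_id", "rank"], kind="stable").groupby("report_id", sort=False)["level"].first()
    return best.reindex(ids.to_numpy())


def outcome_profile(reports: ReportSet) -> OutcomeProfile:
    """Severity profile; denominators are records with a known outcome."""
    primary = _primary_outcome(reports)
    available = primary.dropna()
    n = len(available)
    counts = {lvl: int((available == lvl).sum()) for lvl in OUTCOME_LEVELS}
    percentages = {
        lvl: (proportion(c, n) if n > 0 else None) for lvl, c in counts.items()
    }
    return OutcomeProfile(counts=counts, percentages=percentages, n_available=n)


def characteristics_table(
    reports: ReportSet,
    lexicon: DrugLexicon,
    categories: Sequence[SmqCategory],
) -> pd.DataFrame:
    """Long-form baseline characteristics of the target drug's event records.

    One column block per category plus the all-category total, restricted
    to reports that mention the target drug and at least one category.
    Sections: sex, age, reporting year, country, time-to-onset, outcome;
    each with its own "data available" denominator.
    """
    hd = match_drug_mask(reports, lexicon)
    member = category_membership(reports, list(categories))
    tto = time_to_onset_series(reports, lexicon)
    primary = _primary_outcome(reports)
    demo = reports.demo.set_index("report_id")
    year = reports.reporting_year
    year.index = demo.index

    groups = {"total": member.any(axis=1) & hd}
    for cat in categories:
        groups[cat.name] = member[cat.name] & hd

    rows: list[dict] = []

    def add(section, item, category, count=None, percent=None, value=None):
        rows.append(
            {
                "section": section, "item": item, "category": category,
                "count": count, "percent": percent, "value": value,
            }
        )

    for name, mask in groups.items():
        ids = mask[mask].index
        sub = demo.loc[ids]
        # sex
        sex = sub["sex"].dropna()
        for code, label in (("M", "male"), ("F", "female")):
            c = int((sex == code).sum())
            add("sex", label, name, count=c,
                percent=proportion(c, len(sex)) if len(sex) else None)
        add("sex", "data available", name, count=len(sex))
        # age
        age = sub["age"].dropna()
        if len(age):
            add("age", "mean", name, value=float(age.mean()))
            add("age", "sd", name, value=float(age.std(ddof=1)) if len(age) > 1 else None)
            add("age", "min", name, value=float(age.min()))
            add("age", "max", name, value=float(age.max()))
        add("age", "data available", name, count=len(age))
        # reporting year
        yr = year.loc[ids]
        for y in sorted(yr.unique()):
            c = int((yr == y).sum())
            add("year", str(int(y)), name, count=c, percent=proportion(c, len(yr)) if len(yr) else None)
        add("year", "data available", name, count=len(yr))
        # country
        ctry = sub["country"].dropna()
        for co in sorted(ctry.unique()):
            c = int((ctry == co).sum())
            add("country", co, name, count=c, percent=proportion(c, len(ctry)))
        add("country", "data available", name, count=len(ctry))
        # time to onset
        t = tto.loc[ids].dropna()
        s = tto_summary(t)
        add("time_to_onset", "median", name, value=s.median)
        add("time_to_onset", "q1", name, value=s.q1)
        add("time_to_onset", "q3", name, value=s.q3)
        add("time_to_onset", "prop_30d", name, percent=s.prop_30d)
        add("time_to_onset", "prop_90d", name, percent=s.prop_90d)
        add("time_to_onset", "data available", name, count=s.n_available)
        # outcome
        out = primary.loc[ids].dropna()
        for lvl in OUTCOME_LEVELS:
            c = int((out == lvl).sum())
            add("outcome", lvl, name, count=c,
                percent=proportion(c, len(out)) if len(out) else None)
        add("outcome", "data available", name, count=len(out))

    return pd.DataFrame(rows, columns=["section", "item", "category", "count", "percent", "value"])
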