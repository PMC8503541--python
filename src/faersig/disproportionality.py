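"""Case/non-case disproportionality statistics.

For a drug-event pair the database partitions into the 2x2 table

====================  ==========  =============
..                    event       no event
====================  ==========  =============
target drug           a           b
all other reports     c           d
====================  ==========  =============

with ``n_expected = n_drug * n_event / n_total`` the count expected under
independent reporting.  Two shrinkage-corrected statistics are computed:

* the information component ``IC = log2((a + 0.5) / (n_expected + 0.5))``,
  the observed/expected log-ratio with the +0.5 shrinkage that damps
  small-count noise and removes the zero singularity;
* the reporting odds ratio with Haldane-Anscombe correction,
  ``ROR = ((a+0.5)(d+0.5)) / ((b+0.5)(c+0.5))``, with a log-normal (Woolf)
  95% interval.

A pair is a *signal* when IC025 > 0, ROR025 > 1 and a >= 3 (all strict).

Interval methods for the IC: the default is the standard shrinkage-IC
asymptotic approximation
``ic025 = ic - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2)`` and
``ic975 = ic + 2.4 (a+0.5)^(-1/2) + 0.5 (a+0.5)^(-3/2)``; a gamma-quantile
credible interval (Poisson-gamma posterior of the observed/expected rate)
is selectable via ``ic_interval="gamma"``.  An "as-printed" ROR variant
equal to ``2**IC`` (the shrunk observed/expected ratio itself) is
selectable via ``ror_variant="as-printed"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gamma as _gamma

from .ingest import time_to_onset_series
from .reports import ReportSet
from .vocabulary import DrugLexicon, SmqCategory, category_membership, match_drug_mask

IC_INTERVAL_METHODS = ("approximation", "gamma")
ROR_VARIANTS = ("odds-ratio", "as-printed")

TOTAL_LABEL = "total cardiovascular"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of one drug-event pair against a background set."""

    a: int  # drug and event
    b: int  # drug, no event
    c: int  # event, no drug
    d: int  # neither

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_observed(self) -> int:
        return self.a

    @property
    def n_expected(self) -> float:
        return expected_count(self)


@dataclass(frozen=True)
class SignalEstimate:
    """Shrunk IC and ROR point estimates with 95% bounds for one pair."""

    n: int
    ic: float
    ic025: float
    ic975: float
    ror: float
    ror025: float
    ror975: float
    is_signal: bool


def expected_count(table: ContingencyTable) -> float:
    """Expected pair count under independence: n_drug * n_event / n_total."""
    if table.n_total == 0:
        raise ValueError("expected count undefined for an empty table")
    return table.n_drug * table.n_event / table.n_total


def shrunk_ic(
    table: ContingencyTable, method: str = "approximation"
) -> tuple[float, float, float]:
    """Shrunk information component (bits) with its 95% interval."""
    if method not in IC_INTERVAL_METHODS:
        raise ValueError(f"unknown IC interval method {method!r}")
    a = table.a
    exp = expected_count(table)
    ic = math.log2((a + 0.5) / (exp + 0.5))
    if method == "approximation":
        s = 1.0 / math.sqrt(a + 0.5)
        lo = ic - 3.3 * s - 2.0 * s**3
        hi = ic + 2.4 * s + 0.5 * s**3
    else:  # gamma-quantile credible interval
        lo = math.log2(_gamma.ppf(0.025, a + 0.5) / (exp + 0.5))
        hi = math.log2(_gamma.ppf(0.975, a + 0.5) / (exp + 0.5))
    return ic, lo, hi


def ror_estimate(
    table: ContingencyTable, variant: str = "odds-ratio"
) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% interval.

    The default is the classic corrected odds ratio with the Woolf
    interval on the corrected cells.  The "as-printed" variant is the
    shrunk observed/expected ratio, identical to ``2**ic``.
    """
    if variant not in ROR_VARIANTS:
        raise ValueError(f"unknown ROR variant {variant!r}")
    if variant == "as-printed":
        ic, lo, hi = shrunk_ic(table)
        return 2.0**ic, 2.0**lo, 2.0**hi
    a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-1.96 * se), ror * math.exp(1.96 * se)


def signal_rule(ic025: float, ror025: float, n: int) -> bool:
    """Three-part signal rule, all inequalities strict."""
    return (ic025 > 0.0) and (ror025 > 1.0) and (n >= 3)


def evaluate_signal(estimate: SignalEstimate) -> bool:
    """Apply the signal rule to an existing estimate."""
    return signal_rule(estimate.ic025, estimate.ror025, estimate.n)


def estimate_signal(
    table: ContingencyTable,
    ic_interval: str = "approximation",
    ror_variant: str = "odds-ratio",
) -> SignalEstimate:
    """Full shrunk IC + ROR estimate with the signal flag."""
    ic, ic025, ic975 = shrunk_ic(table, method=ic_interval)
    ror, ror025, ror975 = ror_estimate(table, variant=ror_variant)
    return SignalEstimate(
        n=table.a,
        ic=ic,
        ic025=ic025,
        ic975=ic975,
        ror=ror,
        ror025=ror025,
        ror975=ror975,
        is_signal=signal_rule(ic025, ror025, table.a),
    )


# ---------------------------------------------------------------------------
# building tables from report sets
# ---------------------------------------------------------------------------


def _as_mask(reports: ReportSet, predicate) -> pd.Series:
    """Accept a per-report predicate or a boolean Series keyed by report_id."""
    if isinstance(predicate, pd.Series):
        return predicate.reindex(reports.demo["report_id"].to_numpy()).fillna(False).astype(bool)
    if callable(predicate):
        return reports.id_mask(predicate)
    raise TypeError("predicate must be callable or a boolean Series")


def build_table(
    reports: ReportSet, drug_predicate, event_predicate
) -> ContingencyTable:
    """Classify every report into exactly one 2x2 cell."""
    if len(reports) == 0:
        raise ValueError("cannot build a contingency table from an empty ReportSet")
    hd = _as_mask(reports, drug_predicate).to_numpy()
    he = _as_mask(reports, event_predicate).to_numpy()
    return ContingencyTable(
        a=int((hd & he).sum()),
        b=int((hd & ~he).sum()),
        c=int((~hd & he).sum()),
        d=int((~hd & ~he).sum()),
    )


def reconstruct_table(
    a: int, n_drug: int, n_total: int, ror: float, corrected: bool = True
) -> ContingencyTable:
    """Recover a full 2x2 table from marginals and a published ROR.

    Given the case count ``a``, the drug total and the database total,
    solves for the comparator event count ``c`` such that the (corrected)
    odds ratio equals the published value; ``d`` follows from the total.
    Useful for reconstruction-based checks of published summary tables.
    """
    if not 0 < a <= n_drug < n_total:
        raise ValueError("need 0 < a <= n_drug < n_total")
    b = n_drug - a

    def f(c: float) -> float:
        d = n_total - n_drug - c
        if corrected:
            return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)) - ror
        return a * d / (b * c) - ror

    c = brentq(f, 1.0, n_total - n_drug - 1.0, xtol=1e-6)
    c = int(round(c))
    return ContingencyTable(a=a, b=b, c=c, d=n_total - n_drug - c)


# ---------------------------------------------------------------------------
# analysis surfaces
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = ["category", "n", "ic", "ic025", "ic975", "ror", "ror025", "ror975", "signal"]


def _estimate_row(label: str, table: ContingencyTable, **variants) -> dict:
    est = estimate_signal(table, **variants)
    return {
        "category": label,
        "n": est.n,
        "ic": est.ic,
        "ic025": est.ic025,
        "ic975": est.ic975,
        "ror": est.ror,
        "ror025": est.ror025,
        "ror975": est.ror975,
        "signal": est.is_signal,
    }


def run_category_analysis(
    reports: ReportSet,
    lexicon: DrugLexicon,
    categories: Sequence[SmqCategory],
    ic_interval: str = "approximation",
    ror_variant: str = "odds-ratio",
) -> pd.DataFrame:
    """Signal table for the union of all categories plus each category.

    One row per category preceded by a "total" row; the background for
    every row is the full report set (reports in other categories stay in
    the background).
    """
    hd = match_drug_mask(reports, lexicon)
    member = category_membership(reports, list(categories))
    rows = []
    variants = dict(ic_interval=ic_interval, ror_variant=ror_variant)
    total_mask = pd.Series(member.any(axis=1), index=member.index)
    rows.append(_estimate_row(TOTAL_LABEL, build_table(reports, hd, total_mask), **variants))
    for cat in categories:
        mask = pd.Series(member[cat.name], index=member.index)
        rows.append(_estimate_row(cat.name, build_table(reports, hd, mask), **variants))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def ic_time_series(
    reports: ReportSet,
    lexicon: DrugLexicon,
    category: SmqCategory,
    years: Iterable[int] | None = None,
    ic_interval: str = "approximation",
    ror_variant: str = "odds-ratio",
) -> pd.DataFrame:
    """Cumulative-through-year signal estimates for one category.

    For each year ``y`` the estimate uses every report received in or
    before ``y``; interval widths are therefore non-increasing over years.
    A year whose cumulative subset has no target-drug report yields a row
    with ``n_drug = 0`` and missing estimates, flagged in the ``defined``
    column.
    """
    ry = reports.reporting_year
    if years is None:
        years = sorted(ry.unique())
    hd = match_drug_mask(reports, lexicon)
    member = category_membership(reports, [category])[category.name]
    rows = []
    for y in years:
        sub_mask = (ry <= y).to_numpy()
        sub = reports.filter_mask(pd.Series(sub_mask))
        if len(sub) == 0 or not hd[sub_mask].any():
            rows.append(
                {
                    "year": int(y), "n": 0, "defined": False,
                    **{k: np.nan for k in ("ic", "ic025", "ic975", "ror", "ror025", "ror975")},
                    "signal": False,
                }
            )
            continue
        ids = sub.demo["report_id"].to_numpy()
        table = build_table(sub, hd.loc[ids], pd.Series(member.loc[ids]))
        row = _estimate_row(str(int(y)), table, ic_interval=ic_interval, ror_variant=ror_variant)
        row["year"] = int(y)
        row["defined"] = True
        del row["category"]
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_analysis(
    reports: ReportSet,
    lexicon: DrugLexicon,
    categories: Sequence[SmqCategory],
    age_cutoff: float = 65.0,
    ic_interval: str = "approximation",
    ror_variant: str = "odds-ratio",
) -> pd.DataFrame:
    """Per-stratum signal tables over sex x age-group subpopulations.

    Strata are M/F crossed with age < cutoff / >= cutoff (default 65
    years, the conventional geriatric boundary).  Within a stratum both
    cases and background are restricted to the stratum; reports missing
    the stratum variable are excluded from that stratification.  Strata
    with an empty background are skipped.
    """
    demo = reports.demo
    age = demo["age"]
    sex = demo["sex"]
    strata = {}
    for s in ("M", "F"):
        strata[(s, f"<{age_cutoff:g}")] = (sex == s) & (age < age_cutoff)
        strata[(s, f">={age_cutoff:g}")] = (sex == s) & (age >= age_cutoff)
    frames = []
    for (s, grp), mask in strata.items():
        if not mask.any():
            continue
        sub = reports.filter_mask(pd.Series(mask.to_numpy()))
        res = run_category_analysis(
            sub, lexicon, categories, ic_interval=ic_interval, ror_variant=ror_variant
        )
        res.insert(0, "sex", s)
        res.insert(1, "age_group", grp)
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["sex", "age_group", *_RESULT_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def restricted_background_analysis(
    reports: ReportSet,
    lexicon: DrugLexicon,
    categories: Sequence[SmqCategory],
    background_predicate,
    ic_interval: str = "approximation",
    ror_variant: str = "odds-ratio",
) -> pd.DataFrame:
    """Sensitivity analysis on a restricted background population.

    Runs the identical category analysis on the subset selected by
    ``background_predicate`` (e.g. reports with the target indication) so
    indication-driven confounding can be assessed.
    """
    mask = _as_mask(reports, background_predicate)
    sub = reports.filter_mask(pd.Series(mask.to_numpy()))
    if len(sub) == 0:
        raise ValueError("background restriction selected no reports")
    return run_category_analysis(
        sub, lexicon, categories, ic_interval=ic_interval, ror_variant=ror_variant
    )


def tto_by_category(
    reports: ReportSet, lexicon: DrugLexicon, categories: Sequence[SmqCategory]
) -> dict[str, pd.Series]:
    """Available time-to-onset values (days) for the union and per category."""
    tto = time_to_onset_series(reports, lexicon)
    hd = match_drug_mask(reports, lexicon)
    member = category_membership(reports, list(categories))
    out = {}
    total = member.any(axis=1) & hd
    out[TOTAL_LABEL] = tto[total & tto.notna()]
    for cat in categories:
        m = member[cat.name] & hd
        out[cat.name] = tto[m & tto.notna()]
    return out
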