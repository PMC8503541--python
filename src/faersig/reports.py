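"""In-memory containers for spontaneous adverse-event reports.

A :class:`ReportSet` mirrors the normalized layout of the FAERS quarterly
files: one demographic row per report plus child tables for drug entries,
reaction preferred terms (PTs) and outcome codes, all keyed by an opaque
report identifier.  Columnar pandas frames are the primary representation
(every pipeline stage is vectorized over them); :class:`SafetyReport` is the
per-report object view used by predicates and brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Canonical outcome severity levels, ordered from most to least severe.
#: The ordering is the precedence used when one record carries several
#: outcome codes and a single level must be assigned.
OUTCOME_LEVELS: tuple[str, ...] = (
    "death",
    "life-threatening",
    "disability",
    "hospitalization",
    "congenital anomaly",
    "required intervention",
    "other serious",
)

#: FAERS OUTC_COD values -> outcome level.
OUTCOME_CODE_TO_LEVEL: dict[str, str] = {
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
    "HO": "hospitalization",
    "CA": "congenital anomaly",
    "RI": "required intervention",
    "OT": "other serious",
}

OUTCOME_LEVEL_TO_CODE: dict[str, str] = {v: k for k, v in OUTCOME_CODE_TO_LEVEL.items()}

DEMO_COLUMNS = ["report_id", "sex", "age", "country", "event_date", "fda_date"]
DRUG_COLUMNS = ["report_id", "drug_seq", "name", "start_date", "end_date"]
REAC_COLUMNS = ["report_id", "pt"]
OUTC_COLUMNS = ["report_id", "outcome_code"]


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report with optional therapy dates."""

    name: str
    start_date: pd.Timestamp | None = None
    end_date: pd.Timestamp | None = None


@dataclass(frozen=True)
class SafetyReport:
    """Object view of a single spontaneous report."""

    report_id: str
    sex: str | None  # 'M' / 'F' / None
    age: float | None  # years
    country: str | None
    reporting_year: int
    event_date: pd.Timestamp | None
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[str, ...] = ()
    outcomes: frozenset[str] = field(default_factory=frozenset)


def _as_frame(df: pd.DataFrame | None, columns: Sequence[str]) -> pd.DataFrame:
    if df is None:
        df = pd.DataFrame({c: [] for c in columns})
    df = df.loc[:, list(columns)].reset_index(drop=True)
    for c in ("event_date", "fda_date", "start_date", "end_date"):
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], errors="coerce").astype("datetime64[ns]")
    return df


class ReportSet:
    """A collection of spontaneous reports in normalized columnar form.

    Parameters
    ----------
    demo : DataFrame with columns report_id, sex, age, country, event_date,
        fda_date (receipt date; always present).
    drugs : DataFrame with columns report_id, drug_seq, name, start_date,
        end_date.
    reactions : DataFrame with columns report_id, pt.
    outcomes : DataFrame with columns report_id, outcome_code.
    """

    def __init__(
        self,
        demo: pd.DataFrame,
        drugs: pd.DataFrame | None = None,
        reactions: pd.DataFrame | None = None,
        outcomes: pd.DataFrame | None = None,
    ) -> None:
        self.demo = _as_frame(demo, DEMO_COLUMNS)
        if self.demo["report_id"].duplicated().any():
            raise ValueError("report_id must be unique within a ReportSet")
        self.drugs = _as_frame(drugs, DRUG_COLUMNS)
        self.reactions = _as_frame(reactions, REAC_COLUMNS)
        self.outcomes = _as_frame(outcomes, OUTC_COLUMNS)

    def __len__(self) -> int:
        return len(self.demo)

    @property
    def report_ids(self) -> pd.Series:
        return self.demo["report_id"]

    @property
    def reporting_year(self) -> pd.Series:
        """Calendar year of receipt, indexed like ``demo``."""
        return self.demo["fda_date"].dt.year.astype(int)

    def filter(self, report_ids) -> "ReportSet":
        """Restrict to the given identifiers, preserving input order."""
        keep = set(report_ids)
        demo = self.demo[self.demo["report_id"].isin(keep)]
        return ReportSet(
            demo,
            self.drugs[self.drugs["report_id"].isin(keep)],
            self.reactions[self.reactions["report_id"].isin(keep)],
            self.outcomes[self.outcomes["report_id"].isin(keep)],
        )

    def filter_mask(self, mask: pd.Series) -> "ReportSet":
        """Restrict by a boolean Series aligned with ``demo`` rows."""
        return self.filter(self.demo.loc[np.asarray(mask, dtype=bool), "report_id"])

    def iter_reports(self) -> Iterator[SafetyReport]:
        """Yield one :class:`SafetyReport` per demographic row."""
        drug_groups = _group(self.drugs)
        reac_groups = _group(self.reactions)
        outc_groups = _group(self.outcomes)
        for row in self.demo.itertuples(index=False):
            rid = row.report_id
            drugs = tuple(
                DrugEntry(
                    d.name,
                    None if pd.isna(d.start_date) else d.start_date,
                    None if pd.isna(d.end_date) else d.end_date,
                )
                for d in drug_groups.get(rid, ())
            )
            reactions = tuple(r.pt for r in reac_groups.get(rid, ()))
            outcomes = frozenset(
                OUTCOME_CODE_TO_LEVEL.get(o.outcome_code, o.outcome_code)
                for o in outc_groups.get(rid, ())
            )
            yield SafetyReport(
                report_id=rid,
                sex=None if pd.isna(row.sex) else row.sex,
                age=None if pd.isna(row.age) else float(row.age),
                country=None if pd.isna(row.country) else row.country,
                reporting_year=int(row.fda_date.year),
                event_date=None if pd.isna(row.event_date) else row.event_date,
                drugs=drugs,
                reactions=reactions,
                outcomes=outcomes,
            )

    @classmethod
    def from_reports(cls, reports: Sequence[SafetyReport]) -> "ReportSet":
        demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
        for r in reports:
            demo_rows.append(
                {
                    "report_id": r.report_id,
                    "sex": r.sex,
                    "age": r.age,
                    "country": r.country,
                    "event_date": r.event_date,
                    "fda_date": pd.Timestamp(year=r.reporting_year, month=7, day=1),
                }
            )
            for i, d in enumerate(r.drugs, start=1):
                drug_rows.append(
                    {
                        "report_id": r.report_id,
                        "drug_seq": i,
                        "name": d.name,
                        "start_date": d.start_date,
                        "end_date": d.end_date,
                    }
                )
            for pt in r.reactions:
                reac_rows.append({"report_id": r.report_id, "pt": pt})
            for level in sorted(r.outcomes):
                outc_rows.append(
                    {
                        "report_id": r.report_id,
                        "outcome_code": OUTCOME_LEVEL_TO_CODE.get(level, level),
                    }
                )
        return cls(
            pd.DataFrame(demo_rows, columns=DEMO_COLUMNS),
            pd.DataFrame(drug_rows, columns=DRUG_COLUMNS),
            pd.DataFrame(reac_rows, columns=REAC_COLUMNS),
            pd.DataFrame(outc_rows, columns=OUTC_COLUMNS),
        )

    def id_mask(self, predicate: Callable[[SafetyReport], bool]) -> pd.Series:
        """Evaluate a per-report predicate; boolean Series indexed by report_id."""
        values = [bool(predicate(r)) for r in self.iter_reports()]
        return pd.Series(values, index=self.demo["report_id"].to_numpy())


def _group(df: pd.DataFrame) -> dict:
    groups: dict[str, list] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(row.report_id, []).append(row)
    return groups
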