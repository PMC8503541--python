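"""Reading FAERS-layout tables and the record-cleaning procedure.

Cleaning follows the standard spontaneous-report preparation for
case/non-case studies:

1. **Deduplication** — records sharing the full key (sex, truncated age,
   country, event date, reporting year, the set of normalized drug entries
   with their start/end dates, the reaction-term set, and the outcome set)
   are considered duplicated; only the first in stable input order is
   retained.  Records missing any key field are never merged (missing is
   not equal to missing).
2. **Aberrant-date exclusion** — records whose target-drug start date is
   strictly later than the event onset date are excluded.  Records with
   either date missing are retained; a start date equal to the event date
   (time-to-onset zero) is retained.

Time-to-onset is the day difference between the earliest target-drug start
date and the event onset date.  No imputation is performed anywhere.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reports import ReportSet, SafetyReport
from .vocabulary import DrugLexicon, normalize_drug_name, normalize_term

logger = logging.getLogger(__name__)

_TABLES = {
    "DEMO.txt": ["primaryid", "sex", "age", "reporter_country", "event_dt", "fda_dt"],
    "DRUG.txt": ["primaryid", "drug_seq", "drugname"],
    "THER.txt": ["primaryid", "drug_seq", "start_dt", "end_dt"],
    "REAC.txt": ["primaryid", "pt"],
    "OUTC.txt": ["primaryid", "outc_cod"],
}


@dataclass(frozen=True)
class CleaningReport:
    """Flow-chart counts for the record-selection process."""

    n_input: int
    n_duplicates_removed: int
    n_aberrant_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != (
            self.n_duplicates_removed + self.n_aberrant_removed + self.n_retained
        ):
            raise ValueError("cleaning counts do not partition the input")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _read_table(directory: Path, fname: str) -> pd.DataFrame:
    path = directory / fname
    if not path.exists():
        raise FileNotFoundError(f"mandatory table {fname} missing from {directory}")
    expected = len(_TABLES[fname])
    skipped = [0]

    def _bad(line):  # malformed delimiter line: warn and skip
        skipped[0] += 1
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_bad,
    )
    if skipped[0]:
        logger.warning("%s: skipped %d malformed line(s)", fname, skipped[0])
    if list(df.columns) != _TABLES[fname]:
        raise ValueError(f"{fname}: unexpected header {list(df.columns)}")
    df = df.replace("", None)
    return df


def read_reports(directory) -> ReportSet:
    """Read a directory of dollar-delimited FAERS-layout tables.

    One :class:`SafetyReport` per DEMO row; child rows are joined on the
    report identifier.  Unparseable dates become missing, never dropped.
    """
    directory = Path(directory)
    raw = {f: _read_table(directory, f) for f in _TABLES}
    demo = raw["DEMO.txt"].rename(
        columns={
            "primaryid": "report_id",
            "reporter_country": "country",
            "event_dt": "event_date",
            "fda_dt": "fda_date",
        }
    )
    demo["age"] = pd.to_numeric(demo["age"], errors="coerce")
    for c in ("event_date", "fda_date"):
        demo[c] = pd.to_datetime(demo[c], errors="coerce", format="ISO8601")
    if demo["fda_date"].isna().any():
        raise ValueError("DEMO rows without a parseable receipt date (fda_dt)")

    drug = raw["DRUG.txt"].rename(columns={"primaryid": "report_id", "drugname": "name"})
    ther = raw["THER.txt"].rename(
        columns={"primaryid": "report_id", "start_dt": "start_date", "end_dt": "end_date"}
    )
    for c in ("start_date", "end_date"):
        ther[c] = pd.to_datetime(ther[c], errors="coerce", format="ISO8601")
    drug["drug_seq"] = pd.to_numeric(drug["drug_seq"]).astype(int)
    ther["drug_seq"] = pd.to_numeric(ther["drug_seq"]).astype(int)
    drugs = drug.merge(ther, on=["report_id", "drug_seq"], how="left")

    reac = raw["REAC.txt"].rename(columns={"primaryid": "report_id"})
    outc = raw["OUTC.txt"].rename(columns={"primaryid": "report_id", "outc_cod": "outcome_code"})
    return ReportSet(demo, drugs, reac, outc)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def _dedup_keys(reports: ReportSet) -> pd.Series:
    """Per-report dedup key, or None when any key field is missing."""
    demo = reports.demo
    n = len(demo)
    idx = pd.Index(demo["report_id"])

    def _child_key(df: pd.DataFrame, maker, complete_mask) -> tuple[pd.Series, pd.Series]:
        if df.empty:
            empty = pd.Series([frozenset()] * n, index=idx)
            return empty, pd.Series(True, index=idx)
        keys = df.groupby("report_id", sort=False).apply(maker, include_groups=False)
        keys = keys.reindex(idx, fill_value=frozenset())
        comp = complete_mask.groupby(df["report_id"].to_numpy()).all()
        comp = comp.reindex(idx, fill_value=True)
        return keys, comp

    dr = reports.drugs
    drug_keys, drug_complete = _child_key(
        dr,
        lambda g: frozenset(
            zip(g["name"].map(normalize_drug_name), g["start_date"], g["end_date"])
        ),
        ~(dr["start_date"].isna() | dr["end_date"].isna()),
    )
    rx = reports.reactions
    reac_keys, _ = _child_key(
        rx, lambda g: frozenset(g["pt"].map(normalize_term)), pd.Series(True, index=rx.index)
    )
    oc = reports.outcomes
    outc_keys, _ = _child_key(
        oc, lambda g: frozenset(g["outcome_code"]), pd.Series(True, index=oc.index)
    )

    has_drugs = drug_keys.map(bool)
    has_outcome = outc_keys.map(bool)
    incomplete = (
        demo["sex"].isna().to_numpy()
        | demo["age"].isna().to_numpy()
        | demo["country"].isna().to_numpy()
        | demo["event_date"].isna().to_numpy()
        | ~drug_complete.to_numpy()
        | ~has_drugs.to_numpy()
        | ~has_outcome.to_numpy()
    )
    age_trunc = demo["age"].fillna(-1).astype(float).astype(int)
    year = reports.reporting_year
    keys = [
        None
        if incomplete[i]
        else (
            demo["sex"].iat[i],
            int(age_trunc.iat[i]),
            demo["country"].iat[i],
            demo["event_date"].iat[i],
            int(year.iat[i]),
            drug_keys.iat[i],
            reac_keys.iat[i],
            outc_keys.iat[i],
        )
        for i in range(n)
    ]
    return pd.Series(keys, index=idx)


def deduplicate(reports: ReportSet) -> tuple[ReportSet, CleaningReport]:
    """Drop later records sharing the full dedup key; stable and idempotent."""
    keys = _dedup_keys(reports)
    seen: set = set()
    keep = np.ones(len(reports), bool)
    for i, k in enumerate(keys):
        if k is None:
            continue
        if k in seen:
            keep[i] = False
        else:
            seen.add(k)
    cleaned = reports.filter_mask(pd.Series(keep))
    report = CleaningReport(
        n_input=len(reports),
        n_duplicates_removed=int((~keep).sum()),
        n_aberrant_removed=0,
        n_retained=int(keep.sum()),
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# aberrant dates and time-to-onset
# ---------------------------------------------------------------------------


def _target_start(reports: ReportSet, lexicon: DrugLexicon) -> pd.Series:
    """Earliest target-drug start date per report (NaT when absent)."""
    dr = reports.drugs
    mask = dr["name"].map(normalize_drug_name).isin(lexicon.synonyms)
    starts = dr.loc[mask].groupby("report_id", sort=False)["start_date"].min()
    return starts.reindex(reports.demo["report_id"])


def remove_aberrant(
    reports: ReportSet, target_drug: DrugLexicon
) -> tuple[ReportSet, CleaningReport]:
    """Exclude records whose target-drug start date is after the event date.

    Exclusion requires both dates present and a strictly later start; a
    start equal to the event date (time-to-onset zero) is retained.
    """
    start = _target_start(reports, target_drug).to_numpy()
    event = reports.demo["event_date"].to_numpy()
    aberrant = (~pd.isna(start)) & (~pd.isna(event)) & (start > event)
    cleaned = reports.filter_mask(pd.Series(~aberrant))
    report = CleaningReport(
        n_input=len(reports),
        n_duplicates_removed=0,
        n_aberrant_removed=int(aberrant.sum()),
        n_retained=int((~aberrant).sum()),
    )
    return cleaned, report


def clean(
    reports: ReportSet, target_drug: DrugLexicon
) -> tuple[ReportSet, CleaningReport]:
    """Deduplicate, then drop aberrant-date records; combined flow counts."""
    deduped, r1 = deduplicate(reports)
    final, r2 = remove_aberrant(deduped, target_drug)
    return final, CleaningReport(
        n_input=r1.n_input,
        n_duplicates_removed=r1.n_duplicates_removed,
        n_aberrant_removed=r2.n_aberrant_removed,
        n_retained=r2.n_retained,
    )


def time_to_onset(report: SafetyReport, target_drug: DrugLexicon) -> int | None:
    """Days from earliest target-drug start to event onset; None if unknown."""
    if report.event_date is None:
        return None
    starts = [d.start_date for d in report.drugs if d.name in target_drug and d.start_date is not None]
    if not starts:
        return None
    return int((report.event_date - min(starts)).days)


def time_to_onset_series(reports: ReportSet, target_drug: DrugLexicon) -> pd.Series:
    """Vectorized time-to-onset in days, indexed by report_id (NaN missing)."""
    start = _target_start(reports, target_drug).to_numpy()
    event = reports.demo["event_date"].to_numpy()
    days = (event - start) / np.timedelta64(1, "D")
    return pd.Series(days, index=reports.demo["report_id"].to_numpy())
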