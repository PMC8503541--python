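"""Drug identification and SMQ event grouping.

Adverse events in spontaneous-report databases are coded at the MedDRA
preferred-term (PT) level; Standardized MedDRA Queries (SMQs) group PTs
into clinically meaningful conditions.  This module identifies reports that
mention the target drug (brand or generic name) and assigns each report's
reactions to narrow-SMQ cardiovascular categories.

The MedDRA dictionary is licensed and is not redistributed here: only the
eight narrow-SMQ names and codes are bundled (``CARDIOVASCULAR_SMQ_CODES``);
the PT membership lists are supplied by the user as a delimited table
(``load_smq_table``) or, for synthetic data, derived from the generator
configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .reports import ReportSet, SafetyReport

#: The eight narrow-SMQ cardiovascular categories (name -> SMQ code).
CARDIOVASCULAR_SMQ_CODES: dict[str, int] = {
    "cardiac arrhythmias": 20000049,
    "cardiac failure": 20000004,
    "cardiomyopathy": 20000150,
    "embolic and thrombotic events": 20000081,
    "hypertension": 20000147,
    "ischemic heart disease": 20000043,
    "pulmonary hypertension": 20000130,
    "torsade de pointes/QT prolongation": 20000001,
}

_SMQ_CODE_TO_NAME = {v: k for k, v in CARDIOVASCULAR_SMQ_CODES.items()}

#: Salt/ester suffix tokens stripped when normalizing drug names for
#: deduplication and lexicon matching.
DEFAULT_SALT_SUFFIXES: frozenset[str] = frozenset(
    {
        "hydrochloride",
        "hcl",
        "sodium",
        "potassium",
        "calcium",
        "sulfate",
        "sulphate",
        "citrate",
        "maleate",
        "mesylate",
        "tartrate",
        "acetate",
        "phosphate",
        "besylate",
    }
)

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-fold, trim and collapse internal whitespace."""
    return _WS.sub(" ", str(term).strip()).casefold()


def normalize_drug_name(name: str, salts: frozenset[str] = DEFAULT_SALT_SUFFIXES) -> str:
    """Normalize a drug name: case-fold, trim, drop trailing salt tokens."""
    tokens = normalize_term(name).split(" ")
    while len(tokens) > 1 and tokens[-1] in salts:
        tokens.pop()
    return " ".join(tokens)


class VocabularyError(ValueError):
    """Invalid lexicon or SMQ mapping configuration."""


@dataclass(frozen=True)
class DrugLexicon:
    """Brand + generic names identifying one target drug.

    Matching is case-insensitive on normalized names.
    """

    canonical_name: str
    synonyms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise VocabularyError("drug lexicon must have at least one synonym")
        object.__setattr__(
            self, "synonyms", frozenset(normalize_drug_name(s) for s in self.synonyms)
        )

    def __contains__(self, name: str) -> bool:
        return normalize_drug_name(name) in self.synonyms

    @classmethod
    def from_file(cls, path) -> "DrugLexicon":
        """Read a two-column delimited file: canonical_name, synonym."""
        df = pd.read_csv(path, sep=None, engine="python", header=0)
        if df.shape[1] < 2:
            raise VocabularyError(f"lexicon file {path} needs two columns")
        canonical = str(df.iloc[0, 0])
        synonyms = frozenset(str(s) for s in df.iloc[:, 1])
        return cls(canonical, synonyms)


#: Default target-drug lexicon: carfilzomib and its brand name.
CARFILZOMIB_LEXICON = DrugLexicon("carfilzomib", frozenset({"carfilzomib", "kyprolis"}))


@dataclass(frozen=True)
class SmqCategory:
    """A narrow-scope SMQ: name, code and its preferred-term membership."""

    name: str
    smq_code: int
    preferred_terms: frozenset[str]
    algorithm: str = "narrow"

    def __post_init__(self) -> None:
        if not self.preferred_terms:
            raise VocabularyError(f"SMQ {self.name!r} has an empty PT set")
        object.__setattr__(
            self,
            "preferred_terms",
            frozenset(normalize_term(p) for p in self.preferred_terms),
        )

    def matches(self, pt: str) -> bool:
        return normalize_term(pt) in self.preferred_terms


@dataclass(frozen=True)
class CategoryAssignment:
    """Category membership of one report; cardiovascular iff non-empty."""

    report_id: str
    categories: frozenset[str]

    @property
    def is_cardiovascular(self) -> bool:
        return bool(self.categories)


def load_smq_table(path, registry: dict[str, int] | None = None) -> list[SmqCategory]:
    """Load a user-supplied PT -> SMQ mapping.

    The file is a delimited table with columns ``pt_name`` and ``smq_code``
    (an optional ``algorithm`` column is accepted; only narrow rows are
    kept).  Codes must belong to the bundled registry, by default the eight
    cardiovascular narrow SMQs.
    """
    registry = registry if registry is not None else CARDIOVASCULAR_SMQ_CODES
    code_to_name = {v: k for k, v in registry.items()}
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    cols = {c.strip().lower(): c for c in df.columns}
    if "pt_name" not in cols or "smq_code" not in cols:
        raise VocabularyError(f"SMQ table {path} must have pt_name and smq_code columns")
    if "algorithm" in cols:
        df = df[df[cols["algorithm"]].astype(str).str.strip().str.lower() == "narrow"]
    out: dict[int, set[str]] = {}
    for pt, code in zip(df[cols["pt_name"]], df[cols["smq_code"]]):
        code = int(code)
        if code not in code_to_name:
            raise VocabularyError(f"unknown SMQ code {code} in {path}")
        out.setdefault(code, set()).add(str(pt))
    return [
        SmqCategory(name=code_to_name[code], smq_code=code, preferred_terms=frozenset(pts))
        for code, pts in sorted(out.items())
    ]


def match_drug(report: SafetyReport, lexicon: DrugLexicon) -> bool:
    """True iff any drug on the report matches the lexicon."""
    return any(d.name in lexicon for d in report.drugs)


def assign_categories(
    report: SafetyReport, categories: list[SmqCategory]
) -> CategoryAssignment:
    """Assign a report to every category with >=1 matching reaction PT.

    A report contributes once per category regardless of how many of its
    PTs match; overall cardiovascular membership is the union.
    """
    pts = {normalize_term(p) for p in report.reactions}
    hit = frozenset(c.name for c in categories if pts & c.preferred_terms)
    return CategoryAssignment(report_id=report.report_id, categories=hit)


# -- vectorized counterparts -------------------------------------------------


def match_drug_mask(reports: ReportSet, lexicon: DrugLexicon) -> pd.Series:
    """Boolean Series indexed by report_id: report mentions the target drug."""
    names = reports.drugs["name"]
    lut = {v: normalize_drug_name(v) in lexicon.synonyms for v in names.unique()}
    hits = reports.drugs.loc[names.map(lut), "report_id"]
    ids = reports.demo["report_id"]
    return pd.Series(ids.isin(set(hits)).to_numpy(), index=ids.to_numpy())


def category_membership(
    reports: ReportSet, categories: list[SmqCategory]
) -> pd.DataFrame:
    """Report x category boolean membership matrix (index: report_id)."""
    ids = reports.demo["report_id"]
    pts = reports.reactions["pt"]
    norm_lut = {v: normalize_term(v) for v in pts.unique()}
    norm_pt = pts.map(norm_lut)
    out = {}
    for cat in categories:
        hits = reports.reactions.loc[norm_pt.isin(cat.preferred_terms), "report_id"]
        out[cat.name] = ids.isin(set(hits)).to_numpy()
    return pd.DataFrame(out, index=ids.to_numpy())
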