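"""Synthetic spontaneous-report generator with known statistical structure.

Every downstream stage (cleaning, vocabulary mapping, disproportionality,
descriptive summaries) is testable against this generator because the
drug-event association strength, the number of injected duplicate and
aberrant-date records, and the per-field missingness rates are all part of
the configuration, and the implied 2x2 cell probabilities have a closed
form (:func:`ground_truth`).

Generative model (per base report)
----------------------------------
1. Reactions: each preferred term in the event catalog is included
   independently with its marginal probability.  Event-category flags are
   the union over member PTs.
2. Drugs: each drug's inclusion probability is its marginal probability
   multiplied by the association multiplier ``lambda[(drug, category)]``
   for every event category present on the report (clipped to 1), drawn
   independently per drug.  If no drug is drawn, one is drawn from the
   (tilted) probabilities so every report carries at least one drug.
   ``lambda`` is therefore a reporting-rate ratio: with a rare event and a
   rare drug the implied observed/expected ratio approaches ``lambda``.
3. Dates: the event date is uniform over the configured window; each drug
   entry's start date precedes the event by a log-normal onset lag
   (integer days, truncated at zero); receipt date follows the event by a
   short uniform lag, so the reporting year is always known.
4. Demographics and outcome are drawn from configurable marginals, then
   field-level missingness is applied.

Injected artifacts: ``round(aberrant_fraction * n_reports)`` base reports
have the target drug's start date forced strictly after the event date
(both dates kept non-missing so the aberrancy is detectable), and
``round(duplicate_fraction * n_reports)`` additional reports are emitted as
verbatim copies (fresh report identifier, every dedup-key field identical)
of earlier reports whose key fields are all present.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reports import (
    DEMO_COLUMNS,
    DRUG_COLUMNS,
    OUTC_COLUMNS,
    OUTCOME_LEVEL_TO_CODE,
    REAC_COLUMNS,
    ReportSet,
)
from .vocabulary import CARDIOVASCULAR_SMQ_CODES, SmqCategory


class GeneratorConfigError(ValueError):
    """Invalid synthetic-generator configuration."""


@dataclass(frozen=True)
class DrugSpec:
    """A drug in the catalog with its marginal reporting probability."""

    name: str
    prob: float


@dataclass(frozen=True)
class EventSpec:
    """A preferred term, its marginal probability and SMQ membership."""

    pt: str
    prob: float
    categories: tuple[str, ...] = ()


_DEFAULT_MISSING = {
    "sex": 0.14,
    "age": 0.30,
    "country": 0.0,
    "event_date": 0.30,
    "start_date": 0.25,
    "end_date": 0.40,
    "outcome": 0.10,
}

_DEFAULT_COUNTRIES = {
    "US": 0.47,
    "DE": 0.12,
    "JP": 0.09,
    "GB": 0.03,
    "IT": 0.03,
    "CA": 0.02,
    "FR": 0.24,
}

_DEFAULT_OUTCOMES = {
    "death": 0.16,
    "life-threatening": 0.09,
    "disability": 0.02,
    "hospitalization": 0.38,
    "other serious": 0.35,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic report stream.

    ``association_multipliers`` maps ``(drug name, category name)`` to a
    positive rate ratio ``lambda``; ``lambda = 1`` means no association.
    """

    n_reports: int
    drug_catalog: tuple[DrugSpec, ...]
    event_catalog: tuple[EventSpec, ...]
    association_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    target_drug: str | None = None  # defaults to the first catalog entry
    duplicate_fraction: float = 0.0
    aberrant_fraction: float = 0.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    date_window: tuple[str, str] = ("2015-01-01", "2019-12-31")
    onset_median_days: float = 41.0
    onset_sigma: float = 1.5
    onset_max_days: int = 3650  # truncation of the log-normal right tail
    sex_male_prob: float = 0.55
    age_mean: float = 67.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (1.0, 95.0)
    country_probs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_COUNTRIES))
    outcome_probs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_OUTCOMES))
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_catalog", tuple(self.drug_catalog))
        object.__setattr__(self, "event_catalog", tuple(self.event_catalog))
        rates = dict(_DEFAULT_MISSING)
        rates.update(self.missing_rates)
        object.__setattr__(self, "missing_rates", rates)
        if self.target_drug is None and self.drug_catalog:
            object.__setattr__(self, "target_drug", self.drug_catalog[0].name)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_reports < 1:
            raise GeneratorConfigError("n_reports must be >= 1")
        if not self.drug_catalog or not self.event_catalog:
            raise GeneratorConfigError("drug and event catalogs must be non-empty")
        names = [d.name for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise GeneratorConfigError("duplicate drug names in catalog")
        pts = [e.pt for e in self.event_catalog]
        if len(set(pts)) != len(pts):
            raise GeneratorConfigError("duplicate PTs in event catalog")
        for d in self.drug_catalog:
            if not 0.0 <= d.prob <= 1.0:
                raise GeneratorConfigError(f"drug prob out of [0,1]: {d}")
        if sum(d.prob for d in self.drug_catalog) <= 0:
            raise GeneratorConfigError("at least one drug needs positive probability")
        for e in self.event_catalog:
            if not 0.0 <= e.prob <= 1.0:
                raise GeneratorConfigError(f"event prob out of [0,1]: {e}")
        cats = {c for e in self.event_catalog for c in e.categories}
        for (drug, cat), lam in self.association_multipliers.items():
            if lam <= 0:
                raise GeneratorConfigError(f"multiplier for {(drug, cat)} must be > 0")
            if drug not in set(names):
                raise GeneratorConfigError(f"multiplier names unknown drug {drug!r}")
            if cat not in cats:
                raise GeneratorConfigError(f"multiplier names unknown category {cat!r}")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise GeneratorConfigError("duplicate_fraction must be in [0,1)")
        if not 0.0 <= self.aberrant_fraction < 1.0:
            raise GeneratorConfigError("aberrant_fraction must be in [0,1)")
        for k, v in self.missing_rates.items():
            if k not in _DEFAULT_MISSING:
                raise GeneratorConfigError(f"unknown missing_rates field {k!r}")
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"missing rate out of [0,1]: {k}={v}")
        if self.target_drug not in set(names):
            raise GeneratorConfigError(f"target_drug {self.target_drug!r} not in catalog")
        if self.onset_median_days <= 0 or self.onset_sigma <= 0:
            raise GeneratorConfigError("onset lag parameters must be positive")
        if self.onset_max_days < self.onset_median_days:
            raise GeneratorConfigError("onset_max_days must be >= onset_median_days")
        if pd.Timestamp(self.date_window[0]) > pd.Timestamp(self.date_window[1]):
            raise GeneratorConfigError("date_window start is after end")

    @property
    def category_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.event_catalog:
            for c in e.categories:
                seen.setdefault(c)
        return tuple(seen)


@dataclass
class GenerationLedger:
    """Exact bookkeeping of what the generator injected."""

    n_reports: int
    n_base: int
    n_duplicates: int
    n_aberrant: int
    duplicate_ids: list[str]
    aberrant_ids: list[str]
    n_drug_rows: int
    n_reaction_rows: int
    n_outcome_rows: int
    missing_counts: dict[str, int]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


@dataclass(frozen=True)
class PairTruth:
    """Closed-form cell probabilities for one (drug, category) pair."""

    drug: str
    category: str
    p_a: float  # drug and event
    p_b: float  # drug, no event
    p_c: float  # event, no drug
    p_d: float  # neither
    expected_ic: float  # log2 of implied observed/expected ratio

    @property
    def cell_probabilities(self) -> tuple[float, float, float, float]:
        return (self.p_a, self.p_b, self.p_c, self.p_d)

    @property
    def p_drug(self) -> float:
        return self.p_a + self.p_b

    @property
    def p_event(self) -> float:
        return self.p_a + self.p_c

    def expected_cells(self, n: int) -> tuple[float, float, float, float]:
        return tuple(n * p for p in self.cell_probabilities)


class GroundTruth:
    """Closed-form statistical structure implied by a generator config."""

    def __init__(self, pairs: dict[tuple[str, str], PairTruth]) -> None:
        self.pairs = pairs

    def __getitem__(self, key: tuple[str, str]) -> PairTruth:
        return self.pairs[key]


# ---------------------------------------------------------------------------
# closed-form ground truth
# ---------------------------------------------------------------------------


def _category_pt_probs(config: GeneratorConfig) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for e in config.event_catalog:
        for c in e.categories:
            out.setdefault(c, []).append(e.prob)
    return out


def ground_truth_pair(config: GeneratorConfig, drug: str, category: str) -> PairTruth:
    """Exact cell probabilities for one (drug, category) pair.

    Enumerates the joint presence pattern of the "active" categories (those
    named in any association multiplier, plus the queried one).  Active
    categories must have pairwise-disjoint PT sets so their presence
    indicators are independent; a shared PT raises a config error.
    """
    config.validate()
    cat_probs = _category_pt_probs(config)
    if category not in cat_probs:
        raise GeneratorConfigError(f"category {category!r} not present in event catalog")
    active = sorted({c for (_, c) in config.association_multipliers} | {category})
    # disjointness check over active categories
    seen: dict[str, str] = {}
    for e in config.event_catalog:
        hits = [c for c in e.categories if c in active]
        if len(hits) > 1:
            raise GeneratorConfigError(
                f"PT {e.pt!r} belongs to several active categories {hits}; "
                "ground truth requires disjoint PT sets among active categories"
            )
    q = {c: 1.0 - math.prod(1.0 - p for p in cat_probs[c]) for c in active}

    names = [d.name for d in config.drug_catalog]
    base_p = np.array([d.prob for d in config.drug_catalog], float)
    di = names.index(drug)

    p_drug = 0.0
    p_both = 0.0
    p_event = 0.0
    for pattern in itertools.product((False, True), repeat=len(active)):
        present = {c for c, on in zip(active, pattern) if on}
        p_s = math.prod(q[c] if c in present else 1.0 - q[c] for c in active)
        if p_s == 0.0:
            continue
        pi = base_p.copy()
        for (d, c), lam in config.association_multipliers.items():
            if c in present:
                pi[names.index(d)] *= lam
        np.clip(pi, 0.0, 1.0, out=pi)
        total = pi.sum()
        w = pi / total if total > 0 else base_p / base_p.sum()
        other = np.prod(np.delete(1.0 - pi, di))
        p_d_s = 1.0 - (1.0 - pi[di]) * (1.0 - other * w[di])
        p_drug += p_s * p_d_s
        if category in present:
            p_event += p_s
            p_both += p_s * p_d_s

    a, b, c = p_both, p_drug - p_both, p_event - p_both
    d = 1.0 - a - b - c
    ic = math.log2(a / (p_drug * p_event)) if a > 0 else float("-inf")
    return PairTruth(drug=drug, category=category, p_a=a, p_b=b, p_c=c, p_d=d, expected_ic=ic)


def ground_truth(config: GeneratorConfig, pairs=None) -> GroundTruth:
    """Closed-form ground truth for the requested (drug, category) pairs.

    By default every catalog drug is crossed with every event category.
    """
    config.validate()
    if pairs is None:
        pairs = [
            (d.name, c) for d in config.drug_catalog for c in config.category_names
        ]
    return GroundTruth({p: ground_truth_pair(config, *p) for p in pairs})


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------


def simulate(config: GeneratorConfig) -> tuple[ReportSet, GenerationLedger]:
    """Generate reports plus the exact ledger of injected artifacts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    n_dup = round(config.duplicate_fraction * n)
    n_base = n - n_dup
    n_ab = round(config.aberrant_fraction * n)
    if n_ab > n_base:
        raise GeneratorConfigError("aberrant_fraction too large for the base stream")

    names = [d.name for d in config.drug_catalog]
    base_p = np.array([d.prob for d in config.drug_catalog], float)
    target_idx = names.index(config.target_drug)
    pts = [e.pt for e in config.event_catalog]
    pt_p = np.array([e.prob for e in config.event_catalog], float)

    # 1. reactions ----------------------------------------------------------
    pt_flags = rng.random((n_base, len(pts))) < pt_p

    # 2. drugs (association-tilted Bernoulli + min-1 fallback) --------------
    pi = np.broadcast_to(base_p, (n_base, len(names))).copy()
    cat_members = {c: np.array([c in e.categories for e in config.event_catalog])
                   for c in config.category_names}
    for (drug, cat), lam in config.association_multipliers.items():
        has_cat = pt_flags[:, cat_members[cat]].any(axis=1)
        pi[has_cat, names.index(drug)] *= lam
    np.clip(pi, 0.0, 1.0, out=pi)
    drug_flags = rng.random((n_base, len(names))) < pi
    none_rows = np.flatnonzero(~drug_flags.any(axis=1))
    if none_rows.size:
        w = pi[none_rows]
        dead = w.sum(axis=1) == 0
        if dead.any():
            w[dead] = base_p
        cw = np.cumsum(w, axis=1)
        u = rng.random(none_rows.size) * cw[:, -1]
        pick = (cw < u[:, None]).sum(axis=1)
        drug_flags[none_rows, pick] = True

    # aberrant rows must carry the target drug
    ab_rows = rng.choice(n_base, size=n_ab, replace=False) if n_ab else np.empty(0, int)
    drug_flags[ab_rows, target_idx] = True

    # 3. dates --------------------------------------------------------------
    win0 = np.datetime64(config.date_window[0], "D")
    win1 = np.datetime64(config.date_window[1], "D")
    span = int((win1 - win0) / np.timedelta64(1, "D"))
    event_true = win0 + rng.integers(0, span + 1, n_base).astype("timedelta64[D]")
    fda_date = event_true + rng.integers(0, 61, n_base).astype("timedelta64[D]")

    erows, ecols = np.nonzero(drug_flags)
    n_entries = erows.size
    mu = math.log(config.onset_median_days)
    lag = np.rint(rng.lognormal(mu, config.onset_sigma, n_entries)).astype(int)
    lag = np.clip(lag, 0, config.onset_max_days)
    start = event_true[erows] - lag.astype("timedelta64[D]")
    end = start + rng.integers(1, 181, n_entries).astype("timedelta64[D]")
    if n_ab:
        ab_set = np.zeros(n_base, bool)
        ab_set[ab_rows] = True
        ab_entries = ab_set[erows] & (ecols == target_idx)
        delay = rng.integers(1, 31, int(ab_entries.sum())).astype("timedelta64[D]")
        start[ab_entries] = event_true[erows[ab_entries]] + delay

    # 4. demographics and outcome ------------------------------------------
    sex = np.where(rng.random(n_base) < config.sex_male_prob, "M", "F").astype(object)
    lo, hi = config.age_range
    age = np.rint(np.clip(rng.normal(config.age_mean, config.age_sd, n_base), lo, hi))
    countries = list(config.country_probs)
    cp = np.array([config.country_probs[c] for c in countries], float)
    country = rng.choice(np.array(countries, object), size=n_base, p=cp / cp.sum())
    levels = list(config.outcome_probs)
    op = np.array([config.outcome_probs[c] for c in levels], float)
    outcome = rng.choice(np.array(levels, object), size=n_base, p=op / op.sum())

    # 5. missingness --------------------------------------------------------
    rates = config.missing_rates
    miss = {k: rng.random(n_base) < rates[k]
            for k in ("sex", "age", "country", "event_date", "outcome")}
    start_miss = rng.random(n_entries) < rates["start_date"]
    end_miss = rng.random(n_entries) < rates["end_date"]
    if n_ab:
        miss["event_date"][ab_rows] = False
        start_miss[ab_entries] = False

    # 6. assemble base frames ----------------------------------------------
    ids = np.array([f"R{i + 1:07d}" for i in range(n)], object)
    base_ids = ids[:n_base]
    demo = pd.DataFrame(
        {
            "report_id": base_ids,
            "sex": np.where(miss["sex"], None, sex),
            "age": np.where(miss["age"], np.nan, age),
            "country": np.where(miss["country"], None, country),
            "event_date": pd.Series(event_true).mask(miss["event_date"]),
            "fda_date": fda_date,
        }
    )

    seq = np.zeros(n_entries, int)
    if n_entries:
        first = np.r_[True, erows[1:] != erows[:-1]]
        grp_start = np.flatnonzero(first)
        seq = np.arange(n_entries) - np.repeat(grp_start, np.diff(np.r_[grp_start, n_entries])) + 1
    drugs = pd.DataFrame(
        {
            "report_id": base_ids[erows],
            "drug_seq": seq,
            "name": np.array(names, object)[ecols],
            "start_date": pd.Series(start).mask(start_miss),
            "end_date": pd.Series(end).mask(end_miss),
        }
    )
    rrows, rcols = np.nonzero(pt_flags)
    reac = pd.DataFrame(
        {"report_id": base_ids[rrows], "pt": np.array(pts, object)[rcols]}
    )
    keep_out = ~miss["outcome"]
    outc = pd.DataFrame(
        {
            "report_id": base_ids[keep_out],
            "outcome_code": [OUTCOME_LEVEL_TO_CODE[o] for o in outcome[keep_out]],
        }
    )

    # 7. duplicates: verbatim copies of complete-key base reports -----------
    dup_ids: list[str] = []
    if n_dup:
        entry_bad = start_miss | end_miss
        bad_per_row = np.zeros(n_base, bool)
        np.logical_or.at(bad_per_row, erows, entry_bad)
        has_reac = np.zeros(n_base, bool)
        has_reac[rrows] = True
        eligible = ~(
            miss["sex"] | miss["age"] | miss["country"] | miss["event_date"]
            | miss["outcome"] | bad_per_row | ~has_reac
        )
        eligible[ab_rows] = False
        candidates = np.flatnonzero(eligible)
        if candidates.size == 0:
            raise GeneratorConfigError(
                "no complete-key base report available to duplicate; "
                "lower the missing rates or duplicate_fraction"
            )
        sources = rng.choice(candidates, size=n_dup, replace=True)
        dup_ids = list(ids[n_base:])
        dup_demo = demo.iloc[sources].copy()
        dup_demo["report_id"] = dup_ids
        src_ids = base_ids[sources]

        def _copy_child(df: pd.DataFrame) -> pd.DataFrame:
            parts = []
            for s, new in zip(src_ids, dup_ids):
                part = df[df["report_id"] == s].copy()
                part["report_id"] = new
                parts.append(part)
            return pd.concat(parts, ignore_index=True) if parts else df.iloc[:0]

        demo = pd.concat([demo, dup_demo], ignore_index=True)
        drugs = pd.concat([drugs, _copy_child(drugs.iloc[: n_entries])], ignore_index=True)
        reac = pd.concat([reac, _copy_child(reac.iloc[: rrows.size])], ignore_index=True)
        outc = pd.concat([outc, _copy_child(outc)], ignore_index=True)

    reports = ReportSet(demo, drugs, reac, outc)
    ledger = GenerationLedger(
        n_reports=n,
        n_base=n_base,
        n_duplicates=n_dup,
        n_aberrant=n_ab,
        duplicate_ids=dup_ids,
        aberrant_ids=[base_ids[i] for i in np.sort(ab_rows)],
        n_drug_rows=len(reports.drugs),
        n_reaction_rows=len(reports.reactions),
        n_outcome_rows=len(reports.outcomes),
        missing_counts={k: int(v.sum()) for k, v in miss.items()}
        | {"start_date": int(start_miss.sum()), "end_date": int(end_miss.sum())},
    )
    return reports, ledger


def generate_reports(config: GeneratorConfig) -> ReportSet:
    """Generate a synthetic :class:`ReportSet` (deterministic given seed)."""
    return simulate(config)[0]


# ---------------------------------------------------------------------------
# FAERS-layout round trip
# ---------------------------------------------------------------------------

_LAYOUT = {
    "DEMO.txt": (
        ["primaryid", "sex", "age", "reporter_country", "event_dt", "fda_dt"],
        "demo",
        DEMO_COLUMNS,
    ),
    "DRUG.txt": (["primaryid", "drug_seq", "drugname"], "drugs", DRUG_COLUMNS[:3]),
    "THER.txt": (["primaryid", "drug_seq", "start_dt", "end_dt"], "drugs", None),
    "REAC.txt": (["primaryid", "pt"], "reactions", REAC_COLUMNS),
    "OUTC.txt": (["primaryid", "outc_cod"], "outcomes", OUTC_COLUMNS),
}


def _fmt_dates(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[c]):
            df[c] = df[c].dt.strftime("%Y-%m-%d")
    return df


def write_faers_layout(reports: ReportSet, directory) -> list[Path]:
    """Write dollar-delimited DEMO/DRUG/REAC/OUTC/THER tables.

    Dates are ISO-8601; missing values are empty fields.  The layout
    round-trips losslessly through :func:`faersig.ingest.read_reports`.
    """
    if len(reports) == 0:
        raise ValueError("refusing to write an empty ReportSet")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    demo = _fmt_dates(reports.demo)
    demo["age"] = reports.demo["age"].map(
        lambda v: "" if pd.isna(v) else str(int(v)) if float(v).is_integer() else str(v)
    )
    frames = {
        "DEMO.txt": demo[["report_id", "sex", "age", "country", "event_date", "fda_date"]],
        "DRUG.txt": reports.drugs[["report_id", "drug_seq", "name"]],
        "THER.txt": _fmt_dates(reports.drugs)[["report_id", "drug_seq", "start_date", "end_date"]],
        "REAC.txt": reports.reactions,
        "OUTC.txt": reports.outcomes,
    }
    for fname, (header, _, _) in _LAYOUT.items():
        df = frames[fname].copy()
        df.columns = header
        for c in df.columns:
            if df[c].dtype == object:
                bad = df[c].dropna().astype(str).str.contains(r"\$")
                if bad.any():
                    raise ValueError(f"field value contains the '$' delimiter in {fname}")
        path = directory / fname
        df.to_csv(path, sep="$", index=False, na_rep="")
        out.append(path)
    return out


# ---------------------------------------------------------------------------
# convenience configurations
# ---------------------------------------------------------------------------


def example_config(n_reports: int = 2000, seed: int = 0, **overrides) -> GeneratorConfig:
    """A small, realistic demonstration configuration.

    One proteasome-inhibitor-like target drug against a polypharmacy
    background, cardiovascular PTs spread over four of the eight narrow-SMQ
    categories plus non-cardiovascular noise PTs, and planted associations
    for cardiac failure and pulmonary hypertension.
    """
    drugs = (
        DrugSpec("carfilzomib", 0.05),
        DrugSpec("lenalidomide", 0.20),
        DrugSpec("dexamethasone", 0.30),
        DrugSpec("aspirin", 0.25),
        DrugSpec("metformin", 0.20),
        DrugSpec("atorvastatin", 0.20),
        DrugSpec("lisinopril", 0.15),
        DrugSpec("omeprazole", 0.25),
    )
    events = (
        EventSpec("cardiac failure", 0.010, ("cardiac failure",)),
        EventSpec("cardiac failure congestive", 0.006, ("cardiac failure",)),
        EventSpec("pulmonary hypertension", 0.004, ("pulmonary hypertension",)),
        EventSpec("cardiomyopathy", 0.005, ("cardiomyopathy",)),
        EventSpec("atrial fibrillation", 0.012, ("cardiac arrhythmias",)),
        EventSpec("nausea", 0.15, ()),
        EventSpec("fatigue", 0.18, ()),
        EventSpec("diarrhoea", 0.12, ()),
        EventSpec("headache", 0.14, ()),
        EventSpec("rash", 0.10, ()),
        EventSpec("pyrexia", 0.08, ()),
    )
    cfg = dict(
        n_reports=n_reports,
        drug_catalog=drugs,
        event_catalog=events,
        association_multipliers={
            ("carfilzomib", "cardiac failure"): 3.0,
            ("carfilzomib", "pulmonary hypertension"): 2.5,
        },
        duplicate_fraction=0.05,
        aberrant_fraction=0.02,
        seed=seed,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def categories_from_config(config: GeneratorConfig) -> list[SmqCategory]:
    """Build the SMQ category registry implied by the event catalog.

    Category names present in the bundled cardiovascular registry receive
    their official SMQ codes; other names get synthetic codes >= 90000001.
    """
    out = []
    synth = itertools.count(90000001)
    for i, name in enumerate(config.category_names):
        pts = frozenset(e.pt for e in config.event_catalog if name in e.categories)
        code = CARDIOVASCULAR_SMQ_CODES.get(name, None)
        out.append(
            SmqCategory(name=name, smq_code=code if code is not None else next(synth),
                        preferred_terms=pts)
        )
    return out
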