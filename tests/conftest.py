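import pandas as pd
import pytest
from hypothesis import settings

from faersig.reports import DrugEntry, ReportSet, SafetyReport
from faersig.synthetic import DrugSpec, EventSpec, GeneratorConfig
from faersig.vocabulary import DrugLexicon, SmqCategory

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: All missingness switched off (used by simulation studies).
NO_MISSING = {
    k: 0.0
    for k in ("sex", "age", "country", "event_date", "start_date", "end_date", "outcome")
}


def null_pair_config(seed: int, n: int = 50_000) -> GeneratorConfig:
    """No-association stream with one watched pair (expected count ~50)."""
    drugs = (DrugSpec("drugx", 0.05),) + tuple(
        DrugSpec(f"bg{i}", p) for i, p in enumerate([0.40, 0.35, 0.35, 0.30, 0.30, 0.25])
    )
    events = (
        EventSpec("pt a", 0.012, ("planted",)),
        EventSpec("pt b", 0.008, ("planted",)),
        EventSpec("noise0", 0.15, ()),
        EventSpec("noise1", 0.12, ()),
        EventSpec("noise2", 0.10, ()),
    )
    return GeneratorConfig(
        n_reports=n,
        drug_catalog=drugs,
        event_catalog=events,
        association_multipliers={},
        missing_rates=NO_MISSING,
        seed=seed,
    )


def planted_pair_config(
    seed: int, lam: float = 4.0, n: int = 200_000, event_prob: float = 0.005
) -> GeneratorConfig:
    """Rare-event pair (marginal 0.5%) planted at rate ratio ``lam``.

    The dense polypharmacy background keeps the min-one-drug fallback
    share below ~3% so the implied observed/expected ratio stays close
    to ``lam``.
    """
    bg = [0.40, 0.40, 0.35, 0.35, 0.30, 0.30, 0.30, 0.25, 0.25, 0.25, 0.20, 0.20]
    drugs = (DrugSpec("drugx", 0.10),) + tuple(
        DrugSpec(f"bg{i}", p) for i, p in enumerate(bg)
    )
    events = (EventSpec("event of interest", event_prob, ("planted",)),) + tuple(
        EventSpec(f"noise{i}", p, ())
        for i, p in enumerate([0.15, 0.18, 0.12, 0.14, 0.10, 0.08])
    )
    return GeneratorConfig(
        n_reports=n,
        drug_catalog=drugs,
        event_catalog=events,
        association_multipliers={("drugx", "planted"): lam},
        missing_rates=NO_MISSING,
        seed=seed,
    )


@pytest.fixture
def target_lexicon() -> DrugLexicon:
    return DrugLexicon("drugx", frozenset({"drugx"}))


@pytest.fixture
def planted_category() -> SmqCategory:
    return SmqCategory("planted", 90000001, frozenset({"pt a", "pt b", "event of interest"}))


@pytest.fixture
def three_reports() -> ReportSet:
    """Hand-built three-report set with a missing-field record."""
    ts = pd.Timestamp
    reports = [
        SafetyReport(
            report_id="A1",
            sex="F",
            age=61.0,
            country="US",
            reporting_year=2016,
            event_date=ts("2016-04-01"),
            drugs=(DrugEntry("Kyprolis", ts("2016-03-01"), ts("2016-05-01")),),
            reactions=("cardiac failure",),
            outcomes=frozenset({"hospitalization"}),
        ),
        SafetyReport(
            report_id="A2",
            sex="M",
            age=70.0,
            country="DE",
            reporting_year=2017,
            event_date=ts("2017-06-15"),
            drugs=(
                DrugEntry("carfilzomib", ts("2017-05-01"), None),
                DrugEntry("dexamethasone", ts("2017-05-01"), ts("2017-07-01")),
            ),
            reactions=("pulmonary hypertension", "nausea"),
            outcomes=frozenset({"death"}),
        ),
        SafetyReport(
            report_id="A3",
            sex=None,
            age=None,
            country="JP",
            reporting_year=2018,
            event_date=None,
            drugs=(DrugEntry("bortezomib", None, None),),
            reactions=("rash",),
            outcomes=frozenset(),
        ),
    ]
    return ReportSet.from_reports(reports)
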