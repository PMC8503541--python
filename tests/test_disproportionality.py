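"""Contingency tables, shrunk IC, ROR, the signal rule, and analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import faersig as fs
from faersig import reference as ref
from faersig.disproportionality import (
    ContingencyTable,
    SignalEstimate,
    signal_rule,
)
from faersig.vocabulary import SmqCategory

from conftest import planted_pair_config

cells = st.integers(min_value=0, max_value=10_000)


def _lex():
    return fs.DrugLexicon("drugx", frozenset({"drugx"}))


def _cat(pts=("event of interest",)):
    return SmqCategory("planted", 90000001, frozenset(pts))


class TestExpectedCount:
    def test_zero_drug_margin(self):
        assert fs.expected_count(ContingencyTable(0, 0, 10, 90)) == 0.0

    def test_total_row_reconstruction_value(self):
        table = fs.reconstruct_table(
            a=ref.N_CARDIOVASCULAR, n_drug=ref.N_DRUG, n_total=ref.N_TOTAL,
            ror=ref.TOTAL_ROR,
        )
        assert fs.expected_count(table) == pytest.approx(1805.0, abs=0.5)

    def test_independence_table_expected_equals_observed(self):
        t = ContingencyTable(10, 90, 990, 8910)  # a = n_drug*n_event/n_total exactly
        assert fs.expected_count(t) == pytest.approx(t.a)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            fs.expected_count(ContingencyTable(0, 0, 0, 0))


class TestShrunkIc:
    def test_zero_observed_zero_expected_gives_zero(self):
        ic, _, _ = fs.shrunk_ic(ContingencyTable(0, 0, 0, 100))
        assert ic == 0.0

    def test_identity_case_is_exactly_zero(self):
        # a == n_expected: log2((a+.5)/(a+.5)) == 0
        t = ContingencyTable(10, 90, 990, 8910)
        assert fs.shrunk_ic(t)[0] == pytest.approx(0.0, abs=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_sign_iff_observed_exceeds_expected(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        ic = fs.shrunk_ic(t)[0]
        exp = fs.expected_count(t)
        assert (ic > 0) == (a > exp)

    @given(a=st.integers(1, 10_000), b=cells, c=cells, d=cells)
    def test_shrinkage_attenuates_positive_ratios(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        exp = fs.expected_count(t)
        if exp <= 0 or a <= exp:
            return
        assert fs.shrunk_ic(t)[0] < math.log2(a / exp)

    def test_bounds_bracket_point_estimate_both_methods(self):
        t = ContingencyTable(40, 400, 4000, 100_000)
        for method in ("approximation", "gamma"):
            ic, lo, hi = fs.shrunk_ic(t, method=method)
            assert lo < ic < hi


class TestRor:
    def test_corrected_odds_ratio_arithmetic(self):
        ror, _, _ = fs.ror_estimate(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.43, abs=0.005)

    def test_symmetric_table_is_null(self):
        ror, lo, hi = fs.ror_estimate(ContingencyTable(50, 50, 50, 50))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_as_printed_variant_equals_two_to_the_ic(self):
        t = ContingencyTable(37, 205, 1_111, 55_000)
        ic, lo, hi = fs.shrunk_ic(t)
        ror, rlo, rhi = fs.ror_estimate(t, variant="as-printed")
        assert ror == pytest.approx(2.0**ic, rel=1e-12)
        assert rlo == pytest.approx(2.0**lo, rel=1e-12)
        assert rhi == pytest.approx(2.0**hi, rel=1e-12)


class TestSignalRule:
    @pytest.mark.parametrize(
        "ic025, ror025, n, expect",
        [
            (0.85, 1.95, 3370, True),  # total cardiovascular row
            (0.2, 1.5, 2, False),  # fewer than three records
            (0.0, 1.2, 100, False),  # IC bound exactly zero: strict
            (0.1, 1.0, 100, False),  # ROR bound exactly one: strict
            (0.1, 1.01, 3, True),  # boundary n = 3 counts
        ],
    )
    def test_three_part_rule(self, ic025, ror025, n, expect):
        assert signal_rule(ic025, ror025, n) is expect
        est = SignalEstimate(n=n, ic=1, ic025=ic025, ic975=2, ror=2,
                             ror025=ror025, ror975=3, is_signal=expect)
        assert fs.evaluate_signal(est) is expect


class TestBuildTable:
    def test_one_report_per_cell(self):
        ids = [f"r{i}" for i in range(4)]
        demo = pd.DataFrame(
            {"report_id": ids, "sex": "M", "age": 60.0, "country": "US",
             "event_date": pd.NaT, "fda_date": pd.Timestamp("2018-01-01")}
        )
        reports = fs.ReportSet(demo)
        hd = pd.Series([True, True, False, False], index=ids)
        he = pd.Series([True, False, True, False], index=ids)
        t = fs.build_table(reports, hd, he)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_cells_partition_the_reports(self):
        cfg = planted_pair_config(41, n=20_000)
        reports = fs.generate_reports(cfg)
        t = fs.build_table(
            reports,
            fs.match_drug_mask(reports, _lex()),
            fs.category_membership(reports, [_cat()])["planted"],
        )
        assert t.n_total == len(reports)

    def test_compound_predicate_equals_prefilter(self):
        cfg = planted_pair_config(42, n=10_000)
        reports = fs.generate_reports(cfg)
        stratum = reports.demo["sex"].eq("F").to_numpy()
        hd = fs.match_drug_mask(reports, _lex())
        he = fs.category_membership(reports, [_cat()])["planted"]
        sub = reports.filter_mask(pd.Series(stratum))
        ids = sub.demo["report_id"].to_numpy()
        t_pre = fs.build_table(sub, hd.loc[ids], he.loc[ids])
        in_stratum = pd.Series(stratum, index=reports.demo["report_id"].to_numpy())
        t_comp = fs.build_table(
            reports.filter_mask(pd.Series(stratum)), hd[in_stratum], he[in_stratum]
        )
        assert (t_pre.a, t_pre.b, t_pre.c, t_pre.d) == (t_comp.a, t_comp.b, t_comp.c, t_comp.d)

    def test_empty_reportset_errors(self):
        empty = fs.ReportSet(pd.DataFrame(columns=["report_id", "sex", "age", "country", "event_date", "fda_date"]))
        with pytest.raises(ValueError):
            fs.build_table(empty, lambda r: True, lambda r: True)


class TestCategoryAnalysis:
    def test_planted_association_flagged_alone(self):
        cfg = planted_pair_config(51, lam=4.0, n=100_000, event_prob=0.01)
        # add an unassociated decoy category
        from faersig.synthetic import EventSpec, GeneratorConfig
        events = cfg.event_catalog + (EventSpec("decoy pt", 0.01, ("decoy",)),)
        cfg = GeneratorConfig(**{**cfg.__dict__, "event_catalog": events})
        reports = fs.generate_reports(cfg)
        cats = [_cat(), SmqCategory("decoy", 90000002, frozenset({"decoy pt"}))]
        res = fs.run_category_analysis(reports, _lex(), cats).set_index("category")
        assert bool(res.loc["planted", "signal"])
        assert not bool(res.loc["decoy", "signal"])
        # expected count is large enough for the rule to be meaningful
        gt = fs.ground_truth_pair(cfg, "drugx", "planted")
        assert gt.p_drug * gt.p_event * len(reports) >= 20

    def test_row_counts_match_vocabulary_counts(self):
        cfg = fs.example_config(n_reports=5000, seed=52)
        reports = fs.generate_reports(cfg)
        cats = fs.categories_from_config(cfg)
        lex = fs.CARFILZOMIB_LEXICON
        res = fs.run_category_analysis(reports, lex, cats).set_index("category")
        hd = fs.match_drug_mask(reports, lex)
        member = fs.category_membership(reports, cats)
        for cat in cats:
            assert res.loc[cat.name, "n"] == int((member[cat.name] & hd).sum())
        assert res.iloc[0]["n"] == int((member.any(axis=1) & hd).sum())


class TestTimeSeries:
    def test_single_year_equals_overall(self):
        cfg = planted_pair_config(61, n=20_000)
        cfg = type(cfg)(**{**cfg.__dict__, "date_window": ("2018-01-01", "2018-10-01")})
        reports = fs.generate_reports(cfg)
        ts = fs.ic_time_series(reports, _lex(), _cat())
        assert len(ts) == 1
        overall = fs.run_category_analysis(reports, _lex(), [_cat()]).set_index("category")
        assert ts.iloc[0]["ic"] == pytest.approx(overall.loc["planted", "ic"])

    def test_interval_width_non_increasing_cumulatively(self):
        reports = fs.generate_reports(planted_pair_config(62, lam=3.0, n=60_000, event_prob=0.01))
        ts = fs.ic_time_series(reports, _lex(), _cat())
        widths = (ts["ic975"] - ts["ic025"]).to_numpy()
        assert (np.diff(widths) <= 1e-12).all()

    def test_lambda_ramp_gives_increasing_ic(self):
        frames = []
        for year, lam, seed in ((2015, 1.0, 71), (2016, 3.0, 72), (2017, 9.0, 73)):
            cfg = planted_pair_config(seed, lam=lam, n=20_000, event_prob=0.01)
            r = fs.generate_reports(cfg)
            r.demo["fda_date"] = pd.Timestamp(f"{year}-06-01")
            r.demo["report_id"] = r.demo["report_id"] + f"-{year}"
            r.drugs["report_id"] = r.drugs["report_id"] + f"-{year}"
            r.reactions["report_id"] = r.reactions["report_id"] + f"-{year}"
            r.outcomes["report_id"] = r.outcomes["report_id"] + f"-{year}"
            frames.append(r)
        merged = fs.ReportSet(
            pd.concat([f.demo for f in frames], ignore_index=True),
            pd.concat([f.drugs for f in frames], ignore_index=True),
            pd.concat([f.reactions for f in frames], ignore_index=True),
            pd.concat([f.outcomes for f in frames], ignore_index=True),
        )
        ts = fs.ic_time_series(merged, _lex(), _cat())
        ics = ts["ic"].to_numpy()
        assert list(ts["year"]) == [2015, 2016, 2017]
        assert ics[0] < ics[1] < ics[2]


def _two_stream_set(lam_a, lam_b, column, value_a, value_b, n=30_000, seeds=(81, 82)):
    """Concatenate two generated streams, overriding one demo column."""
    frames = []
    for lam, seed, value, tag in ((lam_a, seeds[0], value_a, "a"), (lam_b, seeds[1], value_b, "b")):
        cfg = planted_pair_config(seed, lam=lam, n=n, event_prob=0.015)
        r = fs.generate_reports(cfg)
        r.demo[column] = value
        for frame in (r.demo, r.drugs, r.reactions, r.outcomes):
            frame["report_id"] = frame["report_id"] + f"-{tag}"
        frames.append(r)
    return fs.ReportSet(
        pd.concat([f.demo for f in frames], ignore_index=True),
        pd.concat([f.drugs for f in frames], ignore_index=True),
        pd.concat([f.reactions for f in frames], ignore_index=True),
        pd.concat([f.outcomes for f in frames], ignore_index=True),
    )


class TestStratified:
    def test_association_planted_in_females_only(self):
        merged = _two_stream_set(6.0, 1.0, "sex", "F", "M")
        res = fs.stratified_analysis(merged, _lex(), [_cat()])
        res = res[res["category"] == "planted"]
        by = res.set_index(["sex", "age_group"]).sort_index()["signal"]
        assert by.loc[("F",)].all()
        assert not by.loc[("M",)].any()

    def test_uniform_association_flagged_in_all_strata(self):
        merged = _two_stream_set(5.0, 5.0, "country", "US", "DE")
        res = fs.stratified_analysis(merged, _lex(), [_cat()])
        res = res[res["category"] == "planted"]
        assert res["signal"].all()

    def test_one_stratum_partition_equals_unstratified(self):
        cfg = planted_pair_config(83, n=20_000)
        reports = fs.generate_reports(cfg)
        reports.demo["sex"] = "F"
        reports.demo["age"] = 70.0
        strat = fs.stratified_analysis(reports, _lex(), [_cat()])
        overall = fs.run_category_analysis(reports, _lex(), [_cat()])
        strat_row = strat[(strat["sex"] == "F") & (strat["category"] == "planted")].iloc[0]
        overall_row = overall.set_index("category").loc["planted"]
        assert strat_row["ic"] == pytest.approx(overall_row["ic"])
        assert len(strat[strat["sex"] == "M"]) == 0


class TestRestrictedBackground:
    def test_always_true_predicate_equals_main_analysis(self):
        reports = fs.generate_reports(planted_pair_config(91, n=20_000))
        ids = reports.demo["report_id"].to_numpy()
        full = fs.run_category_analysis(reports, _lex(), [_cat()])
        restricted = fs.restricted_background_analysis(
            reports, _lex(), [_cat()], pd.Series(True, index=ids)
        )
        pd.testing.assert_frame_equal(full, restricted)

    def test_confounded_association_shrinks_under_restriction(self):
        """An indication subgroup with high drug use AND a high background
        event rate (no within-subgroup association) inflates the pooled IC;
        restricting the background to the subgroup deflates it."""
        from faersig.synthetic import DrugSpec, EventSpec, GeneratorConfig

        def stream(drug_p, event_p, seed, country, tag):
            cfg = GeneratorConfig(
                n_reports=30_000,
                drug_catalog=(DrugSpec("drugx", drug_p), DrugSpec("bg0", 0.5),
                              DrugSpec("bg1", 0.4)),
                event_catalog=(EventSpec("event of interest", event_p, ("planted",)),
                               EventSpec("noise0", 0.2, ())),
                association_multipliers={},
                seed=seed,
            )
            r = fs.generate_reports(cfg)
            r.demo["country"] = country
            for frame in (r.demo, r.drugs, r.reactions, r.outcomes):
                frame["report_id"] = frame["report_id"] + tag
            return r
        indication = stream(0.40, 0.030, 101, "US", "-mm")
        other = stream(0.01, 0.002, 102, "DE", "-bg")
        merged = fs.ReportSet(
            pd.concat([indication.demo, other.demo], ignore_index=True),
            pd.concat([indication.drugs, other.drugs], ignore_index=True),
            pd.concat([indication.reactions, other.reactions], ignore_index=True),
            pd.concat([indication.outcomes, other.outcomes], ignore_index=True),
        )
        ids = merged.demo["report_id"].to_numpy()
        in_indication = pd.Series(merged.demo["country"].eq("US").to_numpy(), index=ids)
        full = fs.run_category_analysis(merged, _lex(), [_cat()]).set_index("category")
        restr = fs.restricted_background_analysis(
            merged, _lex(), [_cat()], in_indication
        ).set_index("category")
        assert full.loc["planted", "ic"] > 0.5  # confounding fakes a signal
        assert restr.loc["planted", "ic"] < full.loc["planted", "ic"]
        assert abs(restr.loc["planted", "ic"]) < 0.3  # restriction removes it

    def test_empty_restriction_errors(self):
        reports = fs.generate_reports(planted_pair_config(92, n=1000))
        ids = reports.demo["report_id"].to_numpy()
        with pytest.raises(ValueError):
            fs.restricted_background_analysis(
                reports, _lex(), [_cat()], pd.Series(False, index=ids)
            )
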