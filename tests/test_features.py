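import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from pvlabel.cohort import LabeledPair
from pvlabel.features import (
    FEATURE_NAMES,
    CaseIndex,
    apply_transform,
    compute_feature_table,
    compute_features,
    finalize_features,
    fit_transform,
    impute_onset_days,
)
from pvlabel.quarters import Quarter
from pvlabel.report_store import DrugEntry, ReactionEntry, ReportCase


def make_case(cid, quarter, drug="D1", pt="Sepsis", onset=None, start=None,
              outcome="recovered", action="continued", rechallenge="unknown",
              version=1, sex="male"):
    return ReportCase(
        case_id=cid,
        quarter_received=Quarter.parse(quarter),
        version=version,
        sex=sex,
        age_band="40-49",
        weight_band="60-69kg",
        drugs=[DrugEntry(drug, start_date=start, action=action, rechallenge=rechallenge)],
        reactions=[ReactionEntry(pt, onset_date=onset, outcome=outcome, version=version)],
        history=["hypertension"],
    )


def pair(drug="D1", disease="Sepsis", as_of="2019Q4", label="positive"):
    return LabeledPair(drug, disease, label, Quarter.parse(as_of))


class TestHandCounts:
    def test_zero_report_pair(self, gmap):
        index = CaseIndex([], gmap)
        v = compute_features(pair(), index)
        assert v["n_patients"] == 0
        assert v["quarters_since_first"] == 0
        assert math.isnan(v["index_a"])
        assert math.isnan(v["onset_days_mean"])

    def test_quarters_since_first_inclusive(self, gmap):
        # first report 2019Q1, as-of 2019Q4, 8 patients -> 4 quarters, 2.0/quarter
        cases = [
            make_case(f"C{i}", q)
            for i, q in enumerate(
                ["2019Q1", "2019Q1", "2019Q2", "2019Q2", "2019Q3", "2019Q3",
                 "2019Q4", "2019Q4"]
            )
        ]
        v = compute_features(pair(), CaseIndex(cases, gmap))
        assert v["n_patients"] == 8
        assert v["quarters_since_first"] == 4
        assert v["patients_per_quarter"] == pytest.approx(2.0)
        assert (v["new_patients_q1"], v["new_patients_q2"],
                v["new_patients_q3"], v["new_patients_q4"]) == (2, 2, 2, 2)

    def test_flag_counts_and_windows(self, gmap):
        start = dt.date(2019, 1, 10)
        cases = [
            make_case("C1", "2019Q1", onset=start + dt.timedelta(days=10), start=start,
                      outcome="death", action="discontinued"),
            make_case("C2", "2019Q2", onset=start + dt.timedelta(days=25), start=start,
                      rechallenge="readministered"),
            make_case("C3", "2019Q4", onset=start + dt.timedelta(days=80), start=start),
            make_case("C4", "2019Q4", onset=None, start=start),
        ]
        v = compute_features(pair(), CaseIndex(cases, gmap))
        assert v["n_deaths"] == 1
        assert v["n_rechallenge"] == 1
        assert v["n_discontinued"] == 1
        assert (v["n_onset_within_15"], v["n_onset_within_30"], v["n_onset_within_90"]) == (1, 2, 3)
        assert v["onset_days_mean"] == pytest.approx((10 + 25 + 80) / 3)
        assert v["onset_days_median"] == 25
        assert v["new_onset_within_90_q1"] == 1  # only C3 is in the last quarter
        assert v["new_deaths_q1"] == 0

    def test_reports_and_missingness_per_case(self, gmap):
        cases = [
            make_case("C1", "2019Q1", version=3),
            make_case("C2", "2019Q1", version=1, sex=""),
        ]
        cases[1].sex = None
        v = compute_features(pair(), CaseIndex(cases, gmap))
        assert v["reports_per_case"] == pytest.approx(2.0)
        # C1 misses onset+start dates (2); C2 additionally misses sex (3)
        assert v["missing_per_case"] == pytest.approx(2.5)

    def test_dispro_features_match_module(self, small_index, gmap):
        from pvlabel import disproportionality as dis

        p = pair("D000", "Interstitial lung disease", "2018Q1")
        v = compute_features(p, small_index)
        t = small_index.contingency("D000", "Interstitial lung disease",
                                    Quarter.parse("2018Q1"))
        assert v["ror"] == pytest.approx(dis.ror(t).value, nan_ok=True)
        assert v["prr"] == pytest.approx(dis.prr(t).value, nan_ok=True)
        assert v["yates_chisq"] == pytest.approx(dis.yates_chisq(t), nan_ok=True)


class TestBruteForceOracle:
    def test_count_features_match_per_report_loop(self, small_cleaned, small_index, gmap):
        """Each count feature equals an independent per-report recount."""
        p = pair("D000", "Interstitial lung disease", "2018Q2")
        v = compute_features(p, small_index)
        as_of = p.as_of_quarter
        n = deaths = rechal = disc = w15 = w30 = w90 = 0
        first = None
        for case in small_cleaned:
            if case.quarter_received > as_of:
                continue
            entries = [d for d in case.suspected() if d.drug_code == p.drug]
            matching = [r for r in case.reactions if gmap.map_pt(r.pt_name) == p.disease]
            if not entries or not matching:
                continue
            n += 1
            first = min(first or case.quarter_received, case.quarter_received)
            deaths += any(r.outcome == "death" for r in matching)
            rechal += any(d.rechallenge == "readministered" for d in entries)
            disc += any(d.action == "discontinued" for d in entries)
            starts = [d.start_date for d in entries if d.start_date]
            days = None
            if starts:
                ds = [(r.onset_date - min(starts)).days for r in matching if r.onset_date]
                days = min(ds) if ds else None
            if days is not None:
                w15 += days <= 15
                w30 += days <= 30
                w90 += days <= 90
        assert v["n_patients"] == n > 0
        assert v["n_deaths"] == deaths
        assert v["n_rechallenge"] == rechal
        assert v["n_discontinued"] == disc
        assert (v["n_onset_within_15"], v["n_onset_within_30"], v["n_onset_within_90"]) \
            == (w15, w30, w90)
        assert v["quarters_since_first"] == as_of - first + 1

    def test_window_monotonicity_everywhere(self, small_index, small_db, gmap):
        pairs = [pair(d, s, "2019Q4") for d, s in
                 [("D000", "Interstitial lung disease"), ("D001", "Hepatic function abnormal"),
                  ("D002", "Anaphylactic reaction")]]
        table = compute_feature_table(pairs, small_index)
        assert (table.n_onset_within_15 <= table.n_onset_within_30).all()
        assert (table.n_onset_within_30 <= table.n_onset_within_90).all()
        assert (table.n_onset_within_90 <= table.n_patients).all()


class TestNoLeakage:
    def test_future_reports_do_not_change_features(self, gmap):
        base = [
            make_case("C1", "2019Q1", onset=dt.date(2019, 1, 20), start=dt.date(2019, 1, 1)),
            make_case("C2", "2019Q2"),
        ]
        future = [
            make_case("C9", "2019Q4", outcome="death", version=5),
            make_case("C8", "2020Q1", drug="D1"),
        ]
        p = pair(as_of="2019Q2")
        v_base = compute_features(p, CaseIndex(base, gmap))
        v_mut = compute_features(p, CaseIndex(base + future, gmap))
        assert v_base == v_mut  # bit-identical, NaNs and all
        # mutate the future reports arbitrarily: still identical
        future[0].reactions = [ReactionEntry("Sepsis", dt.date(2019, 12, 1), "death", 9)]
        v_mut2 = compute_features(p, CaseIndex(base + future, gmap))
        assert v_base == v_mut2


class TestImputation:
    def test_missing_onset_filled_from_other_drugs(self, gmap):
        start = dt.date(2019, 1, 1)
        donors = [
            make_case(f"C{i}", "2019Q1", drug="D2", onset=start + dt.timedelta(days=d),
                      start=start)
            for i, d in enumerate([10, 12, 40])
        ]
        blank = [make_case("C9", "2019Q2", drug="D1", onset=None, start=None)]
        index = CaseIndex(donors + blank, gmap)
        table = compute_feature_table([pair("D1"), pair("D2")], index)
        assert math.isnan(table.loc[0, "onset_days_mean"])
        imputed = impute_onset_days(table, index)
        assert imputed.loc[0, "onset_days_mean"] == 12.0  # donor median
        assert imputed.loc[0, "onset_days_median"] == 12.0
        assert bool(imputed.loc[0, "onset_imputed"])

    def test_observed_values_untouched(self, gmap):
        start = dt.date(2019, 1, 1)
        cases = [make_case("C1", "2019Q1", onset=start + dt.timedelta(days=7), start=start)]
        index = CaseIndex(cases, gmap)
        table = compute_feature_table([pair()], index)
        imputed = impute_onset_days(table, index)
        assert imputed.loc[0, "onset_days_mean"] == 7.0
        assert not bool(imputed.loc[0, "onset_imputed"])

    def test_no_donor_keeps_missing_and_logs(self, gmap, caplog):
        blank = [make_case("C9", "2019Q2", onset=None, start=None)]
        index = CaseIndex(blank, gmap)
        table = compute_feature_table([pair()], index)
        with caplog.at_level("WARNING"):
            imputed = impute_onset_days(table, index)
        assert math.isnan(imputed.loc[0, "onset_days_mean"])
        assert "no donor" in caplog.text
        final = finalize_features(imputed)
        assert final.loc[0, "onset_days_mean"] == 0.0
        assert final[list(FEATURE_NAMES)].notna().all().all()


class TestTransforms:
    @pytest.fixture
    def train_test(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(
            {"x": rng.normal(3, 2, 200), "y": rng.exponential(5, 200), "const": 1.0}
        )
        test = pd.DataFrame({"x": rng.normal(3, 2, 50), "y": rng.exponential(5, 50),
                             "const": 1.0})
        return train, test

    def test_standardize_definition(self, train_test):
        train, test = train_test
        spec, t = fit_transform(train, "standardize")
        assert t["x"].mean() == pytest.approx(0, abs=1e-12)
        assert t["x"].std(ddof=0) == pytest.approx(1)
        assert (t["const"] == 0).all()
        held = apply_transform(spec, test)
        assert held["x"].mean() != pytest.approx(0, abs=1e-3)  # spec is frozen

    def test_quantile_range_and_constant(self, train_test):
        train, test = train_test
        spec, t = fit_transform(train, "quantile")
        assert ((t >= 0) & (t <= 1)).all().all()
        assert (t["const"] == 0.5).all()
        held = apply_transform(spec, test)
        assert ((held >= 0) & (held <= 1)).all().all()
        # monotone: ordering preserved
        order = np.argsort(test["x"].to_numpy())
        assert (np.diff(held["x"].to_numpy()[order]) >= 0).all()

    def test_frozen_spec_differs_from_refit(self, train_test):
        train, test = train_test
        spec, _ = fit_transform(train, "standardize")
        refit_spec, _ = fit_transform(test, "standardize")
        a = apply_transform(spec, test)
        b = apply_transform(refit_spec, test)
        assert not np.allclose(a["x"], b["x"])

    def test_unknown_method_rejected(self, train_test):
        with pytest.raises(ValueError, match="unknown transform"):
            fit_transform(train_test[0], "boxcox")
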