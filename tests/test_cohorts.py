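import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rxcoverage import cohorts
from rxcoverage.cohorts import (
    censor_quarter,
    eligibility_matrix,
    eligible,
    odd_classify,
    odd_classify_bulk,
)
from rxcoverage.quarters import QuarterId, StudyWindow
from rxcoverage.synthetic import SimConfig, generate_diabetes_history, generate_population

from .oracles import odd_oracle

ORIGIN = dt.date(2010, 1, 1)


def _claims(days, code="250"):
    return pd.DataFrame(
        {
            "patient_id": 1,
            "service_date": pd.to_datetime(ORIGIN) + pd.to_timedelta(list(days), unit="D"),
            "diagnosis_code": code,
        }
    )


def _discharges(rows):
    """rows: (day, code, pregnancy_flag)"""
    return pd.DataFrame(
        {
            "patient_id": 1,
            "discharge_date": pd.to_datetime(ORIGIN) + pd.to_timedelta([r[0] for r in rows], unit="D"),
            "diagnosis_code": [r[1] for r in rows],
            "pregnancy_delivery": [r[2] for r in rows],
        }
    )


class TestOddClassify:
    def test_pair_within_two_years(self):
        st = odd_classify(_claims([0, 700]), _discharges([]))
        assert st.positive and st.basis == "claims-pair"
        assert (st.index_date - ORIGIN).days == 700

    def test_pair_outside_two_years(self):
        st = odd_classify(_claims([0, 800]), _discharges([]))
        assert not st.positive and st.index_date is None

    def test_boundary_exactly_730_days(self):
        assert odd_classify(_claims([0, 730]), _discharges([])).positive
        assert not odd_classify(_claims([0, 731]), _discharges([])).positive

    def test_single_hospitalization_suffices(self):
        st = odd_classify(_claims([]), _discharges([(400, "250", False)]))
        assert st.positive and st.basis == "hospitalization"
        assert (st.index_date - ORIGIN).days == 400

    def test_gestational_claim_does_not_count(self):
        # one 250-claim 100 days before a delivery discharge is excluded,
        # leaving a single clean claim -> negative
        claims = _claims([100, 300])  # delivery at day 200
        disch = _discharges([(200, "650", True)])
        st = odd_classify(claims, disch)
        assert not st.positive

    def test_gestational_window_bounds(self):
        disch = _discharges([(200, "650", True)])
        # claims at 200-120 and 200+180 are excluded (inclusive window)
        assert not odd_classify(_claims([80, 380]), disch).positive
        # claims just outside the window survive and pair up (gap 602 days)
        assert odd_classify(_claims([79, 381]), disch).positive

    def test_non_diabetes_codes_ignored(self):
        st = odd_classify(_claims([0, 100], code="780"), _discharges([]))
        assert not st.positive

    def test_index_is_earliest_qualifying_date(self):
        # discharge later than the claim pair: pair wins
        st = odd_classify(_claims([0, 100]), _discharges([(500, "250", False)]))
        assert st.basis == "claims-pair" and (st.index_date - ORIGIN).days == 100

    def test_empty_records_negative(self):
        st = odd_classify(_claims([]), _discharges([]))
        assert not st.positive


class TestOddOracleEquivalence:
    def test_engine_matches_exhaustive_scan(self, rng):
        """Rule engine vs brute-force pair/discharge scan with gestational
        filtering on 1000 random record sets, exact agreement."""
        for _ in range(1000):
            n_claims = int(rng.integers(0, 7))
            n_disch = int(rng.integers(0, 3))
            claim_days = rng.integers(0, 2000, size=n_claims)
            claim_codes = rng.choice(["250", "2501", "780"], size=n_claims, p=[0.6, 0.2, 0.2])
            disch = [
                (
                    int(rng.integers(0, 2000)),
                    str(rng.choice(["250", "650", "480"])),
                    bool(rng.random() < 0.4),
                )
                for _ in range(n_disch)
            ]
            expect_pos, expect_day = odd_oracle(
                list(zip(claim_days, claim_codes)), disch
            )
            st = odd_classify(
                _claims(claim_days).assign(diagnosis_code=claim_codes), _discharges(disch)
            )
            assert st.positive == expect_pos
            if expect_pos:
                assert (st.index_date - ORIGIN).days == expect_day

    def test_bulk_matches_scalar(self, small_bundle):
        bulk = odd_classify_bulk(small_bundle.claims, small_bundle.discharges)
        pids = small_bundle.patients["patient_id"].to_numpy()
        sample = pids[:: max(len(pids) // 120, 1)]
        for pid in sample:
            st = odd_classify(
                small_bundle.claims[small_bundle.claims["patient_id"] == pid],
                small_bundle.discharges[small_bundle.discharges["patient_id"] == pid],
            )
            assert st.positive == (pid in bulk.index)
            if st.positive:
                row = bulk.loc[pid]
                assert row["index_date"].date() == st.index_date
                assert row["basis"] == st.basis


def _window():
    return StudyWindow.calendar_quarters(QuarterId(2010, 1), QuarterId(2016, 4), QuarterId(2013, 2))


def _spells(end="2017-01-01", start="2000-01-01", virtual=False, with_virtual=False):
    d = {
        "patient_id": [1],
        "start_date": pd.to_datetime([start]),
        "end_date": pd.to_datetime([end]),
    }
    if with_virtual:
        d["virtual"] = [virtual]
    return pd.DataFrame(d)


def _patient(death=None, **kw):
    base = {
        "patient_id": 1,
        "birth_date": pd.Timestamp("1940-06-15"),
        "sex": "F",
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "emr_diabetes_flag": False,
        "emr_flag_date": pd.NaT,
        "ami_history_date": pd.NaT,
    }
    base.update(kw)
    return pd.Series(base)


class TestCensorQuarter:
    def test_death_maps_to_its_quarter(self):
        ev = censor_quarter(
            _patient(death="2014-05-10"),
            [dt.date(2016, 12, 1)],
            _spells(),
            _spells(with_virtual=True),
            _window(),
        )
        assert ev.quarter == QuarterId(2014, 2) and ev.reason == "censored-death"

    def test_last_encounter_censors_following_quarter(self):
        ev = censor_quarter(
            _patient(),
            [dt.date(2015, 3, 1)],
            _spells(),
            _spells(with_virtual=True),
            _window(),
        )
        assert ev.quarter == QuarterId(2015, 2)
        assert ev.reason == "censored-last-encounter"

    def test_recent_last_encounter_not_censored(self):
        # contact inside the look-ahead margin of the study end: no event
        ev = censor_quarter(
            _patient(), [dt.date(2016, 8, 1)], _spells(), _spells(with_virtual=True), _window()
        )
        assert ev is None

    def test_eligibility_loss(self):
        ev = censor_quarter(
            _patient(),
            [dt.date(2016, 12, 1)],
            _spells(end="2013-08-15"),
            _spells(with_virtual=True),
            _window(),
        )
        assert ev.quarter == QuarterId(2013, 3)
        assert ev.reason == "censored-eligibility-loss"

    def test_disenrollment(self):
        ev = censor_quarter(
            _patient(),
            [dt.date(2016, 12, 1)],
            _spells(),
            _spells(end="2012-02-01", with_virtual=True),
            _window(),
        )
        assert ev.quarter == QuarterId(2012, 1)
        assert ev.reason == "censored-disenrollment"

    def test_earliest_event_wins(self):
        ev = censor_quarter(
            _patient(death="2016-01-01"),
            [dt.date(2016, 12, 1)],
            _spells(end="2011-06-01"),
            _spells(with_virtual=True),
            _window(),
        )
        assert ev.reason == "censored-eligibility-loss"
        assert ev.quarter == QuarterId(2011, 2)

    def test_no_events(self):
        ev = censor_quarter(
            _patient(), [dt.date(2016, 12, 1)], _spells(), _spells(with_virtual=True), _window()
        )
        assert ev is None

    def test_contradictory_overlapping_enrollment_spells(self):
        spells = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "start_date": pd.to_datetime(["2000-01-01", "2010-01-01"]),
                "end_date": pd.to_datetime(["2012-01-01", "2017-01-01"]),
                "virtual": [False, True],
            }
        )
        with pytest.raises(ValueError, match="contradictory"):
            censor_quarter(_patient(), [dt.date(2016, 12, 1)], _spells(), spells, _window())


class TestEligible:
    def _bundle(self, patients, claims, discharges, encounters=None):
        from rxcoverage.synthetic import PatientBundle, _empty_tables

        t = _empty_tables()
        n = len(patients)
        spells = pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "start_date": pd.Timestamp("2000-01-01"),
                "end_date": pd.Timestamp("2017-01-01"),
            }
        )
        enroll = spells.copy()
        enroll["virtual"] = False
        # a late routine contact per patient so the last-encounter rule
        # does not censor these fixtures
        late = pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "service_date": pd.Timestamp("2016-12-01"),
                "diagnosis_code": "780",
            }
        )
        claims = pd.concat([c for c in (claims, late) if len(c)], ignore_index=True)
        b = PatientBundle(
            patients=patients,
            dispensings=t["dispensings"],
            claims=claims,
            discharges=discharges,
            eligibility_spells=spells,
            enrollment_spells=enroll,
            encounters=encounters if encounters is not None else t["encounters"],
            config=SimConfig(n_patients=n),
        )
        return b

    def test_age_boundary_66th_birthday_inside_quarter(self):
        # 66th birthday on the second day of 2013Q1 -> too young that quarter
        p = _patient(birth_date=pd.Timestamp("1947-01-02"))
        claims = _claims([0, 100])
        b = self._bundle(pd.DataFrame([p]), claims, _discharges([]))
        d1 = eligible(p, QuarterId(2013, 1), "admin", b)
        assert not d1.eligible and d1.reason_if_not == "too-young"
        assert eligible(p, QuarterId(2013, 2), "admin", b).eligible

    def test_diabetes_index_inside_quarter_defers_entry(self):
        # index date falls inside 2012Q3 -> not eligible until 2012Q4
        days = [(dt.date(2012, 8, 1) - ORIGIN).days]
        claims = _claims([days[0] - 100, days[0]])
        p = _patient()
        b = self._bundle(pd.DataFrame([p]), claims, _discharges([]))
        d = eligible(p, QuarterId(2012, 3), "admin", b)
        assert not d.eligible and d.reason_if_not == "no-diabetes-yet"
        assert eligible(p, QuarterId(2012, 4), "admin", b).eligible

    def test_emr_entry_at_first_encounter_quarter(self):
        p = _patient(emr_diabetes_flag=True, emr_flag_date=pd.Timestamp("2009-05-01"))
        enc = pd.DataFrame(
            {"patient_id": [1], "encounter_date": [pd.Timestamp("2012-08-15")]}
        )
        b = self._bundle(pd.DataFrame([p]), _claims([]), _discharges([]), encounters=enc)
        d = eligible(p, QuarterId(2012, 2), "emr", b)
        assert not d.eligible and d.reason_if_not == "pre-entry"
        assert eligible(p, QuarterId(2012, 3), "emr", b).eligible

    def test_emr_without_flag_never_eligible(self):
        p = _patient(emr_diabetes_flag=False)
        b = self._bundle(pd.DataFrame([p]), _claims([0, 100]), _discharges([]))
        d = eligible(p, QuarterId(2014, 1), "emr", b)
        assert not d.eligible and d.reason_if_not == "no-diabetes-yet"


class TestEligibilityMatrixProperties:
    def test_monotone_exit_and_entry(self, small_bundle):
        cq = eligibility_matrix(small_bundle, "admin", with_reasons=True)
        el = cq.eligible
        reasons = cq.reasons
        labels = np.asarray(("",) + cq._REASON_LABELS, dtype=object)[reasons.ravel() + 1]
        labels = labels.reshape(reasons.shape)
        censored = np.char.startswith(labels.astype(str), "censored")
        # once censored, never again eligible
        seen = np.logical_or.accumulate(censored, axis=1)
        assert not (seen & el).any()
        # entry is monotone: eligible at q and not at q+1 only via censoring/age
        left = el[:, :-1] & ~el[:, 1:]
        bad = left & ~censored[:, 1:] & ~(labels[:, 1:] == "too-young")
        assert not bad.any()

    def test_bulk_matches_scalar_decisions(self, small_bundle):
        patients = small_bundle.patients.sort_values("patient_id").reset_index(drop=True)
        for algorithm in ("admin", "emr"):
            cq = eligibility_matrix(small_bundle, algorithm)
            rng = np.random.default_rng(4)
            for i in rng.integers(0, len(patients), size=25):
                j = int(rng.integers(0, len(cq.window)))
                d = eligible(patients.iloc[i], cq.window.quarters[j], algorithm, small_bundle)
                assert d.eligible == cq.eligible[i, j], (algorithm, i, j, d)

    def test_emr_subset_of_admin_age_censor_conditions(self, small_bundle):
        admin = eligibility_matrix(small_bundle, "admin")
        emr = eligibility_matrix(small_bundle, "emr")
        # the generator nests EMR-flagged cases inside administrative cases,
        # so EMR eligibility implies administrative eligibility
        assert not (emr.eligible & ~admin.eligible).any()


class TestGeneratedHistories:
    def test_truth_labels_agree_with_classifier(self):
        cfg = SimConfig(n_patients=0, rng_seed=3)
        rng = np.random.default_rng(99)
        for truth in (True, False):
            for _ in range(50):
                claims, disch = generate_diabetes_history(
                    {"patient_id": 1}, truth, cfg, rng=rng
                )
                st = odd_classify(claims, disch)
                assert st.positive == truth

    def test_truth_positive_index_precedes_window(self):
        cfg = SimConfig(n_patients=0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            claims, disch = generate_diabetes_history({"patient_id": 1}, True, cfg, rng=rng)
            st = odd_classify(claims, disch)
            assert st.index_date < cfg.study_start

    def test_near_miss_and_gestational_styles(self):
        cfg = SimConfig(n_patients=0)
        rng = np.random.default_rng(2)
        claims, disch = generate_diabetes_history(
            {"patient_id": 1}, False, cfg, rng=rng, style="near-miss"
        )
        assert len(claims) == 1 and not odd_classify(claims, disch).positive
        claims, disch = generate_diabetes_history(
            {"patient_id": 1}, False, cfg, rng=rng, style="gestational"
        )
        assert len(claims) == 2 and disch["pregnancy_delivery"].all()
        assert not odd_classify(claims, disch).positive

    def test_population_odd_consistency(self, small_bundle):
        bulk = odd_classify_bulk(small_bundle.claims, small_bundle.discharges)
        pids = np.sort(small_bundle.patients["patient_id"].to_numpy())
        positive = np.isin(pids, bulk.index.to_numpy())
        assert (positive == small_bundle.truth_diabetes).all()
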