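"""Cohort extraction: follow-up arithmetic, incident ascertainment,
look-back linkage and stratum tabulation against brute-force oracles."""
import numpy as np
import pandas as pd
import pytest

from sepsis_nnt import cohort
from sepsis_nnt.bands import ANALYSIS_BANDS, BandError, validate_bands
from sepsis_nnt.errors import ConfigurationError, DataError

from conftest import (
    STUDY_END,
    STUDY_START,
    make_events,
    make_patients,
    make_prescriptions,
    uniform_config,
)


# ---------------------------------------------------------------------------
# follow-up
# ---------------------------------------------------------------------------

class TestFollowUp:
    def test_long_registered_patient_contributes_whole_study(self):
        pats = make_patients([(1, "male", "1950-01-01", "2000-01-01", "2018-06-01", None)])
        fu = cohort.compute_follow_up(pats, STUDY_START, STUDY_END)
        assert fu.loc[0, "start"] == pd.Timestamp("2002-01-01")
        assert fu.loc[0, "end"] == pd.Timestamp("2017-12-31")
        # 16 years within the +-1 day convention (half-open interval)
        assert fu.loc[0, "person_years"] == pytest.approx(16.0, abs=1.5 / 365.25)

    def test_late_registration_contributes_zero(self):
        pats = make_patients([(1, "male", "1950-01-01", "2017-06-01", "2018-06-01", None)])
        fu = cohort.compute_follow_up(pats, STUDY_START, STUDY_END)
        assert fu.loc[0, "person_years"] == 0.0
        assert len(fu) == 1  # returned explicitly, not dropped

    def test_death_truncates_follow_up(self):
        pats = make_patients([(1, "female", "1930-01-01", "1995-01-01", "2017-12-31", "2010-07-01")])
        fu = cohort.compute_follow_up(pats, STUDY_START, STUDY_END)
        assert fu.loc[0, "end"] == pd.Timestamp("2010-07-01")

    def test_reversed_registration_raises(self):
        pats = make_patients([(1, "male", "1950-01-01", "2010-01-01", "2005-01-01", None)])
        with pytest.raises(DataError, match="registration_end"):
            cohort.compute_follow_up(pats, STUDY_START, STUDY_END)

    def test_person_years_match_day_counting_oracle(self, sim_tables):
        fu = cohort.compute_follow_up(sim_tables["patients"], STUDY_START, STUDY_END)
        oracle_days = sum(
            max(0, (row.end - row.start).days) for row in fu.itertuples()
        )
        assert fu["person_years"].sum() == pytest.approx(oracle_days / 365.25, rel=1e-12)

    def test_year_segments_partition_person_time(self, sim_tables):
        fu = cohort.compute_follow_up(sim_tables["patients"], STUDY_START, STUDY_END)
        segs = cohort.person_year_segments(sim_tables["patients"], fu)
        assert segs["person_years"].sum() == pytest.approx(fu["person_years"].sum(), rel=1e-12)


# ---------------------------------------------------------------------------
# incident ascertainment
# ---------------------------------------------------------------------------

class TestIncidentSepsis:
    @staticmethod
    def _fu(pats):
        return cohort.compute_follow_up(pats, STUDY_START, STUDY_END)

    def test_first_of_two_events_kept(self):
        pats = make_patients([(1, "male", "1950-01-01", "2000-01-01", "2018-01-01", None)])
        ev = make_events([(1, "2003-01-10", "sepsis"), (1, "2004-02-10", "sepsis")])
        cases = cohort.ascertain_incident_sepsis(ev, self._fu(pats))
        assert len(cases) == 1
        assert cases.loc[0, "sepsis_date"] == pd.Timestamp("2003-01-10")

    def test_no_sepsis_code_no_case(self):
        pats = make_patients([(1, "male", "1950-01-01", "2000-01-01", "2018-01-01", None)])
        ev = make_events([(1, "2003-01-10", "rti")])
        assert len(cohort.ascertain_incident_sepsis(ev, self._fu(pats))) == 0

    def test_out_of_interval_event_does_not_suppress(self):
        pats = make_patients([(1, "male", "1950-01-01", "2000-01-01", "2018-01-01", None)])
        ev = make_events([(1, "2001-06-01", "sepsis"), (1, "2005-06-01", "sepsis")])
        cases = cohort.ascertain_incident_sepsis(ev, self._fu(pats))
        assert cases.loc[0, "sepsis_date"] == pd.Timestamp("2005-06-01")
        suppressed = cohort.ascertain_incident_sepsis(
            ev, self._fu(pats), suppress_prevalent=True
        )
        assert len(suppressed) == 0

    def test_random_streams_match_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        pats = make_patients(
            [(i, "male", "1950-01-01", "2000-01-01", "2018-01-01", None) for i in range(40)]
        )
        fu = self._fu(pats)
        dates = pd.Timestamp("2000-06-01") + pd.to_timedelta(
            rng.integers(0, 6500, size=300), unit="D"
        )
        ev = pd.DataFrame(
            {
                "patient_id": rng.integers(0, 40, size=300),
                "event_date": dates,
                "category": rng.choice(["sepsis", "rti"], size=300),
                "code": "X",
                "source": "primary_care",
            }
        )
        got = cohort.ascertain_incident_sepsis(ev, fu).set_index("patient_id")["sepsis_date"]
        # brute force
        fu_idx = fu.set_index("patient_id")
        expected = {}
        for row in ev.sort_values("event_date").itertuples():
            if row.category != "sepsis" or row.patient_id in expected:
                continue
            s, e = fu_idx.loc[row.patient_id, ["start", "end"]]
            if s <= row.event_date < e:
                expected[row.patient_id] = row.event_date
        assert got.to_dict() == expected


# ---------------------------------------------------------------------------
# look-back linkage
# ---------------------------------------------------------------------------

class TestLookback:
    cases = pd.DataFrame({"patient_id": [1], "sepsis_date": [pd.Timestamp("2005-03-31")]})

    def test_consultation_with_same_day_ab_links(self):
        cons = make_events([(1, "2005-03-21", "uti")])
        rx = make_prescriptions([(1, "2005-03-21")])
        out = cohort.link_lookback(self.cases, cons, rx, 30)
        assert out.loc[0, "linked_date"] == pd.Timestamp("2005-03-21")
        assert out.loc[0, "infection_type"] == "uti"
        assert bool(out.loc[0, "ab_same_date"])

    @pytest.mark.parametrize("offset,linked", [(30, False), (29, True), (1, True), (0, False)])
    def test_window_boundaries_excluded(self, offset, linked):
        cons = make_events([(1, self.cases.loc[0, "sepsis_date"] - pd.Timedelta(days=offset), "rti")])
        out = cohort.link_lookback(self.cases, cons, make_prescriptions([]), 30)
        assert out.loc[0, "linked_date"].year == 2005 if linked else pd.isna(out.loc[0, "linked_date"])

    def test_most_recent_consultation_defines_exposure(self):
        cons = make_events([(1, "2005-03-10", "rti"), (1, "2005-03-20", "skin")])
        rx = make_prescriptions([(1, "2005-03-10")])  # AB only at the older one
        out = cohort.link_lookback(self.cases, cons, rx, 30)
        assert out.loc[0, "infection_type"] == "skin"
        assert not bool(out.loc[0, "ab_same_date"])
        assert bool(out.loc[0, "ab_other_date_in_window"])
        assert out.loc[0, "n_window_consultations"] == 2
        # the any-AB alternative flips the exposure flag
        any_ab = cohort.link_lookback(self.cases, cons, rx, 30, exposure_rule="any_ab")
        assert bool(any_ab.loc[0, "ab_same_date"])

    def test_window_60_links_superset_of_window_30(self, sim_tables):
        pats = sim_tables["patients"]
        ev = sim_tables["clinical_events"]
        fu = cohort.compute_follow_up(pats, STUDY_START, STUDY_END)
        cases = cohort.ascertain_incident_sepsis(ev, fu)
        l30 = cohort.link_lookback(cases, ev, sim_tables["prescriptions"], 30)
        l60 = cohort.link_lookback(cases, ev, sim_tables["prescriptions"], 60)
        assert l60["linked_date"].notna().sum() >= l30["linked_date"].notna().sum()
        # every 30-day-linked case is also 60-day-linked
        ids30 = set(l30.loc[l30["linked_date"].notna(), "patient_id"])
        ids60 = set(l60.loc[l60["linked_date"].notna(), "patient_id"])
        assert ids30 <= ids60

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigurationError, match="window_days"):
            cohort.link_lookback(self.cases, make_events([]), make_prescriptions([]), 45)


# ---------------------------------------------------------------------------
# multi-source union
# ---------------------------------------------------------------------------

class TestMergeSources:
    def test_earliest_source_defines_incident_date(self):
        prim = make_events([(1, "2005-04-10", "sepsis", "primary_care")])
        hosp = make_events([(1, "2005-03-31", "sepsis", "hospital")])
        merged = cohort.merge_event_sources(prim, hosp)
        pats = make_patients([(1, "male", "1950-01-01", "2000-01-01", "2018-01-01", None)])
        fu = cohort.compute_follow_up(pats, STUDY_START, STUDY_END)
        cases = cohort.ascertain_incident_sepsis(merged, fu)
        assert cases.loc[0, "sepsis_date"] == pd.Timestamp("2005-03-31")

    def test_empty_extra_streams_are_identity(self):
        prim = make_events([(1, "2005-04-10", "sepsis"), (2, "2006-01-01", "sepsis")])
        merged = cohort.merge_event_sources(prim, prim.iloc[:0], prim.iloc[:0])
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True), prim.reset_index(drop=True)
        )

    def test_random_fixture_equals_set_union(self):
        rng = np.random.default_rng(5)
        streams = []
        for src in ("primary_care", "hospital", "mortality"):
            n = 60
            streams.append(
                pd.DataFrame(
                    {
                        "patient_id": rng.integers(0, 15, n),
                        "event_date": pd.Timestamp("2004-01-01")
                        + pd.to_timedelta(rng.integers(0, 400, n), unit="D"),
                        "category": "sepsis",
                        "code": "S",
                        "source": src,
                    }
                )
            )
        merged = cohort.merge_event_sources(*streams)
        expected = {
            (r.patient_id, r.event_date)
            for s in streams
            for r in s.itertuples()
        }
        got = set(zip(merged["patient_id"], merged["event_date"]))
        assert got == expected
        assert not merged.duplicated(["patient_id", "event_date"]).any()


# ---------------------------------------------------------------------------
# stratum tabulation
# ---------------------------------------------------------------------------

class TestTabulate:
    @staticmethod
    def _extract(sim_tables):
        pats = sim_tables["patients"]
        ev = sim_tables["clinical_events"]
        fu = cohort.compute_follow_up(pats, STUDY_START, STUDY_END)
        cases = cohort.ascertain_incident_sepsis(ev, fu)
        cases = cohort.link_lookback(cases, ev, sim_tables["prescriptions"], 30)
        return pats, fu, cases

    def test_counts_conserved_across_strata(self, sim_tables):
        pats, fu, cases = self._extract(sim_tables)
        tab = cohort.tabulate_strata(cases, pats, fu, censor_at_sepsis=False)
        assert tab["n_sepsis"].sum() == len(cases)
        assert tab["n_prior_infection"].sum() == cases["linked_date"].notna().sum()
        assert tab["person_years"].sum() == pytest.approx(fu["person_years"].sum(), rel=1e-9)

    def test_single_band_equals_global_totals(self, sim_tables):
        pats, fu, cases = self._extract(sim_tables)
        tab = cohort.tabulate_strata(cases, pats, fu, bands=((0, None),), censor_at_sepsis=False)
        assert set(tab["age_band"]) == {"0+"}
        assert tab["n_sepsis"].sum() == len(cases)
        by_gender = cases.merge(pats[["patient_id", "gender"]], on="patient_id")
        for g in ("male", "female"):
            assert (
                tab.loc[tab["gender"] == g, "n_sepsis"].sum()
                == (by_gender["gender"] == g).sum()
            )

    def test_counts_match_filtered_count_oracle(self, sim_tables):
        pats, fu, cases = self._extract(sim_tables)
        tab = cohort.tabulate_strata(cases, pats, fu)
        full = cases.merge(pats[["patient_id", "gender", "birth_date"]], on="patient_id")
        full["age"] = cohort.age_at_event(full["birth_date"], full["sepsis_date"])
        from sepsis_nnt.bands import assign_band

        full["age_band"] = assign_band(full["age"].values)
        for row in tab.itertuples():
            sel = full[(full["gender"] == row.gender) & (full["age_band"] == row.age_band)]
            assert row.n_sepsis == len(sel)
            assert row.n_prior_infection == sel["linked_date"].notna().sum()
            assert row.n_same_date_ab == (
                sel["linked_date"].notna() & sel["ab_same_date"].astype(bool)
            ).sum()

    def test_every_case_in_exactly_one_band(self, sim_tables):
        pats, fu, cases = self._extract(sim_tables)
        tab = cohort.tabulate_strata(cases, pats, fu)
        assert tab.duplicated(["gender", "age_band"]).sum() == 0
        assert tab["n_sepsis"].sum() == len(cases)

    def test_overlapping_bands_rejected(self, sim_tables):
        pats, fu, cases = self._extract(sim_tables)
        with pytest.raises(BandError):
            cohort.tabulate_strata(cases, pats, fu, bands=((0, 10), (5, None)))
        with pytest.raises(BandError):
            validate_bands(((0, 10), (12, None)))  # gap

    def test_period_stratification_conserves(self, sim_tables):
        pats, fu, cases = self._extract(sim_tables)
        tab = cohort.tabulate_strata(cases, pats, fu, period_years=4, censor_at_sepsis=False)
        assert tab["n_sepsis"].sum() == len(cases)
        assert tab["person_years"].sum() == pytest.approx(fu["person_years"].sum(), rel=1e-9)
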