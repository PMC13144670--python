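"""Pair identification rules, code mapping, phenotype tables and filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heritmap.cohort_builder import (
    FilterConfig,
    build_phenotype_tables,
    classify_onset,
    filter_phecodes,
    identify_sibling_pairs,
    identify_twin_pairs,
    map_codes,
    phecode_ancestors,
    read_code_map,
    restrict_birth_cohort,
    sibling_cohort,
)
from heritmap.synthetic_registry import (
    PhenotypeSpec,
    SimulationParams,
    simulate_registry,
)

from conftest import make_persons


def _family(n, mother="M1", father="F1", dates=None, sexes=None, place="BP1",
            prefix="P"):
    dates = dates or ["2000-01-01"] * n
    sexes = sexes or ["F"] * n
    return [{"person_id": f"{prefix}{i}", "mother_id": mother, "father_id": father,
             "birth_date": d, "sex": s, "birthplace": place}
            for i, (d, s) in enumerate(zip(dates, sexes))]


class TestTwinIdentification:
    def test_same_day_same_place_forms_one_pair(self):
        persons = make_persons(_family(2, dates=["2000-01-01", "2000-01-01"],
                                       sexes=["M", "F"]))
        pairs = identify_twin_pairs(persons)
        assert len(pairs) == 1
        assert pairs.loc[0, "relationship"] == "twin"
        assert pairs.loc[0, "analysis_group"] == "REF"  # opposite-sex

    def test_one_day_apart_still_twins(self):
        persons = make_persons(_family(2, dates=["2000-01-01", "2000-01-02"],
                                       sexes=["F", "F"]))
        pairs = identify_twin_pairs(persons)
        assert len(pairs) == 1
        assert pairs.loc[0, "analysis_group"] == "SS"

    def test_two_days_apart_not_twins(self):
        persons = make_persons(_family(2, dates=["2000-01-01", "2000-01-03"]))
        assert len(identify_twin_pairs(persons)) == 0

    def test_different_birthplace_not_twins(self):
        rows = _family(2, dates=["2000-01-01", "2000-01-01"])
        rows[1]["birthplace"] = "BP2"
        assert len(identify_twin_pairs(make_persons(rows))) == 0

    def test_only_first_twin_pair_per_couple(self):
        rows = (_family(2, dates=["1995-03-01", "1995-03-01"], prefix="A")
                + _family(2, dates=["1999-07-01", "1999-07-01"], prefix="B"))
        pairs = identify_twin_pairs(make_persons(rows))
        assert len(pairs) == 1
        assert set(pairs[["person_id1", "person_id2"]].iloc[0]) == {"A0", "A1"}

    def test_half_siblings_never_twins(self):
        rows = _family(1, father="F1") + _family(1, father="F2", prefix="Q")
        assert len(identify_twin_pairs(make_persons(rows))) == 0

    def test_duplicate_person_ids_rejected(self):
        rows = _family(2)
        rows[1]["person_id"] = rows[0]["person_id"]
        with pytest.raises(ValueError, match="duplicate"):
            identify_twin_pairs(make_persons(rows))

    def test_followup_is_pairwise_minimum(self):
        rows = _family(2, dates=["2000-01-01", "2000-01-01"])
        rows[0]["emigration_date"] = "2010-06-15"
        pairs = identify_twin_pairs(make_persons(rows), study_end="2021-12-31")
        assert pairs.loc[0, "followup_end"] == pd.Timestamp("2010-06-15")


class TestSiblingIdentification:
    def test_closest_gap_pair_selected(self):
        rows = _family(3, dates=["2000-01-01", "2002-01-01", "2005-01-01"])
        pairs = identify_sibling_pairs(make_persons(rows))
        assert len(pairs) == 1
        assert set(pairs[["person_id1", "person_id2"]].iloc[0]) == {"P0", "P1"}

    def test_gap_above_four_years_excluded(self):
        rows = _family(2, dates=["2000-01-01", "2006-01-01"])
        assert len(identify_sibling_pairs(make_persons(rows))) == 0

    def test_gap_below_eleven_months_excluded(self):
        rows = _family(2, dates=["2000-01-01", "2000-11-01"])  # 305 days
        assert len(identify_sibling_pairs(make_persons(rows))) == 0

    def test_eleven_month_boundary(self):
        ok = _family(2, dates=["2000-01-01", "2000-11-30"])    # 334 days
        assert len(identify_sibling_pairs(make_persons(ok))) == 1
        short = _family(2, dates=["2000-01-01", "2000-11-29"])  # 333 days
        assert len(identify_sibling_pairs(make_persons(short))) == 0

    def test_twins_not_reused_as_siblings(self):
        rows = _family(3, dates=["2000-01-01", "2000-01-01", "2002-01-01"])
        persons = make_persons(rows)
        twins = identify_twin_pairs(persons)
        assert len(twins) == 1
        sibs = identify_sibling_pairs(persons, twins)
        assert len(sibs) == 0  # remaining child has no non-twin partner

    def test_short_gap_triple_uses_nonadjacent_pair(self):
        # adjacent gaps of ~6 months are ineligible, but the outer pair
        # (12 months apart) qualifies
        rows = _family(3, dates=["2000-01-01", "2000-07-01", "2001-01-01"],
                       place="BP1")
        pairs = identify_sibling_pairs(make_persons(rows))
        assert len(pairs) == 1
        assert set(pairs[["person_id1", "person_id2"]].iloc[0]) == {"P0", "P2"}

    def test_sibling_cohort_is_union_of_twin_and_nontwin_pairs(self):
        rows = (_family(2, dates=["2000-01-01", "2000-01-01"], prefix="T")
                + _family(2, mother="M2", father="F2",
                          dates=["2000-01-01", "2002-01-01"], prefix="S"))
        persons = make_persons(rows)
        twins = identify_twin_pairs(persons)
        sibs = identify_sibling_pairs(persons, twins)
        cohort = sibling_cohort(twins, sibs)
        assert len(cohort) == len(twins) + len(sibs) == 2
        assert (cohort.loc[cohort["relationship"] == "nontwin_sibling",
                           "analysis_group"] == "REF").all()


class TestBirthCohorts:
    def _pairs(self, **overrides):
        row = {"pair_id": "x", "person_id1": "a", "person_id2": "b",
               "relationship": "twin", "sex1": "F", "sex2": "F",
               "birth_date1": pd.Timestamp("1980-05-01"),
               "birth_date2": pd.Timestamp("1980-05-01"),
               "death_date1": pd.NaT, "death_date2": pd.NaT,
               "followup_end": pd.Timestamp("2021-12-31"),
               "age_gap_years": 0.0, "analysis_group": "SS"}
        row.update(overrides)
        return pd.DataFrame([row])

    def test_death_before_1977_excluded_from_1955_cohort(self):
        pairs = self._pairs(birth_date1=pd.Timestamp("1960-01-01"),
                            birth_date2=pd.Timestamp("1960-01-01"),
                            death_date1=pd.Timestamp("1976-03-01"))
        assert len(restrict_birth_cohort(pairs, 1955)) == 0

    def test_born_1980_in_both_cohorts(self):
        pairs = self._pairs()
        assert len(restrict_birth_cohort(pairs, 1955)) == 1
        assert len(restrict_birth_cohort(pairs, 1977)) == 1

    def test_born_1960_alive_1977_only_in_1955_cohort(self):
        pairs = self._pairs(birth_date1=pd.Timestamp("1960-01-01"),
                            birth_date2=pd.Timestamp("1960-01-01"))
        assert len(restrict_birth_cohort(pairs, 1955)) == 1
        assert len(restrict_birth_cohort(pairs, 1977)) == 0

    def test_unknown_cohort_label_rejected(self):
        with pytest.raises(ValueError, match="cohort"):
            restrict_birth_cohort(self._pairs(), 1990)


class TestCodeMapping:
    def test_ancestors_of_dotted_decimal(self):
        assert phecode_ancestors("751.11") == ["751.1", "751"]
        assert phecode_ancestors("345") == []

    def test_event_propagates_to_all_ancestors(self):
        diag = pd.DataFrame({"person_id": ["p1"], "code": ["345.12"],
                             "code_system": ["phecode"],
                             "date": [pd.Timestamp("2000-01-01")]})
        out = map_codes(diag)
        assert set(out.events["phecode"]) == {"345.12", "345.1", "345"}

    def test_icd8_to_icd10_to_phecode_composition(self):
        diag = pd.DataFrame({"person_id": ["p1"], "code": ["345.19"],
                             "code_system": ["ICD-8"],
                             "date": [pd.Timestamp("1985-01-01")]})
        out = map_codes(diag, icd8_to_icd10={"345.19": "G40.3"},
                        icd10_to_phecode={"G40.3": "345.1"})
        assert set(out.events["phecode"]) == {"345.1", "345"}
        assert out.n_unmapped_icd8 == 0

    def test_unmapped_codes_counted_not_fatal(self):
        diag = pd.DataFrame({"person_id": ["p1", "p2"],
                             "code": ["G40.3", "Z99.9"],
                             "code_system": ["ICD-10", "ICD-10"],
                             "date": [pd.Timestamp("2000-01-01")] * 2})
        out = map_codes(diag, icd10_to_phecode={"G40.3": "345.1"})
        assert out.n_unmapped_icd10 == 1
        assert set(out.events["phecode"]) == {"345.1", "345"}

    def test_unknown_code_system_rejected(self):
        diag = pd.DataFrame({"person_id": ["p1"], "code": ["x"],
                             "code_system": ["SNOMED"],
                             "date": [pd.Timestamp("2000-01-01")]})
        with pytest.raises(ValueError, match="SNOMED"):
            map_codes(diag)

    def test_malformed_map_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("icd10,phecode\nG40.3,345.1\nbroken-line\n")
        with pytest.raises(ValueError, match="line 3"):
            read_code_map(path)

    def test_map_file_round_trip(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("icd10,phecode\nG40.3,345.1\nF84.0,313.3\n")
        assert read_code_map(path) == {"G40.3": "345.1", "F84.0": "313.3"}


def _one_pair_events(date, followup_end="2021-12-31"):
    pairs = pd.DataFrame([{
        "pair_id": "T:1", "person_id1": "a", "person_id2": "b",
        "relationship": "twin", "sex1": "F", "sex2": "F",
        "birth_date1": pd.Timestamp("1980-01-01"),
        "birth_date2": pd.Timestamp("1980-01-01"),
        "death_date1": pd.NaT, "death_date2": pd.NaT,
        "followup_end": pd.Timestamp(followup_end),
        "age_gap_years": 0.0, "analysis_group": "SS"}])
    events = pd.DataFrame({"person_id": ["a"], "phecode": ["008"],
                           "date": [pd.Timestamp(date)]})
    return pairs, events


class TestPhenotypeTables:
    def test_event_inside_window_sets_y(self):
        pairs, events = _one_pair_events("2000-06-01")
        tab = build_phenotype_tables(pairs, events)["008"]
        assert (tab["y1"].iloc[0], tab["y2"].iloc[0]) == (1, 0)
        assert tab.attrs["K"] == 0.5

    def test_event_after_followup_censored(self):
        pairs, events = _one_pair_events("2012-01-01", followup_end="2010-01-01")
        tab = build_phenotype_tables(pairs, events, phecodes=["008"])["008"]
        assert tab["y1"].iloc[0] == 0
        assert tab.attrs["K"] == 0.0

    def test_event_before_registry_start_left_truncated(self):
        pairs, events = _one_pair_events("1975-01-01")
        tab = build_phenotype_tables(pairs, events, "1977-01-01",
                                     phecodes=["008"])["008"]
        assert tab["y1"].iloc[0] == 0

    def test_no_events_gives_all_zero_table(self):
        pairs, events = _one_pair_events("2000-01-01")
        tab = build_phenotype_tables(pairs, events.iloc[:0],
                                     phecodes=["008"])["008"]
        assert tab.attrs["K"] == 0.0
        assert (tab[["y1", "y2"]] == 0).all().all()

    def test_unknown_person_events_dropped(self, caplog):
        pairs, events = _one_pair_events("2000-01-01")
        events = pd.concat([events, pd.DataFrame({
            "person_id": ["ghost"], "phecode": ["008"],
            "date": [pd.Timestamp("2000-01-01")]})], ignore_index=True)
        with caplog.at_level("WARNING"):
            tab = build_phenotype_tables(pairs, events)["008"]
        assert tab.attrs["K"] == 0.5
        assert "dropping 1 events" in caplog.text


class TestOnsetClassification:
    def _events(self, ages, phecode="008"):
        birth = pd.Timestamp("1980-01-01")
        return (pd.DataFrame({
            "person_id": [f"p{i}" for i in range(len(ages))],
            "phecode": phecode,
            "date": [birth + pd.Timedelta(days=int(a * 365.25)) for a in ages],
        }), make_persons([{"person_id": f"p{i}", "birth_date": "1980-01-01",
                           "mother_id": "m", "father_id": "f"}
                          for i in range(len(ages))]))

    def test_young_onset_labelled_early(self):
        events, persons = self._events([3, 5, 9])
        out = classify_onset(events, persons)
        assert out.loc[0, "onset_class"] == "early"

    def test_late_onset_labelled_late(self):
        events, persons = self._events([41, 45, 52])
        out = classify_onset(events, persons)
        assert out.loc[0, "onset_class"] == "late"

    def test_threshold_boundary_at_ten_percent(self):
        ages = [10.0] * 10 + [40.0] * 90
        out = classify_onset(*self._events(ages))
        assert out.loc[0, "onset_class"] == "early"
        ages = [10.0] * 9 + [40.0] * 91
        out = classify_onset(*self._events(ages))
        assert out.loc[0, "onset_class"] == "late"

    def test_zero_cases_undefined(self):
        events, persons = self._events([30.0])
        out = classify_onset(events.iloc[:0], persons, phecodes=["008"])
        assert out.loc[0, "onset_class"] == "undefined"


def _filter_table(n_pairs, n_concordant_ss, n_concordant_ref,
                  male_cases=0, female_cases=None, phecode="008"):
    """Table with the requested concordant counts; remaining cases discordant."""
    half = n_pairs // 2
    rows = []
    for i in range(n_pairs):
        group = "SS" if i < half else "REF"
        rows.append({"pair_id": f"x{i}", "group": group, "y1": 0, "y2": 0,
                     "sex1": "F", "sex2": "F" if group == "SS" else "M",
                     "birth_year1": 1980 + i % 20, "birth_year2": 1980 + i % 20})
    tab = pd.DataFrame(rows)
    tab.loc[: n_concordant_ss - 1, ["y1", "y2"]] = 1
    tab.loc[half: half + n_concordant_ref - 1, ["y1", "y2"]] = 1
    # add singleton female/male cases among discordant pairs
    got_m = (tab.loc[tab["y1"] == 1, "sex1"] == "M").sum() + \
            (tab.loc[tab["y2"] == 1, "sex2"] == "M").sum()
    i = half - 1
    while male_cases > got_m:
        tab.loc[i, "y2"] = 1
        tab.loc[i, "sex2"] = "M"
        got_m += 1
        i -= 1
    if female_cases is not None:
        got_f = (tab.loc[tab["y1"] == 1, "sex1"] == "F").sum() + \
                (tab.loc[tab["y2"] == 1, "sex2"] == "F").sum()
        i = n_pairs - 1
        while female_cases > got_f:
            tab.loc[i, "y1"] = 1
            got_f += 1
            i -= 1
    tab.attrs["phecode"] = phecode
    tab.attrs["K"] = float((tab["y1"].sum() + tab["y2"].sum()) / (2 * n_pairs))
    return tab


class TestPhecodeFilters:
    cfg = FilterConfig(min_cases=10)

    def test_low_prevalence_excluded(self):
        tab = _filter_table(4000, 8, 8)  # K = 32/8000 = 0.004
        eligible, ledger = filter_phecodes({"008": tab}, self.cfg)
        assert eligible == []
        assert ledger.loc[0, "reason"] == "prevalence"

    def test_concordant_pair_boundary(self):
        ok = _filter_table(1000, 5, 5)
        few = _filter_table(1000, 4, 5)
        eligible, ledger = filter_phecodes({"a": ok, "b": few}, self.cfg)
        assert eligible == ["a"]
        assert ledger.set_index("phecode").loc["b", "reason"] == "concordant_pairs"

    def test_sex_ratio_excludes_phecode_and_its_ancestors(self):
        # 120 female vs 20 male cases: ratio 6 > 5
        child = _filter_table(1000, 10, 10, male_cases=20, female_cases=120,
                              phecode="751.11")
        parent = _filter_table(1000, 10, 10, male_cases=60, female_cases=80,
                               phecode="751.1")
        eligible, ledger = filter_phecodes({"751.11": child, "751.1": parent},
                                           self.cfg)
        assert eligible == []
        led = ledger.set_index("phecode")
        assert led.loc["751.11", "reason"] == "sex_ratio"
        assert led.loc["751.1", "reason"] == "sex_ratio_ancestor"

    def test_min_cases_only_in_twin_design(self):
        tab = _filter_table(1000, 6, 6)   # 24 cases, K = 0.012
        cfg = FilterConfig(min_cases=100)
        eligible_twin, ledger = filter_phecodes({"008": tab}, cfg, design="twin")
        assert eligible_twin == []
        assert ledger.loc[0, "reason"] == "min_cases"
        eligible_sib, _ = filter_phecodes({"008": tab}, cfg, design="sibling")
        assert eligible_sib == ["008"]

    def test_ledger_partitions_all_phecodes(self):
        tables = {"a": _filter_table(1000, 10, 10),
                  "b": _filter_table(1000, 2, 2),
                  "c": _filter_table(4000, 5, 5)}
        eligible, ledger = filter_phecodes(tables, self.cfg)
        assert set(ledger["phecode"]) == set(tables)
        assert set(eligible) | set(ledger.loc[~ledger["eligible"], "phecode"]) \
            == set(tables)


class TestPairInvariantsOnSimulatedRegistry:
    def test_no_person_in_two_pairs_and_counts_add_up(self):
        spec = PhenotypeSpec(phecode="008", h2_true=0.3, prevalence_K=0.2)
        params = SimulationParams(n_families=2000, phenotypes=[spec],
                                  twin_fraction=0.3, seed=5)
        sim = simulate_registry(params)
        twins = identify_twin_pairs(sim.persons)
        sibs = identify_sibling_pairs(sim.persons, twins)
        members = pd.concat([twins, sibs])[["person_id1", "person_id2"]]
        flat = pd.concat([members["person_id1"], members["person_id2"]])
        assert not flat.duplicated().any()
        cohort = sibling_cohort(twins, sibs)
        assert len(cohort) == len(twins) + len(sibs)
        # every simulated family is recovered as exactly one pair
        assert len(cohort) == params.n_families
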