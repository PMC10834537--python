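"""Tests for case selection, contingency construction and the RR screen."""

import numpy as np
import pandas as pd
import pytest

from adrscreen.contingency import ContingencyTable
from adrscreen.datasets import RegistryDataset, VocabMappings, VocabularyError
from adrscreen.registry import (
    RegistryCase,
    RegistryScreen,
    build_contingency,
    screen_registry,
    select_valid_cases,
)


def _mappings():
    return VocabMappings(
        brand_to_generic={"BrandX": "drugX", "BrandY": "drugY", "drugX": "drugX", "drugY": "drugY"},
        raw_to_preferred={"rash raw": "Rash", "headache raw": "Headache", "Rash": "Rash"},
    )


def _dataset(statuses=("continued", "switched", "continued"), withdrawn=(False, False)):
    patients = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "disease": ["RA", "RA"],
            "withdrawn": list(withdrawn),
        }
    )
    events = pd.DataFrame(
        {
            "event_id": [0, 1, 2, 3],
            "patient_id": ["P1", "P1", "P2", "P2"],
            "phase": ["initial", "follow_up", "follow_up", "follow_up"],
            "drug_brand_name": ["BrandX", "BrandX", "BrandY", "BrandY"],
            "drug_status": ["other", statuses[0], statuses[1], statuses[2]],
        }
    )
    reports = pd.DataFrame(
        {
            "report_id": [0, 1, 2],
            "event_id": [1, 1, 3],
            "raw_term": ["rash raw", "headache raw", "rash raw"],
            "relatedness": ["related", "unrelated", "indeterminate"],
            "severity": ["I", "II", "I"],
            "outcome": ["resolved", "resolved", "unknown"],
            "is_lab_abnormality": [False, False, True],
        }
    )
    return RegistryDataset(patients=patients, events=events, adr_reports=reports)


class TestSelectValidCases:
    def test_status_filter_keeps_continued_followups(self):
        cases = select_valid_cases(_dataset(), _mappings())["RA"]
        assert len(cases) == 2  # events 1 and 3; the switched one drops

    def test_unrelated_report_terms_excluded(self):
        cases = select_valid_cases(_dataset(), _mappings())["RA"]
        by_id = {c.case_id: c for c in cases}
        assert by_id["1"].terms == frozenset({"Rash"})  # headache was 'unrelated'
        assert by_id["3"].lab_terms == frozenset({"Rash"})

    def test_withdrawn_patient_excluded(self):
        cases = select_valid_cases(
            _dataset(withdrawn=(True, False)), _mappings()
        )["RA"]
        assert {c.case_id for c in cases} == {"3"}

    def test_brand_names_normalised(self):
        cases = select_valid_cases(_dataset(), _mappings())["RA"]
        assert {c.generic_drug for c in cases} == {"drugX", "drugY"}

    def test_unmapped_brand_raises(self):
        mappings = _mappings()
        del mappings.brand_to_generic["BrandY"]
        with pytest.raises(VocabularyError, match="BrandY"):
            select_valid_cases(_dataset(), mappings)

    def test_unmapped_term_raises(self):
        mappings = _mappings()
        del mappings.raw_to_preferred["rash raw"]
        with pytest.raises(VocabularyError, match="rash raw"):
            select_valid_cases(_dataset(), mappings)


def _random_cases(rng, n=500, n_drugs=6, n_terms=12, disease="RA"):
    drugs = [f"drug{i}" for i in range(n_drugs)]
    terms = [f"term{i}" for i in range(n_terms)]
    cases = []
    for i in range(n):
        terms_i = frozenset(t for t in terms if rng.random() < 0.15)
        cases.append(
            RegistryCase(
                case_id=str(i),
                disease=disease,
                generic_drug=drugs[rng.integers(0, n_drugs)],
                terms=terms_i,
            )
        )
    return cases, drugs, terms


class TestBuildContingency:
    def test_enumeration(self):
        cases = [
            RegistryCase("1", "RA", "drugX", frozenset({"t"})),
            RegistryCase("2", "RA", "drugX", frozenset()),
            RegistryCase("3", "RA", "drugY", frozenset({"t"})),
            RegistryCase("4", "RA", "drugY", frozenset()),
        ]
        assert build_contingency(cases, "drugX", "t").cells() == (1, 1, 1, 1)

    def test_absent_term(self):
        cases = [
            RegistryCase("1", "RA", "drugX", frozenset({"u"})),
            RegistryCase("2", "RA", "drugY", frozenset()),
        ]
        table = build_contingency(cases, "drugX", "t")
        assert table.a == 0 and table.c == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            build_contingency([], "drugX", "t")

    def test_mixed_strata_raise(self):
        cases = [
            RegistryCase("1", "RA", "drugX", frozenset()),
            RegistryCase("2", "AS", "drugX", frozenset()),
        ]
        with pytest.raises(ValueError):
            build_contingency(cases, "drugX", "t")

    def test_counting_oracle(self):
        """Tables match an independent per-case counter on random fixtures."""
        rng = np.random.default_rng(7)
        cases, drugs, terms = _random_cases(rng)
        for _ in range(100):
            drug = drugs[rng.integers(0, len(drugs))]
            term = terms[rng.integers(0, len(terms))]
            table = build_contingency(cases, drug, term)
            # brute-force recount
            a = sum(1 for c in cases if c.generic_drug == drug and term in c.terms)
            b = sum(1 for c in cases if c.generic_drug == drug and term not in c.terms)
            cc = sum(1 for c in cases if c.generic_drug != drug and term in c.terms)
            dd = len(cases) - a - b - cc
            assert table.cells() == (a, b, cc, dd)

    def test_cell_conservation(self):
        rng = np.random.default_rng(3)
        cases, drugs, terms = _random_cases(rng, n=200)
        for drug in drugs:
            for term in terms[:4]:
                assert build_contingency(cases, drug, term).n == len(cases)


class TestScreenRegistry:
    def test_rr_below_one_not_significant(self):
        cases = (
            [RegistryCase(f"a{i}", "RA", "drugX", frozenset({"t"})) for i in range(4)]
            + [RegistryCase(f"b{i}", "RA", "drugX", frozenset()) for i in range(16)]
            + [RegistryCase(f"c{i}", "RA", "drugY", frozenset({"t"})) for i in range(10)]
            + [RegistryCase(f"d{i}", "RA", "drugY", frozenset()) for i in range(10)]
        )
        results = screen_registry(cases, min_count=3)
        by_pair = {(r.generic_drug, r.preferred_term): r for r in results}
        r = by_pair[("drugX", "t")]
        assert r.rr < 1 and not r.significant

    def test_point_estimate_only_switch(self):
        cases = (
            [RegistryCase(f"a{i}", "RA", "drugX", frozenset({"t"})) for i in range(4)]
            + [RegistryCase(f"b{i}", "RA", "drugX", frozenset()) for i in range(16)]
            + [RegistryCase(f"c{i}", "RA", "drugY", frozenset({"t"})) for i in range(3)]
            + [RegistryCase(f"d{i}", "RA", "drugY", frozenset()) for i in range(17)]
        )
        strict = {(r.generic_drug, r.preferred_term): r for r in screen_registry(cases)}
        loose = {
            (r.generic_drug, r.preferred_term): r
            for r in screen_registry(cases, point_estimate_only=True)
        }
        pair = ("drugX", "t")
        assert strict[pair].rr > 1 and not strict[pair].significant
        assert loose[pair].significant

    def test_min_count_gates_reporting(self):
        cases = [
            RegistryCase("1", "RA", "drugX", frozenset({"t"})),
            RegistryCase("2", "RA", "drugY", frozenset({"t"})),
            RegistryCase("3", "RA", "drugY", frozenset()),
        ]
        assert screen_registry(cases, min_count=2) == []

    def test_stratum_isolation(self, demo_bundle):
        """RA results are unchanged by any modification of the AS stratum."""
        ds = demo_bundle.registry
        ra_frame = RegistryScreen(
            select_valid_cases(ds, demo_bundle.mappings)["RA"], min_count=15
        ).fit().frame

        as_patients = set(ds.patients.loc[ds.patients["disease"] == "AS", "patient_id"])
        as_events = set(ds.events.loc[ds.events["patient_id"].isin(as_patients), "event_id"])
        mutated = RegistryDataset(
            patients=ds.patients,
            events=ds.events,
            adr_reports=ds.adr_reports.loc[~ds.adr_reports["event_id"].isin(as_events)],
        )
        ra_mutated = RegistryScreen(
            select_valid_cases(mutated, demo_bundle.mappings)["RA"], min_count=15
        ).fit().frame
        pd.testing.assert_frame_equal(ra_frame, ra_mutated)

    def test_embedded_signals_recovered(self, demo_bundle):
        """Every embedded RA pair is flagged in the demo registry."""
        from adrscreen.registry import select_valid_cases

        cases = select_valid_cases(demo_bundle.registry, demo_bundle.mappings)
        results = RegistryScreen(cases["RA"], min_count=15).fit()
        flagged = set(
            zip(results.significant_frame.generic_drug, results.significant_frame.preferred_term)
        )
        embedded = {
            (d, t)
            for dis, d, t, _ in demo_bundle.ground_truth.embedded_registry_signals
            if dis == "RA"
        }
        assert embedded <= flagged

    def test_lab_flag_carried_through(self, demo_bundle):
        from adrscreen.simulate import demo_registry_config

        cases = select_valid_cases(demo_bundle.registry, demo_bundle.mappings)
        frame = RegistryScreen(cases["RA"], min_count=15).fit().frame
        lab_vocab = demo_registry_config().lab_terms
        flagged_terms = set(frame.loc[frame["is_lab_abnormality"], "preferred_term"])
        unflagged_terms = set(frame.loc[~frame["is_lab_abnormality"], "preferred_term"])
        assert flagged_terms <= lab_vocab
        assert unflagged_terms.isdisjoint(lab_vocab)
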