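"""Tests for the synthetic-data generators and their embedding contracts."""

import numpy as np
import pandas as pd
import pytest

from adrscreen.dispro import Disproportionality, build_case_noncase
from adrscreen.registry import select_valid_cases
from adrscreen.simulate import (
    ConfigurationError,
    EhrLabConfig,
    GroundTruth,
    RegistryConfig,
    SrsConfig,
    Vocabularies,
    child_rng,
    demo_ground_truth,
    generate_ehr_lab,
    generate_mappings_and_labels,
    generate_registry,
    generate_srs,
)
from adrscreen.lab import LabSignalDefinition


def _small_registry_config(**kw):
    terms = tuple(f"T{i:02d}" for i in range(10))
    drugs = tuple(f"drug{i}" for i in range(4))
    defaults = dict(
        n_patients={"RA": 300},
        drugs={"RA": drugs},
        terms=terms,
        baseline_term_prob=0.05,
        mean_followups={"RA": 2.0},
        withdrawal_fraction={"RA": 0.1},
        status_probs={
            "RA": {"continued": 0.6, "switched": 0.2, "discontinued": 0.15, "other": 0.05}
        },
        generic_to_brands={d: (f"Brand-{d}",) for d in drugs},
    )
    defaults.update(kw)
    return RegistryConfig(**defaults)


def _registry_tsv_bytes(ds, tmp_path, tag):
    out = tmp_path / tag
    ds.to_tsv(out)
    return b"".join(sorted(p.read_bytes() for p in out.glob("*.tsv")))


class TestGenerateRegistry:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = _small_registry_config()
        truth = GroundTruth(seed=0)
        ds1 = generate_registry(cfg, truth, 42)
        ds2 = generate_registry(cfg, truth, 42)
        assert _registry_tsv_bytes(ds1, tmp_path, "a") == _registry_tsv_bytes(ds2, tmp_path, "b")

    def test_different_seeds_differ(self):
        cfg = _small_registry_config()
        ds1 = generate_registry(cfg, GroundTruth(seed=0), 1)
        ds2 = generate_registry(cfg, GroundTruth(seed=0), 2)
        assert not ds1.adr_reports.equals(ds2.adr_reports)

    def test_zero_withdrawal_fraction(self):
        cfg = _small_registry_config(withdrawal_fraction={"RA": 0.0})
        ds = generate_registry(cfg, GroundTruth(seed=0), 0)
        assert not ds.patients["withdrawn"].any()

    def test_followups_only_for_non_withdrawn(self):
        cfg = _small_registry_config(withdrawal_fraction={"RA": 0.5})
        ds = generate_registry(cfg, GroundTruth(seed=0), 0)
        withdrawn = set(ds.patients.loc[ds.patients["withdrawn"], "patient_id"])
        followups = ds.events.loc[ds.events["phase"] == "follow_up", "patient_id"]
        assert withdrawn.isdisjoint(set(followups))

    def test_unknown_embedded_pair_raises(self):
        cfg = _small_registry_config()
        truth = GroundTruth(
            embedded_registry_signals=[("RA", "drug0", "NotATerm", 3.0)], seed=0
        )
        with pytest.raises(ConfigurationError, match="NotATerm"):
            generate_registry(cfg, truth, 0)

    def test_excessive_rate_raises(self):
        cfg = _small_registry_config(baseline_term_prob=0.5)
        truth = GroundTruth(embedded_registry_signals=[("RA", "drug0", "T00", 10.0)], seed=0)
        with pytest.raises(ConfigurationError, match="exceeds 1"):
            generate_registry(cfg, truth, 0)

    def test_null_rates_match_baseline(self):
        """With rho = 1 everywhere no pair departs from baseline beyond 3 sigma.

        Checked on ~20,000 cases: the related-or-indeterminate report rate
        of each (drug, term) pair is binomial around baseline * P(rel or ind).
        """
        cfg = _small_registry_config(
            n_patients={"RA": 12_000}, mean_followups={"RA": 3.0},
            withdrawal_fraction={"RA": 0.0},
        )
        truth = GroundTruth(seed=0)
        ds = generate_registry(cfg, truth, 3)
        mappings, _ = generate_mappings_and_labels(
            truth,
            Vocabularies(generic_to_brands=cfg.generic_to_brands, preferred_terms=cfg.terms),
        )
        cases = select_valid_cases(ds, mappings)["RA"]
        assert len(cases) >= 20_000
        p0 = 0.05 * 0.7  # baseline * P(related or indeterminate)
        frame = pd.DataFrame(
            [(c.generic_drug, t) for c in cases for t in c.terms], columns=["drug", "term"]
        )
        n_by_drug = pd.Series([c.generic_drug for c in cases]).value_counts()
        counts = frame.groupby(["drug", "term"]).size()
        for (drug, term), k in counts.items():
            n = n_by_drug[drug]
            sigma = np.sqrt(p0 * (1 - p0) * n)
            assert abs(k - n * p0) < 4 * sigma  # 4 sigma over 40 pairs

    def test_embedding_fidelity(self):
        """The empirical risk ratio of an embedded pair converges to rho."""
        truth = GroundTruth(
            embedded_registry_signals=[("RA", "drug0", "T00", 4.0)], seed=0
        )
        cfg = _small_registry_config(
            n_patients={"RA": 30_000}, mean_followups={"RA": 3.0},
            withdrawal_fraction={"RA": 0.0}, baseline_term_prob=0.02,
        )
        ds = generate_registry(cfg, truth, 5)
        mappings, _ = generate_mappings_and_labels(
            truth,
            Vocabularies(generic_to_brands=cfg.generic_to_brands, preferred_terms=cfg.terms),
        )
        cases = select_valid_cases(ds, mappings)["RA"]
        on_drug = [c for c in cases if c.generic_drug == "drug0"]
        off_drug = [c for c in cases if c.generic_drug != "drug0"]
        p1 = sum("T00" in c.terms for c in on_drug) / len(on_drug)
        p0 = sum("T00" in c.terms for c in off_drug) / len(off_drug)
        assert p1 / p0 == pytest.approx(4.0, rel=0.10)


class TestGenerateSrs:
    def _config(self, n_reports=2000, **kw):
        drugs = {f"d{i}": 1 / 10 for i in range(10)}
        events = {f"e{i}": 1 / 20 for i in range(20)}
        defaults = dict(
            n_reports=n_reports, drug_marginals=drugs, event_marginals=events,
            brand_fraction=0.0, second_drug_prob=0.1,
        )
        defaults.update(kw)
        return SrsConfig(**defaults)

    def test_empty(self):
        srs = generate_srs(self._config(n_reports=0), GroundTruth(seed=0), 0)
        assert len(srs.reports) == 0

    def test_determinism(self):
        cfg = self._config()
        s1 = generate_srs(cfg, GroundTruth(seed=0), 9)
        s2 = generate_srs(cfg, GroundTruth(seed=0), 9)
        pd.testing.assert_frame_equal(s1.reports, s2.reports)

    def test_marginals_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            generate_srs(
                self._config(drug_marginals={"d0": 0.4, "d1": 0.4}), GroundTruth(seed=0), 0
            )

    def test_every_report_has_an_event(self):
        srs = generate_srs(self._config(), GroundTruth(seed=0), 1)
        assert srs.reports.groupby("report_id")["event_term"].size().min() >= 1

    def test_null_symmetry(self):
        """With rho=1, ad > bc on about half of the observed pairs."""
        srs = generate_srs(self._config(n_reports=4000), GroundTruth(seed=0), 2)
        mappings = generate_mappings_and_labels(
            GroundTruth(seed=0),
            Vocabularies(
                generic_to_brands={f"d{i}": () for i in range(10)},
                preferred_terms=tuple(f"e{i}" for i in range(20)),
            ),
        )[0]
        table = build_case_noncase(srs, mappings)
        det = table.pairs["a"] * table.pairs["d"] - table.pairs["b"] * table.pairs["c"]
        nz = det[det != 0]
        frac = (nz > 0).mean()
        sigma = 0.5 / np.sqrt(len(nz))
        assert abs(frac - 0.5) < 4 * sigma

    def test_embedded_pair_detected_across_seeds(self):
        """A rho=5 embedded pair shows sample PRR > 1 in every seed."""
        truth = GroundTruth(embedded_srs_signals=[("d0", "e0", 5.0)], seed=0)
        cfg = self._config(n_reports=20_000)
        mappings = generate_mappings_and_labels(
            truth,
            Vocabularies(
                generic_to_brands={f"d{i}": () for i in range(10)},
                preferred_terms=tuple(f"e{i}" for i in range(20)),
            ),
        )[0]
        for seed in range(5):
            srs = generate_srs(cfg, truth, seed)
            table = build_case_noncase(srs, mappings)
            row = table.pairs.set_index(["drug", "event"]).loc[("d0", "e0")]
            prr = (row.a / (row.a + row.b)) / (row.c / (row.c + row.d))
            assert prr > 1

    def test_brand_substitution_covered_by_mappings(self):
        cfg = self._config(
            brand_fraction=0.5,
            generic_to_brands={f"d{i}": (f"Brand-{i}",) for i in range(10)},
        )
        srs = generate_srs(cfg, GroundTruth(seed=0), 3)
        assert srs.reports["drug_name"].str.startswith("Brand-").any()
        mappings = generate_mappings_and_labels(
            GroundTruth(seed=0),
            Vocabularies(
                generic_to_brands={f"d{i}": (f"Brand-{i}",) for i in range(10)},
                preferred_terms=tuple(f"e{i}" for i in range(20)),
            ),
        )[0]
        # must not raise: every brand used is mapped
        build_case_noncase(srs, mappings)


class TestGenerateEhrLab:
    def _config(self, **kw):
        catalog = (
            LabSignalDefinition("sA", "t1", "above_upper"),
            LabSignalDefinition("sB", "t2", "below_lower"),
        )
        defaults = dict(
            n_patients=50,
            drug_codes=("gX", "gY"),
            catalog=catalog,
            reference_ranges={"t1": (40.0, 60.0), "t2": (40.0, 60.0)},
            background_abnormal_prob=0.05,
            measurements_per_test=3,
        )
        defaults.update(kw)
        return EhrLabConfig(**defaults)

    def test_zero_background_no_embedding_all_normal(self):
        cfg = self._config(background_abnormal_prob=0.0)
        ds = generate_ehr_lab(cfg, GroundTruth(seed=0), 0)
        assert ((ds.measurements["value"] > 40) & (ds.measurements["value"] < 60)).all()

    def test_certain_excursion_forces_abnormality(self):
        truth = GroundTruth(embedded_lab_signals=[("gX", "sA", 1.0)], seed=0)
        cfg = self._config(background_abnormal_prob=0.0)
        ds = generate_ehr_lab(cfg, truth, 1)
        exposed = ds.exposures.loc[ds.exposures["drug_code"] == "gX"]
        for row in exposed.itertuples(index=False):
            meas = ds.measurements.loc[
                (ds.measurements["patient_id"] == row.patient_id)
                & (ds.measurements["test_id"] == "t1")
                & (ds.measurements["day"] >= row.start_day)
                & (ds.measurements["day"] <= row.start_day + cfg.window_days)
            ]
            if len(meas):
                assert (meas["value"] > 60).any()

    def test_determinism(self):
        cfg = self._config()
        d1 = generate_ehr_lab(cfg, GroundTruth(seed=0), 7)
        d2 = generate_ehr_lab(cfg, GroundTruth(seed=0), 7)
        pd.testing.assert_frame_equal(d1.measurements, d2.measurements)

    def test_unknown_signal_raises(self):
        truth = GroundTruth(embedded_lab_signals=[("gX", "nope", 0.5)], seed=0)
        with pytest.raises(ConfigurationError, match="nope"):
            generate_ehr_lab(self._config(), truth, 0)


class TestMappingsAndLabels:
    def test_identity_plus_brand_coverage(self):
        vocab = Vocabularies(
            generic_to_brands={"gX": ("BX1", "BX2"), "gY": ()},
            preferred_terms=("t1", "t2"),
        )
        mappings, kb = generate_mappings_and_labels(
            GroundTruth(label_known_pairs=[("gX", "t1")], seed=0), vocab
        )
        assert mappings.brand_to_generic["BX1"] == "gX"
        assert mappings.brand_to_generic["gX"] == "gX"
        assert mappings.raw_to_preferred["t1 [raw]"] == "t1"
        assert ("gX", "t1") in kb

    def test_label_pair_outside_vocab_raises(self):
        vocab = Vocabularies(generic_to_brands={"gX": ()}, preferred_terms=("t1",))
        with pytest.raises(ConfigurationError):
            generate_mappings_and_labels(
                GroundTruth(label_known_pairs=[("gZ", "t1")], seed=0), vocab
            )

    def test_mappings_round_trip(self, tmp_path):
        from adrscreen.datasets import VocabMappings

        vocab = Vocabularies(generic_to_brands={"gX": ("BX",)}, preferred_terms=("t1",))
        mappings, _ = generate_mappings_and_labels(GroundTruth(seed=0), vocab)
        mappings.to_tsv(tmp_path)
        loaded = VocabMappings.from_tsv(tmp_path)
        assert loaded.brand_to_generic == mappings.brand_to_generic
        assert loaded.raw_to_preferred == mappings.raw_to_preferred


class TestGroundTruth:
    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            GroundTruth(embedded_registry_signals=[("RA", "d", "t", 0.5)])

    def test_json_round_trip(self, tmp_path):
        truth = demo_ground_truth(3)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        loaded = GroundTruth.from_json(path)
        assert loaded == truth


def test_child_rng_streams_are_independent_and_stable():
    a1 = child_rng(5, "registry").random(3)
    a2 = child_rng(5, "registry").random(3)
    b = child_rng(5, "srs").random(3)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)
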