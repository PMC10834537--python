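"""Synthetic data generators with fully known ground truth.

Three sources are emulated, mirroring the statistical structure the screens
assume rather than any real cohort:

* a drug registry: per-disease cohorts with yearly follow-up visits,
  withdrawal / continuation / switch statuses, and ADR reports carrying
  relatedness, severity and outcome labels plus a laboratory-abnormality
  flag. ADR occurrence is sampled independently per follow-up case (the
  analysis's own counting unit); embedded (disease, drug, term, rho) signals
  multiply the related-or-indeterminate reporting rate by rho, so the
  relatedness filter is exercisable and the post-filter risk ratio converges
  to rho.
* a spontaneous reporting system: reports carrying one or two drugs (brand
  or generic names) and one or more events; an embedded (drug, event, rho)
  signal multiplies the event rate conditional on the drug by rho.
* EHR-style laboratory data: drug exposures plus measurement series with
  reference ranges; embedded (drug, signal) pairs trigger post-exposure
  excursions in the signal's direction with a stated probability.

All randomness flows from a single integer seed through labelled child
generators (:func:`child_rng`), so the three sources can be regenerated
independently and identically. Identical (config, seed) yields
byte-identical datasets.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import EhrLabDataset, RegistryDataset, SrsDataset, VocabMappings
from .lab import DIRECTIONS, LabSignalDefinition
from .labels import LabelKnowledgeBase

__all__ = [
    "ConfigurationError",
    "GroundTruth",
    "Vocabularies",
    "RegistryConfig",
    "SrsConfig",
    "EhrLabConfig",
    "child_rng",
    "generate_registry",
    "generate_srs",
    "generate_ehr_lab",
    "generate_mappings_and_labels",
    "default_registry_config",
    "default_term_vocabulary",
    "RA_DRUGS",
    "AS_DRUGS",
    "BRANDS",
    "demo_ground_truth",
    "demo_vocabularies",
    "demo_registry_config",
    "demo_srs_config",
    "demo_ehr_config",
    "demo_catalog",
    "generate_demo",
    "DemoBundle",
]


class ConfigurationError(ValueError):
    """Inconsistent generator configuration (bad probabilities or vocabulary)."""


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-module child generator derived from one master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))])


# --------------------------------------------------------------------------
# ground truth and vocabularies
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Embedded signals and label knowledge for a synthetic study.

    embedded_registry_signals: (disease, generic_drug, preferred_term, rho)
    embedded_srs_signals:      (generic_drug, preferred_term, rho)
    embedded_lab_signals:      (generic_drug, signal_id, excursion_probability)
    label_known_pairs:         (generic_drug, preferred_term)
    """

    embedded_registry_signals: list[tuple[str, str, str, float]] = field(default_factory=list)
    embedded_srs_signals: list[tuple[str, str, float]] = field(default_factory=list)
    embedded_lab_signals: list[tuple[str, str, float]] = field(default_factory=list)
    label_known_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for dis, drug, term, rho in self.embedded_registry_signals:
            if rho < 1:
                raise ConfigurationError(
                    f"registry risk ratio must be >= 1 for ({dis}, {drug}, {term}), got {rho}"
                )
        for drug, term, rho in self.embedded_srs_signals:
            if rho < 1:
                raise ConfigurationError(
                    f"SRS rate ratio must be >= 1 for ({drug}, {term}), got {rho}"
                )
        for drug, sig, p in self.embedded_lab_signals:
            if not 0 < p <= 1:
                raise ConfigurationError(
                    f"excursion probability must lie in (0, 1] for ({drug}, {sig}), got {p}"
                )

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "embedded_registry_signals": [list(t) for t in self.embedded_registry_signals],
            "embedded_srs_signals": [list(t) for t in self.embedded_srs_signals],
            "embedded_lab_signals": [list(t) for t in self.embedded_lab_signals],
            "label_known_pairs": [list(t) for t in self.label_known_pairs],
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            embedded_registry_signals=[tuple(t) for t in payload["embedded_registry_signals"]],
            embedded_srs_signals=[tuple(t) for t in payload["embedded_srs_signals"]],
            embedded_lab_signals=[tuple(t) for t in payload["embedded_lab_signals"]],
            label_known_pairs=[tuple(t) for t in payload["label_known_pairs"]],
            seed=int(payload["seed"]),
        )


@dataclass(frozen=True)
class Vocabularies:
    """Drug and ADR-term vocabularies shared across the generators.

    Each generic drug may carry brand names; each preferred term gets two
    raw spellings (the term itself and a "[raw]" variant) so the
    normalisation step has real work to do.
    """

    generic_to_brands: Mapping[str, tuple[str, ...]]
    preferred_terms: tuple[str, ...]
    lab_terms: frozenset[str] = frozenset()

    @staticmethod
    def raw_variants(term: str) -> tuple[str, str]:
        return (term, f"{term} [raw]")


# --------------------------------------------------------------------------
# registry generator
# --------------------------------------------------------------------------

RA_DRUGS = (
    "etanercept",
    "infliximab",
    "adalimumab",
    "golimumab",
    "rituximab",
    "abatacept",
    "tocilizumab",
    "tofacitinib",
    "baricitinib",
    "certolizumab",
)
AS_DRUGS = (
    "etanercept",
    "infliximab",
    "adalimumab",
    "golimumab",
    "secukinumab",
    "ixekizumab",
)

BRANDS: dict[str, tuple[str, ...]] = {
    "etanercept": ("Enbrel", "Benepali"),
    "infliximab": ("Remicade", "Remsima"),
    "adalimumab": ("Humira", "Amjevita"),
    "golimumab": ("Simponi",),
    "rituximab": ("Mabthera", "Truxima"),
    "abatacept": ("Orencia",),
    "tocilizumab": ("Actemra",),
    "tofacitinib": ("Xeljanz",),
    "baricitinib": ("Olumiant",),
    "certolizumab": ("Cimzia",),
    "secukinumab": ("Cosentyx",),
    "ixekizumab": ("Taltz",),
}

SEVERITIES = ("I", "II", "III")
OUTCOMES = ("not_resolved", "resolved", "resolved_with_sequelae", "unknown", "death")
STATUSES = ("continued", "switched", "discontinued", "other")


@dataclass
class RegistryConfig:
    """Registry cohort settings; defaults follow the emulated study design.

    Cohort sizes, withdrawal fractions, mean yearly follow-ups and the
    fraction of follow-ups on an unchanged agent default to the reported
    registry flow (2279 RA / 1940 AS patients; 81 / 54 withdrawals; about
    three follow-ups per patient; 57.5% / 75.5% of follow-ups continued).
    """

    n_patients: Mapping[str, int] = field(
        default_factory=lambda: {"RA": 2279, "AS": 1940}
    )
    drugs: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"RA": RA_DRUGS, "AS": AS_DRUGS}
    )
    drug_weights: Mapping[str, tuple[float, ...]] | None = None
    terms: tuple[str, ...] = ()
    lab_terms: frozenset[str] = frozenset()
    baseline_term_prob: float | Mapping[str, float] = 0.01
    mean_followups: Mapping[str, float] = field(
        default_factory=lambda: {"RA": 3.0, "AS": 3.4}
    )
    withdrawal_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"RA": 0.034, "AS": 0.027}
    )
    status_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "RA": {"continued": 0.575, "switched": 0.175, "discontinued": 0.2, "other": 0.05},
            "AS": {"continued": 0.755, "switched": 0.1, "discontinued": 0.12, "other": 0.025},
        }
    )
    relatedness_probs: Mapping[str, float] = field(
        default_factory=lambda: {"related": 0.5, "indeterminate": 0.2, "unrelated": 0.3}
    )
    generic_to_brands: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(BRANDS))

    def term_probs(self) -> np.ndarray:
        if isinstance(self.baseline_term_prob, Mapping):
            return np.array([self.baseline_term_prob[t] for t in self.terms], dtype=float)
        return np.full(len(self.terms), float(self.baseline_term_prob))


def default_term_vocabulary(n_terms: int = 600, n_lab: int = 100) -> tuple[tuple[str, ...], frozenset[str]]:
    """Synthetic preferred-term vocabulary with a laboratory-abnormality subset."""
    clinical = tuple(f"Adverse event {i:03d}" for i in range(1, n_terms - n_lab + 1))
    lab = tuple(f"Laboratory abnormality {i:03d}" for i in range(1, n_lab + 1))
    return clinical + lab, frozenset(lab)


def default_registry_config() -> RegistryConfig:
    terms, lab_terms = default_term_vocabulary()
    return RegistryConfig(terms=terms, lab_terms=lab_terms)


def _validate_registry(config: RegistryConfig, truth: GroundTruth) -> None:
    q_related = config.relatedness_probs["related"] + config.relatedness_probs["indeterminate"]
    if not np.isclose(sum(config.relatedness_probs.values()), 1.0, atol=1e-6):
        raise ConfigurationError("relatedness probabilities must sum to 1")
    betas = config.term_probs()
    if np.any(betas < 0) or np.any(betas > 1):
        raise ConfigurationError("baseline term probabilities must lie in [0, 1]")
    term_set = set(config.terms)
    term_index = {t: i for i, t in enumerate(config.terms)}
    for disease, wf in config.withdrawal_fraction.items():
        if not 0 <= wf <= 1:
            raise ConfigurationError(f"withdrawal fraction for {disease} must lie in [0, 1]")
    for disease, drug, term, rho in truth.embedded_registry_signals:
        if disease not in config.n_patients:
            raise ConfigurationError(f"embedded pair references unknown disease: ({disease}, {drug}, {term})")
        if drug not in config.drugs[disease]:
            raise ConfigurationError(f"embedded pair references unknown drug: ({disease}, {drug}, {term})")
        if term not in term_set:
            raise ConfigurationError(f"embedded pair references unknown term: ({disease}, {drug}, {term})")
        if betas[term_index[term]] * rho * q_related > 1.0:
            raise ConfigurationError(
                f"baseline probability x risk ratio exceeds 1 for ({disease}, {drug}, {term})"
            )
    for disease, drug_list in config.drugs.items():
        for drug in drug_list:
            if drug not in config.generic_to_brands:
                raise ConfigurationError(f"drug without brand/generic entry: {drug}")


def generate_registry(
    config: RegistryConfig, ground_truth: GroundTruth, seed: int | None = None
) -> RegistryDataset:
    """Simulate a registry cohort; see the module docstring for the model.

    For an embedded (disease, drug, term, rho) the per-case probability of a
    related-or-indeterminate report of ``term`` is rho times the baseline
    related-or-indeterminate rate; unrelated reporting is unaffected.
    """
    _validate_registry(config, ground_truth)
    seed = ground_truth.seed if seed is None else seed
    rng = child_rng(seed, "registry")

    rel = config.relatedness_probs
    q_ri = rel["related"] + rel["indeterminate"]
    p_related_given_ri = rel["related"] / q_ri if q_ri > 0 else 0.0
    betas = config.term_probs()
    n_terms = len(config.terms)
    lab_mask = np.array([t in config.lab_terms for t in config.terms])
    raw_variant_tables = [Vocabularies.raw_variants(t) for t in config.terms]

    patients_rows = []
    events_rows = []
    report_frames = []
    event_counter = 0
    report_counter = 0

    for disease in config.n_patients:
        n = int(config.n_patients[disease])
        drug_list = list(config.drugs[disease])
        weights = None
        if config.drug_weights is not None:
            w = np.asarray(config.drug_weights[disease], dtype=float)
            weights = w / w.sum()
        pids = [f"{disease}-P{i:05d}" for i in range(n)]
        withdrawn = rng.random(n) < config.withdrawal_fraction.get(disease, 0.0)
        drug_idx = rng.choice(len(drug_list), size=n, p=weights)
        k_followups = rng.poisson(config.mean_followups.get(disease, 3.0), size=n)
        k_followups[withdrawn] = 0

        for pid, wd in zip(pids, withdrawn):
            patients_rows.append((pid, disease, bool(wd)))

        def pick_brand(generic: str) -> str:
            brands = config.generic_to_brands.get(generic) or (generic,)
            return brands[int(rng.integers(0, len(brands)))]

        # initial enrollment events (no ADR reports attach to these)
        for i in range(n):
            events_rows.append(
                (event_counter, pids[i], "initial", pick_brand(drug_list[drug_idx[i]]), "other")
            )
            event_counter += 1

        # follow-up events
        patient_rep = np.repeat(np.arange(n), k_followups)
        m = len(patient_rep)
        status_names = list(config.status_probs[disease])
        status_p = np.array([config.status_probs[disease][s] for s in status_names], dtype=float)
        if not np.isclose(status_p.sum(), 1.0, atol=1e-6):
            raise ConfigurationError(f"drug-status probabilities for {disease} must sum to 1")
        statuses = rng.choice(status_names, size=m, p=status_p / status_p.sum())
        fu_event_ids = np.arange(event_counter, event_counter + m)
        event_counter += m
        for j in range(m):
            i = patient_rep[j]
            events_rows.append(
                (
                    int(fu_event_ids[j]),
                    pids[i],
                    "follow_up",
                    pick_brand(drug_list[drug_idx[i]]),
                    statuses[j],
                )
            )

        # ADR reports on follow-up events
        rho = np.ones((len(drug_list), n_terms))
        for dis, drug, term, r in ground_truth.embedded_registry_signals:
            if dis == disease:
                rho[drug_list.index(drug), config.terms.index(term)] = r
        ev_drug = drug_idx[patient_rep]
        p_ri = np.minimum(betas[None, :] * q_ri * rho[ev_drug], 1.0)
        p_un = np.minimum(betas[None, :] * (1.0 - q_ri), 1.0)
        hits_ri = rng.random((m, n_terms)) < p_ri
        hits_un = rng.random((m, n_terms)) < p_un

        for hits, related_stream in ((hits_ri, True), (hits_un, False)):
            ev_i, term_i = np.nonzero(hits)
            n_hits = len(ev_i)
            if n_hits == 0:
                continue
            if related_stream:
                relatedness = np.where(
                    rng.random(n_hits) < p_related_given_ri, "related", "indeterminate"
                )
            else:
                relatedness = np.full(n_hits, "unrelated")
            severity = rng.choice(SEVERITIES, size=n_hits, p=[0.6, 0.3, 0.1])
            outcome = rng.choice(OUTCOMES, size=n_hits, p=[0.15, 0.6, 0.05, 0.19, 0.01])
            variant_pick = rng.integers(0, 2, size=n_hits)
            raw_terms = [
                raw_variant_tables[t][v] for t, v in zip(term_i, variant_pick)
            ]
            frame = pd.DataFrame(
                {
                    "report_id": np.arange(report_counter, report_counter + n_hits),
                    "event_id": fu_event_ids[ev_i],
                    "raw_term": raw_terms,
                    "relatedness": relatedness,
                    "severity": severity,
                    "outcome": outcome,
                    "is_lab_abnormality": lab_mask[term_i],
                }
            )
            report_counter += n_hits
            report_frames.append(frame)

    patients = pd.DataFrame(patients_rows, columns=list(RegistryDataset.PATIENT_COLUMNS))
    events = pd.DataFrame(events_rows, columns=list(RegistryDataset.EVENT_COLUMNS))
    if report_frames:
        reports = pd.concat(report_frames, ignore_index=True)
        reports = reports.sort_values(["event_id", "report_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        reports = pd.DataFrame(columns=list(RegistryDataset.REPORT_COLUMNS))
    return RegistryDataset(patients=patients, events=events, adr_reports=reports)


# --------------------------------------------------------------------------
# SRS generator
# --------------------------------------------------------------------------


@dataclass
class SrsConfig:
    """Spontaneous-report generator settings.

    Marginals are expected mentions per report and must each sum to 1
    (within 1e-3): every report draws one primary drug from
    ``drug_marginals`` (plus a second with probability
    ``second_drug_prob``), and each event occurs independently with its
    marginal rate, multiplied by rho for embedded (drug, event) pairs.
    Reports that would carry no event draw one from the report's tilted
    event distribution, so every report mentions at least one event.
    """

    n_reports: int = 50_000
    drug_marginals: Mapping[str, float] = field(default_factory=dict)
    event_marginals: Mapping[str, float] = field(default_factory=dict)
    brand_fraction: float = 0.4
    second_drug_prob: float = 0.1
    generic_to_brands: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def _validate_srs(config: SrsConfig, truth: GroundTruth) -> None:
    for name, marg in (("drug", config.drug_marginals), ("event", config.event_marginals)):
        total = float(sum(marg.values()))
        if marg and abs(total - 1.0) > 1e-3:
            raise ConfigurationError(f"{name} marginals must sum to 1 (got {total:.6f})")
        if any(v < 0 for v in marg.values()):
            raise ConfigurationError(f"{name} marginals must be non-negative")
    if not 0 <= config.brand_fraction <= 1:
        raise ConfigurationError("brand_fraction must lie in [0, 1]")
    for drug, event, rho in truth.embedded_srs_signals:
        if drug not in config.drug_marginals:
            raise ConfigurationError(f"embedded SRS pair references unknown drug: ({drug}, {event})")
        if event not in config.event_marginals:
            raise ConfigurationError(f"embedded SRS pair references unknown event: ({drug}, {event})")
        if config.event_marginals[event] * rho > 1.0:
            raise ConfigurationError(
                f"event marginal x rate ratio exceeds 1 for ({drug}, {event})"
            )


def generate_srs(
    config: SrsConfig, ground_truth: GroundTruth, seed: int | None = None
) -> SrsDataset:
    """Simulate spontaneous reports with embedded reporting-rate-ratio signals.

    For an embedded (drug, event, rho), P(event mention | report mentions
    drug) is rho times the background event rate.
    """
    _validate_srs(config, ground_truth)
    seed = ground_truth.seed if seed is None else seed
    rng = child_rng(seed, "srs")
    n = int(config.n_reports)
    if n == 0:
        return SrsDataset(reports=pd.DataFrame(columns=list(SrsDataset.COLUMNS)))

    drug_names = list(config.drug_marginals)
    p_drug = np.array([config.drug_marginals[d] for d in drug_names], dtype=float)
    p_drug = p_drug / p_drug.sum()
    event_names = list(config.event_marginals)
    p_event = np.array([config.event_marginals[e] for e in event_names], dtype=float)
    n_events = len(event_names)

    primary = rng.choice(len(drug_names), size=n, p=p_drug)
    has_second = rng.random(n) < config.second_drug_prob
    second = rng.choice(len(drug_names), size=n, p=p_drug)
    has_second &= second != primary

    # per-report event-rate tilt from embedded signals
    tilt_by_drug: dict[int, dict[int, float]] = {}
    for drug, event, rho in ground_truth.embedded_srs_signals:
        di = drug_names.index(drug)
        ei = event_names.index(event)
        tilt_by_drug.setdefault(di, {})[ei] = max(tilt_by_drug.get(di, {}).get(ei, 1.0), rho)

    factor = np.ones((n, n_events))
    for di, events in tilt_by_drug.items():
        rows = (primary == di) | (has_second & (second == di))
        for ei, rho in events.items():
            factor[rows, ei] = np.maximum(factor[rows, ei], rho)

    prob = np.minimum(p_event[None, :] * factor, 1.0)
    hits = rng.random((n, n_events)) < prob

    # guarantee at least one event per report (tilted top-up draw)
    none = ~hits.any(axis=1)
    idx_none = np.nonzero(none)[0]
    if len(idx_none):
        tilted = prob[idx_none]
        tilted = tilted / tilted.sum(axis=1, keepdims=True)
        cum = np.cumsum(tilted, axis=1)
        u = rng.random(len(idx_none))
        choice = (u[:, None] < cum).argmax(axis=1)
        hits[idx_none, choice] = True

    rep_i, ev_i = np.nonzero(hits)
    event_rows = pd.DataFrame({"report": rep_i, "event": ev_i})
    drug_rows = [pd.DataFrame({"report": np.arange(n), "drug": primary})]
    if has_second.any():
        drug_rows.append(
            pd.DataFrame({"report": np.nonzero(has_second)[0], "drug": second[has_second]})
        )
    drugs_frame = pd.concat(drug_rows, ignore_index=True)

    rows = drugs_frame.merge(event_rows, on="report")
    rows = rows.sort_values(["report", "drug", "event"], kind="stable").reset_index(drop=True)

    # brand-name substitution per (report, drug) mention
    generic = np.array(drug_names, dtype=object)[rows["drug"].to_numpy()]
    use_brand = rng.random(len(rows)) < config.brand_fraction
    names = generic.copy()
    for i in np.nonzero(use_brand)[0]:
        brands = config.generic_to_brands.get(generic[i]) or ()
        if brands:
            names[i] = brands[int(rng.integers(0, len(brands)))]

    frame = pd.DataFrame(
        {
            "report_id": [f"R{r:07d}" for r in rows["report"]],
            "drug_name": names,
            "event_term": np.array(event_names, dtype=object)[rows["event"].to_numpy()],
        }
    )
    return SrsDataset(reports=frame)


# --------------------------------------------------------------------------
# EHR laboratory generator
# --------------------------------------------------------------------------


@dataclass
class EhrLabConfig:
    """EHR laboratory generator settings.

    Every patient receives one catalogued drug at a random start day and a
    fixed number of measurements per catalogued test spread over an
    observation span around the exposure start. Background abnormalities
    occur per measurement with ``background_abnormal_prob`` (random side);
    embedded (drug, signal) pairs force, with the stated per-patient
    probability, one post-exposure measurement of the signal's test outside
    the range in the signal's direction, uniformly timed within
    ``window_days`` of exposure start.
    """

    n_patients: int = 600
    drug_codes: tuple[str, ...] = ()
    disease_codes: tuple[str, ...] = ("M05", "M45")
    catalog: tuple[LabSignalDefinition, ...] = ()
    reference_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    background_abnormal_prob: float = 0.02
    measurements_per_test: int = 3
    pre_days: int = 180
    post_days: int = 540
    window_days: int = 365


def _validate_ehr(config: EhrLabConfig, truth: GroundTruth) -> None:
    if not config.catalog:
        raise ConfigurationError("laboratory signal catalog must be non-empty")
    if not 0 <= config.background_abnormal_prob <= 1:
        raise ConfigurationError("background_abnormal_prob must lie in [0, 1]")
    signal_ids = {s.signal_id for s in config.catalog}
    for s in config.catalog:
        if s.test_id not in config.reference_ranges:
            raise ConfigurationError(f"signal {s.signal_id} references test without reference range")
        lo, hi = config.reference_ranges[s.test_id]
        if not lo < hi:
            raise ConfigurationError(f"reference range for {s.test_id} must satisfy lower < upper")
    for drug, sig, _ in truth.embedded_lab_signals:
        if drug not in config.drug_codes:
            raise ConfigurationError(f"embedded lab pair references unknown drug: ({drug}, {sig})")
        if sig not in signal_ids:
            raise ConfigurationError(f"embedded lab pair references unknown signal: ({drug}, {sig})")


def _abnormal_value(rng, lo, hi, direction):
    width = hi - lo
    offset = (0.1 + 0.5 * rng.random()) * width
    if direction == "above_upper":
        return hi + offset
    if direction == "below_lower":
        return lo - offset
    return hi + offset if rng.random() < 0.5 else lo - offset


def generate_ehr_lab(
    config: EhrLabConfig, ground_truth: GroundTruth, seed: int | None = None
) -> EhrLabDataset:
    """Simulate drug exposures plus laboratory series with excursions."""
    _validate_ehr(config, ground_truth)
    seed = ground_truth.seed if seed is None else seed
    rng = child_rng(seed, "ehr_lab")
    n = int(config.n_patients)
    drug_codes = list(config.drug_codes)
    pids = [f"EHR-P{i:05d}" for i in range(n)]
    drug_idx = rng.integers(0, len(drug_codes), size=n)
    disease = rng.choice(list(config.disease_codes), size=n)
    start = rng.integers(1000, 3000, size=n)

    exposures = pd.DataFrame(
        {
            "patient_id": pids,
            "disease_code": disease,
            "drug_code": [drug_codes[i] for i in drug_idx],
            "start_day": start,
        }
    )

    tests = sorted({s.test_id for s in config.catalog})
    m = config.measurements_per_test
    meas_rows = []
    for t in tests:
        lo, hi = config.reference_ranges[t]
        for i in range(n):
            days = start[i] - config.pre_days + rng.integers(
                0, config.pre_days + config.post_days, size=m
            )
            days = np.sort(days)
            for day in days:
                if rng.random() < config.background_abnormal_prob:
                    side = "above_upper" if rng.random() < 0.5 else "below_lower"
                    value = _abnormal_value(rng, lo, hi, side)
                else:
                    value = lo + (hi - lo) * rng.random()
                meas_rows.append((pids[i], t, float(value), int(day)))

    measurements = pd.DataFrame(
        meas_rows, columns=list(EhrLabDataset.MEASUREMENT_COLUMNS)
    )

    # embedded post-exposure excursions
    catalog_by_id = {s.signal_id: s for s in config.catalog}
    for drug, sig_id, p_exc in ground_truth.embedded_lab_signals:
        sig = catalog_by_id[sig_id]
        lo, hi = config.reference_ranges[sig.test_id]
        exposed = [i for i in range(n) if drug_codes[drug_idx[i]] == drug]
        for i in exposed:
            if rng.random() >= p_exc:
                continue
            in_window = measurements.index[
                (measurements["patient_id"] == pids[i])
                & (measurements["test_id"] == sig.test_id)
                & (measurements["day"] >= start[i])
                & (measurements["day"] <= start[i] + config.window_days)
            ]
            if len(in_window) == 0:
                continue
            target = in_window[int(rng.integers(0, len(in_window)))]
            measurements.loc[target, "value"] = _abnormal_value(rng, lo, hi, sig.direction)

    reference = pd.DataFrame(
        [(t, *config.reference_ranges[t]) for t in tests],
        columns=list(EhrLabDataset.RANGE_COLUMNS),
    )
    return EhrLabDataset(
        exposures=exposures, measurements=measurements, reference_ranges=reference
    )


# --------------------------------------------------------------------------
# mappings and label knowledge base
# --------------------------------------------------------------------------


def generate_mappings_and_labels(
    ground_truth: GroundTruth, vocabularies: Vocabularies
) -> tuple[VocabMappings, LabelKnowledgeBase]:
    """Build normalisation tables and the label knowledge base.

    The brand table covers every brand plus identity rows for the generics;
    the term table covers every raw spelling variant plus identity rows for
    the preferred terms. The knowledge base equals the ground truth's
    label-known pairs.
    """
    if not vocabularies.generic_to_brands or not vocabularies.preferred_terms:
        raise ConfigurationError("vocabularies must be non-empty")
    brand_to_generic: dict[str, str] = {}
    for generic, brands in vocabularies.generic_to_brands.items():
        brand_to_generic[generic] = generic
        for brand in brands:
            brand_to_generic[brand] = generic
    raw_to_preferred: dict[str, str] = {}
    for term in vocabularies.preferred_terms:
        for variant in Vocabularies.raw_variants(term):
            raw_to_preferred[variant] = term
    term_set = set(vocabularies.preferred_terms)
    generic_set = set(vocabularies.generic_to_brands)
    for drug, term in ground_truth.label_known_pairs:
        if drug not in generic_set or term not in term_set:
            raise ConfigurationError(f"label-known pair outside the vocabularies: ({drug}, {term})")
    kb = LabelKnowledgeBase.from_pairs(ground_truth.label_known_pairs, provenance="ground truth")
    return VocabMappings(brand_to_generic, raw_to_preferred), kb


# --------------------------------------------------------------------------
# demo fixture: the full multi-source flow at desk scale
# --------------------------------------------------------------------------

_DEMO_RA_EMBED_DRUGS = (
    "etanercept",
    "infliximab",
    "adalimumab",
    "golimumab",
    "rituximab",
    "abatacept",
    "tocilizumab",
    "tofacitinib",
)
_DEMO_AS_EMBED_DRUGS = ("etanercept", "infliximab", "adalimumab", "golimumab")
_DEMO_SHARED_PAIRS = (
    ("etanercept", "Demo shared signal 01"),
    ("infliximab", "Demo shared signal 02"),
    ("adalimumab", "Demo shared signal 03"),
    ("golimumab", "Demo shared signal 04"),
    ("adalimumab", "Demo shared signal 05"),
)
_DEMO_REGISTRY_RHO = 30.0
_DEMO_SRS_RHO = 25.0


def _round_robin(drugs: Sequence[str], terms: Sequence[str]) -> list[tuple[str, str]]:
    return [(drugs[i % len(drugs)], t) for i, t in enumerate(terms)]


def demo_ground_truth(seed: int = 0) -> GroundTruth:
    """Construct the demo ground truth by set arithmetic.

    Per stratum: 51 embedded RA pairs of which 16 are label-known (35
    novel) and 36 embedded AS pairs of which 10 are label-known (26 novel).
    14 distinct pairs carry SRS signals: 8 RA-only, 1 AS-only and 5 shared
    between the strata — so 13 RA and 6 AS novel candidates are
    SRS-confirmed and the merged final set has 14 members.
    """
    shared = list(_DEMO_SHARED_PAIRS)
    ra_confirmed = _round_robin(
        _DEMO_RA_EMBED_DRUGS, [f"Demo RA confirmed {i:02d}" for i in range(1, 9)]
    )
    ra_novel_only = _round_robin(
        _DEMO_RA_EMBED_DRUGS, [f"Demo RA novel {i:02d}" for i in range(1, 23)]
    )
    ra_labeled = _round_robin(
        _DEMO_RA_EMBED_DRUGS, [f"Demo RA labeled {i:02d}" for i in range(1, 17)]
    )
    as_confirmed = [("etanercept", "Demo AS confirmed 01")]
    as_novel_only = _round_robin(
        _DEMO_AS_EMBED_DRUGS, [f"Demo AS novel {i:02d}" for i in range(1, 21)]
    )
    as_labeled = _round_robin(
        _DEMO_AS_EMBED_DRUGS, [f"Demo AS labeled {i:02d}" for i in range(1, 11)]
    )

    ra_pairs = shared + ra_confirmed + ra_novel_only + ra_labeled  # 5+8+22+16 = 51
    as_pairs = shared + as_confirmed + as_novel_only + as_labeled  # 5+1+20+10 = 36
    srs_pairs = shared + ra_confirmed + as_confirmed  # 14 distinct

    return GroundTruth(
        embedded_registry_signals=[
            ("RA", d, t, _DEMO_REGISTRY_RHO) for d, t in ra_pairs
        ]
        + [("AS", d, t, _DEMO_REGISTRY_RHO) for d, t in as_pairs],
        embedded_srs_signals=[(d, t, _DEMO_SRS_RHO) for d, t in srs_pairs],
        embedded_lab_signals=[
            ("tocilizumab", "sig_above_01", 0.9),
            ("tofacitinib", "sig_below_01", 0.9),
        ],
        label_known_pairs=ra_labeled + as_labeled,
        seed=seed,
    )


def _demo_terms(truth: GroundTruth) -> tuple[tuple[str, ...], frozenset[str]]:
    embedded_terms: list[str] = []
    for _, _, term, _ in truth.embedded_registry_signals:
        if term not in embedded_terms:
            embedded_terms.append(term)
    filler = [f"Demo background event {i:02d}" for i in range(1, 21)]
    terms = tuple(embedded_terms + filler)
    lab = frozenset(t for i, t in enumerate(terms) if i % 4 == 0)
    return terms, lab


def demo_vocabularies() -> Vocabularies:
    truth = demo_ground_truth()
    terms, lab = _demo_terms(truth)
    srs_events = tuple(f"SRS background event {i:02d}" for i in range(1, 25))
    generic_to_brands = dict(BRANDS)
    for i in range(1, 9):
        generic_to_brands[f"Background drug {i:02d}"] = ()
    return Vocabularies(
        generic_to_brands=generic_to_brands,
        preferred_terms=terms + srs_events,
        lab_terms=lab,
    )


def demo_registry_config() -> RegistryConfig:
    truth = demo_ground_truth()
    terms, lab = _demo_terms(truth)
    return RegistryConfig(
        n_patients={"RA": 1000, "AS": 1000},
        drugs={
            "RA": _DEMO_RA_EMBED_DRUGS + ("baricitinib", "certolizumab"),
            "AS": _DEMO_AS_EMBED_DRUGS + ("secukinumab", "ixekizumab"),
        },
        terms=terms,
        lab_terms=lab,
        baseline_term_prob=0.015,
        mean_followups={"RA": 3.0, "AS": 3.0},
        withdrawal_fraction={"RA": 0.03, "AS": 0.03},
        status_probs={
            "RA": {"continued": 0.6, "switched": 0.2, "discontinued": 0.15, "other": 0.05},
            "AS": {"continued": 0.6, "switched": 0.2, "discontinued": 0.15, "other": 0.05},
        },
    )


def demo_srs_config() -> SrsConfig:
    truth = demo_ground_truth()
    confirmed_terms = [t for _, t, _ in truth.embedded_srs_signals]
    # dict keys preserve order; the 14 confirmed terms are distinct
    target_drugs = [
        "etanercept",
        "infliximab",
        "adalimumab",
        "golimumab",
        "rituximab",
        "abatacept",
        "tocilizumab",
        "tofacitinib",
        "baricitinib",
        "certolizumab",
        "secukinumab",
        "ixekizumab",
    ]
    drug_marginals = {d: 0.04 for d in target_drugs}
    for i in range(1, 9):
        drug_marginals[f"Background drug {i:02d}"] = 0.065
    event_marginals = {t: 0.004 for t in confirmed_terms}
    fillers = [f"SRS background event {i:02d}" for i in range(1, 25)]
    for t in fillers:
        event_marginals[t] = (1.0 - 0.004 * len(confirmed_terms)) / len(fillers)
    return SrsConfig(
        n_reports=50_000,
        drug_marginals=drug_marginals,
        event_marginals=event_marginals,
        brand_fraction=0.4,
        second_drug_prob=0.1,
        generic_to_brands=dict(BRANDS),
    )


def demo_catalog() -> tuple[list[LabSignalDefinition], dict[str, tuple[float, float]]]:
    """102 laboratory signals partitioned 38 above / 39 below / 25 outside."""
    tests = [f"lab_test_{i:02d}" for i in range(1, 35)]
    ranges = {t: (40.0, 60.0) for t in tests}
    catalog: list[LabSignalDefinition] = []
    counts = {"above_upper": 38, "below_lower": 39, "outside_range": 25}
    prefixes = {"above_upper": "sig_above", "below_lower": "sig_below", "outside_range": "sig_outside"}
    lab_pts = {
        "sig_above_01": "Laboratory marker increased",
        "sig_below_01": "Laboratory marker decreased",
    }
    for direction, count in counts.items():
        for i in range(1, count + 1):
            sig_id = f"{prefixes[direction]}_{i:02d}"
            catalog.append(
                LabSignalDefinition(
                    signal_id=sig_id,
                    test_id=tests[(len(catalog)) % len(tests)],
                    direction=direction,
                    preferred_term=lab_pts.get(sig_id, ""),
                )
            )
    return catalog, ranges


def demo_ehr_config() -> EhrLabConfig:
    catalog, ranges = demo_catalog()
    return EhrLabConfig(
        n_patients=600,
        drug_codes=_DEMO_RA_EMBED_DRUGS + ("baricitinib", "certolizumab"),
        catalog=tuple(catalog),
        reference_ranges=ranges,
        background_abnormal_prob=0.02,
        measurements_per_test=3,
    )


@dataclass
class DemoBundle:
    """All demo inputs: datasets, mappings, knowledge base and ground truth."""

    registry: RegistryDataset
    srs: SrsDataset
    ehr: EhrLabDataset
    mappings: VocabMappings
    kb: LabelKnowledgeBase
    catalog: list[LabSignalDefinition]
    ground_truth: GroundTruth


def generate_demo(seed: int = 0) -> DemoBundle:
    """Generate the complete seeded demo study."""
    truth = demo_ground_truth(seed)
    vocab = demo_vocabularies()
    mappings, kb = generate_mappings_and_labels(truth, vocab)
    registry = generate_registry(demo_registry_config(), truth, seed)
    srs = generate_srs(demo_srs_config(), truth, seed)
    ehr = generate_ehr_lab(demo_ehr_config(), truth, seed)
    catalog, _ = demo_catalog()
    return DemoBundle(
        registry=registry,
        srs=srs,
        ehr=ehr,
        mappings=mappings,
        kb=kb,
        catalog=catalog,
        ground_truth=truth,
    )
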