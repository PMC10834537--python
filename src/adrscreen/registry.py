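"""Registry relative-risk screen.

The registry is a per-disease cohort of patients on biologic DMARDs or
targeted therapies with yearly follow-up visits. Each follow-up interval of
a patient who stayed on the same agent is one independent *case*; a case
carries the set of preferred-term ADRs reported for that interval with
relatedness 'related' or 'indeterminate'. Per disease stratum, every
(drug, term) pair with enough cases gets a 2x2 table against all other
drugs and a risk ratio with a Katz confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, relative_risk
from .datasets import RegistryDataset, VocabMappings

__all__ = [
    "RegistryCase",
    "SignalResult",
    "select_valid_cases",
    "build_contingency",
    "screen_registry",
    "RegistryScreen",
    "RegistryScreenResults",
]

KEPT_RELATEDNESS = frozenset({"related", "indeterminate"})
KEPT_STATUS = "continued"


@dataclass(frozen=True)
class RegistryCase:
    """One follow-up interval of one patient on one (generic) drug."""

    case_id: str
    disease: str
    generic_drug: str
    terms: frozenset[str]
    lab_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.generic_drug:
            raise ValueError("generic_drug must be non-empty")
        if not self.lab_terms <= self.terms:
            raise ValueError("lab_terms must be a subset of terms")


@dataclass(frozen=True)
class SignalResult:
    """A screened drug--event pair in one disease stratum."""

    disease: str
    generic_drug: str
    preferred_term: str
    a: int
    rr: float
    ci_low: float
    ci_high: float
    significant: bool
    is_lab_abnormality: bool

    def __post_init__(self) -> None:
        if self.significant and not self.rr > 1.0:
            raise ValueError("significant signal requires rr > 1")


def select_valid_cases(
    dataset: RegistryDataset, mappings: VocabMappings
) -> dict[str, list[RegistryCase]]:
    """Select analysable registry cases, normalising vocabularies.

    Keeps one case per follow-up event with drug status 'continued' from a
    non-withdrawn patient. A case's term set contains the preferred terms of
    its reports with relatedness 'related' or 'indeterminate'; severity and
    outcome are ignored. Unmapped brand names or raw terms raise
    :class:`~adrscreen.datasets.VocabularyError` (nothing is dropped
    silently). Returns cases grouped by disease stratum.
    """
    patients = dataset.patients
    kept_patients = patients.loc[~patients["withdrawn"].astype(bool)]
    events = dataset.events
    kept = events.loc[
        (events["phase"] == "follow_up") & (events["drug_status"] == KEPT_STATUS)
    ].merge(kept_patients[["patient_id", "disease"]], on="patient_id", how="inner")
    kept = kept.copy()
    kept["generic_drug"] = mappings.map_drugs(kept["drug_brand_name"])

    reports = dataset.adr_reports
    reports = reports.loc[reports["relatedness"].isin(KEPT_RELATEDNESS)]
    reports = reports.merge(kept[["event_id"]], on="event_id", how="inner").copy()
    reports["preferred_term"] = mappings.map_terms(reports["raw_term"])

    terms_by_event: dict = {}
    lab_by_event: dict = {}
    for event_id, grp in reports.groupby("event_id"):
        terms_by_event[event_id] = frozenset(grp["preferred_term"])
        lab_by_event[event_id] = frozenset(
            grp.loc[grp["is_lab_abnormality"].astype(bool), "preferred_term"]
        )

    out: dict[str, list[RegistryCase]] = {}
    for row in kept.sort_values("event_id").itertuples(index=False):
        case = RegistryCase(
            case_id=str(row.event_id),
            disease=row.disease,
            generic_drug=row.generic_drug,
            terms=terms_by_event.get(row.event_id, frozenset()),
            lab_terms=lab_by_event.get(row.event_id, frozenset()),
        )
        out.setdefault(row.disease, []).append(case)
    return out


def build_contingency(
    cases: Sequence[RegistryCase], drug: str, term: str
) -> ContingencyTable:
    """Case-level 2x2 table for one (drug, term) pair within one stratum."""
    if not cases:
        raise ValueError("cannot build a contingency table from an empty case list")
    diseases = {case.disease for case in cases}
    if len(diseases) > 1:
        raise ValueError(f"cases span multiple disease strata: {sorted(diseases)}")
    a = b = c = d = 0
    for case in cases:
        on_drug = case.generic_drug == drug
        has_term = term in case.terms
        if on_drug and has_term:
            a += 1
        elif on_drug:
            b += 1
        elif has_term:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _case_frames(cases: Sequence[RegistryCase]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten cases to (case, drug) and exploded (case, term, is_lab) frames."""
    drug_rows = [(i, case.generic_drug) for i, case in enumerate(cases)]
    term_rows = [
        (i, term, term in case.lab_terms)
        for i, case in enumerate(cases)
        for term in case.terms
    ]
    drugs = pd.DataFrame(drug_rows, columns=["case", "drug"])
    terms = pd.DataFrame(term_rows, columns=["case", "term", "is_lab"])
    return drugs, terms


def screen_registry(
    cases: Sequence[RegistryCase],
    alpha: float = 0.05,
    min_count: int = 3,
    point_estimate_only: bool = False,
) -> list[SignalResult]:
    """Screen every (drug, term) pair with at least ``min_count`` co-occurrences.

    Significance requires RR > 1 and, unless ``point_estimate_only`` is set,
    a lower confidence bound strictly above 1, both evaluated on unrounded
    values. The literal RR > 1 rule is available through
    ``point_estimate_only=True``.
    """
    return RegistryScreen(
        cases, alpha=alpha, min_count=min_count, point_estimate_only=point_estimate_only
    ).fit().signals


class RegistryScreen:
    """Relative-risk screening model for one disease stratum of registry cases.

    Parameters
    ----------
    cases
        Cases from :func:`select_valid_cases` (a single disease stratum).
    alpha
        Two-sided CI level for the Katz interval (default 0.05 -> 95% CI).
    min_count
        Minimum cell 'a' for a pair to be reported (default 3).
    point_estimate_only
        If True, flag significance on RR > 1 alone instead of requiring the
        CI lower bound to exceed 1.
    """

    def __init__(
        self,
        cases: Sequence[RegistryCase],
        *,
        alpha: float = 0.05,
        min_count: int = 3,
        point_estimate_only: bool = False,
    ):
        if not cases:
            raise ValueError("no cases to screen")
        diseases = {case.disease for case in cases}
        if len(diseases) > 1:
            raise ValueError(f"cases span multiple disease strata: {sorted(diseases)}")
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        self.cases = list(cases)
        self.disease = next(iter(diseases))
        self.alpha = alpha
        self.min_count = min_count
        self.point_estimate_only = point_estimate_only

    def fit(self) -> "RegistryScreenResults":
        drugs, terms = _case_frames(self.cases)
        n_cases = len(self.cases)
        n_by_drug = drugs.groupby("drug").size()
        n_by_term = terms.groupby("term").size()
        lab_flag = terms.groupby("term")["is_lab"].any()

        joint = terms.merge(drugs, on="case").groupby(["drug", "term"]).size()
        rows = []
        for (drug, term), a in joint.items():
            if a < self.min_count:
                continue
            b = int(n_by_drug[drug] - a)
            c = int(n_by_term[term] - a)
            d = int(n_cases - a - b - c)
            table = ContingencyTable(int(a), b, c, d)
            rr, lo, hi = relative_risk(table, self.alpha)
            if self.point_estimate_only:
                significant = bool(rr > 1.0)
            else:
                significant = bool(rr > 1.0 and not math.isnan(lo) and lo > 1.0)
            rows.append(
                dict(
                    disease=self.disease,
                    generic_drug=drug,
                    preferred_term=term,
                    a=int(a),
                    b=b,
                    c=c,
                    d=d,
                    rr=rr,
                    ci_low=lo,
                    ci_high=hi,
                    significant=significant,
                    is_lab_abnormality=bool(lab_flag[term]),
                )
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "disease",
                "generic_drug",
                "preferred_term",
                "a",
                "b",
                "c",
                "d",
                "rr",
                "ci_low",
                "ci_high",
                "significant",
                "is_lab_abnormality",
            ],
        )
        frame = frame.sort_values(["generic_drug", "preferred_term"], kind="stable").reset_index(
            drop=True
        )
        return RegistryScreenResults(self, frame)


class RegistryScreenResults:
    """Per-pair risk ratios, confidence intervals and significance flags."""

    def __init__(self, model: RegistryScreen, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def signals(self) -> list[SignalResult]:
        return [
            SignalResult(
                disease=row.disease,
                generic_drug=row.generic_drug,
                preferred_term=row.preferred_term,
                a=int(row.a),
                rr=row.rr,
                ci_low=row.ci_low,
                ci_high=row.ci_high,
                significant=bool(row.significant),
                is_lab_abnormality=bool(row.is_lab_abnormality),
            )
            for row in self.frame.itertuples(index=False)
        ]

    @property
    def significant_frame(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        sig = self.significant_frame
        lines = [
            f"Registry screen: stratum={self.model.disease}, "
            f"cases={len(self.model.cases)}, alpha={self.model.alpha}, "
            f"min_count={self.model.min_count}",
            f"pairs evaluated: {len(self.frame)}; significant (RR>1, CI low>1): {len(sig)}",
        ]
        if len(sig):
            lines.append(
                sig[
                    ["generic_drug", "preferred_term", "a", "rr", "ci_low", "ci_high"]
                ].to_string(index=False, float_format=lambda v: f"{v:.3f}")
            )
        return "\n".join(lines)
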