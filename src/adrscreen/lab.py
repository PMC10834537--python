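"""Laboratory-abnormality signal screen on EHR-style data.

A laboratory signal is a test paired with an abnormality direction: value
above the upper reference limit, below the lower limit, or outside the
reference range (either side). Patients are classified by whether any
measurement of the test inside their assessment window satisfies the
direction predicate; exposed patients are assessed within a fixed window
after their first exposure to the drug of interest, unexposed patients over
their whole observation span. The patient-level 2x2 table per (drug,
signal) pair yields a risk ratio and a two-sided p-value (Pearson
chi-square, or Fisher's exact test when any expected cell is below 5).

Values exactly equal to a reference limit are normal: all direction
predicates use strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .contingency import ContingencyTable, relative_risk
from .datasets import EhrLabDataset

__all__ = [
    "DIRECTIONS",
    "LabSignalDefinition",
    "LabScreenResult",
    "load_catalog",
    "classify_patient_signal",
    "screen_lab",
    "LabScreen",
    "LabScreenResults",
]

DIRECTIONS = ("above_upper", "below_lower", "outside_range")


@dataclass(frozen=True)
class LabSignalDefinition:
    """A catalogued laboratory signal: test plus abnormality direction."""

    signal_id: str
    test_id: str
    direction: str
    preferred_term: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )

    def predicate(self, values: np.ndarray, lower: float, upper: float) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction == "above_upper":
            return values > upper
        if self.direction == "below_lower":
            return values < lower
        return (values < lower) | (values > upper)


@dataclass(frozen=True)
class LabScreenResult:
    generic_drug: str
    signal_id: str
    table: ContingencyTable
    rr: float
    p_value: float
    significant: bool


def load_catalog(path: str | Path) -> list[LabSignalDefinition]:
    """Read a signal catalog TSV (signal_id, test_id, direction[, preferred_term])."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        LabSignalDefinition(
            signal_id=str(r.signal_id),
            test_id=str(r.test_id),
            direction=str(r.direction),
            preferred_term=str(getattr(r, "preferred_term", "")),
        )
        for r in frame.itertuples(index=False)
    ]


def catalog_to_tsv(catalog: Sequence[LabSignalDefinition], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            dict(
                signal_id=s.signal_id,
                test_id=s.test_id,
                direction=s.direction,
                preferred_term=s.preferred_term,
            )
            for s in catalog
        ]
    ).to_csv(path, sep="\t", index=False)


def classify_patient_signal(
    days: Sequence[float],
    values: Sequence[float],
    definition: LabSignalDefinition,
    lower: float,
    upper: float,
    window: tuple[float, float] | None = None,
) -> bool:
    """True iff any measurement inside the window is abnormal in the direction.

    ``window`` is a closed (start, end) day interval; None means the
    patient's whole observation span (the unexposed convention).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape:
        raise ValueError("days and values must align")
    if window is not None:
        start, end = window
        keep = (days >= start) & (days <= end)
        days, values = days[keep], values[keep]
    if len(values) == 0:
        return False
    return bool(definition.predicate(values, lower, upper).any())


def _pair_p_value(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Pearson chi-square, falling back to Fisher's exact test
    when any expected cell count is below 5."""
    table = np.array([[a, b], [c, d]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if (expected < 5).any():
        return float(_stats.fisher_exact(table, alternative="two-sided")[1])
    return float(_stats.chi2_contingency(table, correction=False)[1])


class LabScreen:
    """Patient-level screen for drug-associated laboratory abnormalities.

    Parameters
    ----------
    ehr
        Exposures, measurements and reference ranges.
    catalog
        Laboratory signal definitions; every catalogued test must have a
        reference range.
    drug_codes
        Drugs to screen; defaults to every drug present in the exposures.
    window_days
        Assessment window after first exposure (default 365 days).
    comparator
        'other_drugs' (default): the comparator group is patients exposed to
        other screened drugs but not the drug of interest; 'all_others':
        every other patient.
    alpha
        CI level for the Katz interval on the patient-level RR.
    """

    def __init__(
        self,
        ehr: EhrLabDataset,
        catalog: Sequence[LabSignalDefinition],
        *,
        drug_codes: Sequence[str] | None = None,
        window_days: float = 365.0,
        comparator: str = "other_drugs",
        alpha: float = 0.05,
    ):
        if not catalog:
            raise ValueError("catalog must be non-empty")
        if comparator not in ("other_drugs", "all_others"):
            raise ValueError("comparator must be 'other_drugs' or 'all_others'")
        self.ehr = ehr
        self.catalog = list(catalog)
        self.window_days = float(window_days)
        self.comparator = comparator
        self.alpha = alpha
        exposures = ehr.exposures
        if drug_codes is None:
            drug_codes = sorted(exposures["drug_code"].unique())
        self.drug_codes = list(drug_codes)
        ranges = ehr.reference_ranges.set_index("test_id")
        measured_tests = set(ehr.measurements["test_id"].unique())
        missing = measured_tests - set(ranges.index)
        if missing:
            raise ValueError(f"measurements for tests without reference ranges: {sorted(missing)}")
        self._ranges = ranges

    def fit(self) -> "LabScreenResults":
        ehr = self.ehr
        first_exposure = (
            ehr.exposures.groupby(["patient_id", "drug_code"])["start_day"].min().reset_index()
        )
        exposed_sets = {
            drug: dict(zip(grp["patient_id"], grp["start_day"]))
            for drug, grp in first_exposure.groupby("drug_code")
        }
        screened_patients = sorted(
            set(
                first_exposure.loc[
                    first_exposure["drug_code"].isin(self.drug_codes), "patient_id"
                ]
            )
        )
        all_patients = sorted(set(ehr.exposures["patient_id"]))

        measurements = ehr.measurements
        rows = []
        for signal in self.catalog:
            limits = self._ranges.loc[signal.test_id]
            lower, upper = float(limits["lower_limit"]), float(limits["upper_limit"])
            meas = measurements.loc[measurements["test_id"] == signal.test_id]
            abnormal = signal.predicate(meas["value"].to_numpy(), lower, upper)
            abn = meas.loc[abnormal, ["patient_id", "day"]]
            abn_days = {pid: grp["day"].to_numpy() for pid, grp in abn.groupby("patient_id")}
            abn_any = set(abn_days)

            for drug in self.drug_codes:
                exposure_days = exposed_sets.get(drug, {})
                exposed = set(exposure_days)
                if self.comparator == "other_drugs":
                    pool = set(screened_patients)
                else:
                    pool = set(all_patients)
                unexposed = pool - exposed
                if not exposed or not unexposed:
                    continue
                a = sum(
                    1
                    for pid in exposed
                    if pid in abn_days
                    and np.any(
                        (abn_days[pid] >= exposure_days[pid])
                        & (abn_days[pid] <= exposure_days[pid] + self.window_days)
                    )
                )
                b = len(exposed) - a
                c = sum(1 for pid in unexposed if pid in abn_any)
                d = len(unexposed) - c
                table = ContingencyTable(a, b, c, d)
                rr, ci_low, ci_high = relative_risk(table, self.alpha)
                p = _pair_p_value(a, b, c, d)
                significant = bool(rr > 1.0 and p < 0.05)
                rows.append(
                    dict(
                        generic_drug=drug,
                        signal_id=signal.signal_id,
                        test_id=signal.test_id,
                        direction=signal.direction,
                        preferred_term=signal.preferred_term,
                        a=a,
                        b=b,
                        c=c,
                        d=d,
                        rr=rr,
                        ci_low=ci_low,
                        ci_high=ci_high,
                        p_value=p,
                        significant=significant,
                    )
                )
        frame = pd.DataFrame(
            rows,
            columns=[
                "generic_drug",
                "signal_id",
                "test_id",
                "direction",
                "preferred_term",
                "a",
                "b",
                "c",
                "d",
                "rr",
                "ci_low",
                "ci_high",
                "p_value",
                "significant",
            ],
        )
        return LabScreenResults(self, frame)


class LabScreenResults:
    """Per (drug, signal) patient-level tables, risk ratios and p-values."""

    def __init__(self, model: LabScreen, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def significant_frame(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["significant"]].reset_index(drop=True)

    @property
    def results(self) -> list[LabScreenResult]:
        return [
            LabScreenResult(
                generic_drug=row.generic_drug,
                signal_id=row.signal_id,
                table=ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d)),
                rr=row.rr,
                p_value=row.p_value,
                significant=bool(row.significant),
            )
            for row in self.frame.itertuples(index=False)
        ]

    def summary(self) -> str:
        sig = self.significant_frame
        lines = [
            f"Laboratory screen: {len(self.model.catalog)} signals x "
            f"{len(self.model.drug_codes)} drugs, window={self.model.window_days:g} days, "
            f"comparator={self.model.comparator}",
            f"pairs evaluated: {len(self.frame)}; significant (RR>1, p<0.05): {len(sig)}",
        ]
        if len(sig):
            lines.append(
                sig[["generic_drug", "signal_id", "direction", "a", "rr", "p_value"]].to_string(
                    index=False, float_format=lambda v: f"{v:.3g}"
                )
            )
        return "\n".join(lines)


def screen_lab(
    ehr: EhrLabDataset,
    catalog: Sequence[LabSignalDefinition],
    drug_codes: Sequence[str] | None = None,
    window_days: float = 365.0,
    comparator: str = "other_drugs",
) -> list[LabScreenResult]:
    """Functional wrapper around :class:`LabScreen`."""
    return (
        LabScreen(
            ehr,
            catalog,
            drug_codes=drug_codes,
            window_days=window_days,
            comparator=comparator,
        )
        .fit()
        .results
    )
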