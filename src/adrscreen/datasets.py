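"""In-memory containers for the three data sources and their TSV schemas.

Everything is plain UTF-8 tab-separated text with a header row, so datasets
round-trip between the synthetic generators, the screens and user-supplied
files in the same schema.

Schemas
-------
registry (three files in one directory)
    patients.tsv      patient_id, disease, withdrawn
    events.tsv        event_id, patient_id, phase, drug_brand_name, drug_status
    adr_reports.tsv   report_id, event_id, raw_term, relatedness, severity,
                      outcome, is_lab_abnormality
srs
    reports.tsv       report_id, drug_name, event_term   (one row per mention)
ehr laboratory (three files in one directory)
    exposures.tsv         patient_id, disease_code, drug_code, start_day
    measurements.tsv      patient_id, test_id, value, day
    reference_ranges.tsv  test_id, lower_limit, upper_limit
mappings (two files)
    brand_to_generic.tsv  brand_name, generic_name
    term_to_pt.tsv        raw_term, preferred_term
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RegistryDataset",
    "SrsDataset",
    "EhrLabDataset",
    "VocabMappings",
    "VocabularyError",
]

_TSV_KW = dict(sep="\t", index=False)


def _read(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


class VocabularyError(ValueError):
    """A brand name or raw ADR term is not covered by the mapping tables."""

    def __init__(self, kind: str, values: Iterable[str]):
        self.kind = kind
        self.values = sorted(set(values))
        super().__init__(f"unmapped {kind}: {', '.join(map(repr, self.values))}")


@dataclass
class VocabMappings:
    """Brand-name and raw-term normalisation tables.

    ``brand_to_generic`` maps every drug name that may appear in raw data
    (brands and the generics themselves) to a generic name;
    ``raw_to_preferred`` maps every raw ADR term to a preferred term.
    """

    brand_to_generic: dict[str, str]
    raw_to_preferred: dict[str, str]

    def map_drugs(self, names: pd.Series) -> pd.Series:
        mapped = names.map(self.brand_to_generic)
        missing = names[mapped.isna()]
        if len(missing):
            raise VocabularyError("brand name", missing.unique())
        return mapped

    def map_terms(self, terms: pd.Series) -> pd.Series:
        mapped = terms.map(self.raw_to_preferred)
        missing = terms[mapped.isna()]
        if len(missing):
            raise VocabularyError("raw ADR term", missing.unique())
        return mapped

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            sorted(self.brand_to_generic.items()), columns=["brand_name", "generic_name"]
        ).to_csv(directory / "brand_to_generic.tsv", **_TSV_KW)
        pd.DataFrame(
            sorted(self.raw_to_preferred.items()), columns=["raw_term", "preferred_term"]
        ).to_csv(directory / "term_to_pt.tsv", **_TSV_KW)

    @classmethod
    def from_tsv(cls, directory: str | Path) -> "VocabMappings":
        directory = Path(directory)
        brands = _read(directory / "brand_to_generic.tsv")
        terms = _read(directory / "term_to_pt.tsv")
        return cls(
            brand_to_generic=dict(zip(brands["brand_name"], brands["generic_name"])),
            raw_to_preferred=dict(zip(terms["raw_term"], terms["preferred_term"])),
        )


@dataclass
class RegistryDataset:
    """Drug-registry extract: patients, enrollment events and ADR reports."""

    patients: pd.DataFrame
    events: pd.DataFrame
    adr_reports: pd.DataFrame

    PATIENT_COLUMNS = ("patient_id", "disease", "withdrawn")
    EVENT_COLUMNS = ("event_id", "patient_id", "phase", "drug_brand_name", "drug_status")
    REPORT_COLUMNS = (
        "report_id",
        "event_id",
        "raw_term",
        "relatedness",
        "severity",
        "outcome",
        "is_lab_abnormality",
    )

    def __post_init__(self) -> None:
        for frame, cols in (
            (self.patients, self.PATIENT_COLUMNS),
            (self.events, self.EVENT_COLUMNS),
            (self.adr_reports, self.REPORT_COLUMNS),
        ):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"registry frame missing columns {sorted(missing)}")

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(directory / "patients.tsv", **_TSV_KW)
        self.events.to_csv(directory / "events.tsv", **_TSV_KW)
        self.adr_reports.to_csv(directory / "adr_reports.tsv", **_TSV_KW)

    @classmethod
    def from_tsv(cls, directory: str | Path) -> "RegistryDataset":
        directory = Path(directory)
        return cls(
            patients=_read(directory / "patients.tsv"),
            events=_read(directory / "events.tsv"),
            adr_reports=_read(directory / "adr_reports.tsv"),
        )


@dataclass
class SrsDataset:
    """Spontaneous-report extract: one row per (report, drug, event) mention."""

    reports: pd.DataFrame

    COLUMNS = ("report_id", "drug_name", "event_term")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.reports.columns)
        if missing:
            raise ValueError(f"SRS frame missing columns {sorted(missing)}")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.reports.to_csv(path, **_TSV_KW)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SrsDataset":
        return cls(reports=_read(Path(path)))


@dataclass
class EhrLabDataset:
    """EHR-style drug exposures plus laboratory measurements.

    Days are integer offsets from an arbitrary common origin; only their
    ordering and differences matter.
    """

    exposures: pd.DataFrame
    measurements: pd.DataFrame
    reference_ranges: pd.DataFrame

    EXPOSURE_COLUMNS = ("patient_id", "disease_code", "drug_code", "start_day")
    MEASUREMENT_COLUMNS = ("patient_id", "test_id", "value", "day")
    RANGE_COLUMNS = ("test_id", "lower_limit", "upper_limit")

    def __post_init__(self) -> None:
        for frame, cols in (
            (self.exposures, self.EXPOSURE_COLUMNS),
            (self.measurements, self.MEASUREMENT_COLUMNS),
            (self.reference_ranges, self.RANGE_COLUMNS),
        ):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"EHR frame missing columns {sorted(missing)}")
        bad = self.reference_ranges.query("lower_limit >= upper_limit")
        if len(bad):
            raise ValueError(
                f"reference ranges with lower_limit >= upper_limit: {bad['test_id'].tolist()}"
            )

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.exposures.to_csv(directory / "exposures.tsv", **_TSV_KW)
        self.measurements.to_csv(directory / "measurements.tsv", **_TSV_KW)
        self.reference_ranges.to_csv(directory / "reference_ranges.tsv", **_TSV_KW)

    @classmethod
    def from_tsv(cls, directory: str | Path) -> "EhrLabDataset":
        directory = Path(directory)
        return cls(
            exposures=_read(directory / "exposures.tsv"),
            measurements=_read(directory / "measurements.tsv"),
            reference_ranges=_read(directory / "reference_ranges.tsv"),
        )
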