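"""Patient data model and cohort CSV input/output.

The unit of analysis is one man with Grade Group 1 (Gleason 3+3=6) prostate
cancer at radical prostatectomy: his pre-operative serum PSA, anthropometrics
(height in meters, weight in kilograms), the weight of the resected prostate
without seminal vesicles, race/ethnicity, and the pathologically measured
tumor volume (either directly in cm^3 or as a histologic grid count in mm^2).

A single documented CSV schema (SI units) is the interchange format; reading
validates every row against the record invariants, either strictly (any bad
row aborts) or leniently (bad rows are collected with reasons and skipped).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd


class RaceEthnicity(enum.Enum):
    """Combined race/ethnicity analysis group."""

    NHW = "NHW"
    NHB = "NHB"
    HISPANIC_LATINO = "HISPANIC_LATINO"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"

    @property
    def analysis_group(self) -> "RaceEthnicity":
        """UNKNOWN is analyzed inside the OTHER group."""
        return RaceEthnicity.OTHER if self is RaceEthnicity.UNKNOWN else self


class RaceCode(enum.Enum):
    """Registry race code, used by the surname-based ethnicity algorithm."""

    WHITE = "White"
    BLACK = "Black"
    ASIAN = "Asian"
    AMERICAN_INDIAN = "AmericanIndian"
    ALEUTIAN = "Aleutian"
    ESKIMO = "Eskimo"
    FILIPINO = "Filipino"
    PACIFIC_ISLANDER = "PacificIslander"
    HAWAIIAN = "Hawaiian"
    OTHER = "Other"
    UNKNOWN = "Unknown"


class Institution(enum.Enum):
    UM = "UM"
    JHU = "JHU"
    OTHER = "OTHER"


class ValidationError(ValueError):
    """A record violates a documented invariant."""


class SchemaError(ValueError):
    """A cohort file does not match the documented CSV schema."""


#: Documented CSV column order. Height is in meters and weight in kilograms.
CSV_COLUMNS = [
    "id",
    "age",
    "race_ethnicity",
    "race_code",
    "surname",
    "institution",
    "height_m",
    "weight_kg",
    "psa_ng_ml",
    "prostate_weight_g",
    "tumor_grid_mm2",
    "tumor_volume_cm3",
]

_MANDATORY_COLUMNS = [c for c in CSV_COLUMNS if c not in ("surname", "tumor_grid_mm2", "tumor_volume_cm3")]


@dataclass
class PatientRecord:
    """One man's raw clinical and pathology measurements.

    Invariants (checked by :meth:`validate`):

    * ``psa >= 0``, ``prostate_weight > 0``, ``18 <= age <= 100``;
    * ``height`` and ``weight`` are optional (some records lack them, and are
      then excluded from BMI-dependent analyses) but must be positive when
      present;
    * at least one of ``tumor_grid_mm2`` / ``tumor_volume`` is present for a
      record to enter the tumor-volume analyses.
    """

    id: str
    age: float
    race_ethnicity: RaceEthnicity
    race_code: RaceCode
    institution: Institution
    psa: float
    prostate_weight: float
    surname: Optional[str] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    tumor_grid_mm2: Optional[float] = None
    tumor_volume: Optional[float] = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated invariant."""
        if not (18 <= self.age <= 100):
            raise ValidationError(f"record {self.id!r}: age must be in [18, 100], got {self.age}")
        if self.psa is None or math.isnan(self.psa) or self.psa < 0:
            raise ValidationError(f"record {self.id!r}: psa must be >= 0, got {self.psa}")
        if self.prostate_weight is None or not self.prostate_weight > 0:
            raise ValidationError(
                f"record {self.id!r}: prostate_weight must be > 0, got {self.prostate_weight}"
            )
        for name in ("height", "weight"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValidationError(f"record {self.id!r}: {name} must be > 0 when present, got {value}")
        if self.tumor_grid_mm2 is not None and self.tumor_grid_mm2 < 0:
            raise ValidationError(
                f"record {self.id!r}: tumor_grid_mm2 must be >= 0, got {self.tumor_grid_mm2}"
            )
        if self.tumor_volume is not None and self.tumor_volume < 0:
            raise ValidationError(
                f"record {self.id!r}: tumor_volume must be >= 0, got {self.tumor_volume}"
            )

    @property
    def has_body_size(self) -> bool:
        return self.height is not None and self.weight is not None

    @property
    def has_tumor_measure(self) -> bool:
        return self.tumor_grid_mm2 is not None or self.tumor_volume is not None


@dataclass
class Cohort:
    """Ordered collection of validated patient records.

    ``rejected`` holds ``(row_index, reason)`` pairs collected during lenient
    reading; it is empty for cohorts built in memory or read strictly.
    """

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate record id {dup!r} in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame with the documented CSV columns."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "age": r.age,
                    "race_ethnicity": r.race_ethnicity.value,
                    "race_code": r.race_code.value,
                    "surname": r.surname if r.surname is not None else "",
                    "institution": r.institution.value,
                    "height_m": r.height,
                    "weight_kg": r.weight,
                    "psa_ng_ml": r.psa,
                    "prostate_weight_g": r.prostate_weight,
                    "tumor_grid_mm2": r.tumor_grid_mm2,
                    "tumor_volume_cm3": r.tumor_volume,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_optional_float(value, column: str, row_id: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"record {row_id!r}: non-numeric value {value!r} in column {column!r}")


def _record_from_row(row: pd.Series, index: int) -> PatientRecord:
    rid = str(row["id"])
    try:
        race_eth = RaceEthnicity(str(row["race_ethnicity"]))
    except ValueError:
        raise ValidationError(f"record {rid!r}: unknown race_ethnicity {row['race_ethnicity']!r}")
    try:
        race_code = RaceCode(str(row["race_code"]))
    except ValueError:
        raise ValidationError(f"record {rid!r}: unknown race_code {row['race_code']!r}")
    try:
        institution = Institution(str(row["institution"]))
    except ValueError:
        raise ValidationError(f"record {rid!r}: unknown institution {row['institution']!r}")
    surname = row.get("surname")
    if surname is None or (isinstance(surname, float) and math.isnan(surname)) or str(surname) == "":
        surname = None
    else:
        surname = str(surname)
    age = _parse_optional_float(row["age"], "age", rid)
    if age is None:
        raise ValidationError(f"record {rid!r}: age is mandatory")
    psa = _parse_optional_float(row["psa_ng_ml"], "psa_ng_ml", rid)
    if psa is None:
        raise ValidationError(f"record {rid!r}: psa_ng_ml is mandatory")
    pw = _parse_optional_float(row["prostate_weight_g"], "prostate_weight_g", rid)
    if pw is None:
        raise ValidationError(f"record {rid!r}: prostate_weight_g is mandatory")
    record = PatientRecord(
        id=rid,
        age=age,
        race_ethnicity=race_eth,
        race_code=race_code,
        institution=institution,
        surname=surname,
        height=_parse_optional_float(row.get("height_m"), "height_m", rid),
        weight=_parse_optional_float(row.get("weight_kg"), "weight_kg", rid),
        psa=psa,
        prostate_weight=pw,
        tumor_grid_mm2=_parse_optional_float(row.get("tumor_grid_mm2"), "tumor_grid_mm2", rid),
        tumor_volume=_parse_optional_float(row.get("tumor_volume_cm3"), "tumor_volume_cm3", rid),
    )
    record.validate()
    return record


def read_cohort(path: str | Path, strict: bool = True, provenance: str | None = None) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with the documented header (:data:`CSV_COLUMNS`).
    strict
        If True (default), any invalid row raises :class:`ValidationError`.
        If False, invalid rows are skipped and collected in
        ``cohort.rejected`` as ``(row_index, reason)`` pairs.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "surname": str}, float_precision="round_trip")
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}; expected header {CSV_COLUMNS}")
    records: list[PatientRecord] = []
    rejected: list[tuple[int, str]] = []
    for index, row in df.iterrows():
        try:
            records.append(_record_from_row(row, int(index)))
        except ValidationError as err:
            if strict:
                raise
            rejected.append((int(index), str(err)))
    return Cohort(records=records, provenance=provenance or str(path), rejected=rejected)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV so that :func:`read_cohort` recovers it exactly.

    Floats are written with full repr precision, so numeric fields round-trip
    bit-identically.
    """
    for record in cohort.records:
        record.validate()
    cohort.to_frame().to_csv(Path(path), index=False)


def cohort_from_records(records: Iterable[PatientRecord], provenance: str = "") -> Cohort:
    records = list(records)
    for r in records:
        r.validate()
    return Cohort(records=records, provenance=provenance)
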