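"""Surname-based Hispanic ethnicity assignment (NHIA-style).

The NAACCR Hispanic Identification Algorithm classifies surnames into five
tiers — heavily, generally, moderately, occasionally, or rarely Hispanic —
against the 1990 U.S. Census Spanish Surname List.  Only surnames in the
*heavily* tier are coded Hispanic; every other surname (including those
absent from the list) is coded Non-Hispanic.  Race information then removes
candidates who identify as Asian, American Indian, Aleutian, Eskimo,
Filipino, Pacific Islander, or Hawaiian, since Spanish surnames in those
groups are usually not of Hispanic ethnicity.

The real census list is not redistributable here; a small synthetic table
spanning all five tiers ships with the package for testing, and
:func:`load_surname_table` accepts any user-supplied two-column file
(SURNAME<TAB>CATEGORY, one per line).
"""

from __future__ import annotations

import enum
import logging
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .cohort import PatientRecord, RaceCode

logger = logging.getLogger(__name__)


class SurnameCategory(enum.Enum):
    HEAVILY = "HEAVILY"
    GENERALLY = "GENERALLY"
    MODERATELY = "MODERATELY"
    OCCASIONALLY = "OCCASIONALLY"
    RARELY = "RARELY"


class NhiaEthnicity(enum.Enum):
    HISPANIC = "HISPANIC"
    NON_HISPANIC = "NON_HISPANIC"


#: Race codes whose Spanish-surname carriers are excluded from Hispanic coding.
EXCLUDED_RACE_CODES = frozenset(
    {
        RaceCode.ASIAN,
        RaceCode.AMERICAN_INDIAN,
        RaceCode.ALEUTIAN,
        RaceCode.ESKIMO,
        RaceCode.FILIPINO,
        RaceCode.PACIFIC_ISLANDER,
        RaceCode.HAWAIIAN,
    }
)


@dataclass(frozen=True)
class SurnameTable:
    """Uppercase surname -> tier mapping."""

    entries: dict[str, SurnameCategory]

    def lookup(self, surname: str) -> Optional[SurnameCategory]:
        return self.entries.get(normalize_surname(surname))


def normalize_surname(raw: str) -> str:
    """Uppercase, strip accents and surrounding whitespace.

    Internal hyphens and spaces are preserved; compound surnames are matched
    as whole strings, never token-wise.
    """
    if raw is None or raw.strip() == "":
        raise ValueError("surname must be a non-empty string")
    decomposed = unicodedata.normalize("NFKD", raw.strip())
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return stripped.upper()


def load_surname_table(path: str | Path | None = None) -> SurnameTable:
    """Load a surname table (tab- or comma-delimited SURNAME, CATEGORY).

    Without a path, the shipped synthetic test table is loaded.  Lines
    starting with ``#`` are comments.  Duplicate surnames (after
    normalization) are an error.
    """
    if path is None:
        text = resources.files("psakit.data").joinpath("synthetic_surname_table.tsv").read_text()
    else:
        text = Path(path).read_text()
    entries: dict[str, SurnameCategory] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'SURNAME<TAB>CATEGORY', got {line!r}")
        name = normalize_surname(parts[0])
        try:
            category = SurnameCategory(parts[1].strip().upper())
        except ValueError:
            raise ValueError(
                f"line {lineno}: unknown category {parts[1]!r}; "
                f"valid: {[c.value for c in SurnameCategory]}"
            )
        if name in entries:
            raise ValueError(f"line {lineno}: duplicate surname {name!r} after normalization")
        entries[name] = category
    return SurnameTable(entries=entries)


def classify_surname(surname: str, table: SurnameTable) -> Optional[SurnameCategory]:
    """Tier of a surname, or ``None`` when absent from the table."""
    return table.lookup(surname)


def assign_ethnicity(record: PatientRecord, table: SurnameTable) -> NhiaEthnicity:
    """HISPANIC iff the surname is *heavily* Hispanic and the race code is not
    in the exclusion set; all other cases are NON_HISPANIC.

    A missing surname yields NON_HISPANIC with a logged warning (the
    conservative choice; the algorithm cannot run without a surname).
    """
    if record.surname is None:
        logger.warning("record %r has no surname; coding NON_HISPANIC", record.id)
        return NhiaEthnicity.NON_HISPANIC
    category = classify_surname(record.surname, table)
    if category is SurnameCategory.HEAVILY and record.race_code not in EXCLUDED_RACE_CODES:
        return NhiaEthnicity.HISPANIC
    return NhiaEthnicity.NON_HISPANIC


def annotate_cohort(df, table: SurnameTable):
    """Add an ``ethnicity_nhia`` column to a cohort DataFrame."""
    out = df.copy()
    labels = []
    for _, row in out.iterrows():
        surname = row.get("surname")
        if surname is None or str(surname) == "" or str(surname) == "nan":
            labels.append(NhiaEthnicity.NON_HISPANIC.value)
            continue
        category = classify_surname(str(surname), table)
        try:
            race = RaceCode(str(row["race_code"]))
        except ValueError:
            race = RaceCode.UNKNOWN
        hispanic = category is SurnameCategory.HEAVILY and race not in EXCLUDED_RACE_CODES
        labels.append(NhiaEthnicity.HISPANIC.value if hispanic else NhiaEthnicity.NON_HISPANIC.value)
    out["ethnicity_nhia"] = labels
    return out
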