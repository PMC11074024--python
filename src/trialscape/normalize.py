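"""Raw-record normalization: singleton flattening, age/date/sex transformers,
term dictionaries and typed study records."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, model_validator

from .errors import FieldParseError, ShapeError
from .ingest import NCT_ID_RE, RawStudyRecord, Snapshot

ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

CONDITIONS_FIELD = "Conditions"
COUNTRY_FIELD = "LocationCountry"


class Sex(str, Enum):
    all = "all"
    female = "female"
    male = "male"
    unknown = "unknown"


def flatten_singleton(values: Sequence[str], field_name: str = "value") -> str | None:
    """Collapse the registry's one-element list wrapping to a scalar.

    Empty list means the value is absent; two or more elements in a
    declared-singleton field is a shape error.
    """
    if len(values) == 0:
        return None
    if len(values) > 1:
        raise ShapeError(
            f"field {field_name!r} expected at most one value, got {len(values)}"
        )
    return values[0]


# Unit divisors to express any eligibility-age unit in years. The registry
# documents months ("6 Months") next to years; weeks/days occur in the wild.
_AGE_UNITS = (("month", 12.0), ("year", 1.0), ("week", 52.0), ("day", 365.0))


def transform_age(values: Sequence[str], field_name: str = "age") -> float | None:
    """Normalize an eligibility-age string list to decimal years.

    The number is obtained by deleting every non-digit character, so
    ``"11 Years"`` and ``"11years"`` behave identically; month values are
    divided by 12 (weeks by 52, days by 365).
    """
    raw = flatten_singleton(values, field_name)
    if raw is None:
        return None
    lowered = raw.lower()
    digits = re.sub(r"\D", "", lowered)
    if not digits:
        raise FieldParseError(f"no digits in age string {raw!r}", raw=raw)
    number = float(digits)
    for unit, divisor in _AGE_UNITS:
        if unit in lowered:
            return number / divisor
    raise FieldParseError(f"unrecognized age unit in {raw!r}", raw=raw)


_DATE_FORMATS = ("%B %d, %Y", "%b %d, %Y")
_MONTH_YEAR_FORMATS = ("%B %Y", "%b %Y")


def transform_date(values: Sequence[str], field_name: str = "date") -> str | None:
    """Normalize a registry date to ``YYYY-MM-DD``.

    Accepts the two registry dialects "Month D, YYYY" and "Month YYYY"; when
    the day is missing it is set to the first of the month.
    """
    raw = flatten_singleton(values, field_name)
    if raw is None:
        return None
    text = raw.strip()
    for fmt in _DATE_FORMATS:
        try:
            return datetime.strptime(text, fmt).strftime("%Y-%m-%d")
        except ValueError:
            pass
    for fmt in _MONTH_YEAR_FORMATS:
        try:
            return datetime.strptime(text, fmt).strftime("%Y-%m-01")
        except ValueError:
            pass
    raise FieldParseError(f"unparseable date string {raw!r}", raw=raw)


def transform_sex(values: Sequence[str], field_name: str = "sex") -> Sex:
    raw = flatten_singleton(values, field_name)
    if raw is None:
        return Sex.unknown
    try:
        return Sex(raw.strip().lower())
    except ValueError:
        return Sex.unknown


@dataclass
class TermDictionary:
    """Ordered term → ID mapping; IDs are 1..K in first-occurrence order."""

    kind: str
    entries: dict[str, int] = field(default_factory=dict)

    def add(self, term: str) -> int:
        if term not in self.entries:
            self.entries[term] = len(self.entries) + 1
        return self.entries[term]

    def id_for(self, term: str) -> int:
        return self.entries[term]

    def term_for(self, term_id: int) -> str:
        for term, tid in self.entries.items():
            if tid == term_id:
                return term
        raise KeyError(term_id)

    def __len__(self) -> int:
        return len(self.entries)


def build_term_dictionary(records: Iterable[RawStudyRecord], field_name: str) -> TermDictionary:
    """Scan a list-valued field for unique values in record-stream order."""
    kind = "country" if field_name == COUNTRY_FIELD else "condition"
    dictionary = TermDictionary(kind=kind)
    for record in records:
        for term in record.get(field_name):
            dictionary.add(term)
    return dictionary


class StudyRecord(BaseModel):
    """A normalized trial with scalar typed fields and term-ID references.

    ``country_ids`` preserves one entry per location (duplicates included);
    the once-per-study country rule is applied by the analytics layer.
    """

    nct_id: str = Field(pattern=r"^NCT\d{8}$")
    brief_title: str | None = None
    official_title: str | None = None
    brief_summary: str | None = None
    sex: Sex = Sex.unknown
    min_age_years: float | None = Field(default=None, ge=0)
    max_age_years: float | None = Field(default=None, ge=0)
    overall_status: str = ""
    start_date: str | None = None
    completion_date: str | None = None
    first_posted_date: str | None = None
    last_update_date: str | None = None
    condition_ids: list[int] = Field(default_factory=list)
    country_ids: list[int] = Field(default_factory=list)
    intervention_names: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "StudyRecord":
        if (
            self.min_age_years is not None
            and self.max_age_years is not None
            and self.min_age_years > self.max_age_years
        ):
            raise ValueError(
                f"min_age_years {self.min_age_years} > max_age_years {self.max_age_years}"
            )
        for name in ("start_date", "completion_date", "first_posted_date", "last_update_date"):
            value = getattr(self, name)
            if value is None:
                continue
            if not ISO_DATE_RE.match(value):
                raise ValueError(f"{name} {value!r} is not YYYY-MM-DD")
            datetime.strptime(value, "%Y-%m-%d")  # valid calendar date
        return self


@dataclass
class SkippedRecord:
    rank: int
    nct_id: str | None
    reason: str


@dataclass
class ProcessResult:
    records: list[StudyRecord]
    conditions: TermDictionary
    countries: TermDictionary
    skipped: list[SkippedRecord] = field(default_factory=list)


def _normalize_record(
    raw: RawStudyRecord, conditions: TermDictionary, countries: TermDictionary
) -> StudyRecord:
    nct_id = flatten_singleton(raw.get("NCTId"), "NCTId")
    if nct_id is None or not NCT_ID_RE.match(nct_id):
        raise FieldParseError(f"missing or malformed NCTId {nct_id!r}")
    return StudyRecord(
        nct_id=nct_id,
        brief_title=flatten_singleton(raw.get("BriefTitle"), "BriefTitle"),
        official_title=flatten_singleton(raw.get("OfficialTitle"), "OfficialTitle"),
        brief_summary=flatten_singleton(raw.get("BriefSummary"), "BriefSummary"),
        sex=transform_sex(raw.get("Gender"), "Gender"),
        min_age_years=transform_age(raw.get("MinimumAge"), "MinimumAge"),
        max_age_years=transform_age(raw.get("MaximumAge"), "MaximumAge"),
        overall_status=flatten_singleton(raw.get("OverallStatus"), "OverallStatus") or "",
        start_date=transform_date(raw.get("StartDate"), "StartDate"),
        completion_date=transform_date(raw.get("CompletionDate"), "CompletionDate"),
        first_posted_date=transform_date(raw.get("StudyFirstPostDate"), "StudyFirstPostDate"),
        last_update_date=transform_date(raw.get("LastUpdatePostDate"), "LastUpdatePostDate"),
        condition_ids=[conditions.add(t) for t in raw.get(CONDITIONS_FIELD)],
        country_ids=[countries.add(t) for t in raw.get(COUNTRY_FIELD)],
        intervention_names=list(raw.get("InterventionName")),
    )


def process_snapshot(snapshot: Snapshot) -> ProcessResult:
    """Normalize every raw record; per-record failures are reported, not fatal.

    Deterministic: term IDs follow snapshot rank order, so re-running on the
    same snapshot yields identical output.
    """
    conditions = TermDictionary(kind="condition")
    countries = TermDictionary(kind="country")
    records: list[StudyRecord] = []
    skipped: list[SkippedRecord] = []
    for raw in snapshot.records:
        try:
            records.append(_normalize_record(raw, conditions, countries))
        except (ValueError, ShapeError) as exc:
            skipped.append(SkippedRecord(rank=raw.rank, nct_id=raw.nct_id, reason=str(exc)))
    return ProcessResult(records=records, conditions=conditions, countries=countries, skipped=skipped)
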