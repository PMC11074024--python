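"""Query construction, paged retrieval and snapshot persistence.

The classic registry ``study_fields`` endpoint returns JSON envelopes of the
form::

    {"StudyFieldsResponse": {"NRecordsFound": <int>,
                             "StudyFields": [{"Rank": 1, "NCTId": [...], ...}]}}

Snapshot files on disk reuse the same envelope (plus ``Expression`` and
``RetrievedAt`` stamps) so offline fixtures and live pulls share one parser.
"""

from __future__ import annotations

import json
import re
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from pydantic import BaseModel, Field, field_validator

from .errors import ContractError, FormatError, RetrievalError

NCT_ID_RE = re.compile(r"^NCT\d{8}$")

#: Fields harvested by default: the registry basics plus the extra columns the
#: downstream analytics need (first-posted date, locations, interventions).
DEFAULT_FIELDS: tuple[str, ...] = (
    "NCTId",
    "OfficialTitle",
    "BriefTitle",
    "BriefSummary",
    "Conditions",
    "Gender",
    "MaximumAge",
    "MinimumAge",
    "OverallStatus",
    "StartDate",
    "CompletionDate",
    "LastUpdatePostDate",
    "StudyFirstPostDate",
    "LocationCountry",
    "LocationFacility",
    "InterventionName",
)

CLASSIC_API_BASE = "https://classic.clinicaltrials.gov/api/query/study_fields"


class QueryConfig(BaseModel):
    """Configuration of one harvest run."""

    drug_terms: list[str]
    fields: list[str] = Field(default_factory=lambda: list(DEFAULT_FIELDS))
    page_size: int = Field(default=1000, ge=1, le=1000)
    api_base: str = CLASSIC_API_BASE
    offline_path: Path | None = None
    min_request_delay: float = Field(default=0.5, ge=0.0)

    @field_validator("drug_terms")
    @classmethod
    def _terms_non_blank(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("drug_terms must be non-empty")
        if any(not t.strip() for t in v):
            raise ValueError("drug_terms must not contain blank terms")
        return v

    @field_validator("fields")
    @classmethod
    def _fields_include_nctid(cls, v: list[str]) -> list[str]:
        if "NCTId" not in v:
            raise ValueError('field list must contain "NCTId"')
        return v


class RawStudyRecord(BaseModel):
    """One ``StudyFields`` entry: every field maps to a list of strings."""

    rank: int = Field(ge=1)
    values: dict[str, list[str]]

    def get(self, field_name: str) -> list[str]:
        return self.values.get(field_name, [])

    @property
    def nct_id(self) -> str | None:
        ids = self.get("NCTId")
        if len(ids) == 1 and NCT_ID_RE.match(ids[0]):
            return ids[0]
        return None


class Snapshot(BaseModel):
    """A dated, query-stamped capture of raw records; the unit of provenance."""

    retrieved_at: str = ""
    query_expression: str = ""
    n_records_found: int = Field(default=0, ge=0)
    records: list[RawStudyRecord] = Field(default_factory=list)

    def nct_ids(self) -> list[str]:
        return [r.nct_id for r in self.records if r.nct_id is not None]


@dataclass
class FetchResult:
    """Outcome of :func:`fetch_all`: the snapshot plus per-record skips."""

    snapshot: Snapshot
    skipped: list[tuple[int, str]] = field(default_factory=list)  # (rank, reason)


def build_query(drug_terms: Sequence[str]) -> str:
    """Join drug terms into the registry search expression ``a OR b OR c``."""
    if not drug_terms:
        raise ContractError("drug_terms must be non-empty")
    terms = [t.strip() for t in drug_terms]
    if any(not t for t in terms):
        raise ContractError("drug_terms must not contain blank terms")
    return " OR ".join(terms)


# A transport fetches one rank window and returns the parsed JSON envelope.
Transport = Callable[[str, Sequence[str], int, int], Mapping]


def http_transport(api_base: str) -> Transport:
    """Live transport against the classic study_fields endpoint."""

    def fetch(expr: str, fields: Sequence[str], min_rank: int, max_rank: int) -> Mapping:
        params = urllib.parse.urlencode(
            {
                "expr": expr,
                "fields": ",".join(fields),
                "min_rnk": min_rank,
                "max_rnk": max_rank,
                "fmt": "json",
            }
        )
        with urllib.request.urlopen(f"{api_base}?{params}", timeout=60) as resp:
            return json.loads(resp.read().decode("utf-8"))

    return fetch


def offline_transport(path: str | Path) -> Transport:
    """Serve rank windows out of a saved snapshot file."""
    snapshot = load_snapshot(path)

    def fetch(expr: str, fields: Sequence[str], min_rank: int, max_rank: int) -> Mapping:
        page = [
            {"Rank": r.rank, **r.values}
            for r in snapshot.records
            if min_rank <= r.rank <= max_rank
        ]
        return {
            "StudyFieldsResponse": {
                "NRecordsFound": snapshot.n_records_found,
                "StudyFields": page,
            }
        }

    return fetch


def _parse_page(payload: Mapping, window: tuple[int, int]) -> tuple[int, list[dict]]:
    try:
        envelope = payload["StudyFieldsResponse"]
        n_found = int(envelope["NRecordsFound"])
        entries = envelope["StudyFields"]
    except (KeyError, TypeError, ValueError) as exc:
        raise RetrievalError(
            f"malformed response for rank window {window[0]}-{window[1]}: {exc!r}"
        ) from exc
    return n_found, list(entries)


def fetch_all(
    config: QueryConfig,
    transport: Transport | None = None,
    sleep: Callable[[float], None] = time.sleep,
) -> FetchResult:
    """Page through the endpoint in contiguous rank windows and deduplicate.

    Records whose NCTId is missing or malformed are skipped and reported in
    ``FetchResult.skipped``; duplicate NCTIds keep the first occurrence.
    """
    if transport is None:
        if config.offline_path is not None:
            transport = offline_transport(config.offline_path)
        else:
            transport = http_transport(config.api_base)

    expr = build_query(config.drug_terms)
    records: list[RawStudyRecord] = []
    skipped: list[tuple[int, str]] = []
    seen: set[str] = set()

    min_rank = 1
    n_found: int | None = None
    first = True
    while n_found is None or min_rank <= n_found:
        max_rank = min_rank + config.page_size - 1
        if not first and config.min_request_delay > 0:
            sleep(config.min_request_delay)
        first = False
        try:
            payload = transport(expr, config.fields, min_rank, max_rank)
        except RetrievalError:
            raise
        except Exception as exc:  # network / decode failure
            raise RetrievalError(
                f"request failed for rank window {min_rank}-{max_rank}: {exc}"
            ) from exc
        n_found, entries = _parse_page(payload, (min_rank, max_rank))
        for entry in entries:
            rank = int(entry.get("Rank", 0))
            values = {k: list(v) for k, v in entry.items() if k != "Rank"}
            record = RawStudyRecord(rank=rank if rank >= 1 else min_rank, values=values)
            if record.nct_id is None:
                skipped.append((record.rank, "missing or malformed NCTId"))
                continue
            if record.nct_id in seen:
                continue
            seen.add(record.nct_id)
            records.append(record)
        min_rank = max_rank + 1

    snapshot = Snapshot(
        retrieved_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        query_expression=expr,
        n_records_found=n_found or 0,
        records=records,
    )
    return FetchResult(snapshot=snapshot, skipped=skipped)


def save_snapshot(snapshot: Snapshot, path: str | Path) -> None:
    """Write a snapshot to disk in the study_fields envelope dialect."""
    payload = {
        "StudyFieldsResponse": {
            "Expression": snapshot.query_expression,
            "RetrievedAt": snapshot.retrieved_at,
            "NRecordsFound": snapshot.n_records_found,
            "StudyFields": [{"Rank": r.rank, **r.values} for r in snapshot.records],
        }
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_snapshot(path: str | Path) -> Snapshot:
    """Read a snapshot file; raises :class:`FormatError` naming missing keys."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"snapshot file {path} is not valid JSON: {exc}") from exc
    if "StudyFieldsResponse" not in payload:
        raise FormatError('snapshot file missing "StudyFieldsResponse" envelope')
    envelope = payload["StudyFieldsResponse"]
    for key in ("NRecordsFound", "StudyFields"):
        if key not in envelope:
            raise FormatError(f'snapshot envelope missing "{key}" key')
    records = [
        RawStudyRecord(
            rank=int(entry.get("Rank", i + 1)),
            values={k: list(v) for k, v in entry.items() if k != "Rank"},
        )
        for i, entry in enumerate(envelope["StudyFields"])
    ]
    return Snapshot(
        retrieved_at=envelope.get("RetrievedAt", ""),
        query_expression=envelope.get("Expression", ""),
        n_records_found=int(envelope["NRecordsFound"]),
        records=records,
    )
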