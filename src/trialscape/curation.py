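"""Single source of truth: an embedded SQLite store for normalized trials,
term dictionaries and manual curation annotations.

The schema mirrors the relational shape of the original pipeline — trials,
terms, trial–term links, annotations — without requiring a database server.
Backups are plain SQL dumps (schema + rows) so a store can be recreated from
one text file.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import BackupError, ContractError, FormatError, NotFoundError
from .ingest import Snapshot
from .normalize import Sex, StudyRecord, TermDictionary


class DrugRole(str, Enum):
    """Curator-assigned role of the drug of interest within a trial."""

    combination = "combination"
    comparison = "comparison"
    control = "control"
    main = "main"
    minimal = "minimal"
    not_included = "not_included"
    premedication = "premedication"
    rescue_medication = "rescue_medication"


class PublicationStatus(str, Enum):
    paper = "paper"
    registry_results = "registry_results"
    none = "none"


class Annotation(BaseModel):
    """Manual curation payload for one trial."""

    nct_id: str = Field(pattern=r"^NCT\d{8}$")
    primary_drug: str = ""
    additional_drugs: list[str] = Field(default_factory=list)
    legacy_search_term: str | None = None
    use_case: str = ""
    drug_role: DrugRole
    repurposing: bool = False
    publication_status: PublicationStatus = PublicationStatus.none
    publication_ref: str | None = None
    notes: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "Annotation":
        if self.publication_status == PublicationStatus.paper and not self.publication_ref:
            raise ValueError("publication_status=paper requires publication_ref")
        if self.primary_drug and self.primary_drug in self.additional_drugs:
            raise ValueError("primary_drug must not appear in additional_drugs")
        if not self.primary_drug and self.drug_role != DrugRole.not_included:
            raise ValueError("primary_drug required unless drug_role is not_included")
        return self


@dataclass
class UpdateReport:
    """Diff of two snapshots: added / changed / withdrawn trial IDs."""

    new_ids: list[str] = field(default_factory=list)
    updated_ids: list[str] = field(default_factory=list)
    removed_ids: list[str] = field(default_factory=list)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS trials (
    nct_id TEXT PRIMARY KEY,
    brief_title TEXT, official_title TEXT, brief_summary TEXT,
    sex TEXT NOT NULL, min_age_years REAL, max_age_years REAL,
    overall_status TEXT NOT NULL,
    start_date TEXT, completion_date TEXT, first_posted_date TEXT, last_update_date TEXT,
    intervention_names TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS terms (
    kind TEXT NOT NULL, term_id INTEGER NOT NULL, term TEXT NOT NULL,
    PRIMARY KEY (kind, term_id)
);
CREATE TABLE IF NOT EXISTS trial_terms (
    nct_id TEXT NOT NULL REFERENCES trials(nct_id),
    kind TEXT NOT NULL, term_id INTEGER NOT NULL, position INTEGER NOT NULL,
    PRIMARY KEY (nct_id, kind, position)
);
CREATE TABLE IF NOT EXISTS annotations (
    nct_id TEXT PRIMARY KEY REFERENCES trials(nct_id),
    primary_drug TEXT NOT NULL, additional_drugs TEXT NOT NULL,
    legacy_search_term TEXT, use_case TEXT NOT NULL, drug_role TEXT NOT NULL,
    repurposing INTEGER NOT NULL, publication_status TEXT NOT NULL,
    publication_ref TEXT, notes TEXT
);
"""

ANNOTATION_CSV_HEADER = [
    "nct_id",
    "primary_drug",
    "additional_drugs",
    "legacy_search_term",
    "use_case",
    "drug_role",
    "repurposing",
    "publication_status",
    "publication_ref",
    "notes",
]


class CurationStore:
    """Wrapper around a SQLite database file (or ``:memory:``)."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.row_factory = sqlite3.Row
        self._conn.executescript(_SCHEMA)

    def close(self) -> None:
        self._conn.close()

    # -- trials ------------------------------------------------------------

    def upsert_records(self, records: Iterable[StudyRecord]) -> None:
        """Idempotent upsert keyed on nct_id; last write wins."""
        cur = self._conn.cursor()
        for r in records:
            cur.execute(
                """INSERT INTO trials VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)
                   ON CONFLICT(nct_id) DO UPDATE SET
                     brief_title=excluded.brief_title,
                     official_title=excluded.official_title,
                     brief_summary=excluded.brief_summary,
                     sex=excluded.sex,
                     min_age_years=excluded.min_age_years,
                     max_age_years=excluded.max_age_years,
                     overall_status=excluded.overall_status,
                     start_date=excluded.start_date,
                     completion_date=excluded.completion_date,
                     first_posted_date=excluded.first_posted_date,
                     last_update_date=excluded.last_update_date,
                     intervention_names=excluded.intervention_names""",
                (
                    r.nct_id, r.brief_title, r.official_title, r.brief_summary,
                    r.sex.value, r.min_age_years, r.max_age_years, r.overall_status,
                    r.start_date, r.completion_date, r.first_posted_date,
                    r.last_update_date, json.dumps(r.intervention_names),
                ),
            )
            cur.execute("DELETE FROM trial_terms WHERE nct_id=?", (r.nct_id,))
            for kind, ids in (("condition", r.condition_ids), ("country", r.country_ids)):
                for pos, term_id in enumerate(ids):
                    cur.execute(
                        "INSERT INTO trial_terms VALUES (?,?,?,?)",
                        (r.nct_id, kind, term_id, pos),
                    )
        self._conn.commit()

    def upsert_terms(self, dictionary: TermDictionary) -> None:
        cur = self._conn.cursor()
        for term, term_id in dictionary.entries.items():
            cur.execute(
                "INSERT OR REPLACE INTO terms VALUES (?,?,?)",
                (dictionary.kind, term_id, term),
            )
        self._conn.commit()

    def term_dictionary(self, kind: str) -> TermDictionary:
        rows = self._conn.execute(
            "SELECT term, term_id FROM terms WHERE kind=? ORDER BY term_id", (kind,)
        ).fetchall()
        return TermDictionary(kind=kind, entries={r["term"]: r["term_id"] for r in rows})

    def _row_to_record(self, row: sqlite3.Row) -> StudyRecord:
        links = self._conn.execute(
            "SELECT kind, term_id FROM trial_terms WHERE nct_id=? ORDER BY kind, position",
            (row["nct_id"],),
        ).fetchall()
        return StudyRecord(
            nct_id=row["nct_id"],
            brief_title=row["brief_title"],
            official_title=row["official_title"],
            brief_summary=row["brief_summary"],
            sex=Sex(row["sex"]),
            min_age_years=row["min_age_years"],
            max_age_years=row["max_age_years"],
            overall_status=row["overall_status"],
            start_date=row["start_date"],
            completion_date=row["completion_date"],
            first_posted_date=row["first_posted_date"],
            last_update_date=row["last_update_date"],
            condition_ids=[l["term_id"] for l in links if l["kind"] == "condition"],
            country_ids=[l["term_id"] for l in links if l["kind"] == "country"],
            intervention_names=json.loads(row["intervention_names"]),
        )

    def get_record(self, nct_id: str) -> StudyRecord:
        row = self._conn.execute(
            "SELECT * FROM trials WHERE nct_id=?", (nct_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no trial {nct_id} in store")
        return self._row_to_record(row)

    def records(self) -> list[StudyRecord]:
        rows = self._conn.execute("SELECT * FROM trials ORDER BY nct_id").fetchall()
        return [self._row_to_record(r) for r in rows]

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM trials").fetchone()[0]

    # -- annotations -------------------------------------------------------

    def set_annotation(self, annotation: Annotation, drug_terms: Sequence[str] | None = None) -> None:
        """Replace any prior annotation for the trial.

        When ``drug_terms`` is given, ``primary_drug`` must be one of them
        unless the role is ``not_included``.
        """
        if (
            drug_terms is not None
            and annotation.drug_role != DrugRole.not_included
            and annotation.primary_drug not in drug_terms
        ):
            raise ContractError(
                f"primary_drug {annotation.primary_drug!r} not in configured drug_terms"
            )
        exists = self._conn.execute(
            "SELECT 1 FROM trials WHERE nct_id=?", (annotation.nct_id,)
        ).fetchone()
        if exists is None:
            raise NotFoundError(f"no trial {annotation.nct_id} in store")
        self._conn.execute(
            "INSERT OR REPLACE INTO annotations VALUES (?,?,?,?,?,?,?,?,?,?)",
            (
                annotation.nct_id,
                annotation.primary_drug,
                json.dumps(annotation.additional_drugs),
                annotation.legacy_search_term,
                annotation.use_case,
                annotation.drug_role.value,
                int(annotation.repurposing),
                annotation.publication_status.value,
                annotation.publication_ref,
                annotation.notes,
            ),
        )
        self._conn.commit()

    def get_annotation(self, nct_id: str) -> Annotation:
        row = self._conn.execute(
            "SELECT * FROM annotations WHERE nct_id=?", (nct_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no annotation for {nct_id}")
        return self._row_to_annotation(row)

    @staticmethod
    def _row_to_annotation(row: sqlite3.Row) -> Annotation:
        return Annotation(
            nct_id=row["nct_id"],
            primary_drug=row["primary_drug"],
            additional_drugs=json.loads(row["additional_drugs"]),
            legacy_search_term=row["legacy_search_term"],
            use_case=row["use_case"],
            drug_role=DrugRole(row["drug_role"]),
            repurposing=bool(row["repurposing"]),
            publication_status=PublicationStatus(row["publication_status"]),
            publication_ref=row["publication_ref"],
            notes=row["notes"],
        )

    def annotations(self) -> list[Annotation]:
        rows = self._conn.execute("SELECT * FROM annotations ORDER BY nct_id").fetchall()
        return [self._row_to_annotation(r) for r in rows]

    def annotated_pairs(self) -> list[tuple[StudyRecord, Annotation]]:
        """All (record, annotation) pairs, ordered by nct_id."""
        return [(self.get_record(a.nct_id), a) for a in self.annotations()]

    # -- CSV round-trip ----------------------------------------------------

    def export_annotations_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(ANNOTATION_CSV_HEADER)
            for a in self.annotations():
                writer.writerow(
                    [
                        a.nct_id,
                        a.primary_drug,
                        ";".join(a.additional_drugs),
                        a.legacy_search_term or "",
                        a.use_case,
                        a.drug_role.value,
                        "true" if a.repurposing else "false",
                        a.publication_status.value,
                        a.publication_ref or "",
                        a.notes or "",
                    ]
                )

    def import_annotations_csv(
        self, path: str | Path, drug_terms: Sequence[str] | None = None
    ) -> int:
        """Validate every row, then commit all-or-nothing. Returns row count."""
        annotations: list[Annotation] = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != ANNOTATION_CSV_HEADER:
                raise FormatError(
                    f"annotation CSV header mismatch: {reader.fieldnames}"
                )
            for line_no, row in enumerate(reader, start=2):
                try:
                    annotations.append(_annotation_from_csv_row(row))
                except (ValidationError, ValueError) as exc:
                    raise FormatError(f"row {line_no}: {exc}") from exc
        for line_no, a in enumerate(annotations, start=2):
            exists = self._conn.execute(
                "SELECT 1 FROM trials WHERE nct_id=?", (a.nct_id,)
            ).fetchone()
            if exists is None:
                raise FormatError(f"row {line_no}: no trial {a.nct_id} in store")
            if (
                drug_terms is not None
                and a.drug_role != DrugRole.not_included
                and a.primary_drug not in drug_terms
            ):
                raise FormatError(
                    f"row {line_no}: primary_drug {a.primary_drug!r} not in drug_terms"
                )
        for a in annotations:
            self.set_annotation(a, drug_terms=None)
        return len(annotations)

    # -- backup ------------------------------------------------------------

    def dump_backup(self, path: str | Path) -> None:
        """Write a plain-SQL dump (schema + rows) recreating the whole store."""
        Path(path).write_text("\n".join(self._conn.iterdump()) + "\n", encoding="utf-8")


def _normalize_enum_token(value: str) -> str:
    return value.strip().lower().replace(" ", "_").replace("-", "_")


def _annotation_from_csv_row(row: dict) -> Annotation:
    repurposing_token = _normalize_enum_token(row.get("repurposing") or "false")
    if repurposing_token not in ("true", "false"):
        raise ValueError(f"repurposing must be true/false, got {row['repurposing']!r}")
    return Annotation(
        nct_id=(row.get("nct_id") or "").strip(),
        primary_drug=(row.get("primary_drug") or "").strip(),
        additional_drugs=[
            d.strip() for d in (row.get("additional_drugs") or "").split(";") if d.strip()
        ],
        legacy_search_term=(row.get("legacy_search_term") or "").strip() or None,
        use_case=(row.get("use_case") or "").strip(),
        drug_role=DrugRole(_normalize_enum_token(row.get("drug_role") or "")),
        repurposing=repurposing_token == "true",
        publication_status=PublicationStatus(
            _normalize_enum_token(row.get("publication_status") or "none")
        ),
        publication_ref=(row.get("publication_ref") or "").strip() or None,
        notes=(row.get("notes") or "").strip() or None,
    )


def restore_backup(path: str | Path, store_path: str | Path = ":memory:") -> CurationStore:
    """Recreate a store from a SQL dump; the dump file is validated first."""
    try:
        script = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise BackupError(f"cannot read backup {path}: {exc}") from exc
    conn = sqlite3.connect(":memory:")
    try:
        conn.executescript(script)
        for table in ("trials", "terms", "trial_terms", "annotations"):
            conn.execute(f"SELECT COUNT(*) FROM {table}")
    except sqlite3.Error as exc:
        raise BackupError(f"backup {path} is not a valid store dump: {exc}") from exc
    finally:
        conn.close()
    store = CurationStore(store_path)
    store._conn.executescript("DROP TABLE annotations; DROP TABLE trial_terms; DROP TABLE terms; DROP TABLE trials;")
    store._conn.executescript(script)
    store._conn.commit()
    return store


def detect_updates(old: Snapshot, new: Snapshot) -> UpdateReport:
    """Diff two snapshots on NCTId and the raw LastUpdatePostDate string."""

    def index(s: Snapshot) -> dict[str, str]:
        out: dict[str, str] = {}
        for r in s.records:
            if r.nct_id is not None and r.nct_id not in out:
                out[r.nct_id] = "|".join(r.get("LastUpdatePostDate"))
        return out

    old_idx, new_idx = index(old), index(new)
    return UpdateReport(
        new_ids=sorted(set(new_idx) - set(old_idx)),
        removed_ids=sorted(set(old_idx) - set(new_idx)),
        updated_ids=sorted(
            i for i in set(old_idx) & set(new_idx) if old_idx[i] != new_idx[i]
        ),
    )
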