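"""Landscape analytics over the curated store.

Each routine returns a long-format :class:`SummaryTable` (group-key columns
plus one value column) together with a tally of the records it excluded and
why — nothing is silently dropped. Unless noted otherwise, routines operate
on the relevance-filtered set: annotated trials whose drug role is not one of
``minimal`` / ``not_included`` / ``rescue_medication``.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .curation import Annotation, CurationStore, DrugRole, PublicationStatus
from .errors import ContractError
from .normalize import StudyRecord

#: Roles excluded from every analysis except the all-roles drug overview.
EXCLUDED_ROLES = frozenset(
    {DrugRole.minimal, DrugRole.not_included, DrugRole.rescue_medication}
)

#: Use-case labels counted as the "classic" bucket of the triage funnel.
CLASSIC_USE_CASES = frozenset(
    {"bioequivalence", "bioavailability", "pharmacokinetics", "taste"}
)

#: Maps variant labels onto the canonical classic bucket terms.
CLASSIC_USE_CASE_SYNONYMS = {
    "taste [form and preference]": "taste",
    "taste (form and preference)": "taste",
}


class AgeGroup(str, Enum):
    child = "child"          # [0, 18)
    adult = "adult"          # [18, 65)
    older_adult = "older_adult"  # [65, inf)


_AGE_GROUP_BOUNDS = {
    AgeGroup.child: (0.0, 18.0),
    AgeGroup.adult: (18.0, 65.0),
    AgeGroup.older_adult: (65.0, math.inf),
}


@dataclass(frozen=True)
class SummaryTable:
    """Long-format result table: unique key-tuples with one numeric value."""

    group_keys: tuple[str, ...]
    rows: tuple[tuple[tuple, float], ...]
    value_kind: str  # "count" | "ratio" | "mean"

    def __post_init__(self):
        keys = [k for k, _ in self.rows]
        if len(keys) != len(set(keys)):
            raise ContractError("SummaryTable key-tuples must be unique")

    def to_dict(self) -> dict[tuple, float]:
        return {k: v for k, v in self.rows}

    def to_csv(self, path: str | Path) -> None:
        lines = [",".join([*self.group_keys, "value"])]
        for key, value in self.rows:
            cells = [_csv_cell(c) for c in key]
            if self.value_kind == "count":
                cells.append(str(int(value)))
            else:
                cells.append(repr(float(value)))
            lines.append(",".join(cells))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _csv_cell(value) -> str:
    text = str(value)
    if any(c in text for c in ',"\n'):
        text = '"' + text.replace('"', '""') + '"'
    return text


@dataclass
class TableResult:
    """A summary table plus the excluded-record tally (reason → count)."""

    table: SummaryTable
    excluded: dict[str, int] = field(default_factory=dict)


Pair = tuple[StudyRecord, Annotation]


def _counts_table(group_keys: Sequence[str], counter: Counter) -> SummaryTable:
    rows = tuple(sorted((k, float(v)) for k, v in counter.items()))
    return SummaryTable(group_keys=tuple(group_keys), rows=rows, value_kind="count")


def _ratio_table(group_keys: Sequence[str], counter: Counter, group_index: int = 0) -> SummaryTable:
    """Turn per-key counts into within-group ratios (group = first key part)."""
    totals: Counter = Counter()
    for key, n in counter.items():
        totals[key[group_index]] += n
    rows = tuple(
        sorted((k, v / totals[k[group_index]]) for k, v in counter.items())
    )
    return SummaryTable(group_keys=tuple(group_keys), rows=rows, value_kind="ratio")


def filter_relevant(store: CurationStore) -> tuple[list[Pair], dict[str, int]]:
    """Annotated trials whose drug role is relevant to the landscape.

    Returns the retained (record, annotation) pairs and the exclusion tally:
    unannotated trials and trials with an excluded role.
    """
    pairs = store.annotated_pairs()
    retained = [(r, a) for r, a in pairs if a.drug_role not in EXCLUDED_ROLES]
    excluded = {
        "unannotated": len(store) - len(pairs),
        "excluded_role": len(pairs) - len(retained),
    }
    return retained, excluded


def counts_by_drug_and_role(store: CurationStore, include_all_roles: bool = False) -> TableResult:
    """Trial counts keyed by (primary_drug, drug_role).

    The all-roles variant is the one overview that keeps the excluded roles
    visible; every other routine works on the filtered set.
    """
    if include_all_roles:
        pairs = store.annotated_pairs()
        excluded = {"unannotated": len(store) - len(pairs)}
    else:
        pairs, excluded = filter_relevant(store)
    counter = Counter((a.primary_drug, a.drug_role.value) for _, a in pairs)
    return TableResult(_counts_table(("primary_drug", "drug_role"), counter), excluded)


def timeline(store: CurationStore, date_field: str = "start") -> TableResult:
    """Trial counts keyed by (year, primary_drug) of the chosen date field."""
    if date_field not in ("start", "first_posted"):
        raise ContractError(f"date_field must be 'start' or 'first_posted', got {date_field!r}")
    attr = "start_date" if date_field == "start" else "first_posted_date"
    pairs, excluded = filter_relevant(store)
    counter: Counter = Counter()
    missing = 0
    for record, annotation in pairs:
        date = getattr(record, attr)
        if date is None:
            missing += 1
            continue
        counter[(int(date[:4]), annotation.primary_drug)] += 1
    excluded[f"missing_{attr}"] = missing
    return TableResult(_counts_table(("year", "primary_drug"), counter), excluded)


def registration_lag(store: CurationStore, include_same_year: bool = False) -> TableResult:
    """Registration-lag table keyed by (first_posted_year, measure).

    ``n_differing`` counts trials whose start and first-posted years differ;
    ``mean_lag`` is the mean of (first_posted_year − start_year), by default
    over the differing-year trials only (positive = post-registration).
    """
    pairs, excluded = filter_relevant(store)
    diff_counts: Counter = Counter()
    lags: dict[int, list[int]] = defaultdict(list)
    missing = 0
    for record, _ in pairs:
        if record.start_date is None or record.first_posted_date is None:
            missing += 1
            continue
        start_year = int(record.start_date[:4])
        posted_year = int(record.first_posted_date[:4])
        lag = posted_year - start_year
        diff_counts.setdefault((posted_year,), 0)
        if lag != 0:
            diff_counts[(posted_year,)] += 1
        if lag != 0 or include_same_year:
            lags[posted_year].append(lag)
    excluded["missing_dates"] = missing
    rows: list[tuple[tuple, float]] = []
    for (year,), n in diff_counts.items():
        rows.append(((year, "n_differing"), float(n)))
    for year, values in lags.items():
        rows.append(((year, "mean_lag"), sum(values) / len(values)))
    table = SummaryTable(
        group_keys=("first_posted_year", "measure"),
        rows=tuple(sorted(rows)),
        value_kind="mean",
    )
    return TableResult(table, excluded)


def status_distribution(store: CurationStore) -> TableResult:
    """Per-drug ratio of overall-status categories (sums to 1 per drug)."""
    pairs, excluded = filter_relevant(store)
    counter = Counter((a.primary_drug, r.overall_status) for r, a in pairs)
    return TableResult(_ratio_table(("primary_drug", "overall_status"), counter), excluded)


def age_groups_for(min_age: float | None, max_age: float | None) -> frozenset[AgeGroup]:
    """Age groups whose interval intersects [min_age, max_age].

    Absent bounds default to 0 and infinity — an unbounded trial intersects
    every group.
    """
    lo = 0.0 if min_age is None else min_age
    hi = math.inf if max_age is None else max_age
    return frozenset(
        g for g, (glo, ghi) in _AGE_GROUP_BOUNDS.items() if lo < ghi and hi >= glo
    )


def age_group_label(groups: frozenset[AgeGroup]) -> str:
    ordered = [g.value for g in AgeGroup if g in groups]
    return "+".join(ordered) if ordered else "none"


def age_group_distribution(store: CurationStore) -> TableResult:
    """Per-drug ratio of age-group combinations eligible for participation."""
    pairs, excluded = filter_relevant(store)
    counter = Counter(
        (a.primary_drug, age_group_label(age_groups_for(r.min_age_years, r.max_age_years)))
        for r, a in pairs
    )
    return TableResult(_ratio_table(("primary_drug", "age_groups"), counter), excluded)


def sex_distribution(store: CurationStore) -> TableResult:
    """Per-drug ratio of eligible-sex categories."""
    pairs, excluded = filter_relevant(store)
    counter = Counter((a.primary_drug, r.sex.value) for r, a in pairs)
    return TableResult(_ratio_table(("primary_drug", "sex"), counter), excluded)


def usecase_table(store: CurationStore) -> TableResult:
    """Counts keyed by (use_case, primary_drug, repurposing).

    Rows are ordered by descending total per use case; ties break
    lexicographically for reproducibility.
    """
    pairs, excluded = filter_relevant(store)
    counter = Counter(
        (a.use_case, a.primary_drug, "true" if a.repurposing else "false")
        for _, a in pairs
    )
    totals: Counter = Counter()
    for (use_case, _, _), n in counter.items():
        totals[use_case] += n
    rows = tuple(
        sorted(
            ((k, float(v)) for k, v in counter.items()),
            key=lambda kv: (-totals[kv[0][0]], kv[0]),
        )
    )
    table = SummaryTable(
        group_keys=("use_case", "primary_drug", "repurposing"),
        rows=rows,
        value_kind="count",
    )
    return TableResult(table, excluded)


def country_counts(store: CurationStore) -> TableResult:
    """Distinct-trial counts per country: a trial adds at most 1 per country,
    however many sites it runs there."""
    pairs, excluded = filter_relevant(store)
    countries = store.term_dictionary("country")
    id_to_term = {v: k for k, v in countries.entries.items()}
    counter: Counter = Counter()
    for record, _ in pairs:
        for term_id in set(record.country_ids):
            counter[(id_to_term[term_id],)] += 1
    return TableResult(_counts_table(("country",), counter), excluded)


def publication_crosstab(store: CurationStore) -> TableResult:
    """Counts keyed by (overall_status, publication_status), repurposing only."""
    pairs, excluded = filter_relevant(store)
    repurposing = [(r, a) for r, a in pairs if a.repurposing]
    excluded["not_repurposing"] = len(pairs) - len(repurposing)
    counter = Counter(
        (r.overall_status, a.publication_status.value) for r, a in repurposing
    )
    return TableResult(
        _counts_table(("overall_status", "publication_status"), counter), excluded
    )


def publication_percentage(n_published: int, n_total: int) -> float:
    """Share of published trials among a status bucket, in percent (1 dp)."""
    if n_total <= 0:
        raise ContractError("n_total must be positive")
    return round(100.0 * n_published / n_total, 1)


FUNNEL_STAGES = (
    "total",
    "classic_bioequivalence_bucket",
    "classic_other",
    "repurposing",
    "repurposing_paper_published",
)


def is_classic_use_case(use_case: str) -> bool:
    label = use_case.strip().lower()
    label = CLASSIC_USE_CASE_SYNONYMS.get(label, label)
    return label in CLASSIC_USE_CASES


def triage_funnel(store: CurationStore) -> TableResult:
    """Staged triage counts from all annotated trials down to published
    repurposing trials.

    Conservation: total = repurposing + classic_bioequivalence_bucket +
    classic_other; unannotated trials are reported in ``excluded``.
    """
    pairs = store.annotated_pairs()
    excluded = {"unannotated": len(store) - len(pairs)}
    n_total = len(pairs)
    n_repurposing = sum(1 for _, a in pairs if a.repurposing)
    n_classic_bio = sum(
        1 for _, a in pairs if not a.repurposing and is_classic_use_case(a.use_case)
    )
    n_classic_other = n_total - n_repurposing - n_classic_bio
    n_published = sum(
        1
        for _, a in pairs
        if a.repurposing and a.publication_status == PublicationStatus.paper
    )
    values = (n_total, n_classic_bio, n_classic_other, n_repurposing, n_published)
    table = SummaryTable(
        group_keys=("stage",),
        rows=tuple(((stage,), float(v)) for stage, v in zip(FUNNEL_STAGES, values)),
        value_kind="count",
    )
    return TableResult(table, excluded)


#: Name → callable registry used by the CLI's ``analyze --table`` command.
TABLES = {
    "drug-roles": lambda s: counts_by_drug_and_role(s, include_all_roles=True),
    "drug-roles-filtered": lambda s: counts_by_drug_and_role(s, include_all_roles=False),
    "timeline-start": lambda s: timeline(s, "start"),
    "timeline-posted": lambda s: timeline(s, "first_posted"),
    "lag": registration_lag,
    "status": status_distribution,
    "age-groups": age_group_distribution,
    "sex": sex_distribution,
    "use-cases": usecase_table,
    "countries": country_counts,
    "publication": publication_crosstab,
    "funnel": triage_funnel,
}
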