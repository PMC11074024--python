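"""Seeded synthetic registry snapshots with known ground-truth composition.

Every record draws from its own pseudo-random stream keyed by (seed, rank),
so extending a snapshot with new ranks never perturbs existing records —
snapshot pairs stay coherent. Synthetic NCT IDs live in a reserved high range
(NCT99xxxxxx) so they are visibly fake.

The generator emulates the registry's quirks: singleton fields wrapped in
lists, ages in months, dates missing the day, multi-site country lists, and
false-positive records where a search term only matches a person's name.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, field_validator

from .analytics import EXCLUDED_ROLES, FUNNEL_STAGES, is_classic_use_case
from .curation import Annotation, DrugRole, PublicationStatus
from .errors import ContractError
from .ingest import RawStudyRecord, Snapshot, build_query

_MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)

DEFAULT_DRUG_TERMS = [
    "Cetirizine", "Levocetirizine", "Fexofenadine", "Loratadine", "Desloratadine",
]

_COUNTRIES = (
    "United States", "Canada", "Germany", "France", "United Kingdom", "India",
    "China", "Japan", "Brazil", "Mexico", "Spain", "Italy", "Netherlands",
    "Sweden", "Poland", "Turkey", "Egypt", "South Korea", "Australia", "Iran",
)

_CONDITIONS = (
    "Rhinitis, Allergic", "Urticaria", "Asthma", "Conjunctivitis", "Pruritus",
    "Healthy", "Dermatitis, Atopic", "COVID-19", "Alopecia", "Neoplasms",
    "Bone Pain", "Hypersensitivity",
)

_SURNAMES = ("Rossi", "Martin", "Garcia", "Novak", "Keller", "Tanaka")

# (min_age_years, max_age_years) candidates; None means absent. Fractions are
# exact multiples of 1/12 so the months representation round-trips losslessly.
_AGE_WINDOWS = (
    (0.0, 17.0),
    (0.5, 11.0),
    (2.0, 17.0),
    (18.0, 64.0),
    (18.0, 55.0),
    (18.0, None),
    (65.0, None),
    (0.0, None),
    (None, None),
    (12.0, 75.0),
)


def _weights_sum_to_one(v: dict) -> dict:
    if abs(sum(v.values()) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(v.values())}")
    if any(w < 0 for w in v.values()):
        raise ValueError("weights must be non-negative")
    return v


class FixtureConfig(BaseModel):
    """Knobs of the synthetic snapshot generator."""

    n_records: int = Field(default=200, ge=0)
    seed: int = 0
    drug_terms: list[str] = Field(default_factory=lambda: list(DEFAULT_DRUG_TERMS))
    role_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "main": 0.40, "comparison": 0.15, "combination": 0.12, "control": 0.08,
            "premedication": 0.05, "minimal": 0.08, "not_included": 0.07,
            "rescue_medication": 0.05,
        }
    )
    status_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "Completed": 0.55, "Recruiting": 0.12, "Terminated": 0.08,
            "Unknown status": 0.10, "Active, not recruiting": 0.06,
            "Not yet recruiting": 0.04, "Withdrawn": 0.05,
        }
    )
    sex_mix: dict[str, float] = Field(
        default_factory=lambda: {"All": 0.92, "Male": 0.06, "Female": 0.02}
    )
    usecase_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "allergic rhinitis": 0.30, "urticaria": 0.20, "bioequivalence": 0.15,
            "asthma": 0.08, "pharmacokinetics": 0.06, "bioavailability": 0.04,
            "taste [form and preference]": 0.03, "COVID-19": 0.04, "alopecia": 0.03,
            "infusion-associated reactions": 0.03, "bone pain": 0.02, "other": 0.02,
        }
    )
    publication_mix: dict[str, float] = Field(
        default_factory=lambda: {"none": 0.70, "registry_results": 0.18, "paper": 0.12}
    )
    lag_years: dict[int, float] = Field(
        default_factory=lambda: {0: 0.60, 1: 0.20, 2: 0.10, 5: 0.06, 8: 0.04}
    )
    p_repurposing: float = Field(default=0.12, ge=0.0, le=1.0)
    p_month_age: float = Field(default=0.10, ge=0.0, le=1.0)
    p_partial_date: float = Field(default=0.15, ge=0.0, le=1.0)
    p_multi_country: float = Field(default=0.25, ge=0.0, le=1.0)
    p_false_positive: float = Field(default=0.05, ge=0.0, le=1.0)
    p_invalid: float = Field(default=0.03, ge=0.0, le=1.0)

    _check_role = field_validator("role_mix", "status_mix", "sex_mix", "usecase_mix", "publication_mix")(_weights_sum_to_one)

    @field_validator("lag_years")
    @classmethod
    def _check_lags(cls, v: dict) -> dict:
        return _weights_sum_to_one(v)


@dataclass
class _Profile:
    """Planted attributes of one synthetic record."""

    rank: int
    nct_id: str
    invalid: bool
    false_positive: bool
    drug: str
    role: DrugRole
    status: str
    sex: str
    use_case: str
    repurposing: bool
    publication_status: PublicationStatus
    min_age: float | None
    max_age: float | None
    month_age: bool
    start_year: int
    start_month: int
    start_day: int
    partial_date: bool
    lag: int
    posted_month: int
    posted_day: int
    update_month: int
    update_day: int
    countries: list[str]
    conditions: list[str]
    surname: str

    @property
    def annotated(self) -> bool:
        return not self.invalid and not self.false_positive


@dataclass
class GroundTruth:
    """Planted composition: what every analytics table must recover."""

    n_records: int = 0
    n_invalid: int = 0
    n_false_positive: int = 0
    n_annotated: int = 0
    tables: dict[str, dict] = field(default_factory=dict)
    new_ids: list[str] = field(default_factory=list)
    updated_ids: list[str] = field(default_factory=list)


def _weighted(rng: random.Random, mix: dict) -> object:
    population = list(mix.keys())
    return rng.choices(population, weights=[mix[k] for k in population], k=1)[0]


def _profile(config: FixtureConfig, rank: int) -> _Profile:
    # One stream per (seed, rank); every draw happens unconditionally so that
    # flag combinations never shift later draws.
    rng = random.Random(f"{config.seed}:{rank}")
    invalid = rng.random() < config.p_invalid
    false_positive = rng.random() < config.p_false_positive and not invalid
    drug = rng.choice(config.drug_terms)
    role = DrugRole(_weighted(rng, config.role_mix))
    status = str(_weighted(rng, config.status_mix))
    sex = str(_weighted(rng, config.sex_mix))
    use_case = str(_weighted(rng, config.usecase_mix))
    repurposing = rng.random() < config.p_repurposing
    publication = PublicationStatus(str(_weighted(rng, config.publication_mix)))
    min_age, max_age = _AGE_WINDOWS[rng.randrange(len(_AGE_WINDOWS))]
    month_age = rng.random() < config.p_month_age
    start_year = rng.randint(2000, 2020)
    start_month = rng.randint(1, 12)
    start_day = rng.randint(1, 28)
    partial_date = rng.random() < config.p_partial_date
    lag = int(_weighted(rng, config.lag_years))
    posted_month = rng.randint(1, 12)
    posted_day = rng.randint(1, 28)
    update_month = rng.randint(1, 12)
    update_day = rng.randint(1, 28)
    base_country = rng.choice(_COUNTRIES)
    countries = [base_country]
    if rng.random() < config.p_multi_country:
        countries += [base_country] * rng.randint(1, 3)
        if rng.random() < 0.5:
            countries.append(rng.choice(_COUNTRIES))
    conditions = rng.sample(_CONDITIONS, rng.randint(1, 3))
    surname = rng.choice(_SURNAMES)
    return _Profile(
        rank=rank,
        nct_id=f"NCT99{rank:06d}",
        invalid=invalid,
        false_positive=false_positive,
        drug=drug,
        role=DrugRole.not_included if false_positive else role,
        status=status,
        sex=sex,
        use_case=use_case,
        repurposing=repurposing,
        publication_status=publication,
        min_age=min_age,
        max_age=max_age,
        month_age=month_age,
        start_year=start_year,
        start_month=start_month,
        start_day=start_day,
        partial_date=partial_date,
        lag=lag,
        posted_month=posted_month,
        posted_day=posted_day,
        update_month=update_month,
        update_day=update_day,
        countries=countries,
        conditions=conditions,
        surname=surname,
    )


def _profiles(config: FixtureConfig, n: int) -> list[_Profile]:
    return [_profile(config, rank) for rank in range(1, n + 1)]


def _age_string(years: float, as_months: bool) -> str:
    if as_months:
        return f"{round(years * 12)} Months"
    return f"{round(years)} Years"


def _date_string(year: int, month: int, day: int, partial: bool) -> str:
    if partial:
        return f"{_MONTH_NAMES[month - 1]} {year}"
    return f"{_MONTH_NAMES[month - 1]} {day}, {year}"


def _record_from_profile(p: _Profile) -> RawStudyRecord:
    if p.false_positive:
        title = f"Trial of placebo conducted by Dr. {p.drug.title()} {p.surname}"
        interventions = ["Placebo"]
    else:
        title = f"Study of {p.drug} for {p.use_case}"
        interventions = [p.drug]
    if p.invalid:
        # Planted contradiction: min age above max age fails normalization.
        min_age_values = ["65 Years"]
        max_age_values = ["1 Years"]
    else:
        as_months = p.month_age or (p.min_age is not None and p.min_age != int(p.min_age))
        min_age_values = (
            [] if p.min_age is None else [_age_string(p.min_age, as_months)]
        )
        max_age_values = [] if p.max_age is None else [_age_string(p.max_age, False)]
    posted_year = p.start_year + p.lag
    values = {
        "NCTId": [p.nct_id],
        "BriefTitle": [title],
        "OfficialTitle": [f"Official: {title}"],
        "BriefSummary": [f"A synthetic record about {p.use_case}."],
        "Conditions": list(p.conditions),
        "Gender": [p.sex],
        "MinimumAge": min_age_values,
        "MaximumAge": max_age_values,
        "OverallStatus": [p.status],
        "StartDate": [_date_string(p.start_year, p.start_month, p.start_day, p.partial_date)],
        "CompletionDate": [_date_string(posted_year + 1, p.posted_month, p.posted_day, False)],
        "StudyFirstPostDate": [_date_string(posted_year, p.posted_month, p.posted_day, False)],
        "LastUpdatePostDate": [_date_string(2022, p.update_month, p.update_day, False)],
        "LocationCountry": list(p.countries),
        "LocationFacility": [f"Site {i + 1}" for i in range(len(p.countries))],
        "InterventionName": interventions,
    }
    return RawStudyRecord(rank=p.rank, values=values)


def _annotation_from_profile(p: _Profile) -> Annotation:
    publication_ref = (
        f"https://doi.org/10.9999/{p.nct_id}"
        if p.publication_status == PublicationStatus.paper
        else None
    )
    return Annotation(
        nct_id=p.nct_id,
        primary_drug=p.drug,
        additional_drugs=[],
        legacy_search_term=p.drug.lower(),
        use_case=p.use_case,
        drug_role=p.role,
        repurposing=p.repurposing,
        publication_status=p.publication_status,
        publication_ref=publication_ref,
        notes=None,
    )


def _ground_truth(profiles: Sequence[_Profile]) -> GroundTruth:
    """Tabulate what analytics must recover, by direct loops over the plan."""
    gt = GroundTruth(n_records=len(profiles))
    gt.n_invalid = sum(1 for p in profiles if p.invalid)
    gt.n_false_positive = sum(1 for p in profiles if p.false_positive)
    annotated = [p for p in profiles if p.annotated]
    gt.n_annotated = len(annotated)
    relevant = [p for p in annotated if p.role not in EXCLUDED_ROLES]

    gt.tables["drug-roles"] = {
        k: float(v)
        for k, v in Counter((p.drug, p.role.value) for p in annotated).items()
    }
    gt.tables["drug-roles-filtered"] = {
        k: float(v)
        for k, v in Counter((p.drug, p.role.value) for p in relevant).items()
    }
    gt.tables["timeline-start"] = {
        k: float(v) for k, v in Counter((p.start_year, p.drug) for p in relevant).items()
    }
    gt.tables["timeline-posted"] = {
        k: float(v)
        for k, v in Counter((p.start_year + p.lag, p.drug) for p in relevant).items()
    }

    lag_table: dict = {}
    lags_by_year: dict[int, list[int]] = defaultdict(list)
    for p in relevant:
        year = p.start_year + p.lag
        lag_table.setdefault((year, "n_differing"), 0.0)
        if p.lag != 0:
            lag_table[(year, "n_differing")] += 1.0
            lags_by_year[year].append(p.lag)
    for year, lags in lags_by_year.items():
        lag_table[(year, "mean_lag")] = sum(lags) / len(lags)
    gt.tables["lag"] = lag_table

    def ratios(counter: Counter) -> dict:
        totals: Counter = Counter()
        for key, n in counter.items():
            totals[key[0]] += n
        return {k: v / totals[k[0]] for k, v in counter.items()}

    gt.tables["status"] = ratios(Counter((p.drug, p.status) for p in relevant))
    gt.tables["sex"] = ratios(Counter((p.drug, p.sex.lower()) for p in relevant))
    gt.tables["age-groups"] = ratios(
        Counter((p.drug, _age_label(p.min_age, p.max_age)) for p in relevant)
    )
    gt.tables["use-cases"] = {
        k: float(v)
        for k, v in Counter(
            (p.use_case, p.drug, "true" if p.repurposing else "false") for p in relevant
        ).items()
    }

    country_counter: Counter = Counter()
    for p in relevant:
        for country in set(p.countries):
            country_counter[(country,)] += 1
    gt.tables["countries"] = {k: float(v) for k, v in country_counter.items()}

    gt.tables["publication"] = {
        k: float(v)
        for k, v in Counter(
            (p.status, p.publication_status.value) for p in relevant if p.repurposing
        ).items()
    }

    n_total = len(annotated)
    n_rep = sum(1 for p in annotated if p.repurposing)
    n_classic_bio = sum(
        1 for p in annotated if not p.repurposing and is_classic_use_case(p.use_case)
    )
    n_paper = sum(
        1
        for p in annotated
        if p.repurposing and p.publication_status == PublicationStatus.paper
    )
    funnel_values = (
        n_total, n_classic_bio, n_total - n_rep - n_classic_bio, n_rep, n_paper
    )
    gt.tables["funnel"] = {
        (stage,): float(v) for stage, v in zip(FUNNEL_STAGES, funnel_values)
    }
    return gt


def _age_label(min_age: float | None, max_age: float | None) -> str:
    """Independent re-statement of the age-group intersection rule."""
    lo = 0.0 if min_age is None else min_age
    hi = float("inf") if max_age is None else max_age
    parts = []
    if lo < 18 and hi >= 0:
        parts.append("child")
    if lo < 65 and hi >= 18:
        parts.append("adult")
    if hi >= 65:
        parts.append("older_adult")
    return "+".join(parts) if parts else "none"


def _snapshot_from_profiles(config: FixtureConfig, profiles: Sequence[_Profile]) -> Snapshot:
    records = [_record_from_profile(p) for p in profiles]
    return Snapshot(
        retrieved_at="2023-01-15T00:00:00+00:00",
        query_expression=build_query(config.drug_terms) if config.drug_terms else "",
        n_records_found=len(records),
        records=records,
    )


def generate_snapshot(config: FixtureConfig) -> tuple[Snapshot, GroundTruth]:
    """Deterministic synthetic snapshot plus its planted ground truth."""
    profiles = _profiles(config, config.n_records)
    return _snapshot_from_profiles(config, profiles), _ground_truth(profiles)


def generate_annotations(snapshot: Snapshot, config: FixtureConfig) -> list[Annotation]:
    """Annotation set for every valid, non-false-positive record in the
    snapshot, consistent with the planted ground truth."""
    present = set(snapshot.nct_ids())
    max_rank = max((r.rank for r in snapshot.records), default=0)
    return [
        _annotation_from_profile(p)
        for p in _profiles(config, max_rank)
        if p.annotated and p.nct_id in present
    ]


def generate_snapshot_pair(
    config: FixtureConfig, n_new: int, n_updated: int
) -> tuple[Snapshot, Snapshot, GroundTruth]:
    """A before/after snapshot pair planting additions and date changes."""
    if n_updated > config.n_records:
        raise ContractError("n_updated cannot exceed n_records")
    base = _profiles(config, config.n_records)
    extended = _profiles(config, config.n_records + n_new)
    old = _snapshot_from_profiles(config, base)
    new = _snapshot_from_profiles(config, extended)

    rng = random.Random(f"{config.seed}:pair")
    updated_ids = sorted(rng.sample([p.nct_id for p in base], n_updated))
    updated_set = set(updated_ids)
    for record in new.records:
        if record.nct_id in updated_set:
            record.values["LastUpdatePostDate"] = ["August 1, 2023"]

    gt = _ground_truth(base)
    gt.new_ids = [p.nct_id for p in extended[config.n_records:]]
    gt.updated_ids = updated_ids
    return old, new, gt
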