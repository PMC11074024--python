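"""Analytics unit tests: trivial worked examples, planted-composition
recovery, and independent brute-force loop oracles."""

from collections import Counter

import pytest

from trialscape import FixtureConfig
from trialscape.analytics import (
    EXCLUDED_ROLES,
    AgeGroup,
    age_group_label,
    age_groups_for,
    counts_by_drug_and_role,
    country_counts,
    filter_relevant,
    publication_crosstab,
    publication_percentage,
    registration_lag,
    sex_distribution,
    status_distribution,
    timeline,
    triage_funnel,
    usecase_table,
    TABLES,
)
from trialscape.curation import Annotation, CurationStore, DrugRole, PublicationStatus
from trialscape.errors import ContractError
from trialscape.normalize import StudyRecord

from conftest import build_store


def small_store(entries):
    """entries: list of (record-kwargs, annotation-kwargs)."""
    store = CurationStore()
    for i, (rkw, akw) in enumerate(entries, start=1):
        nct = f"NCT000000{i:02d}"
        store.upsert_records([StudyRecord(nct_id=nct, **rkw)])
        if akw is not None:
            defaults = dict(primary_drug="Cetirizine", drug_role=DrugRole.main)
            defaults.update(akw)
            store.set_annotation(Annotation(nct_id=nct, **defaults))
    return store


class TestFilterRelevant:
    def test_one_per_role_keeps_five(self):
        entries = [({}, {"drug_role": role, "primary_drug": "" if role == DrugRole.not_included else "Cetirizine"}) for role in DrugRole]
        store = small_store(entries)
        pairs, excluded = filter_relevant(store)
        assert len(pairs) == 5
        assert excluded == {"unannotated": 0, "excluded_role": 3}

    def test_all_main_is_identity(self):
        store = small_store([({}, {}) for _ in range(4)])
        pairs, _ = filter_relevant(store)
        assert len(pairs) == 4

    def test_never_emits_excluded_roles(self, populated):
        store, _, _ = populated
        pairs, _ = filter_relevant(store)
        assert all(a.drug_role not in EXCLUDED_ROLES for _, a in pairs)

    def test_unannotated_counted(self):
        store = small_store([({}, {}), ({}, None)])
        pairs, excluded = filter_relevant(store)
        assert len(pairs) == 1
        assert excluded["unannotated"] == 1


class TestCountsByDrugAndRole:
    def test_two_trials(self):
        store = small_store(
            [({}, {"drug_role": DrugRole.main}), ({}, {"drug_role": DrugRole.control})]
        )
        table = counts_by_drug_and_role(store, include_all_roles=True).table
        assert table.to_dict() == {
            ("Cetirizine", "control"): 1.0,
            ("Cetirizine", "main"): 1.0,
        }

    def test_empty_store(self):
        table = counts_by_drug_and_role(CurationStore()).table
        assert table.rows == ()


class TestTimeline:
    def test_two_records(self):
        store = small_store(
            [
                ({"start_date": "2005-03-01"}, {}),
                ({"start_date": "2005-07-12"}, {"primary_drug": "Loratadine"}),
            ]
        )
        assert timeline(store, "start").table.to_dict() == {
            (2005, "Cetirizine"): 1.0,
            (2005, "Loratadine"): 1.0,
        }

    def test_missing_dates_reported(self):
        store = small_store([({}, {}), ({"start_date": "2010-01-01"}, {})])
        result = timeline(store, "start")
        assert result.excluded["missing_start_date"] == 1
        assert sum(v for v in result.table.to_dict().values()) == 1

    def test_bad_field_rejected(self):
        with pytest.raises(ContractError):
            timeline(CurationStore(), "completion")


class TestRegistrationLag:
    def test_started_2003_posted_2009(self):
        store = small_store(
            [({"start_date": "2003-05-01", "first_posted_date": "2009-02-10"}, {})]
        )
        assert registration_lag(store).table.to_dict() == {
            (2009, "n_differing"): 1.0,
            (2009, "mean_lag"): 6.0,
        }

    def test_same_year_not_in_mean(self):
        store = small_store(
            [({"start_date": "2010-01-01", "first_posted_date": "2010-11-01"}, {})]
        )
        assert registration_lag(store).table.to_dict() == {(2010, "n_differing"): 0.0}

    def test_mean_against_brute_force(self, populated):
        store, _, _ = populated
        pairs, _ = filter_relevant(store)
        by_year = {}
        for record, _ in pairs:
            lag = int(record.first_posted_date[:4]) - int(record.start_date[:4])
            if lag != 0:
                by_year.setdefault(int(record.first_posted_date[:4]), []).append(lag)
        got = registration_lag(store).table.to_dict()
        for year, lags in by_year.items():
            assert got[(year, "n_differing")] == len(lags)
            assert got[(year, "mean_lag")] == pytest.approx(sum(lags) / len(lags))


class TestStatusDistribution:
    def test_three_to_one(self):
        store = small_store(
            [({"overall_status": "Completed"}, {})] * 3
            + [({"overall_status": "Terminated"}, {})]
        )
        assert status_distribution(store).table.to_dict() == {
            ("Cetirizine", "Completed"): 0.75,
            ("Cetirizine", "Terminated"): 0.25,
        }

    def test_single_status_is_one(self):
        store = small_store([({"overall_status": "Completed"}, {})])
        assert status_distribution(store).table.to_dict() == {
            ("Cetirizine", "Completed"): 1.0
        }


class TestAgeGroups:
    def test_adult_only(self):
        assert age_groups_for(18, 64) == frozenset({AgeGroup.adult})

    def test_unbounded_hits_all(self):
        assert age_groups_for(None, None) == frozenset(
            {AgeGroup.child, AgeGroup.adult, AgeGroup.older_adult}
        )

    def test_child_only(self):
        assert age_groups_for(0, 17) == frozenset({AgeGroup.child})

    def test_older_adult_boundary(self):
        assert age_groups_for(65, None) == frozenset({AgeGroup.older_adult})

    def test_label_order(self):
        groups = frozenset({AgeGroup.older_adult, AgeGroup.child, AgeGroup.adult})
        assert age_group_label(groups) == "child+adult+older_adult"


class TestRatioTablesSumToOne:
    @pytest.mark.parametrize("fn", [status_distribution, sex_distribution])
    def test_per_drug_sum(self, populated, fn):
        store, _, _ = populated
        table = fn(store).table
        totals = Counter()
        for (drug, *_), ratio in table.rows:
            totals[drug] += ratio
        assert totals
        for total in totals.values():
            assert abs(total - 1.0) < 1e-9

    def test_age_group_sum(self, populated):
        store, _, _ = populated
        totals = Counter()
        for (drug, _), ratio in age_group_distribution_rows(store):
            totals[drug] += ratio
        for total in totals.values():
            assert abs(total - 1.0) < 1e-9


def age_group_distribution_rows(store):
    from trialscape.analytics import age_group_distribution

    return age_group_distribution(store).table.rows


class TestUseCaseTable:
    def test_descending_order_with_lexicographic_ties(self):
        store = small_store(
            [({}, {"use_case": "urticaria"})] * 3
            + [({}, {"use_case": "asthma"})]
            + [({}, {"use_case": "alopecia"})]
        )
        rows = usecase_table(store).table.rows
        use_cases = [key[0] for key, _ in rows]
        assert use_cases == ["urticaria", "alopecia", "asthma"]


class TestCountryCounts:
    def test_multi_site_counts_once(self):
        store = CurationStore()
        from trialscape.normalize import TermDictionary

        d = TermDictionary(kind="country", entries={"United States": 1, "Canada": 2})
        store.upsert_terms(d)
        store.upsert_records(
            [StudyRecord(nct_id="NCT00000001", country_ids=[1, 1, 1, 2])]
        )
        store.set_annotation(
            Annotation(nct_id="NCT00000001", primary_drug="Cetirizine", drug_role=DrugRole.main)
        )
        assert country_counts(store).table.to_dict() == {
            ("United States",): 1.0,
            ("Canada",): 1.0,
        }

    def test_no_locations_empty(self):
        store = small_store([({}, {})])
        assert country_counts(store).table.rows == ()

    def test_brute_force_and_site_excess(self, populated):
        store, _, _ = populated
        pairs, _ = filter_relevant(store)
        id_to_term = {
            v: k for k, v in store.term_dictionary("country").entries.items()
        }
        expected = Counter()
        total_sites = 0
        for record, _ in pairs:
            total_sites += len(record.country_ids)
            for cid in set(record.country_ids):
                expected[(id_to_term[cid],)] += 1
        got = country_counts(store).table.to_dict()
        assert got == {k: float(v) for k, v in expected.items()}
        assert total_sites > sum(got.values())  # multi-site trials planted
        assert all(v <= len(pairs) for v in got.values())


class TestPublicationCrosstab:
    def test_single_cell(self):
        store = small_store(
            [
                (
                    {"overall_status": "Completed"},
                    {
                        "repurposing": True,
                        "publication_status": PublicationStatus.paper,
                        "publication_ref": "doi:10.1/x",
                    },
                )
            ]
        )
        assert publication_crosstab(store).table.to_dict() == {
            ("Completed", "paper"): 1.0
        }

    def test_no_repurposing_empty(self):
        store = small_store([({}, {"repurposing": False})])
        result = publication_crosstab(store)
        assert result.table.rows == ()
        assert result.excluded["not_repurposing"] == 1

    def test_percentage_helper(self):
        assert publication_percentage(10, 22) == 45.5
        assert publication_percentage(1, 2) == 50.0
        with pytest.raises(ContractError):
            publication_percentage(1, 0)


class TestTriageFunnel:
    def test_four_trial_worked_example(self):
        store = small_store(
            [
                ({}, {"repurposing": True, "publication_status": PublicationStatus.paper,
                      "publication_ref": "doi:10.1/x"}),
                ({}, {"repurposing": True}),
                ({}, {"use_case": "bioequivalence"}),
                ({}, {"use_case": "allergic rhinitis"}),
            ]
        )
        table = triage_funnel(store).table
        assert [v for _, v in table.rows] == [4.0, 1.0, 1.0, 2.0, 1.0]

    def test_all_repurposing_empties_classic(self):
        store = small_store([({}, {"repurposing": True})] * 3)
        values = dict(triage_funnel(store).table.rows)
        assert values[("classic_bioequivalence_bucket",)] == 0.0
        assert values[("classic_other",)] == 0.0
        assert values[("repurposing",)] == 3.0


class TestGroundTruthRecovery:
    def test_every_table_matches_planted_composition(self, populated):
        store, truth, _ = populated
        for name, fn in TABLES.items():
            assert fn(store).table.to_dict() == truth.tables[name], name

    def test_count_tables_match_brute_force(self, populated):
        store, _, _ = populated
        pairs, _ = filter_relevant(store)
        brute = Counter()
        for record, annotation in pairs:
            brute[(annotation.use_case, annotation.primary_drug,
                   "true" if annotation.repurposing else "false")] += 1
        assert usecase_table(store).table.to_dict() == {
            k: float(v) for k, v in brute.items()
        }


class TestDeterminism:
    def test_byte_identical_csv_exports(self, tmp_path, fixture_config):
        out = []
        for i in range(2):
            store = build_store(fixture_config)
            path = tmp_path / f"funnel{i}.csv"
            triage_funnel(store).table.to_csv(path)
            out.append(path.read_bytes())
            store.close()
        assert out[0] == out[1]
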