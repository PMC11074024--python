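# trialscape

A semi-automated pipeline for landscape analyses of clinical-trial registry
metadata. It harvests study records for a configurable drug list from the
classic clinicaltrials.gov `study_fields` JSON endpoint (or from saved
snapshot files), normalizes the registry's messy fields, manages manual
curation annotations (drug role, use case, repurposing flag, publication
status), and computes the full battery of landscape analytics: drug/role
counts, start and first-posted timelines, registration lag, status / age /
sex distributions, country aggregation, publication-bias cross-tabs, and a
repurposing triage funnel.

## Modules

| module | purpose |
| --- | --- |
| `trialscape.ingest` | search-expression building, paged retrieval, snapshot save/load |
| `trialscape.normalize` | singleton flattening, age/date/sex transformers, term dictionaries, typed records |
| `trialscape.curation` | SQLite single-source-of-truth store, annotation CSV round-trip, SQL-dump backup, snapshot diffing |
| `trialscape.analytics` | long-format summary tables behind every landscape figure |
| `trialscape.fixtures` | seeded synthetic snapshot generator with planted ground truth |
| `trialscape.cli` | `trialscape` command-line front door |

## CLI

Offline-first end-to-end run on a synthetic fixture:

```sh
trialscape simulate --seed 1 --n 200 --out-snapshot snap.json --out-annotations ann.csv
trialscape process --snapshot snap.json --store store.db
trialscape annotate-import --store store.db --csv ann.csv
trialscape analyze --store store.db --table funnel --out funnel.csv
```

Other commands: `download` (reads a saved snapshot unless `--live` opts in to
the network), `annotate-export`, `check-updates --old a.json --new b.json`,
`backup` / `restore`. Every run writes a provenance line (timestamp, command,
config hash) to stderr.

Snapshot files use the classic `StudyFieldsResponse` JSON envelope, so saved
live pulls and synthetic fixtures are interchangeable. Annotation CSVs carry
the header
`nct_id,primary_drug,additional_drugs,legacy_search_term,use_case,drug_role,repurposing,publication_status,publication_ref,notes`
and are imported all-or-nothing after validating every row.

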