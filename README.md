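# fieldform

A library and CLI for running structured field-survey projects of the kind
used in epidemiological and citizen-science data gathering: a project is a
chain of questionnaire forms linked one-to-many (school → class → pupil),
optionally with *branch* forms hanging off specific questions (record each
teacher absence for a class), collected on many devices and synchronised to
a single central store.

It is aimed at people who need the data-management core of a mobile
collection workflow — form definition, skip logic, validation, key-linked
storage, sync, export — as plain, testable Python, without any device or
web UI.

## What it does

- **Declarative project definitions.** A project is one XML document (or an
  equivalent JSON mirror): forms in hierarchy order, each field with its
  kind (text, long text, dropdown, checkbox, radio, location, image, video,
  audio, barcode, branch trigger), choices, validation rules and jump
  clauses. Unknown elements/attributes round-trip untouched, so the
  vocabulary stays extensible. A bundled XSD/JSON Schema describes the core
  dialect.
- **Interview sessions with skip logic.** Fields are asked in order; a jump
  clause on a dropdown/radio field sends the interview to a later field (or
  the end) when its answer is among the clause's trigger values — first
  matching clause wins, jumps are forward-only, so every interview
  terminates in at most one visit per field.
- **Validation.** required, integer/decimal with min/max ranges, datetime
  formats such as `dd/mm/yyyy` and `mm:ss`, regular-expression patterns
  (e.g. checking a scanned barcode's prefix), and double entry — the value
  typed twice and cross-checked for equality. All rule violations for a
  submission are reported together.
- **Keys and integrity.** Each entry carries a key, either a designated
  text/barcode field or an auto key `<device uuid>_<entry time in ms>`. A
  store only accepts an entry whose parent key already resolves, and
  rejects duplicate keys within the same (form, parent) scope — which makes
  re-submission idempotent.
- **Sync.** Client stores batch entries top-down (level 1 first, branch
  entries right after their host) so no child arrives before its parent;
  rejected entries are retried and sync converges to the union of client
  entries. Image thumbnails transfer immediately, full media defer by
  policy.
- **Pre-load, filter, chart, export.** Pull all entries at-and-above a
  hierarchy level onto a fresh device; filter entries by time window and
  choice values; count answer distributions for chartable fields; export
  per-form CSV/TSV (RFC-4180 quoting) or a nested XML document, both of
  which re-import losslessly. Entries can also be ingested through the same
  validation pipeline from a web-style submission.

## Worked example

```
$ fieldform fixtures schools-demo --out project.xml
$ fieldform validate project.xml
ok

$ cat class.tsv                      # scripted interview: one answer per line
class_name	5B
class_size	30
teacher_name	Ms June
record_absences	2
[branch]
reason	illness
days	3
[/branch]
[branch]
reason	training
days	1
[/branch]

$ fieldform collect project.xml --form school --script school.tsv --store client.xml
school entry 'Hilltop Primary': accepted
$ fieldform collect project.xml --form class --script class.tsv \
      --store client.xml --parent-key "Hilltop Primary"
class entry '5B': accepted
absence entry 'cli_1790142588335': accepted
absence entry 'cli_1790142588337': accepted

$ fieldform sync client.xml --project project.xml --server server.xml
converged in 1 round(s); server now holds 4 entries

$ fieldform export server.xml --project project.xml --form class --format csv
entry_id,created_at,device_id,parent_key,key,class_name,class_size,teacher_name,record_absences
cli_1790142588338,2026-09-23T05:49:48.338Z,cli,Hilltop Primary,5B,5B,30,Ms June,2
```

Reading the output: the class entry is keyed `5B` and linked to its parent
school through `parent_key`; answering `2` to the absence question paused
the interview for two branch sub-sessions, whose entries got auto keys
(device id + creation time in ms) and the class's key as their parent. The
sync round delivered school before class before absences, so nothing
arrived as an orphan.

The same flows are available as a library — see `fieldform.start_session`,
`submit_answer`, `finalize_entry`, `EntryStore.insert_entry`,
`build_batches` / `apply_batch`, `export_table` / `export_xml`, and the
generators in `fieldform.fixtures`.

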