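# Methods

## The data-collection model

A project is a non-empty ordered list of forms. The *hierarchy* forms make
a strict linear chain — form *k+1*'s entries each reference one parent
entry of form *k* through its key — which captures the one-to-many pattern
of survey work (each school has many classes, each class many pupils).
*Branch* forms attach to a single `branch_trigger` question of one host
form and are filled 0..n times per host entry; they exist precisely for
data whose multiplicity is unknown in advance (a teacher may have had no
absences or several), which cannot be modelled as a hierarchy level
(that would force at least one entry per parent). General form trees are
deliberately out of scope: the linear chain plus one level of branching
covers the worked use cases, and nesting branches would complicate sync
ordering for no modelled need.

Each field has a kind, optional choices (`name` shown, `value` stored),
validation rules and jump clauses. Jumps are restricted to dropdown/radio
fields — the only kinds whose answer is a single choice value — and are
forward-only: a clause's destination must be strictly later in the form (or
`END`). Forward-only jumps give a hard termination bound (each field is
visited at most once per interview) and make "first declared matching
clause wins" a complete, order-independent semantics for overlapping
clauses.

## Validation semantics

Rules are applied in a fixed order — required, type/choice membership,
numeric parse, min/max, datetime format, regex, double-entry equality — and
all violations are collected rather than stopping at the first, because a
field worker fixing an entry should see every problem at once. Decisions
worth noting:

- **Blank optional fields** are *skipped*: no answer is stored, exports
  render an empty cell. Storing explicit nulls would make "unanswered" and
  "answered empty" indistinguishable in chart denominators.
- **Double entry** compares the two submissions byte-for-byte after
  stripping leading/trailing whitespace, case-sensitively ("identical"
  means identical).
- **Regex failures** are hard errors by default; `regex_mode="warn"`
  downgrades them to warnings that accompany an accepted answer, matching
  the barcode use case where a wrong-prefix scan should warn rather than
  block.
- **Datetime formats** are display-style patterns translated to `strptime`
  (`dd/mm/yyyy` → `%d/%m/%Y`). `mm` is read as month when the pattern also
  contains a day or year token, minutes otherwise (`mm:ss`).
- **Numeric text answers** are stored as parsed numbers (int/float), so
  range checks and exports are canonical; everything else stores the raw
  (stripped) string.
- **Locations** are four numbers `lat;lon;alt;accuracy` (degrees, metres);
  only plausibility of latitude/longitude is checked. **Media** answers are
  references (paths/URIs), never payloads; image answers derive a thumbnail
  reference.

## Keys, ids and clocks

An entry's key is either the value of a designated text/barcode field or an
auto key `<device uuid>_<creation ms>` — the underscore keeps the two parts
recoverable. Entry ids are `<device>_<creation ms>`. Both are unique only
if a device never stamps two entries in the same millisecond, so clocks are
injected and required to be strictly increasing: `ManualClock` (start,
step) for deterministic runs, and a process-wide monotonic wall clock for
the CLI. Nothing reads host time or hardware identifiers implicitly.

Key uniqueness is enforced per (form, parent) scope, not globally: two
classes named "5B" in different schools are legal, two in the same school
are not. A consequence: a branch entry's `parent_key` (the host's key
value) can in principle match hosts under different parents; integrity is
satisfied by any match. Globally unique keys would break the natural
worked examples, and auto keys are globally unique anyway.

Branch sub-sessions may finish before their host's key exists (the host key
field may be answered after the trigger, or be AUTO), so branch entries are
sealed with a pending parent and stamped with the host's key at host
finalisation.

## Stores and sync

`insert_entry` accepts an entry iff its parent resolves (or it is top
level) and its scoped key is new; failures are reported
(`orphan`/`duplicate`), never raised. Duplicate rejection is what makes
re-submission idempotent. `insert_with_branches` is the client-side helper
that walks a host's attached children; sync batches instead list branch
entries explicitly after their host, and the server inserts shallow copies,
so batch application never double-counts children.

Batches are built one per hierarchy level, top level first, containing
every unsynced entry exactly once. Applying batches in build order can
therefore never create an orphan; applied out of order, rejected entries
simply remain queued and reappear next round, and repeated rounds converge
to server = union of clients (each round strictly shrinks the unsynced set
whose parents are present). Conflicting user-chosen keys from different
devices resolve first-writer-wins; the loser is reported `duplicate`.

Media plans: `default` sends image thumbnails immediately and defers full
images, video and audio; `send_all` defers nothing; `defer_all` sends only
thumbnails. Thumbnails are never deferred.

Transport is an in-process pair of operations (`SyncServer.fetch_project`,
`SyncServer.submit`); the library is the contract, and no networking is
involved anywhere.

## Serialisation

The XML dialect is one attribute-rich element per concept (`project`,
`form`, `field`, `choice`, `jump`) with a fixed attribute order and
defaults omitted, so serialisation is canonical: writing the same project
twice is byte-identical, `parse ∘ write` is the identity, and
`write ∘ parse` is idempotent after one pass. Unknown attributes and child
elements are preserved verbatim (extensibility is a design requirement);
the bundled XSD describes the core dialect, with foreign-namespace
extension points. Documents are UTF-8 only. Pattern strings are opaque at
parse time — regex compilation happens in the engine, so parsing untrusted
documents executes nothing.

Table exports use the `csv` module with RFC-4180-style quoting and CRLF
rows; `created_at` exports as ISO-8601 UTC with milliseconds and re-parses
exactly (the epoch-ms value is also kept as an XML attribute). The checkbox
and location separator is `;`; a choice *value* containing `;` would be
ambiguous in exports and is best avoided in project designs (values are
author-chosen codes, not free text). Imports re-run the full validation
pipeline cell by cell, so a tampered file fails loudly.

## Synthetic data

`schools_demo_project()` is the fixed demonstration project (3 levels plus
an absence branch, covering text, numeric, choice, image, location, audio
and double-entered pattern-checked barcode fields). `random_project(seed,…)`
generates structurally valid projects covering every field kind and rule;
regex rules are drawn from a small catalogue of patterns paired with
conforming-string generators, so `simulate_collection` can always produce
rule-satisfying answers (arbitrary-regex string synthesis is deliberately
not attempted). `simulate_collection` drives real engine sessions — it
cannot bypass validation — with one seeded RNG stream and one ticking clock
per device, giving byte-identical serialised stores per seed.

What the generators do *not* emulate: realistic answer distributions,
entry-rate patterns, device failures mid-session, media payload bytes, or
concurrent edits to one store. Passing tests therefore demonstrate the
logical contracts (routing, validation, integrity, convergence,
round-trips), not robustness to messy real-world streams.

## Problem sizes

The test suite and the acceptance script use: 100 seeded projects for
round-trip identity and 50 seeded stores for the export fixed point; 500
random choice-only forms (≤ 6 fields × ≤ 3 choices) checked exhaustively
over every answer combination (~4·10⁴ interviews) against an independent
naive clause-scanning interpreter; 20 three-device sync scenarios with
shuffled, partial and duplicated batch deliveries; and 10⁴ (device, ms)
pairs for key uniqueness. These sizes exercise every code path many times
while keeping the whole suite in a few seconds.

## Known limitations

- Branch entries can only be added inline while the host session is paused
  at the trigger; there is no post-hoc attachment.
- A jump may skip a required field; a skipped field is not "missing" at
  finalisation. Whether that is desirable is a form-design question.
- Web-path submissions record a branch trigger's count but attach no
  branch entries.
- The store is single-writer; there are no concurrent transactions.
- The number of chartable fields is not limited.
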