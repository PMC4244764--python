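"""Hierarchical entry repository.

The store enforces the two integrity rules that make one-to-many collection
safe: an entry below the top of the hierarchy is only accepted when its
parent entry is already present, and a key that already exists under the
same (form, parent) scope is rejected as a duplicate — which is exactly what
makes re-submission of the same entry idempotent.

Key uniqueness is scoped per (form, parent): two classes named "5B" in two
different schools are legal; two in the same school are not.

Timestamps are UTC epoch milliseconds throughout; the temporal filter is
closed on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .form_engine import Answer, Entry
from .project_model import BranchRole, CHOICE_KINDS, Form, Project


@dataclass
class Filter:
    """Entry filter: an optional closed time window plus any number of
    choice-field filters (checkbox fields match when the selection
    intersects the accepted set)."""

    time_window: tuple[int, int] | None = None
    choice_filters: list[tuple[str, set[str]]] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.time_window is not None and self.time_window[0] > self.time_window[1]:
            raise ValueError("time window start is after its end")


@dataclass
class InsertResult:
    accepted: bool
    reason: str | None = None  # orphan | duplicate when rejected

    def __bool__(self) -> bool:
        return self.accepted


class StoreError(ValueError):
    pass


class EntryStore:
    """Per-form collections of entries with referential-integrity checks on
    insert. Insertion order is preserved per form."""

    def __init__(self, project: Project):
        self.project = project
        self.entries: dict[str, list[Entry]] = {f.form_id: [] for f in project.forms}
        # (form_id, parent_key or "", key_value) -> entry
        self._index: dict[tuple[str, str, str], Entry] = {}
        self.synced: set[str] = set()  # entry ids acknowledged by the server

    # -- basic queries ----------------------------------------------------

    def form_entries(self, form_id: str) -> list[Entry]:
        if form_id not in self.entries:
            raise StoreError(f"no form {form_id!r} in project {self.project.name!r}")
        return list(self.entries[form_id])

    def lookup(self, form_id: str, key_value: str, parent_key: str | None = None) -> Entry | None:
        if parent_key is not None:
            return self._index.get((form_id, parent_key, key_value))
        for e in self.entries.get(form_id, []):
            if e.key_value == key_value:
                return e
        return None

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def all_entries(self) -> list[Entry]:
        out: list[Entry] = []
        for form in self.project.forms:
            out.extend(self.entries[form.form_id])
        return out

    # -- insertion --------------------------------------------------------

    def insert_entry(self, entry: Entry) -> InsertResult:
        """Insert one entry. Accepted iff its parent exists (or it is top
        level) and its key is not already present in its (form, parent)
        scope. Never raises for integrity problems — they are reported."""
        if entry.form_id not in self.entries:
            raise StoreError(f"entry belongs to unknown form {entry.form_id!r}")
        form = self.project.get_form(entry.form_id)

        parent_form_id = self._parent_form_id(form)
        if parent_form_id is not None:
            if not entry.parent_key:
                return InsertResult(False, "orphan")
            if not self._parent_exists(parent_form_id, entry.parent_key):
                return InsertResult(False, "orphan")

        scope = (entry.form_id, entry.parent_key or "", entry.key_value)
        if scope in self._index:
            return InsertResult(False, "duplicate")

        self.entries[entry.form_id].append(entry)
        self._index[scope] = entry
        return InsertResult(True)

    def insert_with_branches(self, entry: Entry) -> list[tuple[Entry, InsertResult]]:
        """Insert a host entry followed by its attached branch children.
        Returns the per-entry outcomes in insertion order."""
        results = [(entry, self.insert_entry(entry))]
        for children in entry.branch_children.values():
            for child in children:
                results.append((child, self.insert_entry(child)))
        return results

    def _parent_form_id(self, form: Form) -> str | None:
        if isinstance(form.role, BranchRole):
            return form.role.host_form
        if form.role.level >= 2:
            chain = self.project.hierarchy_forms()
            return chain[form.role.level - 2].form_id
        return None

    def _parent_exists(self, parent_form_id: str, parent_key: str) -> bool:
        return any(e.key_value == parent_key for e in self.entries[parent_form_id])

    # -- integrity audit ---------------------------------------------------

    def check_integrity(self) -> list[str]:
        """Full referential-integrity audit; returns a list of problems
        (empty when the store is sound). Usable after any operation
        sequence."""
        problems: list[str] = []
        seen: set[tuple[str, str, str]] = set()
        for form in self.project.forms:
            parent_form_id = self._parent_form_id(form)
            for e in self.entries[form.form_id]:
                scope = (e.form_id, e.parent_key or "", e.key_value)
                if scope in seen:
                    problems.append(f"duplicate key {e.key_value!r} in {e.form_id!r}")
                seen.add(scope)
                if parent_form_id is not None:
                    if not e.parent_key or not self._parent_exists(parent_form_id, e.parent_key):
                        problems.append(
                            f"orphan entry {e.entry_id!r} in {e.form_id!r} (parent {e.parent_key!r})"
                        )
        return problems


# ---------------------------------------------------------------------------
# Level pre-loading
# ---------------------------------------------------------------------------

def preload(store: EntryStore, level: int) -> list[Entry]:
    """All entries of hierarchy levels 1..level (no branch entries, nothing
    below), ordered level-then-insertion: what a freshly provisioned device
    receives so collection can resume mid-project."""
    chain = store.project.hierarchy_forms()
    if not 1 <= level <= len(chain):
        raise StoreError(f"level {level} out of range 1..{len(chain)}")
    out: list[Entry] = []
    for form in chain[:level]:
        out.extend(store.entries[form.form_id])
    return out


# ---------------------------------------------------------------------------
# Filtering and chart aggregation
# ---------------------------------------------------------------------------

def query(store: EntryStore, form_id: str, filt: Filter | None = None) -> list[Entry]:
    """Entries of a form passing the time window AND every choice filter,
    in stable (insertion) order."""
    entries = store.form_entries(form_id)
    if filt is None:
        return entries
    form = store.project.get_form(form_id)
    for field_id, _ in filt.choice_filters:
        fld = form.get_field(field_id)  # KeyError for unknown fields
        if fld.kind not in CHOICE_KINDS:
            raise StoreError(f"filter field {field_id!r} is kind {fld.kind!r}, not a choice field")
    out = []
    for e in entries:
        if filt.time_window is not None:
            lo, hi = filt.time_window
            if not lo <= e.created_at <= hi:
                continue
        if all(_matches(e.answers.get(fid), accepted) for fid, accepted in filt.choice_filters):
            out.append(e)
    return out


def _matches(answer: Answer | None, accepted: set[str]) -> bool:
    if answer is None:
        return False
    if isinstance(answer.value, tuple):  # checkbox: intersection non-empty
        return bool(set(answer.value) & accepted)
    return answer.value in accepted


def chart_counts(
    store: EntryStore, form_id: str, field_id: str, filt: Filter | None = None
) -> dict[str, int]:
    """Answer distribution of a dropdown/checkbox/radio field over (filtered)
    entries, for pie/bar charts. Every declared choice value appears, with 0
    when unused; a checkbox answer contributes to each selected value.
    Entries that skipped the field are not counted."""
    form = store.project.get_form(form_id)
    fld = form.get_field(field_id)
    if fld.kind not in CHOICE_KINDS:
        raise StoreError(f"chart field {field_id!r} is kind {fld.kind!r}, not a choice field")
    counts = {v: 0 for v in fld.choice_values()}
    for e in query(store, form_id, filt):
        ans = e.answers.get(field_id)
        if ans is None:
            continue
        values = ans.value if isinstance(ans.value, tuple) else (ans.value,)
        for v in values:
            counts[v] += 1  # generated answers are validated, so v is declared
    return counts


# ---------------------------------------------------------------------------
# Persistence (single on-disk document, same dialect family as exports)
# ---------------------------------------------------------------------------

def save_store(store: EntryStore, path: str) -> None:
    from .export_import import export_xml

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(export_xml(store))


def load_store(project: Project, path: str) -> EntryStore:
    from .export_import import import_xml

    with open(path, "r", encoding="utf-8") as fh:
        return import_xml(project, fh.read())
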