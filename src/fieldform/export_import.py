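"""Export entries as delimited text or nested XML, and ingest entries back —
including entries typed directly into the web interface rather than a phone.

Table exports are flat, one row per entry of one form: five fixed columns
(entry_id, created_at, device_id, parent_key, key) then the form's fields in
declared order. Checkbox selections join with ";", locations serialise as
``lat;lon;alt;accuracy``, media cells carry the stored URI/path, and fields
a jump skipped are empty cells. CSV uses RFC-4180-style quoting, so commas
and quotes inside values round-trip.

The XML export nests entries by hierarchy (school elements contain class
elements contain pupil elements; branch entries nest under their host), and
is the same document family the store persists to — export, import and
export again is byte-identical.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io

from lxml import etree

from .datastore import EntryStore, InsertResult
from .form_engine import (
    Answer,
    Entry,
    Location,
    MediaRef,
    check_answer,
    next_field,
)
from .project_model import END, Field, Form, Project

FIXED_COLUMNS = ("entry_id", "created_at", "device_id", "parent_key", "key")

_CHECKBOX_SEP = ";"


# ---------------------------------------------------------------------------
# Cell rendering / parsing (the raw-string form the engine validates)
# ---------------------------------------------------------------------------

def render_answer(answer: Answer | None) -> str:
    """Render an answer as the raw string the validation pipeline accepts,
    so exported values re-validate on import. Skipped fields render empty."""
    if answer is None:
        return ""
    v = answer.value
    if isinstance(v, tuple):
        return _CHECKBOX_SEP.join(v)
    if isinstance(v, Location):
        return _CHECKBOX_SEP.join(_fmt_num(x) for x in (v.lat, v.lon, v.alt, v.accuracy))
    if isinstance(v, MediaRef):
        return v.uri
    if isinstance(v, float):
        return _fmt_num(v)
    return str(v)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def format_timestamp(ms: int) -> str:
    """Epoch milliseconds -> ISO-8601 UTC with millisecond precision."""
    sec, frac = divmod(int(ms), 1000)
    dt = _dt.datetime.fromtimestamp(sec, tz=_dt.timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S") + f".{frac:03d}Z"


def parse_timestamp(text: str) -> int:
    dt = _dt.datetime.strptime(text, "%Y-%m-%dT%H:%M:%S.%fZ").replace(tzinfo=_dt.timezone.utc)
    return int(round(dt.timestamp() * 1000))


# ---------------------------------------------------------------------------
# Delimited-text export / import
# ---------------------------------------------------------------------------

def export_table(store: EntryStore, form_id: str, format: str = "csv") -> str:
    """One row per entry of ``form_id``; ``format`` is ``csv`` or ``tsv``."""
    if format not in ("csv", "tsv"):
        raise ValueError(f"format must be csv or tsv, got {format!r}")
    form = store.project.get_form(form_id)
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="," if format == "csv" else "\t", lineterminator="\r\n")
    writer.writerow(list(FIXED_COLUMNS) + form.field_ids())
    for e in store.form_entries(form_id):
        row = [
            e.entry_id,
            format_timestamp(e.created_at),
            e.device_id,
            e.parent_key or "",
            e.key_value,
        ]
        for fld in form.fields:
            row.append(render_answer(e.answers.get(fld.field_id)))
        writer.writerow(row)
    return buf.getvalue()


def import_table(store: EntryStore, form_id: str, text: str, format: str = "csv") -> list[InsertResult]:
    """Parse a table export back into entries and insert them (in row
    order). Values re-run the validation pipeline, so a tampered file fails
    loudly rather than silently storing bad data."""
    if format not in ("csv", "tsv"):
        raise ValueError(f"format must be csv or tsv, got {format!r}")
    form = store.project.get_form(form_id)
    reader = csv.reader(io.StringIO(text), delimiter="," if format == "csv" else "\t")
    rows = list(reader)
    if not rows:
        raise ValueError("empty table document")
    header = rows[0]
    expected = list(FIXED_COLUMNS) + form.field_ids()
    if header != expected:
        raise ValueError(f"unexpected header {header!r}; expected {expected!r}")
    results = []
    for row in rows[1:]:
        if not row:
            continue
        entry = _entry_from_cells(form, row)
        results.append(store.insert_entry(entry))
    return results


def _entry_from_cells(form: Form, row: list[str]) -> Entry:
    fixed, cells = row[: len(FIXED_COLUMNS)], row[len(FIXED_COLUMNS):]
    answers: dict[str, Answer] = {}
    for fld, cell in zip(form.fields, cells):
        if cell == "":
            continue
        answers[fld.field_id] = _revalidate(fld, cell)
    return Entry(
        entry_id=fixed[0],
        form_id=form.form_id,
        key_value=fixed[4],
        parent_key=fixed[3] or None,
        created_at=parse_timestamp(fixed[1]),
        device_id=fixed[2],
        answers=answers,
    )


def _revalidate(fld: Field, cell: str) -> Answer:
    raw = (cell, cell) if fld.double_entry else cell
    answer, issues = check_answer(fld, raw)
    errors = [i for i in issues if i.severity == "error"]
    if errors or answer is None:
        msgs = "; ".join(i.message for i in errors) or "blank value"
        raise ValueError(f"field {fld.field_id!r}: {msgs}")
    return answer


# ---------------------------------------------------------------------------
# Nested XML export / import
# ---------------------------------------------------------------------------

def export_xml(store: EntryStore, form_id: str | None = None) -> str:
    """Nested entry document: children of the hierarchy nest under their
    parent entry, branch entries nest under their host. With ``form_id`` the
    export is restricted to that form's subtree roots."""
    project = store.project
    root = etree.Element("entries")
    root.set("project", project.name)
    chain = [f.form_id for f in project.hierarchy_forms()]
    start_forms = chain if form_id is None else [form_id]
    top = start_forms[0]
    for e in store.form_entries(top):
        root.append(_entry_element(store, e, chain))
    blob = etree.tostring(root, encoding="UTF-8", xml_declaration=True, pretty_print=True)
    return blob.decode("utf-8")


def _entry_element(store: EntryStore, entry: Entry, chain: list[str]) -> etree._Element:
    el = etree.Element("entry")
    el.set("id", entry.entry_id)
    el.set("form", entry.form_id)
    el.set("key", entry.key_value)
    if entry.parent_key is not None:
        el.set("parent", entry.parent_key)
    el.set("created", str(entry.created_at))
    el.set("created-iso", format_timestamp(entry.created_at))
    el.set("device", entry.device_id)
    form = store.project.get_form(entry.form_id)
    for fld in form.fields:
        ans = entry.answers.get(fld.field_id)
        if ans is None:
            continue
        ael = etree.SubElement(el, "answer")
        ael.set("field", fld.field_id)
        ael.set("value", render_answer(ans))
    # branch entries nest under their host
    from .project_model import branches_of

    for _, branch_form_id in branches_of(store.project, entry.form_id):
        for be in store.form_entries(branch_form_id):
            if be.parent_key == entry.key_value:
                el.append(_entry_element(store, be, chain))
    # hierarchy children nest under their parent
    if entry.form_id in chain:
        level = chain.index(entry.form_id)
        if level + 1 < len(chain):
            child_form = chain[level + 1]
            for ce in store.form_entries(child_form):
                if ce.parent_key == entry.key_value:
                    el.append(_entry_element(store, ce, chain))
    return el


def import_xml(project: Project, text: str) -> EntryStore:
    """Rebuild a store from a nested entry document. Entries insert parents
    before children by construction of the nesting."""
    root = etree.fromstring(text.encode("utf-8") if isinstance(text, str) else text)
    if root.tag != "entries":
        raise ValueError(f"root element must be <entries>, got <{root.tag}>")
    if root.get("project") != project.name:
        raise ValueError(
            f"document is for project {root.get('project')!r}, not {project.name!r}"
        )
    store = EntryStore(project)
    for el in root:
        if isinstance(el.tag, str) and el.tag == "entry":
            _import_entry_element(store, el)
    return store


def _import_entry_element(store: EntryStore, el: etree._Element) -> None:
    form = store.project.get_form(el.get("form", ""))
    answers: dict[str, Answer] = {}
    for ael in el:
        if isinstance(ael.tag, str) and ael.tag == "answer":
            fld = form.get_field(ael.get("field", ""))
            answers[fld.field_id] = _revalidate(fld, ael.get("value", ""))
    entry = Entry(
        entry_id=el.get("id", ""),
        form_id=form.form_id,
        key_value=el.get("key", ""),
        parent_key=el.get("parent"),
        created_at=int(el.get("created", "0")),
        device_id=el.get("device", ""),
        answers=answers,
    )
    res = store.insert_entry(entry)
    if not res.accepted:
        raise ValueError(f"entry {entry.entry_id!r} rejected on import: {res.reason}")
    for cel in el:
        if isinstance(cel.tag, str) and cel.tag == "entry":
            _import_entry_element(store, cel)


# ---------------------------------------------------------------------------
# Web-path entry
# ---------------------------------------------------------------------------

def import_web_entry(
    store: EntryStore,
    form_id: str,
    answers: dict[str, str | tuple[str, str]],
    parent_key: str | None = None,
    *,
    clock,
    regex_mode: str = "error",
) -> tuple[Entry | None, dict[str, list], InsertResult | None]:
    """Enter one entry through the web path: the same field-by-field
    validation pipeline as the phone, with the jump logic deciding which
    fields are asked; ``device_id`` is fixed to ``"web"``. Media answers are
    uploaded-file references and barcodes arrive as decoded text.

    Returns ``(entry, field_errors, insert_result)``: on any validation
    failure nothing is inserted and ``field_errors`` maps field ids to their
    errors. Branch triggers answered through the web record their count but
    attach no branch entries.
    """
    form = store.project.get_form(form_id)
    field_errors: dict[str, list] = {}
    collected: dict[str, Answer] = {}
    cursor = form.fields[0].field_id
    while cursor != END:
        fld = form.get_field(cursor)
        raw = answers.get(cursor, "")
        answer, issues = check_answer(fld, raw, regex_mode=regex_mode)
        errors = [i for i in issues if i.severity == "error"]
        if errors:
            field_errors[cursor] = errors
            answer = None
        elif answer is not None:
            collected[cursor] = answer
        cursor = next_field(form, cursor, answer)
    if field_errors:
        return None, field_errors, None

    from .form_engine import generate_auto_key
    from .project_model import AUTO

    created_at = int(clock())
    if form.key_field == AUTO:
        key_value = generate_auto_key("web", created_at)
    else:
        key_ans = collected.get(form.key_field)
        if key_ans is None or str(key_ans.value) == "":
            field_errors[form.key_field] = [("required", "key field must be answered")]
            return None, field_errors, None
        key_value = str(key_ans.value)
    entry = Entry(
        entry_id=f"web_{created_at}",
        form_id=form_id,
        key_value=key_value,
        parent_key=parent_key,
        created_at=created_at,
        device_id="web",
        answers=collected,
    )
    return entry, {}, store.insert_entry(entry)
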