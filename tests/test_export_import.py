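"""Exports, imports, the web entry path, positional integrity."""

import random

import pytest

import fieldform as ff


@pytest.fixture
def populated(schools):
    return ff.simulate_collection(schools, n_devices=1, entries_per_level=2, seed=17)[0]


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def test_column_count_five_fixed_plus_fields():
    p = ff.Project(name="p", title="P", version="1", forms=[
        ff.Form("f", "F", [
            ff.Field(f"q{i}", "text", f"Q{i}", validation=ff.ValidationSpec(required=True))
            for i in range(1, 6)
        ], key_field="q1")])
    store = ff.EntryStore(p)
    clock = ff.ManualClock()
    for k in ("one", "two"):
        s = ff.start_session(p, "f", device_id="dev", clock=clock)
        for i in range(1, 6):
            ff.submit_answer(s, f"{k}-{i}")
        store.insert_entry(ff.finalize_entry(s))
    import csv as _csv
    import io

    rows = list(_csv.reader(io.StringIO(ff.export_table(store, "f", "csv"))))
    assert len(rows) == 3  # header + 2 entries
    assert all(len(r) == 10 for r in rows)  # 5 fixed + 5 fields


def test_empty_form_exports_header_only(schools):
    store = ff.EntryStore(schools)
    text = ff.export_table(store, "school", "csv")
    lines = text.splitlines()
    assert len(lines) == 1
    assert lines[0].startswith("entry_id,created_at,device_id,parent_key,key,school_name")


def test_comma_and_quote_values_roundtrip(schools):
    store = ff.EntryStore(schools)
    clock = ff.ManualClock()
    s = ff.start_session(schools, "school", device_id="dev", clock=clock)
    tricky = 'St "Mary\'s", The Hill'
    ff.submit_answer(s, tricky)
    ff.submit_answer(s, "state")
    ff.submit_answer(s, "mixed")
    ff.submit_answer(s, "12")
    ff.submit_answer(s, "250")
    ff.submit_answer(s, "media/s.jpg")
    ff.submit_answer(s, "51.5;-0.1;30;5")
    store.insert_entry(ff.finalize_entry(s))
    text = ff.export_table(store, "school", "csv")
    fresh = ff.EntryStore(schools)
    results = ff.import_table(fresh, "school", text, "csv")
    assert all(r.accepted for r in results)
    back = fresh.form_entries("school")[0]
    assert back.key_value == tricky
    assert back.answers["school_name"].value == tricky
    assert ff.export_table(fresh, "school", "csv") == text


def test_tsv_roundtrip(populated, schools):
    text = ff.export_table(populated, "class", "tsv")
    fresh = ff.EntryStore(schools)
    # classes need their schools first
    ff.import_table(fresh, "school", ff.export_table(populated, "school", "tsv"), "tsv")
    results = ff.import_table(fresh, "class", text, "tsv")
    assert all(r.accepted for r in results)
    assert ff.export_table(fresh, "class", "tsv") == text


def test_table_roundtrip_preserves_all_field_kinds(populated, schools):
    fresh = ff.EntryStore(schools)
    for form_id in ff.hierarchy_chain(schools):
        text = ff.export_table(populated, form_id, "csv")
        ff.import_table(fresh, form_id, text, "csv")
        orig = populated.form_entries(form_id)
        back = fresh.form_entries(form_id)
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert (a.entry_id, a.key_value, a.parent_key, a.created_at) == \
                (b.entry_id, b.key_value, b.parent_key, b.created_at)
            assert a.answers == b.answers


def test_skipped_fields_export_as_empty_cells():
    p = ff.Project(name="p", title="P", version="1", forms=[
        ff.Form("f", "F", [
            ff.Field("q1", "dropdown", "Q1",
                     choices=[ff.Choice("A", "a"), ff.Choice("B", "b")],
                     jumps=[ff.JumpClause(("a",), "q3")],
                     validation=ff.ValidationSpec(required=True)),
            ff.Field("q2", "text", "Q2"),
            ff.Field("q3", "text", "Q3", validation=ff.ValidationSpec(required=True)),
        ], key_field=ff.AUTO)])
    store = ff.EntryStore(p)
    s = ff.start_session(p, "f", device_id="dev", clock=ff.ManualClock())
    ff.submit_answer(s, "a")
    ff.submit_answer(s, "end")
    store.insert_entry(ff.finalize_entry(s))
    row = ff.export_table(store, "f", "csv").splitlines()[1]
    assert row.endswith(",a,,end")  # q2 skipped -> empty cell


def test_header_mismatch_rejected(populated, schools):
    text = ff.export_table(populated, "school", "csv")
    with pytest.raises(ValueError, match="header"):
        ff.import_table(ff.EntryStore(schools), "class", text, "csv")


# ---------------------------------------------------------------------------
# Nested XML
# ---------------------------------------------------------------------------

def test_xml_nesting_depth_three_for_pupils(populated):
    from lxml import etree

    root = etree.fromstring(ff.export_xml(populated).encode())
    pupil_depths = {
        len([a for a in el.iterancestors() if a.tag == "entry"])
        for el in root.iter("entry") if el.get("form") == "pupil"
    }
    assert pupil_depths == {2}  # school > class > pupil
    absence_parents = {
        next(el.iterancestors()).get("form")
        for el in root.iter("entry") if el.get("form") == "absence"
    }
    assert absence_parents <= {"class"}


def test_single_top_level_entry_exports_one_element(schools):
    store = ff.EntryStore(schools)
    s = ff.start_session(schools, "school", device_id="dev", clock=ff.ManualClock())
    for raw in ("Hilltop Primary", "state", "mixed", "9", "120", "media/h.jpg", "0;0;0;1"):
        ff.submit_answer(s, raw)
    store.insert_entry(ff.finalize_entry(s))
    from lxml import etree

    root = etree.fromstring(ff.export_xml(store).encode())
    entries = root.findall("entry")
    assert len(entries) == 1
    assert entries[0].findall("entry") == []


def test_export_import_export_fixed_point(schools):
    for seed in range(5):
        store = ff.simulate_collection(schools, 1, 2, seed=seed)[0]
        x1 = ff.export_xml(store)
        x2 = ff.export_xml(ff.import_xml(schools, x1))
        assert x1 == x2


def test_import_rejects_wrong_project(populated):
    other = ff.random_project(1)
    with pytest.raises(ValueError, match="project"):
        ff.import_xml(other, ff.export_xml(populated))


# ---------------------------------------------------------------------------
# Web-path entries
# ---------------------------------------------------------------------------

def test_web_entry_linked_against_phone_collected_parent(populated, schools):
    """Lab-style workflow: a result entered via the web against a key that
    was collected by phone lower in the hierarchy."""
    clock = ff.ManualClock(start_ms=1_500_000_000_000)
    a_class = populated.form_entries("class")[0]
    entry, errors, res = ff.import_web_entry(
        populated, "pupil",
        {"name_audio": "uploads/name.3gp", "blood_barcode": ("SC-00042", "SC-00042")},
        parent_key=a_class.key_value, clock=clock,
    )
    assert errors == {}
    assert res.accepted
    assert entry.device_id == "web"
    assert populated.check_integrity() == []


def test_web_entry_invalid_integer_nothing_inserted(populated):
    n_before = len(populated)
    entry, errors, res = ff.import_web_entry(
        populated, "class",
        {"class_name": "9Z", "class_size": "thirty", "teacher_name": "X",
         "record_absences": "0"},
        parent_key=populated.form_entries("school")[0].key_value,
        clock=ff.ManualClock(),
    )
    assert entry is None and res is None
    assert "class_size" in errors
    assert len(populated) == n_before


def test_web_and_phone_entries_export_identically_modulo_fixed_columns(schools):
    answers = {"class_name": "7A", "class_size": "25", "teacher_name": "Mr Fig",
               "record_absences": "0"}
    clock = ff.ManualClock()
    store = ff.EntryStore(schools)
    s = ff.start_session(schools, "school", device_id="phone", clock=clock)
    for raw in ("Hilltop Primary", "state", "mixed", "9", "120", "media/h.jpg", "0;0;0;1"):
        ff.submit_answer(s, raw)
    store.insert_entry(ff.finalize_entry(s))

    phone = ff.start_session(schools, "class", "Hilltop Primary", device_id="phone", clock=clock)
    for fid in ("class_name", "class_size", "teacher_name", "record_absences"):
        ff.submit_answer(phone, answers[fid])
    store.insert_entry(ff.finalize_entry(phone))

    web_store = ff.EntryStore(schools)
    web_store.insert_entry(store.form_entries("school")[0])
    _, _, res = ff.import_web_entry(
        web_store, "class", dict(answers, class_name="7A"),
        parent_key="Hilltop Primary", clock=clock,
    )
    assert res.accepted
    phone_row = ff.export_table(store, "class", "csv").splitlines()[1].split(",")
    web_row = ff.export_table(web_store, "class", "csv").splitlines()[1].split(",")
    assert phone_row[5:] == web_row[5:]  # answer columns identical
    assert phone_row[:3] != web_row[:3]  # entry_id/timestamp/device differ


def test_web_entry_respects_jump_logic():
    p = ff.Project(name="p", title="P", version="1", forms=[
        ff.Form("f", "F", [
            ff.Field("q1", "dropdown", "Q1",
                     choices=[ff.Choice("A", "a"), ff.Choice("B", "b")],
                     jumps=[ff.JumpClause(("a",), ff.END)],
                     validation=ff.ValidationSpec(required=True)),
            ff.Field("q2", "text", "Q2", validation=ff.ValidationSpec(required=True)),
        ], key_field=ff.AUTO)])
    store = ff.EntryStore(p)
    # q2 is required but jumped over: the web path must not demand it
    entry, errors, res = ff.import_web_entry(
        store, "f", {"q1": "a"}, clock=ff.ManualClock())
    assert errors == {} and res.accepted
    assert "q2" not in entry.answers


# ---------------------------------------------------------------------------
# Positional integrity
# ---------------------------------------------------------------------------

def test_no_answer_under_wrong_column_on_seeded_stores(schools):
    """Re-parse exports and check each cell re-validates under its own
    column's field: a positional oracle over many random entries."""
    import csv as _csv
    import io

    rng = random.Random(0)
    checked = 0
    for seed in range(4):
        store = ff.simulate_collection(schools, 1, 2, seed=rng.randrange(10**6))[0]
        for form_id in ff.hierarchy_chain(schools) + ["absence"]:
            form = schools.get_form(form_id)
            text = ff.export_table(store, form_id, "csv")
            rows = list(_csv.reader(io.StringIO(text)))
            header = rows[0][5:]
            assert header == form.field_ids()
            for row in rows[1:]:
                for fld_id, cell in zip(header, row[5:]):
                    fld = form.get_field(fld_id)
                    if cell == "":
                        continue
                    raw = (cell, cell) if fld.double_entry else cell
                    assert not isinstance(ff.validate_answer(fld, raw), list)
                    checked += 1
    assert checked > 100
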