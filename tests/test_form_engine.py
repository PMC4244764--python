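"""Interview engine: validation matrix, skip logic, branches, keys."""

import pytest

import fieldform as ff
from conftest import (
    all_assignments,
    choice_form_project,
    engine_visit_sequence,
    naive_visit_sequence,
)


def _field(kind="text", *, required=False, numeric="none", min=None, max=None,
           date=None, regex=None, double_entry=False, choices=()):
    return ff.Field(
        "q", kind, "Q",
        choices=[ff.Choice(c.upper(), c) for c in choices],
        validation=ff.ValidationSpec(
            required=required, numeric=numeric, min=min, max=max,
            datetime_format=date, regex=regex,
        ),
        double_entry=double_entry,
    )


# ---------------------------------------------------------------------------
# validate_answer: every rule has accept and reject cases
# ---------------------------------------------------------------------------

ACCEPT_CASES = [
    ("required text", _field(required=True), "yes", "yes"),
    ("integer in range", _field(numeric="integer", min=0, max=100), "42", 42),
    ("integer at min bound", _field(numeric="integer", min=0, max=100), "0", 0),
    ("decimal", _field(numeric="decimal", min=0.5, max=2.5), "1.25", 1.25),
    ("date dd/mm/yyyy", _field(date="dd/mm/yyyy"), "31/12/2013", "31/12/2013"),
    ("time mm:ss", _field(date="mm:ss"), "05:59", "05:59"),
    ("regex match", _field(regex="^SC-[0-9]{5}$"), "SC-00173", "SC-00173"),
    ("double entry identical", _field(double_entry=True), ("twice", "twice"), "twice"),
    ("double entry barcode", _field("barcode", double_entry=True),
     ("SC-00173", "SC-00173"), "SC-00173"),
    ("dropdown member", _field("dropdown", choices=("a", "b")), "a", "a"),
    ("checkbox subset", _field("checkbox", choices=("a", "b", "c")), "c;a", ("a", "c")),
]

REJECT_CASES = [
    ("required blank", _field(required=True), "", "required"),
    ("not an integer", _field(numeric="integer"), "4.2", "numeric"),
    ("below min", _field(numeric="integer", min=0, max=100), "-1", "min"),
    ("above max", _field(numeric="integer", min=0, max=100), "101", "max"),
    ("decimal out of range", _field(numeric="decimal", min=0.5, max=2.5), "9.9", "max"),
    ("iso date against dd/mm/yyyy", _field(date="dd/mm/yyyy"), "2013-12-31", "datetime"),
    ("minutes overflow mm:ss", _field(date="mm:ss"), "61:00", "datetime"),
    ("wrong barcode prefix", _field("barcode", regex="^SC-[0-9]{5}$"), "XX-00173", "regex"),
    ("double entry mismatch", _field("barcode", double_entry=True),
     ("SC-00173", "SC-00174"), "double_entry"),
    ("undeclared choice", _field("dropdown", choices=("a", "b")), "z", "choice"),
    ("undeclared checkbox value", _field("checkbox", choices=("a", "b")), "a;z", "choice"),
    ("malformed location", _field("location"), "51.5;-0.1", "location"),
    ("latitude out of range", _field("location"), "123;0;0;5", "location"),
]


@pytest.mark.parametrize("label, field, raw, expected", ACCEPT_CASES,
                         ids=[c[0] for c in ACCEPT_CASES])
def test_validation_accepts(label, field, raw, expected):
    result = ff.validate_answer(field, raw)
    assert isinstance(result, ff.Answer), result
    assert result.value == expected


@pytest.mark.parametrize("label, field, raw, code", REJECT_CASES,
                         ids=[c[0] for c in REJECT_CASES])
def test_validation_rejects(label, field, raw, code):
    result = ff.validate_answer(field, raw)
    assert isinstance(result, list) and result
    assert any(e.code == code for e in result), result


def test_all_failures_collected_not_just_first():
    fld = _field(numeric="integer", min=0, max=10, double_entry=True)
    result = ff.validate_answer(fld, ("abc", "abd"))
    codes = {e.code for e in result}
    assert {"double_entry", "numeric"} <= codes


def test_blank_optional_field_is_skipped_not_error():
    assert ff.validate_answer(_field(), "") is None
    assert ff.validate_answer(_field(double_entry=True), ("", "")) is None


def test_regex_warn_mode_accepts_with_warning():
    fld = _field("barcode", regex="^SC-[0-9]{5}$")
    answer, issues = ff.check_answer(fld, "XX-00173", regex_mode="warn")
    assert isinstance(answer, ff.Answer)
    assert [i.severity for i in issues] == ["warning"]


def test_double_entry_strips_whitespace_but_is_case_sensitive():
    fld = _field(double_entry=True)
    assert ff.validate_answer(fld, (" x ", "x")).value == "x"
    assert isinstance(ff.validate_answer(fld, ("x", "X")), list)


def test_media_answers_are_typed_refs():
    img = ff.validate_answer(_field("image"), "media/a.jpg")
    assert img.value == ff.MediaRef("image", "media/a.jpg", "media/a.jpg.thumb.jpg")
    aud = ff.validate_answer(_field("audio"), "media/a.3gp")
    assert aud.value.thumbnail_uri is None
    loc = ff.validate_answer(_field("location"), "51.5;-0.1;35;4.5")
    assert loc.value == ff.Location(51.5, -0.1, 35.0, 4.5)


# ---------------------------------------------------------------------------
# next_field: the quoted routing examples
# ---------------------------------------------------------------------------

def _jump_form():
    fields = [
        ff.Field("q1", "dropdown", "Q1",
                 choices=[ff.Choice(v.upper(), v) for v in "abcd"],
                 jumps=[ff.JumpClause(("a", "c"), "q5"), ff.JumpClause(("b",), "q7")]),
    ] + [ff.Field(f"q{i}", "text", f"Q{i}") for i in range(2, 8)]
    return ff.Form("jumps", "Jumps", fields, key_field=ff.AUTO)


@pytest.mark.parametrize("answer, destination",
                         [("a", "q5"), ("c", "q5"), ("b", "q7"), ("d", "q2")])
def test_multi_clause_jump_routing(answer, destination):
    """Answer A or C jumps to Q5, B jumps to Q7, anything else continues to Q2."""
    form = _jump_form()
    assert ff.next_field(form, "q1", ff.Answer("dropdown", answer)) == destination


def test_favourite_colour_example():
    """Named colours skip the free-text 'other colour' question; choosing
    'other' falls through to it."""
    colour = ff.Field(
        "q1", "dropdown", "What is your favourite colour?",
        choices=[ff.Choice(v.title(), v) for v in ("blue", "red", "green", "other")],
        jumps=[ff.JumpClause(("blue", "red", "green"), "q3")],
    )
    other = ff.Field("q2", "text", "Please enter your favourite colour")
    final = ff.Field("q3", "dropdown", "Done?", choices=[ff.Choice("Yes", "yes")])
    form = ff.Form("colours", "Colours", [colour, other, final], key_field=ff.AUTO)
    for named in ("blue", "red", "green"):
        assert ff.next_field(form, "q1", ff.Answer("dropdown", named)) == "q3"
    assert ff.next_field(form, "q1", ff.Answer("dropdown", "other")) == "q2"


def test_default_advance_and_end():
    form = _jump_form()
    assert ff.next_field(form, "q2", ff.Answer("text", "x")) == "q3"
    assert ff.next_field(form, "q7", ff.Answer("text", "x")) == ff.END


def test_jump_with_incompatible_answer_type_errors():
    form = _jump_form()
    with pytest.raises(TypeError):
        ff.next_field(form, "q1", ff.Answer("checkbox", ("a", "b")))


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def test_session_starts_at_first_field(schools, clock):
    s = ff.start_session(schools, "school", device_id="dev", clock=clock)
    assert s.cursor == "school_name"


def test_orphan_session_rejected(schools, clock):
    with pytest.raises(ff.FormFlowError, match="orphan"):
        ff.start_session(schools, "pupil", device_id="dev", clock=clock)


def test_parent_key_carried_into_entry(schools, clock):
    s = ff.start_session(schools, "class", "Hilltop Primary", device_id="dev", clock=clock)
    ff.submit_answer(s, "5B")
    ff.submit_answer(s, "30")
    ff.submit_answer(s, "Ms June")
    ff.submit_answer(s, "0")
    entry = ff.finalize_entry(s)
    assert entry.parent_key == "Hilltop Primary"
    assert entry.key_value == "5B"


def test_invalid_answer_leaves_cursor(schools, clock):
    s = ff.start_session(schools, "school", device_id="dev", clock=clock)
    result = ff.submit_answer(s, "")  # required name left blank
    assert result.status == "invalid"
    assert s.cursor == "school_name"
    assert s.answers == {}


def test_skipped_fields_store_nothing(clock):
    project = choice_form_project(
        ff.Form("flow", "Flow", [
            ff.Field("q1", "dropdown", "Q1",
                     choices=[ff.Choice("A", "a"), ff.Choice("B", "b")],
                     jumps=[ff.JumpClause(("a",), "q3")]),
            ff.Field("q2", "text", "Q2"),
            ff.Field("q3", "text", "Q3"),
        ], key_field=ff.AUTO)
    )
    s = ff.start_session(project, "flow", device_id="dev", clock=clock)
    ff.submit_answer(s, "a")
    ff.submit_answer(s, "three")
    entry = ff.finalize_entry(s)
    assert "q2" not in entry.answers
    assert set(entry.answers) == {"q1", "q3"}


def test_termination_within_field_count():
    """Forward-only jumps: every session completes in <= |fields| submissions."""
    for seed in range(30):
        form = ff.random_choice_form(seed)
        project = choice_form_project(form)
        for assignment in list(all_assignments(form))[:10]:
            visited = engine_visit_sequence(project, form, assignment)
            assert len(visited) <= len(form.fields)
            assert len(visited) == len(set(visited))  # no field twice


def test_engine_matches_naive_interpreter_small():
    for seed in range(40):
        form = ff.random_choice_form(seed, n_fields=5, n_choices=3)
        project = choice_form_project(form)
        for assignment in all_assignments(form):
            assert engine_visit_sequence(project, form, assignment) == \
                naive_visit_sequence(form, assignment), (seed, assignment)


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------

def _class_session(schools, clock, absences):
    s = ff.start_session(schools, "class", "Hilltop Primary", device_id="dev", clock=clock)
    ff.submit_answer(s, "5B")
    ff.submit_answer(s, "30")
    ff.submit_answer(s, "Ms June")
    return s, ff.submit_answer(s, str(absences))


def test_zero_absences_continues_automatically(schools, clock):
    s, result = _class_session(schools, clock, 0)
    assert result.status == "complete"  # trigger was the last question
    entry = ff.finalize_entry(s)
    assert entry.branch_children == {}


def test_two_absences_attach_two_branch_entries(schools, clock):
    s, result = _class_session(schools, clock, 2)
    assert result.status == "branch_prompt"
    assert result.host_field == "record_absences"
    for reason in ("illness", "training"):
        b = ff.begin_branch(s)
        assert b.form_id == "absence"
        ff.submit_answer(b, reason)
        ff.submit_answer(b, "3")
        ff.attach_branch_entry(s, ff.finalize_entry(b))
    assert ff.proceed_after_branch(s).status == "complete"
    entry = ff.finalize_entry(s)
    children = entry.branch_children["record_absences"]
    assert len(children) == 2
    assert all(c.parent_key == "5B" for c in children)
    assert [c.answers["reason"].value for c in children] == ["illness", "training"]


def test_submit_while_branch_pending_is_an_error(schools, clock):
    s, result = _class_session(schools, clock, 1)
    assert result.status == "branch_prompt"
    with pytest.raises(ff.FormFlowError, match="branch prompt"):
        ff.submit_answer(s, "anything")


# ---------------------------------------------------------------------------
# Keys and finalisation
# ---------------------------------------------------------------------------

def test_auto_key_concatenation():
    assert ff.generate_auto_key("a1b2c3", 1408500000000) == "a1b2c3_1408500000000"
    assert ff.generate_auto_key("a1b2c3", 1408500000000) == \
        ff.generate_auto_key("a1b2c3", 1408500000000)


def test_auto_key_rejects_empty_uuid_and_negative_time():
    with pytest.raises(ValueError):
        ff.generate_auto_key("", 1)
    with pytest.raises(ValueError):
        ff.generate_auto_key("dev", -5)


def test_auto_key_distinct_pairs_distinct_keys():
    keys = {ff.generate_auto_key(f"dev{i % 7}", 1_000_000 + i) for i in range(500)}
    assert len(keys) == 500


def test_auto_keyed_entry_matches_pattern(schools, clock):
    import re

    s = ff.start_session(schools, "pupil", "5B", device_id="phone-uuid-9", clock=clock)
    ff.submit_answer(s, "media/name.3gp")
    ff.submit_answer(s, ("SC-00173", "SC-00173"))
    entry = ff.finalize_entry(s)
    assert re.fullmatch(r"phone-uuid-9_[0-9]+", entry.key_value)
    assert entry.created_at >= s.started_at


def test_finalize_incomplete_session_errors(schools, clock):
    s = ff.start_session(schools, "school", device_id="dev", clock=clock)
    ff.submit_answer(s, "Hilltop Primary")
    with pytest.raises(ff.FormFlowError, match="not complete"):
        ff.finalize_entry(s)


# ---------------------------------------------------------------------------
# Scripted sessions
# ---------------------------------------------------------------------------

SCRIPT = """\
# a class with one teacher absence
class_name\t5C
class_size\t28
teacher_name\tMr Okoye
record_absences\t1
[branch]
reason\tillness
days\t4
[/branch]
"""


def test_scripted_session_with_branch_block(schools, clock):
    records = ff.parse_script(SCRIPT)
    entry = ff.run_script(
        schools, "class", records,
        parent_key="Hilltop Primary", device_id="dev", clock=clock,
    )
    assert entry.key_value == "5C"
    assert len(entry.branch_children["record_absences"]) == 1
    assert entry.branch_children["record_absences"][0].answers["days"].value == 4


def test_script_cursor_mismatch_errors(schools, clock):
    records = ff.parse_script("class_size\t28\n")
    with pytest.raises(ff.FormFlowError, match="cursor"):
        ff.run_script(schools, "class", records,
                      parent_key="Hilltop Primary", device_id="dev", clock=clock)


def test_script_double_entry_third_column(schools, clock):
    records = ff.parse_script("name_audio\tmedia/a.3gp\nblood_barcode\tSC-00001\tSC-00001\n")
    entry = ff.run_script(schools, "pupil", records,
                          parent_key="5C", device_id="dev", clock=clock)
    assert entry.answers["blood_barcode"].value == "SC-00001"


def test_unterminated_branch_block_rejected():
    with pytest.raises(ValueError, match="unterminated"):
        ff.parse_script("q\t1\n[branch]\nr\t2\n")
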