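"""Deterministic generators: the schools demo project, seeded random
projects, and simulated multi-device collection runs.

Every generator takes an explicit seed and draws from a single private
``random.Random`` stream, so the same call always produces the same
artefact — down to byte-identical serialised stores. Generated projects
always pass structural validation and generated answers always pass the
field validation pipeline; that is asserted by the test suite, not assumed.
"""

from __future__ import annotations

import random

from .datastore import EntryStore
from .form_engine import (
    Entry,
    ManualClock,
    attach_branch_entry,
    begin_branch,
    finalize_entry,
    proceed_after_branch,
    start_session,
    submit_answer,
)
from .project_model import (
    AUTO,
    END,
    BranchRole,
    Choice,
    Field,
    Form,
    HierarchyRole,
    JumpClause,
    Project,
    ValidationSpec,
)

_WORDS = (
    "acacia", "baobab", "cedar", "doum", "ebony", "fig", "gum", "ironwood",
    "jacaranda", "kapok", "marula", "neem", "olive", "palm", "quiver",
    "rosewood", "sausage", "tamarind", "umbrella", "wattle",
)

#: Regex patterns paired with a generator of conforming strings, so random
#: projects only carry patterns the simulator knows how to satisfy.
PATTERN_CATALOGUE: list[tuple[str, "callable"]] = [
    ("^SC-[0-9]{5}$", lambda rng: f"SC-{rng.randrange(100000):05d}"),
    ("^[A-Z]{3}[0-9]{2}$", lambda rng: "".join(rng.choice("ABCDEFGHJK") for _ in range(3)) + f"{rng.randrange(100):02d}"),
    ("^[a-z]+-[0-9]+$", lambda rng: f"{rng.choice(_WORDS)}-{rng.randrange(1000)}"),
]

DATE_GENERATORS = {
    "dd/mm/yyyy": lambda rng: f"{rng.randint(1, 28):02d}/{rng.randint(1, 12):02d}/{rng.randint(1990, 2024):04d}",
    "mm:ss": lambda rng: f"{rng.randint(0, 59):02d}:{rng.randint(0, 59):02d}",
}


# ---------------------------------------------------------------------------
# Schools demo: a 3-level hierarchy (school -> class -> pupil) with an
# absence branch on the class form
# ---------------------------------------------------------------------------

def schools_demo_project() -> Project:
    """The worked demonstration project: survey schools, the classes in each
    school and the pupils in each class; record teacher absences per class
    as a branch; tag pupils' blood samples with pre-printed barcodes and an
    audio clip of the pupil's name."""
    school = Form(
        form_id="school",
        title="School",
        key_field="school_name",
        role=HierarchyRole(1),
        fields=[
            Field("school_name", "text", "School name", validation=ValidationSpec(required=True)),
            Field(
                "school_type", "dropdown", "Type of school",
                choices=[Choice("State", "state"), Choice("Independent", "independent"), Choice("Other", "other")],
                chartable=True,
            ),
            Field(
                "sex_mix", "radio", "Single-sex or mixed?",
                choices=[Choice("Single-sex", "single_sex"), Choice("Mixed", "mixed")],
                chartable=True,
            ),
            Field(
                "n_teachers", "text", "Number of teachers",
                validation=ValidationSpec(required=True, numeric="integer", min=1, max=500),
            ),
            Field(
                "n_pupils", "text", "Number of pupils",
                validation=ValidationSpec(numeric="integer", min=1, max=5000),
            ),
            Field("school_photo", "image", "Photo of the school"),
            Field("school_location", "location", "School location"),
        ],
    )
    klass = Form(
        form_id="class",
        title="Class",
        key_field="class_name",
        role=HierarchyRole(2),
        fields=[
            Field("class_name", "text", "Class name", validation=ValidationSpec(required=True)),
            Field(
                "class_size", "text", "Class size",
                validation=ValidationSpec(required=True, numeric="integer", min=1, max=60),
            ),
            Field("teacher_name", "text", "Class teacher"),
            Field(
                "record_absences", "branch_trigger", "Please record absences",
                validation=ValidationSpec(required=True, numeric="integer", min=0, max=50),
            ),
        ],
    )
    pupil = Form(
        form_id="pupil",
        title="Pupil",
        key_field=AUTO,
        role=HierarchyRole(3),
        fields=[
            Field("name_audio", "audio", "Pupil pronouncing their own name"),
            Field(
                "blood_barcode", "barcode", "Scan the blood sample barcode",
                validation=ValidationSpec(required=True, regex="^SC-[0-9]{5}$"),
                double_entry=True,
            ),
        ],
    )
    absence = Form(
        form_id="absence",
        title="Absence",
        key_field=AUTO,
        role=BranchRole(host_form="class", host_field="record_absences"),
        fields=[
            Field(
                "reason", "dropdown", "Reason for absence",
                choices=[Choice("Illness", "illness"), Choice("Training", "training"), Choice("Other", "other")],
                chartable=True,
            ),
            Field(
                "days", "text", "Number of days absent",
                validation=ValidationSpec(required=True, numeric="integer", min=1, max=365),
            ),
        ],
    )
    return Project(
        name="schools-demo",
        title="Schools survey",
        version="1",
        forms=[school, klass, pupil, absence],
    )


# ---------------------------------------------------------------------------
# Random projects
# ---------------------------------------------------------------------------

_GENERABLE_KINDS = (
    "text", "long_text", "dropdown", "checkbox", "radio",
    "location", "image", "video", "audio", "barcode",
)


def random_project(
    seed: int,
    depth: int = 3,
    fields_per_form: int = 5,
    branch_prob: float = 0.3,
) -> Project:
    """A valid random project: a linear hierarchy of ``depth`` forms, each
    with ``fields_per_form`` fields covering all field kinds and validation
    rules, plus branch forms with probability ``branch_prob`` per level.
    Deterministic per seed."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if fields_per_form < 1:
        raise ValueError("fields_per_form must be >= 1")
    if not 0 <= branch_prob <= 1:
        raise ValueError("branch_prob must be in [0, 1]")
    rng = random.Random(seed)
    forms: list[Form] = []
    branches: list[Form] = []
    for level in range(1, depth + 1):
        form_id = f"form{level}"
        fields: list[Field] = [
            # first field: plain required text, usable as a key
            Field(f"{form_id}_q1", "text", f"Name of {form_id}", validation=ValidationSpec(required=True))
        ]
        for i in range(2, fields_per_form + 1):
            fields.append(_random_field(rng, f"{form_id}_q{i}"))
        if rng.random() < branch_prob:
            trigger_id = f"{form_id}_branchq"
            fields.append(
                Field(
                    trigger_id, "branch_trigger", f"How many extra records for {form_id}?",
                    validation=ValidationSpec(required=True, numeric="integer", min=0, max=5),
                )
            )
            branches.append(_branch_form(rng, f"{form_id}_branch", form_id, trigger_id))
        _add_random_jumps(rng, fields)
        key = fields[0].field_id if rng.random() < 0.5 else AUTO
        forms.append(
            Form(form_id=form_id, title=form_id.title(), fields=fields, key_field=key, role=HierarchyRole(level))
        )
    return Project(
        name=f"random-{seed}",
        title=f"Random project {seed}",
        version="1",
        forms=forms + branches,
        visibility=rng.choice(("public", "private")),
    )


def _random_field(rng: random.Random, field_id: str) -> Field:
    kind = rng.choice(_GENERABLE_KINDS)
    label = f"Question {field_id}"
    required = rng.random() < 0.4
    if kind in ("dropdown", "checkbox", "radio"):
        n = rng.randint(2, 4)
        choices = [Choice(f"Option {c}", f"v{c}") for c in range(1, n + 1)]
        return Field(
            field_id, kind, label, choices=choices,
            validation=ValidationSpec(required=required),
            chartable=rng.random() < 0.5,
        )
    if kind in ("text", "long_text"):
        rule = rng.choice(("plain", "integer", "decimal", "date", "regex"))
        v = ValidationSpec(required=required)
        if rule == "integer":
            lo = rng.randint(0, 50)
            v = ValidationSpec(required=required, numeric="integer", min=lo, max=lo + rng.randint(1, 100))
        elif rule == "decimal":
            lo = rng.randint(0, 10)
            v = ValidationSpec(required=required, numeric="decimal", min=float(lo), max=float(lo + 5))
        elif rule == "date":
            v = ValidationSpec(required=required, datetime_format=rng.choice(tuple(DATE_GENERATORS)))
        elif rule == "regex" and kind == "text":
            v = ValidationSpec(required=required, regex=rng.choice(PATTERN_CATALOGUE)[0])
        double = kind == "text" and v.regex is None and rng.random() < 0.2
        return Field(field_id, kind, label, validation=v, double_entry=double)
    if kind == "barcode":
        v = ValidationSpec(required=required)
        if rng.random() < 0.5:
            v = ValidationSpec(required=required, regex=rng.choice(PATTERN_CATALOGUE)[0])
        return Field(field_id, kind, label, validation=v, double_entry=rng.random() < 0.3)
    return Field(field_id, kind, label, validation=ValidationSpec(required=required))


def _add_random_jumps(rng: random.Random, fields: list[Field]) -> None:
    for pos, fld in enumerate(fields):
        if fld.kind not in ("dropdown", "radio") or pos == len(fields) - 1:
            continue
        if rng.random() >= 0.4:
            continue
        later = [f.field_id for f in fields[pos + 1:]] + [END]
        values = fld.choice_values()
        rng.shuffle(values)
        n_clauses = rng.randint(1, min(2, len(values)))
        used = 0
        for _ in range(n_clauses):
            take = rng.randint(1, max(1, len(values) - used - 1)) if used < len(values) - 1 else 0
            if take == 0:
                break
            triggers = tuple(values[used: used + take])
            used += take
            fld.jumps.append(JumpClause(triggers, rng.choice(later)))


def _branch_form(rng: random.Random, form_id: str, host_form: str, host_field: str) -> Form:
    n = rng.randint(2, 3)
    fields = [
        Field(
            f"{form_id}_reason", "dropdown", "Reason",
            choices=[Choice(f"Reason {c}", f"r{c}") for c in range(1, n + 1)],
            chartable=True,
        ),
        Field(
            f"{form_id}_count", "text", "Count",
            validation=ValidationSpec(required=True, numeric="integer", min=1, max=30),
        ),
    ]
    return Form(
        form_id=form_id, title=form_id.title(), fields=fields,
        key_field=AUTO, role=BranchRole(host_form, host_field),
    )


def random_choice_form(seed: int, n_fields: int = 6, n_choices: int = 3) -> Form:
    """A single choice-only form (all dropdowns) with random forward jumps:
    the workhorse for exhaustive skip-logic checks."""
    rng = random.Random(seed)
    fields = [
        Field(
            f"q{i}", "dropdown", f"Question {i}",
            choices=[Choice(f"Choice {c}", f"c{c}") for c in range(1, rng.randint(2, n_choices) + 1)],
            validation=ValidationSpec(required=True),
        )
        for i in range(1, rng.randint(2, n_fields) + 1)
    ]
    _add_random_jumps(rng, fields)
    return Form(form_id="flow", title="Flow", fields=fields, key_field=AUTO, role=HierarchyRole(1))


# ---------------------------------------------------------------------------
# Answer generation and simulated collection
# ---------------------------------------------------------------------------

def generate_raw(field: Field, rng: random.Random) -> str | tuple[str, str]:
    """A raw answer string guaranteed to satisfy the field's rules (a pair
    for double-entry fields)."""
    raw = _generate_single(field, rng)
    return (raw, raw) if field.double_entry else raw


def _generate_single(field: Field, rng: random.Random) -> str:
    v = field.validation
    kind = field.kind
    if kind in ("dropdown", "radio"):
        return rng.choice(field.choice_values())
    if kind == "checkbox":
        values = field.choice_values()
        k = rng.randint(1, len(values))
        return ";".join(sorted(rng.sample(values, k), key=values.index))
    if kind == "location":
        lat = round(rng.uniform(-90, 90), 6)
        lon = round(rng.uniform(-180, 180), 6)
        alt = round(rng.uniform(0, 2000), 1)
        acc = round(rng.uniform(1, 50), 1)
        return f"{lat};{lon};{alt};{acc}"
    if kind in ("image", "video", "audio"):
        ext = {"image": "jpg", "video": "mp4", "audio": "3gp"}[kind]
        return f"media/{kind}_{rng.randrange(10**8):08d}.{ext}"
    if kind == "branch_trigger":
        hi = int(v.max) if v.max is not None else 3
        lo = int(v.min) if v.min is not None else 0
        return str(rng.randint(lo, min(hi, lo + 3)))
    # text-like kinds (text, long_text, barcode)
    if v.regex is not None:
        for pattern, gen in PATTERN_CATALOGUE:
            if pattern == v.regex:
                return gen(rng)
        raise ValueError(f"no generator for pattern {v.regex!r}")
    if v.numeric == "integer":
        lo = int(v.min) if v.min is not None else 0
        hi = int(v.max) if v.max is not None else lo + 100
        return str(rng.randint(lo, hi))
    if v.numeric == "decimal":
        lo = v.min if v.min is not None else 0.0
        hi = v.max if v.max is not None else lo + 10.0
        return str(round(rng.uniform(lo, hi), 3))
    if v.datetime_format is not None:
        return DATE_GENERATORS[v.datetime_format](rng)
    return f"{rng.choice(_WORDS)} {rng.choice(_WORDS)}"


def _collect_entry(
    project: Project,
    form_id: str,
    rng: random.Random,
    *,
    parent_key: str | None,
    device_id: str,
    clock,
    key_override: str | None = None,
) -> Entry:
    """Run one simulated interview to completion and finalise it."""
    session = start_session(project, form_id, parent_key, device_id=device_id, clock=clock)
    form = project.get_form(form_id)
    guard = 0
    while not session.complete:
        guard += 1
        if guard > len(form.fields) + 1:
            raise RuntimeError("simulated session did not terminate")
        fld = form.get_field(session.cursor)
        if key_override is not None and fld.field_id == form.key_field:
            raw: str | tuple[str, str] = key_override
        else:
            raw = generate_raw(fld, rng)
        result = submit_answer(session, raw)
        if result.status == "invalid":
            raise RuntimeError(
                f"generator produced an invalid answer for {fld.field_id!r}: "
                + "; ".join(e.message for e in result.errors)
            )
        if result.status == "branch_prompt":
            ans = session.answers[result.host_field]
            for _ in range(int(ans.value)):  # type: ignore[arg-type]
                branch = begin_branch(session)
                bform = project.get_form(branch.form_id)
                while not branch.complete:
                    braw = generate_raw(bform.get_field(branch.cursor), rng)
                    bres = submit_answer(branch, braw)
                    if bres.status == "invalid":
                        raise RuntimeError("generator produced an invalid branch answer")
                attach_branch_entry(session, finalize_entry(branch))
            proceed_after_branch(session)
    return finalize_entry(session)


def simulate_collection(
    project: Project,
    n_devices: int = 2,
    entries_per_level: int | list[int] = 2,
    seed: int = 0,
) -> list[EntryStore]:
    """Emulate ``n_devices`` phones each gathering a full hierarchy:
    ``entries_per_level`` top-level entries per device, and that many child
    entries under every parent at each lower level. Returns one store per
    device; answers are drawn from declared choices and rule-satisfying
    values and the whole run is deterministic per seed."""
    chain = [f.form_id for f in project.hierarchy_forms()]
    if isinstance(entries_per_level, int):
        per_level = [entries_per_level] * len(chain)
    else:
        per_level = list(entries_per_level)
        if len(per_level) != len(chain):
            raise ValueError("entries_per_level must match the hierarchy depth")

    stores: list[EntryStore] = []
    for d in range(n_devices):
        rng = random.Random(seed * 10_007 + d)  # stable per-device stream
        device_id = f"device-{d + 1:02d}"
        clock = ManualClock(start_ms=1_408_500_000_000 + d * 86_400_000, step_ms=1000)
        store = EntryStore(project)
        serial = 0

        def make(form_pos: int, parent_key: str | None) -> None:
            nonlocal serial
            form_id = chain[form_pos]
            form = project.get_form(form_id)
            for _ in range(per_level[form_pos]):
                serial += 1
                key_override = None
                if form.key_field != AUTO:
                    key_override = f"{form_id} {device_id} #{serial}"
                entry = _collect_entry(
                    project, form_id, rng,
                    parent_key=parent_key, device_id=device_id, clock=clock,
                    key_override=key_override,
                )
                for _, res in store.insert_with_branches(entry):
                    if not res.accepted:
                        raise RuntimeError(f"simulated entry rejected: {res.reason}")
                if form_pos + 1 < len(chain):
                    make(form_pos + 1, entry.key_value)

        make(0, None)
        stores.append(store)
    return stores
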