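"""Domain model for hierarchical survey projects.

A *project* is an ordered chain of forms (school -> class -> pupil style,
one-to-many at each step) plus any number of *branch* forms attached to
specific questions of a host form. Each form is an ordered questionnaire of
typed fields with optional validation rules and forward-only jump (skip
logic) clauses. Nothing here touches disk; serialisation lives in
:mod:`fieldform.project_io`.

Structural validation is report-based: :func:`validate_project` never raises
for a rule violation, it accumulates every problem it can find so a project
author sees the whole picture at once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Iterator

# Sentinel used for auto-generated key fields (device uuid + entry time).
AUTO = "AUTO"

#: Destination sentinel meaning "skip to the end of the form".
END = "END"

TEXT_KINDS = frozenset({"text", "long_text"})
CHOICE_KINDS = frozenset({"dropdown", "checkbox", "radio"})
MEDIA_KINDS = frozenset({"location", "image", "video", "audio", "barcode"})
FIELD_KINDS = TEXT_KINDS | CHOICE_KINDS | MEDIA_KINDS | {"branch_trigger"}

#: Field kinds whose answers are single choice values, and therefore the only
#: kinds on which jump clauses may be declared.
JUMPABLE_KINDS = frozenset({"dropdown", "radio"})

#: Field kinds that may serve as a user-chosen key.
KEYABLE_KINDS = frozenset({"text", "barcode"})

NUMERIC_MODES = ("none", "integer", "decimal")


@dataclass
class Choice:
    """One option of a choice field: ``name`` is shown, ``value`` is stored."""

    name: str
    value: str


@dataclass
class ValidationSpec:
    """Per-field validation rules, applied in a fixed order by the engine."""

    required: bool = False
    numeric: str = "none"  # none | integer | decimal
    min: float | None = None
    max: float | None = None
    datetime_format: str | None = None  # e.g. "dd/mm/yyyy" or "mm:ss"
    regex: str | None = None

    def is_default(self) -> bool:
        return self == ValidationSpec()


@dataclass
class JumpClause:
    """Skip rule: if the answer is one of ``trigger_values``, go to
    ``destination`` (a later field id, or :data:`END`)."""

    trigger_values: tuple[str, ...]
    destination: str


@dataclass
class Field:
    field_id: str
    kind: str
    label: str
    choices: list[Choice] = dc_field(default_factory=list)
    validation: ValidationSpec = dc_field(default_factory=ValidationSpec)
    jumps: list[JumpClause] = dc_field(default_factory=list)
    chartable: bool = False
    double_entry: bool = False
    #: unknown XML attributes carried through serialisation untouched
    extra_attrs: dict[str, str] = dc_field(default_factory=dict)
    #: unknown child elements, kept as verbatim markup strings
    extensions: list[str] = dc_field(default_factory=list)

    def choice_values(self) -> list[str]:
        return [c.value for c in self.choices]


@dataclass
class HierarchyRole:
    level: int  # 1 = top of the chain


@dataclass
class BranchRole:
    host_form: str
    host_field: str


@dataclass
class Form:
    form_id: str
    title: str
    fields: list[Field]
    key_field: str = AUTO  # field id, or AUTO
    role: HierarchyRole | BranchRole = dc_field(default_factory=lambda: HierarchyRole(1))
    extra_attrs: dict[str, str] = dc_field(default_factory=dict)
    extensions: list[str] = dc_field(default_factory=list)

    @property
    def is_branch(self) -> bool:
        return isinstance(self.role, BranchRole)

    def field_ids(self) -> list[str]:
        return [f.field_id for f in self.fields]

    def get_field(self, field_id: str) -> Field:
        for f in self.fields:
            if f.field_id == field_id:
                return f
        raise KeyError(f"no field {field_id!r} in form {self.form_id!r}")


@dataclass
class Project:
    """Named, versioned container of forms: the hierarchy chain in order,
    then branch forms in any order (their attachment point is in their role).
    """

    name: str
    title: str
    version: str
    forms: list[Form]
    visibility: str = "public"  # public | private
    extra_attrs: dict[str, str] = dc_field(default_factory=dict)
    extensions: list[str] = dc_field(default_factory=list)

    def get_form(self, form_id: str) -> Form:
        for f in self.forms:
            if f.form_id == form_id:
                return f
        raise KeyError(f"no form {form_id!r} in project {self.name!r}")

    def hierarchy_forms(self) -> list[Form]:
        return [f for f in self.forms if not f.is_branch]

    def branch_forms(self) -> list[Form]:
        return [f for f in self.forms if f.is_branch]

    @property
    def depth(self) -> int:
        return len(self.hierarchy_forms())


@dataclass
class Issue:
    severity: str  # error | warning
    location: str  # path such as "form[pupil].field[height]"
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def __str__(self) -> str:  # human-readable summary for CLI output
        if not self.issues:
            return "ok"
        return "\n".join(f"{i.severity}: {i.location}: {i.message}" for i in self.issues)


class InvalidProjectError(ValueError):
    """Raised by operations that refuse to run on an invalid project."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(f"invalid project:\n{report}")


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------

def validate_project(project: Project) -> ValidationReport:
    """Check every structural invariant of a project and report all
    violations. Total: any well-formed :class:`Project` object yields a
    report, never an exception.
    """
    rep = ValidationReport()

    def err(loc: str, msg: str) -> None:
        rep.issues.append(Issue("error", loc, msg))

    def warn(loc: str, msg: str) -> None:
        rep.issues.append(Issue("warning", loc, msg))

    if project.visibility not in ("public", "private"):
        err("project", f"visibility must be public or private, got {project.visibility!r}")
    if not project.forms:
        err("project", "forms empty: a project needs at least one form")
        return rep

    seen_form_ids: set[str] = set()
    for form in project.forms:
        if form.form_id in seen_form_ids:
            err(f"form[{form.form_id}]", "duplicate form id")
        seen_form_ids.add(form.form_id)

    # hierarchy must be a single linear chain with levels 1..n in list order
    hier = project.hierarchy_forms()
    if not hier:
        err("project", "no hierarchy forms (branch forms cannot stand alone)")
    for expected_level, form in enumerate(hier, start=1):
        level = form.role.level  # type: ignore[union-attr]
        if level != expected_level:
            err(
                f"form[{form.form_id}]",
                f"broken hierarchy chain: expected level {expected_level}, got {level}",
            )

    form_ids = {f.form_id for f in project.forms}

    # branch registry: each branch form hosted exactly once, host exists,
    # host field exists and is a branch_trigger; one level of branching only
    trigger_targets: dict[tuple[str, str], str] = {}
    for form in project.forms:
        for fld in form.fields:
            if fld.kind == "branch_trigger":
                if form.is_branch:
                    err(
                        f"form[{form.form_id}].field[{fld.field_id}]",
                        "branch forms may not declare branch_trigger fields (no nesting)",
                    )

    for bform in project.branch_forms():
        loc = f"form[{bform.form_id}]"
        role = bform.role
        assert isinstance(role, BranchRole)
        if role.host_form not in form_ids:
            err(loc, f"branch host form {role.host_form!r} missing")
            continue
        host = project.get_form(role.host_form)
        if host.is_branch:
            err(loc, f"branch host {role.host_form!r} is itself a branch form")
            continue
        try:
            host_field = host.get_field(role.host_field)
        except KeyError:
            err(loc, f"branch host field {role.host_field!r} missing in form {host.form_id!r}")
            continue
        if host_field.kind != "branch_trigger":
            err(loc, f"host field {role.host_field!r} is kind {host_field.kind!r}, not branch_trigger")
            continue
        key = (role.host_form, role.host_field)
        if key in trigger_targets:
            err(loc, f"host field {role.host_field!r} already hosts branch {trigger_targets[key]!r}")
        trigger_targets[key] = bform.form_id

    # every branch_trigger field must have exactly one attached branch form
    for form in project.forms:
        if form.is_branch:
            continue
        for fld in form.fields:
            if fld.kind == "branch_trigger" and (form.form_id, fld.field_id) not in trigger_targets:
                err(
                    f"form[{form.form_id}].field[{fld.field_id}]",
                    "branch_trigger field has no attached branch form",
                )

    for form in project.forms:
        _validate_form(project, form, err, warn)

    return rep


def _validate_form(project: Project, form: Form, err, warn) -> None:
    floc = f"form[{form.form_id}]"
    ids = form.field_ids()
    seen: set[str] = set()
    for fid in ids:
        if fid in seen:
            err(f"{floc}.field[{fid}]", "duplicate field id")
        seen.add(fid)

    if form.key_field != AUTO:
        try:
            kf = form.get_field(form.key_field)
        except KeyError:
            err(floc, f"key_field missing: no field {form.key_field!r} in form")
        else:
            if kf.kind not in KEYABLE_KINDS:
                err(floc, f"key_field {form.key_field!r} is kind {kf.kind!r}, must be text or barcode")

    index = {fid: i for i, fid in enumerate(ids)}
    for pos, fld in enumerate(form.fields):
        loc = f"{floc}.field[{fld.field_id}]"
        if fld.kind not in FIELD_KINDS:
            err(loc, f"unknown field kind {fld.kind!r}")
            continue

        if fld.kind in CHOICE_KINDS:
            if not fld.choices:
                err(loc, "choice field declares no choices")
            vals = fld.choice_values()
            if len(vals) != len(set(vals)):
                err(loc, "duplicate choice values")
            for c in fld.choices:
                if not c.value:
                    err(loc, f"choice {c.name!r} has empty value")
        elif fld.choices:
            err(loc, f"choices are only legal on dropdown/checkbox/radio, not {fld.kind!r}")

        if fld.chartable and fld.kind not in CHOICE_KINDS:
            err(loc, f"chartable on non-choice field of kind {fld.kind!r}")
        if fld.double_entry and fld.kind not in ("text", "barcode"):
            err(loc, f"double_entry only legal on text and barcode fields, not {fld.kind!r}")

        _validate_rules(fld, loc, err)
        _validate_jumps(form, fld, pos, index, loc, err, warn)


def _validate_rules(fld: Field, loc: str, err) -> None:
    v = fld.validation
    if v.numeric not in NUMERIC_MODES:
        err(loc, f"numeric mode must be one of {NUMERIC_MODES}, got {v.numeric!r}")
    if (v.min is not None or v.max is not None) and v.numeric == "none":
        err(loc, "min/max require a numeric rule")
    if v.min is not None and v.max is not None and v.min > v.max:
        err(loc, f"min {v.min} greater than max {v.max}")
    if v.datetime_format is not None and fld.kind not in TEXT_KINDS:
        err(loc, f"datetime_format only legal on text fields, not {fld.kind!r}")
    if v.regex is not None:
        try:
            re.compile(v.regex)
        except re.error as e:
            err(loc, f"invalid regex: {e}")


def _validate_jumps(form: Form, fld: Field, pos: int, index: dict[str, int], loc: str, err, warn) -> None:
    if fld.jumps and fld.kind not in JUMPABLE_KINDS:
        err(loc, f"jump clauses only legal on dropdown/radio fields, not {fld.kind!r}")
        return
    declared = set(fld.choice_values())
    for clause in fld.jumps:
        for tv in clause.trigger_values:
            if tv not in declared:
                err(loc, f"jump trigger {tv!r} is not a declared choice value")
        if clause.destination == END:
            continue
        dest_pos = index.get(clause.destination)
        if dest_pos is None:
            err(loc, f"dangling jump destination {clause.destination!r}")
        elif dest_pos <= pos:
            err(loc, f"backward jump to {clause.destination!r} (destination must be later in form order)")
        else:
            if form.fields[dest_pos].kind == "branch_trigger":
                warn(loc, f"jump targets branch_trigger field {clause.destination!r}")


# ---------------------------------------------------------------------------
# Hierarchy queries
# ---------------------------------------------------------------------------

def _require_valid(project: Project) -> None:
    report = validate_project(project)
    if not report.ok:
        raise InvalidProjectError(report)


def hierarchy_chain(project: Project) -> list[str]:
    """Hierarchy form ids top-down (branch forms excluded): the order in
    which forms are listed and must be entered."""
    _require_valid(project)
    return [f.form_id for f in project.hierarchy_forms()]


def branches_of(project: Project, form_id: str) -> list[tuple[str, str]]:
    """Branch attachments of ``form_id`` as ``(host_field_id, branch_form_id)``
    pairs in host-field order; empty if the form has none."""
    form = project.get_form(form_id)  # raises KeyError for unknown form
    by_trigger = {
        (b.role.host_form, b.role.host_field): b.form_id  # type: ignore[union-attr]
        for b in project.branch_forms()
    }
    out: list[tuple[str, str]] = []
    for fld in form.fields:
        if fld.kind == "branch_trigger":
            target = by_trigger.get((form_id, fld.field_id))
            if target is not None:
                out.append((fld.field_id, target))
    return out


def iter_fields(project: Project) -> Iterator[tuple[Form, Field]]:
    for form in project.forms:
        for fld in form.fields:
            yield form, fld
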