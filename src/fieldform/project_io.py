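"""Read and write project definitions.

Dialect v1, one attribute-rich element per concept::

    <project name=".." title=".." version=".." visibility=".." dialect="1">
      <form id=".." title=".." key="<field id>|AUTO" level="1">
        <field id=".." type="dropdown" label=".." required="true" chartable="true">
          <choice name="State" value="state"/>
          <jump when="a,c" to="q5"/>
        </field>
      </form>
      <form id=".." title=".." key="AUTO" branch-of="<form>" branch-at="<field>">..</form>
    </project>

The vocabulary is extensible: unknown attributes and child elements are
preserved on parse and re-emitted verbatim on write, so a document produced
by a later dialect round-trips through this reader without loss. A JSON
mirror of the same structure is provided (`project_to_json` and friends).
Serialisation is canonical — fixed attribute order, defaults omitted — so
writing the same project twice yields byte-identical documents.

Pattern strings (regexes, datetime formats) are carried as opaque text here;
compilation happens in the interview engine, never during parsing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from lxml import etree

from .project_model import (
    AUTO,
    BranchRole,
    Choice,
    Field,
    Form,
    HierarchyRole,
    InvalidProjectError,
    JumpClause,
    Project,
    ValidationSpec,
    validate_project,
)

DIALECT_VERSION = "1"

_PROJECT_ATTRS = ("name", "title", "version", "visibility", "dialect")
_FORM_ATTRS = ("id", "title", "key", "level", "branch-of", "branch-at")
_FIELD_ATTRS = (
    "id", "type", "label", "required", "numeric", "min", "max",
    "date", "regex", "double-entry", "chartable",
)
_KNOWN_CHILDREN = {"project": {"form"}, "form": {"field"}, "field": {"choice", "jump"}}


@dataclass
class ProjectDocument:
    """A serialised project definition (UTF-8 XML text)."""

    text: str
    dialect_version: str = DIALECT_VERSION


class ProjectParseError(ValueError):
    """Malformed markup; carries the source line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class ProjectSchemaError(ValueError):
    """Well-formed markup that violates the dialect; names the element path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_project(doc: ProjectDocument | str) -> Project:
    """Parse a project-definition document into a :class:`Project`.

    Unknown elements and attributes are kept as opaque extensions. Raises
    :class:`ProjectParseError` for malformed markup and
    :class:`ProjectSchemaError` when a mandatory part of the dialect is
    missing or ill-typed.
    """
    text = doc.text if isinstance(doc, ProjectDocument) else doc
    data = text.encode("utf-8") if isinstance(text, str) else text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as e:
        line = e.lineno if e.lineno else None
        raise ProjectParseError(str(e), line) from e
    tree = root.getroottree()
    enc = (tree.docinfo.encoding or "UTF-8").upper()
    if enc not in ("UTF-8", "US-ASCII"):
        raise ProjectParseError(f"documents must be UTF-8 encoded, declared {enc}")
    if root.tag != "project":
        raise ProjectSchemaError("/", f"root element must be <project>, got <{root.tag}>")

    name = _req_attr(root, "name", "project")
    project = Project(
        name=name,
        title=root.get("title", name),
        version=root.get("version", "1"),
        visibility=root.get("visibility", "public"),
        forms=[],
        extra_attrs=_extra_attrs(root, _PROJECT_ATTRS),
        extensions=_extensions(root, "project"),
    )
    forms = [el for el in root if isinstance(el.tag, str) and el.tag == "form"]
    if not forms:
        raise ProjectSchemaError(f"project[{name}]", "forms empty: a project needs at least one form")
    for fel in forms:
        project.forms.append(_parse_form(fel, name))
    return project


def _req_attr(el: etree._Element, attr: str, path: str) -> str:
    val = el.get(attr)
    if val is None:
        raise ProjectSchemaError(path, f"missing mandatory attribute {attr!r}")
    return val


def _extra_attrs(el: etree._Element, known: tuple[str, ...]) -> dict[str, str]:
    return {k: v for k, v in el.attrib.items() if k not in known}


def _extensions(el: etree._Element, tag: str) -> list[str]:
    known = _KNOWN_CHILDREN[tag]
    out = []
    for child in el:
        if isinstance(child.tag, str) and child.tag not in known:
            node = _detached(child)
            out.append(etree.tostring(node, encoding="unicode"))
    return out


def _detached(el: etree._Element) -> etree._Element:
    import copy

    node = copy.deepcopy(el)
    node.tail = None
    return node


def _parse_form(fel: etree._Element, project_name: str) -> Form:
    form_id = _req_attr(fel, "id", f"project[{project_name}].form")
    path = f"form[{form_id}]"
    branch_of = fel.get("branch-of")
    if branch_of is not None:
        host_field = _req_attr(fel, "branch-at", path)
        role: HierarchyRole | BranchRole = BranchRole(branch_of, host_field)
    else:
        level_s = fel.get("level")
        if level_s is None:
            raise ProjectSchemaError(path, "form needs either level= or branch-of=")
        try:
            role = HierarchyRole(int(level_s))
        except ValueError:
            raise ProjectSchemaError(path, f"level must be an integer, got {level_s!r}") from None
    form = Form(
        form_id=form_id,
        title=fel.get("title", form_id),
        fields=[],
        key_field=fel.get("key", AUTO),
        role=role,
        extra_attrs=_extra_attrs(fel, _FORM_ATTRS),
        extensions=_extensions(fel, "form"),
    )
    for el in fel:
        if isinstance(el.tag, str) and el.tag == "field":
            form.fields.append(_parse_field(el, path))
    return form


def _parse_field(el: etree._Element, form_path: str) -> Field:
    fid = _req_attr(el, "id", f"{form_path}.field")
    path = f"{form_path}.field[{fid}]"
    kind = _req_attr(el, "type", path)
    label = _req_attr(el, "label", path)
    validation = ValidationSpec(
        required=_bool(el.get("required", "false"), path),
        numeric=el.get("numeric", "none"),
        min=_num_or_none(el.get("min"), path),
        max=_num_or_none(el.get("max"), path),
        datetime_format=el.get("date"),
        regex=el.get("regex"),
    )
    fld = Field(
        field_id=fid,
        kind=kind,
        label=label,
        validation=validation,
        chartable=_bool(el.get("chartable", "false"), path),
        double_entry=_bool(el.get("double-entry", "false"), path),
        extra_attrs=_extra_attrs(el, _FIELD_ATTRS),
        extensions=_extensions(el, "field"),
    )
    for child in el:
        if not isinstance(child.tag, str):
            continue
        if child.tag == "choice":
            fld.choices.append(
                Choice(name=_req_attr(child, "name", path), value=_req_attr(child, "value", path))
            )
        elif child.tag == "jump":
            when = _req_attr(child, "when", path)
            fld.jumps.append(
                JumpClause(
                    trigger_values=tuple(v for v in when.split(",") if v),
                    destination=_req_attr(child, "to", path),
                )
            )
    return fld


def _bool(s: str, path: str) -> bool:
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ProjectSchemaError(path, f"boolean attribute must be true/false, got {s!r}")


def _num_or_none(s: str | None, path: str) -> float | None:
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        raise ProjectSchemaError(path, f"numeric attribute must be a number, got {s!r}") from None


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_project(project: Project) -> ProjectDocument:
    """Serialise a valid project canonically (deterministic attribute order,
    defaults omitted). Refuses invalid projects, attaching the report."""
    report = validate_project(project)
    if not report.ok:
        raise InvalidProjectError(report)
    root = etree.Element("project")
    root.set("name", project.name)
    root.set("title", project.title)
    root.set("version", project.version)
    root.set("visibility", project.visibility)
    root.set("dialect", DIALECT_VERSION)
    _set_extras(root, project.extra_attrs)
    level = 0
    for form in project.forms:
        fel = etree.SubElement(root, "form")
        fel.set("id", form.form_id)
        fel.set("title", form.title)
        fel.set("key", form.key_field)
        if form.is_branch:
            fel.set("branch-of", form.role.host_form)  # type: ignore[union-attr]
            fel.set("branch-at", form.role.host_field)  # type: ignore[union-attr]
        else:
            level += 1
            fel.set("level", str(level))
        _set_extras(fel, form.extra_attrs)
        for fld in form.fields:
            _write_field(fel, fld)
        _append_extensions(fel, form.extensions)
    _append_extensions(root, project.extensions)
    blob = etree.tostring(
        root, encoding="UTF-8", xml_declaration=True, pretty_print=True
    )
    return ProjectDocument(text=blob.decode("utf-8"))


def _write_field(parent: etree._Element, fld: Field) -> None:
    el = etree.SubElement(parent, "field")
    el.set("id", fld.field_id)
    el.set("type", fld.kind)
    el.set("label", fld.label)
    v = fld.validation
    if v.required:
        el.set("required", "true")
    if v.numeric != "none":
        el.set("numeric", v.numeric)
    if v.min is not None:
        el.set("min", _fmt_num(v.min))
    if v.max is not None:
        el.set("max", _fmt_num(v.max))
    if v.datetime_format is not None:
        el.set("date", v.datetime_format)
    if v.regex is not None:
        el.set("regex", v.regex)
    if fld.double_entry:
        el.set("double-entry", "true")
    if fld.chartable:
        el.set("chartable", "true")
    _set_extras(el, fld.extra_attrs)
    for c in fld.choices:
        cel = etree.SubElement(el, "choice")
        cel.set("name", c.name)
        cel.set("value", c.value)
    for j in fld.jumps:
        jel = etree.SubElement(el, "jump")
        jel.set("when", ",".join(j.trigger_values))
        jel.set("to", j.destination)
    _append_extensions(el, fld.extensions)


def _set_extras(el: etree._Element, extras: dict[str, str]) -> None:
    for k in sorted(extras):
        el.set(k, extras[k])


def _append_extensions(el: etree._Element, extensions: list[str]) -> None:
    for markup in extensions:
        el.append(etree.fromstring(markup))


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


# ---------------------------------------------------------------------------
# JSON mirror
# ---------------------------------------------------------------------------

def project_to_json(project: Project) -> dict:
    """Field-for-field JSON mirror of the XML dialect."""
    report = validate_project(project)
    if not report.ok:
        raise InvalidProjectError(report)
    return {
        "dialect": DIALECT_VERSION,
        "name": project.name,
        "title": project.title,
        "version": project.version,
        "visibility": project.visibility,
        "extra_attrs": project.extra_attrs,
        "extensions": project.extensions,
        "forms": [_form_to_json(f) for f in project.forms],
    }


def _form_to_json(form: Form) -> dict:
    d: dict = {"id": form.form_id, "title": form.title, "key": form.key_field}
    if form.is_branch:
        d["branch_of"] = form.role.host_form  # type: ignore[union-attr]
        d["branch_at"] = form.role.host_field  # type: ignore[union-attr]
    else:
        d["level"] = form.role.level  # type: ignore[union-attr]
    d["extra_attrs"] = form.extra_attrs
    d["extensions"] = form.extensions
    d["fields"] = [_field_to_json(f) for f in form.fields]
    return d


def _field_to_json(fld: Field) -> dict:
    v = fld.validation
    return {
        "id": fld.field_id,
        "type": fld.kind,
        "label": fld.label,
        "required": v.required,
        "numeric": v.numeric,
        "min": v.min,
        "max": v.max,
        "date": v.datetime_format,
        "regex": v.regex,
        "double_entry": fld.double_entry,
        "chartable": fld.chartable,
        "choices": [{"name": c.name, "value": c.value} for c in fld.choices],
        "jumps": [{"when": list(j.trigger_values), "to": j.destination} for j in fld.jumps],
        "extra_attrs": fld.extra_attrs,
        "extensions": fld.extensions,
    }


def project_from_json(data: dict) -> Project:
    project = Project(
        name=data["name"],
        title=data.get("title", data["name"]),
        version=data.get("version", "1"),
        visibility=data.get("visibility", "public"),
        forms=[],
        extra_attrs=dict(data.get("extra_attrs", {})),
        extensions=list(data.get("extensions", [])),
    )
    for fd in data["forms"]:
        if "branch_of" in fd:
            role: HierarchyRole | BranchRole = BranchRole(fd["branch_of"], fd["branch_at"])
        else:
            role = HierarchyRole(int(fd["level"]))
        form = Form(
            form_id=fd["id"],
            title=fd.get("title", fd["id"]),
            fields=[],
            key_field=fd.get("key", AUTO),
            role=role,
            extra_attrs=dict(fd.get("extra_attrs", {})),
            extensions=list(fd.get("extensions", [])),
        )
        for fld in fd.get("fields", []):
            form.fields.append(
                Field(
                    field_id=fld["id"],
                    kind=fld["type"],
                    label=fld["label"],
                    choices=[Choice(c["name"], c["value"]) for c in fld.get("choices", [])],
                    validation=ValidationSpec(
                        required=fld.get("required", False),
                        numeric=fld.get("numeric", "none"),
                        min=fld.get("min"),
                        max=fld.get("max"),
                        datetime_format=fld.get("date"),
                        regex=fld.get("regex"),
                    ),
                    jumps=[
                        JumpClause(tuple(j["when"]), j["to"]) for j in fld.get("jumps", [])
                    ],
                    chartable=fld.get("chartable", False),
                    double_entry=fld.get("double_entry", False),
                    extra_attrs=dict(fld.get("extra_attrs", {})),
                    extensions=list(fld.get("extensions", [])),
                )
            )
        project.forms.append(form)
    return project


def write_project_json(project: Project) -> str:
    return json.dumps(project_to_json(project), indent=2) + "\n"


def parse_project_json(text: str) -> Project:
    return project_from_json(json.loads(text))


# ---------------------------------------------------------------------------
# Bundled schema
# ---------------------------------------------------------------------------

def load_xml_schema() -> etree.XMLSchema:
    """The bundled XSD for the core dialect (extension elements fall outside
    it by design; they live in foreign namespaces or are validated by parse)."""
    with resources.files("fieldform.schemas").joinpath("project.xsd").open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def validate_document(doc: ProjectDocument | str) -> list[str]:
    """Validate a document against the bundled XSD; returns a list of
    messages, empty when the document conforms."""
    text = doc.text if isinstance(doc, ProjectDocument) else doc
    schema = load_xml_schema()
    try:
        root = etree.fromstring(text.encode("utf-8") if isinstance(text, str) else text)
    except etree.XMLSyntaxError as e:
        return [str(e)]
    if schema.validate(root):
        return []
    return [str(e) for e in schema.error_log]
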