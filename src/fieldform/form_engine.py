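"""Interview engine: run a session over one form.

Fields are presented in declared order; answering a dropdown/radio question
may *jump* the cursor to a later field (or the end) according to the field's
jump clauses — the first declared clause whose trigger values contain the
answer wins, otherwise the interview continues with the next field. Jumps are
forward-only, so every session terminates in at most ``len(fields)``
submissions and no field is visited twice.

Answers are validated before the cursor moves: a failed submission leaves the
session exactly where it was. Validation rules are applied in a fixed order
(required, choice membership / type, numeric parse, min/max, datetime format,
regex, double-entry cross-check) and *all* failures are collected, not just
the first.

Answering a ``branch_trigger`` question with a positive count pauses the
session (``BRANCH_PROMPT``) so the caller can fill in any number of branch
sub-sessions before continuing; the resulting branch entries are attached to
the host entry when it is finalised.

The clock and device identifier are injected, never read from the host, so
every flow is reproducible.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

from .project_model import (
    AUTO,
    END,
    Field,
    Form,
    Project,
    branches_of,
)

Clock = Callable[[], int]  # returns UTC epoch milliseconds


_last_system_ms = 0


def system_clock() -> int:
    """Wall clock in epoch ms, strictly increasing within the process: two
    entries finalised in the same millisecond must still get distinct
    timestamps, or their auto keys and ids would collide."""
    global _last_system_ms
    now = time.time_ns() // 1_000_000
    if now <= _last_system_ms:
        now = _last_system_ms + 1
    _last_system_ms = now
    return now


class ManualClock:
    """Deterministic strictly-increasing clock for tests and simulations."""

    def __init__(self, start_ms: int = 1_400_000_000_000, step_ms: int = 1):
        self.now = start_ms
        self.step = step_ms

    def __call__(self) -> int:
        t = self.now
        self.now += self.step
        return t


# ---------------------------------------------------------------------------
# Answer values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Location:
    """A GPS fix: latitude/longitude in decimal degrees, altitude and
    accuracy in metres."""

    lat: float
    lon: float
    alt: float
    accuracy: float


@dataclass(frozen=True)
class MediaRef:
    kind: str  # image | video | audio
    uri: str
    thumbnail_uri: str | None = None  # images only


@dataclass(frozen=True)
class Answer:
    """A typed, validated answer. ``value`` is a str for text/choice/barcode
    kinds, a tuple of choice values for checkbox, an int/float for numeric
    fields and branch-trigger counts, a :class:`Location` or a
    :class:`MediaRef` for media kinds."""

    kind: str
    value: object


@dataclass(frozen=True)
class ValidationError:
    code: str
    message: str
    severity: str = "error"  # error | warning


@dataclass
class Entry:
    """One completed form instance. Every entry gets a globally unique id and
    a creation timestamp; entries below the top of the hierarchy carry the
    key of their parent entry."""

    entry_id: str
    form_id: str
    key_value: str
    parent_key: str | None
    created_at: int  # epoch ms
    device_id: str
    answers: dict[str, Answer]
    branch_children: dict[str, list["Entry"]] = dc_field(default_factory=dict)


class FormFlowError(ValueError):
    """Session misuse: orphan session, submit after completion, premature
    finalise, script/cursor mismatch."""


# ---------------------------------------------------------------------------
# Answer validation
# ---------------------------------------------------------------------------

_LOCATION_SEP = ";"
_CHECKBOX_SEP = ";"

_DATE_TOKENS = [("yyyy", "%Y"), ("yy", "%y"), ("dd", "%d"), ("hh", "%H"), ("ss", "%S")]


def _strptime_pattern(fmt: str) -> str:
    """Translate a display-style datetime pattern (dd/mm/yyyy, mm:ss, ...)
    into a strptime pattern. ``mm`` means month in a date context (pattern
    also mentions dd or a year token) and minutes otherwise."""
    month_context = "dd" in fmt or "yy" in fmt
    out = fmt
    for tok, rep in _DATE_TOKENS:
        out = out.replace(tok, rep)
    out = out.replace("mm", "%m" if month_context else "%M")
    return out


def check_answer(
    field: Field,
    raw: str | Sequence[str] | None,
    *,
    regex_mode: str = "error",
) -> tuple[Answer | None, list[ValidationError]]:
    """Validate a raw submission against a field, returning the typed answer
    (or ``None`` for a blank optional field) plus every rule violation.

    ``regex_mode`` is ``"error"`` (default) or ``"warn"``: in warn mode a
    pattern mismatch is reported but does not block the answer.
    """
    issues: list[ValidationError] = []
    v = field.validation

    # normalise raw: a pair for double-entry fields, a single string otherwise
    second: str | None = None
    if isinstance(raw, (tuple, list)):
        if len(raw) != 2:
            return None, [ValidationError("raw_shape", "expected (value, repeat) pair")]
        raw, second = raw[0], raw[1]
    if raw is None:
        raw = ""
    raw = raw.strip()
    if field.double_entry:
        if second is None:
            issues.append(ValidationError("double_entry", "field requires the value to be entered twice"))
        else:
            second = second.strip()
            if second != raw:
                issues.append(ValidationError("double_entry", "the two entries differ; they must be identical"))

    if raw == "":
        if v.required:
            issues.append(ValidationError("required", f"{field.label!r} must be answered"))
            return None, issues
        # a blank optional field is skipped; only a non-blank repeat conflicts
        return None, [i for i in issues if not (i.code == "double_entry" and not second)]

    answer, typed_issues = _typed_value(field, raw)
    issues.extend(typed_issues)

    # numeric / range rules (text-like kinds and branch triggers)
    value = answer.value if answer is not None else None
    if v.numeric != "none" and isinstance(value, str):
        num, num_issues = _parse_number(value, v.numeric)
        issues.extend(num_issues)
        if num is not None:
            value = num
            answer = Answer(field.kind, num)
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if v.min is not None and value < v.min:
            issues.append(ValidationError("min", f"value {value} below minimum {_fmt_num(v.min)}"))
        if v.max is not None and value > v.max:
            issues.append(ValidationError("max", f"value {value} above maximum {_fmt_num(v.max)}"))

    if v.datetime_format is not None and isinstance(value, str):
        import datetime as _dt

        try:
            _dt.datetime.strptime(value, _strptime_pattern(v.datetime_format))
        except ValueError:
            issues.append(
                ValidationError("datetime", f"value does not match format {v.datetime_format!r}")
            )

    if v.regex is not None:
        if not re.search(v.regex, raw):
            severity = "warning" if regex_mode == "warn" else "error"
            issues.append(
                ValidationError("regex", f"value does not match pattern {v.regex!r}", severity)
            )

    if any(i.severity == "error" for i in issues):
        return None, issues
    return answer, issues


def validate_answer(
    field: Field,
    raw: str | Sequence[str] | None,
    *,
    regex_mode: str = "error",
) -> Answer | None | list[ValidationError]:
    """Spec-shaped wrapper around :func:`check_answer`: the typed answer on
    success (``None`` for blank optional), otherwise the list of errors."""
    answer, issues = check_answer(field, raw, regex_mode=regex_mode)
    errors = [i for i in issues if i.severity == "error"]
    return errors if errors else answer


def _typed_value(field: Field, raw: str) -> tuple[Answer | None, list[ValidationError]]:
    kind = field.kind
    if kind in ("text", "long_text", "barcode"):
        return Answer(kind, raw), []
    if kind in ("dropdown", "radio"):
        if raw not in field.choice_values():
            return None, [ValidationError("choice", f"{raw!r} is not one of the declared choices")]
        return Answer(kind, raw), []
    if kind == "checkbox":
        parts = [p.strip() for p in raw.split(_CHECKBOX_SEP) if p.strip()]
        declared = field.choice_values()
        bad = [p for p in parts if p not in declared]
        if bad:
            return None, [ValidationError("choice", f"{bad[0]!r} is not one of the declared choices")]
        # store in declared-choice order, deduplicated
        chosen = tuple(v for v in declared if v in set(parts))
        return Answer(kind, chosen), []
    if kind == "location":
        parts = raw.split(_LOCATION_SEP)
        if len(parts) != 4:
            return None, [
                ValidationError("location", "expected lat;lon;alt;accuracy (four numbers)")
            ]
        try:
            lat, lon, alt, acc = (float(p) for p in parts)
        except ValueError:
            return None, [ValidationError("location", "location components must be numbers")]
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            return None, [ValidationError("location", "latitude/longitude out of range")]
        return Answer(kind, Location(lat, lon, alt, acc)), []
    if kind in ("image", "video", "audio"):
        thumb = raw + ".thumb.jpg" if kind == "image" else None
        return Answer(kind, MediaRef(kind, raw, thumb)), []
    if kind == "branch_trigger":
        num, issues = _parse_number(raw, "integer")
        if num is None:
            return None, issues
        if num < 0:
            return None, [ValidationError("min", "branch count cannot be negative")]
        return Answer(kind, int(num)), []
    return None, [ValidationError("kind", f"unknown field kind {kind!r}")]


def _parse_number(raw: str, mode: str) -> tuple[int | float | None, list[ValidationError]]:
    try:
        if mode == "integer":
            return int(raw), []
        return float(raw), []
    except ValueError:
        noun = "an integer" if mode == "integer" else "a number"
        return None, [ValidationError("numeric", f"value must be {noun}, got {raw!r}")]


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


# ---------------------------------------------------------------------------
# Skip logic
# ---------------------------------------------------------------------------

def next_field(form: Form, at: str, answer: Answer | None) -> str:
    """The field the interview moves to after ``at`` is answered: the first
    matching jump clause wins, otherwise the next field in order; past the
    last field the result is :data:`END`."""
    fld = form.get_field(at)
    if fld.jumps:
        if answer is not None and not isinstance(answer.value, str):
            raise TypeError(
                f"jump triggers need a single choice value, got {type(answer.value).__name__}"
            )
        if answer is not None:
            for clause in fld.jumps:
                if answer.value in clause.trigger_values:
                    return clause.destination
    ids = form.field_ids()
    pos = ids.index(at)
    return ids[pos + 1] if pos + 1 < len(ids) else END


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

@dataclass
class Session:
    project: Project
    form_id: str
    parent_key: str | None
    device_id: str
    clock: Clock
    cursor: str  # field id, or END when complete
    started_at: int
    answers: dict[str, Answer] = dc_field(default_factory=dict)
    visited: list[str] = dc_field(default_factory=list)
    pending_branch_entries: dict[str, list[Entry]] = dc_field(default_factory=dict)
    warnings: list[ValidationError] = dc_field(default_factory=list)
    awaiting_branch: str | None = None  # host field id while at a BRANCH_PROMPT
    _resume_cursor: str | None = None
    regex_mode: str = "error"

    @property
    def form(self) -> Form:
        return self.project.get_form(self.form_id)

    @property
    def complete(self) -> bool:
        return self.cursor == END and self.awaiting_branch is None


@dataclass
class SubmitResult:
    status: str  # next | branch_prompt | complete | invalid
    next: str | None = None  # field id when status == next
    host_field: str | None = None  # when status == branch_prompt
    errors: list[ValidationError] = dc_field(default_factory=list)


def start_session(
    project: Project,
    form_id: str,
    parent_key: str | None = None,
    *,
    device_id: str,
    clock: Clock,
    regex_mode: str = "error",
) -> Session:
    """Open an interview over ``form_id``. Forms below the top of the
    hierarchy, and branch forms, need the key of the entry they hang off."""
    form = project.get_form(form_id)
    needs_parent = form.is_branch or form.role.level >= 2  # type: ignore[union-attr]
    if needs_parent and parent_key is None:
        raise FormFlowError(
            f"orphan session: form {form_id!r} needs the parent entry's key"
        )
    if not form.fields:
        raise FormFlowError(f"form {form_id!r} has no fields")
    return Session(
        project=project,
        form_id=form_id,
        parent_key=parent_key,
        device_id=device_id,
        clock=clock,
        cursor=form.fields[0].field_id,
        started_at=clock(),
        regex_mode=regex_mode,
    )


def submit_answer(session: Session, raw: str | Sequence[str] | None) -> SubmitResult:
    """Validate and record the answer to the field at the cursor, then
    advance. Validation errors leave the cursor unmoved. Answering a
    branch-trigger question with a positive count pauses at a
    ``branch_prompt``; resume with :func:`proceed_after_branch`."""
    if session.awaiting_branch is not None:
        raise FormFlowError("session is at a branch prompt; call proceed_after_branch")
    if session.cursor == END:
        raise FormFlowError("session already complete")
    fld = session.form.get_field(session.cursor)
    answer, issues = check_answer(fld, raw, regex_mode=session.regex_mode)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        return SubmitResult(status="invalid", errors=errors)
    session.warnings.extend(i for i in issues if i.severity == "warning")
    if session.cursor not in session.visited:
        session.visited.append(session.cursor)
    if answer is not None:
        session.answers[fld.field_id] = answer
    nxt = next_field(session.form, session.cursor, answer)

    if (
        fld.kind == "branch_trigger"
        and answer is not None
        and isinstance(answer.value, int)
        and answer.value > 0
        and any(hf == fld.field_id for hf, _ in branches_of(session.project, session.form_id))
    ):
        session.awaiting_branch = fld.field_id
        session._resume_cursor = nxt
        return SubmitResult(status="branch_prompt", host_field=fld.field_id)

    session.cursor = nxt
    if nxt == END:
        return SubmitResult(status="complete")
    return SubmitResult(status="next", next=nxt)


def begin_branch(session: Session) -> Session:
    """Open a sub-session for the branch form attached to the trigger the
    host session is paused at. The branch entry's parent key is the host
    entry's key; if the host key is not known yet (AUTO, or a later field)
    it is stamped in at host finalise time."""
    if session.awaiting_branch is None:
        raise FormFlowError("no branch prompt pending")
    host_field = session.awaiting_branch
    attachments = dict(branches_of(session.project, session.form_id))
    branch_form_id = attachments[host_field]
    host_key = _current_key(session)
    branch = Session(
        project=session.project,
        form_id=branch_form_id,
        parent_key=host_key,  # may be None until the host is finalised
        device_id=session.device_id,
        clock=session.clock,
        cursor=session.project.get_form(branch_form_id).fields[0].field_id,
        started_at=session.clock(),
        regex_mode=session.regex_mode,
    )
    return branch


def attach_branch_entry(session: Session, entry: Entry) -> None:
    if session.awaiting_branch is None:
        raise FormFlowError("no branch prompt pending")
    session.pending_branch_entries.setdefault(session.awaiting_branch, []).append(entry)


def proceed_after_branch(session: Session) -> SubmitResult:
    """Resume the host session after 0..n branch sub-sessions."""
    if session.awaiting_branch is None:
        raise FormFlowError("no branch prompt pending")
    session.awaiting_branch = None
    nxt = session._resume_cursor
    session._resume_cursor = None
    assert nxt is not None
    session.cursor = nxt
    if nxt == END:
        return SubmitResult(status="complete")
    return SubmitResult(status="next", next=nxt)


def _current_key(session: Session) -> str | None:
    kf = session.form.key_field
    if kf == AUTO:
        return None
    ans = session.answers.get(kf)
    if ans is None:
        return None
    return str(ans.value)


# ---------------------------------------------------------------------------
# Keys and finalisation
# ---------------------------------------------------------------------------

def generate_auto_key(device_uuid: str, timestamp_ms: int) -> str:
    """Auto key: the device's unique identifier joined to the entry creation
    time in milliseconds. Distinct (uuid, time) pairs give distinct keys, so
    re-submitting the same entry can be recognised and dropped."""
    if not device_uuid:
        raise ValueError("device uuid must be non-empty")
    if timestamp_ms < 0:
        raise ValueError("timestamp must be non-negative")
    return f"{device_uuid}_{int(timestamp_ms)}"


def finalize_entry(session: Session) -> Entry:
    """Seal a completed session into an :class:`Entry`: stamp the creation
    time, derive the key (user-chosen field or auto), copy the parent key and
    attach any branch children collected along the way."""
    if not session.complete:
        raise FormFlowError("session is not complete")
    missing = [
        fid
        for fid in session.visited
        if session.form.get_field(fid).validation.required and fid not in session.answers
    ]
    if missing:
        raise FormFlowError(f"missing required answers: {', '.join(missing)}")

    created_at = session.clock()
    form = session.form
    if form.key_field == AUTO:
        key_value = generate_auto_key(session.device_id, created_at)
    else:
        ans = session.answers.get(form.key_field)
        if ans is None or str(ans.value) == "":
            raise FormFlowError(f"key field {form.key_field!r} was not answered")
        key_value = str(ans.value)

    # branch entries may be sealed before their host's key exists; the host
    # finalise stamps their parent_key in
    if not form.is_branch and form.role.level >= 2 and session.parent_key is None:
        raise FormFlowError("entry below the top level needs a parent key")

    children = {hf: list(entries) for hf, entries in session.pending_branch_entries.items()}
    for entries in children.values():
        for child in entries:
            child.parent_key = key_value

    return Entry(
        entry_id=f"{session.device_id}_{created_at}",
        form_id=session.form_id,
        key_value=key_value,
        parent_key=session.parent_key,
        created_at=created_at,
        device_id=session.device_id,
        answers=dict(session.answers),
        branch_children=children,
    )


# ---------------------------------------------------------------------------
# Scripted sessions (non-interactive collection)
# ---------------------------------------------------------------------------

@dataclass
class ScriptAnswer:
    field_id: str
    raw: str
    second: str | None = None


@dataclass
class ScriptBranch:
    records: list["ScriptRecord"]


ScriptRecord = ScriptAnswer | ScriptBranch


def parse_script(text: str) -> list[ScriptRecord]:
    """Parse a scripted-answer file: one tab-separated record per submission
    (``field_id<TAB>value[<TAB>repeat]``); branch sub-sessions are wrapped in
    ``[branch]`` / ``[/branch]`` lines; ``#`` starts a comment."""
    records: list[ScriptRecord] = []
    stack: list[list[ScriptRecord]] = [records]
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        stripped = line.strip()
        if stripped == "[branch]":
            branch = ScriptBranch(records=[])
            stack[-1].append(branch)
            stack.append(branch.records)
            continue
        if stripped == "[/branch]":
            if len(stack) == 1:
                raise ValueError(f"line {lineno}: [/branch] without [branch]")
            stack.pop()
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ValueError(f"line {lineno}: expected field_id<TAB>value[<TAB>repeat]")
        stack[-1].append(ScriptAnswer(parts[0], parts[1], parts[2] if len(parts) == 3 else None))
    if len(stack) != 1:
        raise ValueError("unterminated [branch] block")
    return records


def run_script(
    project: Project,
    form_id: str,
    records: list[ScriptRecord],
    *,
    parent_key: str | None = None,
    device_id: str,
    clock: Clock,
    regex_mode: str = "error",
) -> Entry:
    """Execute a scripted session and return the finalised entry. Each answer
    record must name the field the cursor is at; branch blocks right after a
    trigger answer become branch entries."""
    session = start_session(
        project, form_id, parent_key, device_id=device_id, clock=clock, regex_mode=regex_mode
    )
    i = 0
    while i < len(records):
        rec = records[i]
        if isinstance(rec, ScriptBranch):
            raise FormFlowError("branch block without a pending branch prompt")
        if rec.field_id != session.cursor:
            raise FormFlowError(
                f"script answers {rec.field_id!r} but the cursor is at {session.cursor!r}"
            )
        raw: str | tuple[str, str] = rec.raw if rec.second is None else (rec.raw, rec.second)
        result = submit_answer(session, raw)
        if result.status == "invalid":
            msgs = "; ".join(e.message for e in result.errors)
            raise FormFlowError(f"invalid answer for {rec.field_id!r}: {msgs}")
        i += 1
        if result.status == "branch_prompt":
            while i < len(records) and isinstance(records[i], ScriptBranch):
                block = records[i]
                assert isinstance(block, ScriptBranch)
                branch_session = begin_branch(session)
                child = _run_branch(branch_session, block.records)
                attach_branch_entry(session, child)
                i += 1
            proceed_after_branch(session)
    if not session.complete:
        raise FormFlowError(f"script ended but the cursor is at {session.cursor!r}")
    return finalize_entry(session)


def _run_branch(session: Session, records: list[ScriptRecord]) -> Entry:
    for rec in records:
        if isinstance(rec, ScriptBranch):
            raise FormFlowError("nested branch blocks are not supported")
        if rec.field_id != session.cursor:
            raise FormFlowError(
                f"branch script answers {rec.field_id!r} but the cursor is at {session.cursor!r}"
            )
        raw: str | tuple[str, str] = rec.raw if rec.second is None else (rec.raw, rec.second)
        result = submit_answer(session, raw)
        if result.status == "invalid":
            msgs = "; ".join(e.message for e in result.errors)
            raise FormFlowError(f"invalid branch answer for {rec.field_id!r}: {msgs}")
    if not session.complete:
        raise FormFlowError("branch script incomplete")
    return finalize_entry(session)
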