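"""Shared fixtures and the naive skip-logic oracle.

The naive interpreter below scans jump clauses literally over the field
list, independent of the session engine, so the two can be compared
exhaustively on generated forms.
"""

from __future__ import annotations

import itertools

import pytest

import fieldform as ff


@pytest.fixture
def schools():
    return ff.schools_demo_project()


@pytest.fixture
def clock():
    return ff.ManualClock(start_ms=1_408_500_000_000, step_ms=1000)


def naive_visit_sequence(form, assignment: dict[str, str]) -> list[str]:
    """Brute-force interpretation of a choice-only form: walk the field
    list, scanning each field's clauses in declared order and following the
    first whose triggers contain the answer."""
    order = [f.field_id for f in form.fields]
    visited: list[str] = []
    i = 0
    while i < len(order):
        fld = form.fields[i]
        visited.append(fld.field_id)
        ans = assignment[fld.field_id]
        dest = None
        for clause in fld.jumps:
            if ans in clause.trigger_values:
                dest = clause.destination
                break
        if dest is None:
            i += 1
        elif dest == ff.END:
            break
        else:
            i = order.index(dest)
    return visited


def engine_visit_sequence(project, form, assignment: dict[str, str]) -> list[str]:
    """The same interview executed by the session engine."""
    session = ff.start_session(
        project, form.form_id, device_id="oracle", clock=ff.ManualClock()
    )
    visited: list[str] = []
    while not session.complete:
        visited.append(session.cursor)
        result = ff.submit_answer(session, assignment[session.cursor])
        assert result.status != "invalid", result.errors
    return visited


def choice_form_project(form) -> "ff.Project":
    """Wrap a single choice-only form as a minimal project."""
    return ff.Project(name="flow", title="Flow", version="1", forms=[form])


def all_assignments(form):
    """Every combination of choice answers for a choice-only form."""
    ids = [f.field_id for f in form.fields]
    value_sets = [f.choice_values() for f in form.fields]
    for combo in itertools.product(*value_sets):
        yield dict(zip(ids, combo))
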