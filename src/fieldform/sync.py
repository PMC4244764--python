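"""Client -> server synchronisation.

Entries travel top-down: level 1 first, then each level below, so a child
can never reach the server before its parent and key integrity is preserved
end to end. Branch entries travel immediately after their host entry.
Textual data syncs in full; for photos only a thumbnail is sent by default,
with full images, video and audio deferred to a separate transfer (the
user's choice of when to pay for the large payloads).

Rejected entries stay queued client-side and reappear in the next batch
build, so repeated sync rounds converge: once every parent has arrived,
every child is accepted, and applying any batch twice is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .datastore import EntryStore
from .form_engine import Entry, MediaRef
from .project_model import Project

MEDIA_POLICIES = ("default", "send_all", "defer_all")


@dataclass
class MediaTransfer:
    entry_id: str
    field_id: str
    payload_class: str  # thumbnail | full_image | video | audio
    deferred: bool


@dataclass
class SyncBatch:
    """Entries of one hierarchy level (hosts interleaved with their branch
    entries, host first), plus the media transfer plan for them."""

    entries: list[Entry]
    media_plan: list[MediaTransfer] = dc_field(default_factory=list)


@dataclass
class SyncResult:
    statuses: dict[str, tuple[str, str | None]]  # entry_id -> (status, reason)

    @property
    def counts(self) -> dict[str, int]:
        out = {"accepted": 0, "rejected": 0, "duplicate": 0}
        for status, _ in self.statuses.values():
            out[status] += 1
        return out


def build_batches(client_store: EntryStore, policy: str = "default") -> list[SyncBatch]:
    """One batch per hierarchy level, top level first, containing every
    unsynced entry exactly once; each host entry is immediately followed by
    its unsynced branch entries. Deterministic given the store state."""
    project = client_store.project
    branch_by_host_form: dict[str, list[str]] = {}
    for b in project.branch_forms():
        branch_by_host_form.setdefault(b.role.host_form, []).append(b.form_id)  # type: ignore[union-attr]

    batches: list[SyncBatch] = []
    for form in project.hierarchy_forms():
        ordered: list[Entry] = []
        hosts = client_store.entries[form.form_id]
        branch_forms = branch_by_host_form.get(form.form_id, [])
        branch_entries: dict[str, list[Entry]] = {
            bf: [e for e in client_store.entries[bf] if e.entry_id not in client_store.synced]
            for bf in branch_forms
        }
        for host in hosts:
            if host.entry_id not in client_store.synced:
                ordered.append(host)
            for bf in branch_forms:
                for be in branch_entries[bf]:
                    if be.parent_key == host.key_value:
                        ordered.append(be)
            for bf in branch_forms:
                branch_entries[bf] = [
                    be for be in branch_entries[bf] if be.parent_key != host.key_value
                ]
        # branch entries whose host is not in this store (should not happen
        # for engine-produced stores) still go out, after all hosts
        for bf in branch_forms:
            ordered.extend(branch_entries[bf])
        if ordered:
            batches.append(SyncBatch(entries=ordered, media_plan=plan_media(ordered, policy)))
    return batches


def plan_media(entries: list[Entry], policy: str = "default") -> list[MediaTransfer]:
    """Media transfer plan for a set of finalised entries.

    default   — image thumbnails immediate; full images, video, audio deferred
    send_all  — nothing deferred
    defer_all — only thumbnails immediate
    """
    if policy not in MEDIA_POLICIES:
        raise ValueError(f"unknown media policy {policy!r}")
    plan: list[MediaTransfer] = []
    for entry in entries:
        for field_id, answer in entry.answers.items():
            ref = answer.value
            if not isinstance(ref, MediaRef):
                continue
            if ref.kind == "image":
                plan.append(MediaTransfer(entry.entry_id, field_id, "thumbnail", deferred=False))
                plan.append(
                    MediaTransfer(
                        entry.entry_id, field_id, "full_image", deferred=(policy != "send_all")
                    )
                )
            else:
                plan.append(
                    MediaTransfer(
                        entry.entry_id, field_id, ref.kind, deferred=(policy != "send_all")
                    )
                )
    return plan


def apply_batch(server_store: EntryStore, batch: SyncBatch) -> SyncResult:
    """Apply a batch entry by entry. Duplicates are reported, not errors —
    the same batch can safely arrive twice. Server integrity holds after any
    sequence of applications."""
    statuses: dict[str, tuple[str, str | None]] = {}
    for entry in batch.entries:
        res = server_store.insert_entry(_shallow(entry))
        if res.accepted:
            statuses[entry.entry_id] = ("accepted", None)
        elif res.reason == "duplicate":
            statuses[entry.entry_id] = ("duplicate", None)
        else:
            statuses[entry.entry_id] = ("rejected", res.reason)
    return SyncResult(statuses=statuses)


def _shallow(entry: Entry) -> Entry:
    """Server-side copy without nested branch children: branch entries are
    listed in the batch in their own right, right after their host."""
    return Entry(
        entry_id=entry.entry_id,
        form_id=entry.form_id,
        key_value=entry.key_value,
        parent_key=entry.parent_key,
        created_at=entry.created_at,
        device_id=entry.device_id,
        answers=dict(entry.answers),
        branch_children={},
    )


def sync_round(client_store: EntryStore, server_store: EntryStore, policy: str = "default") -> SyncResult:
    """One full client->server round: build batches, apply them in order,
    mark accepted (and already-present) entries as synced client-side."""
    statuses: dict[str, tuple[str, str | None]] = {}
    for batch in build_batches(client_store, policy):
        result = apply_batch(server_store, batch)
        statuses.update(result.statuses)
        for entry_id, (status, _) in result.statuses.items():
            if status in ("accepted", "duplicate"):
                client_store.synced.add(entry_id)
    return SyncResult(statuses=statuses)


def sync_until_converged(
    client_store: EntryStore, server_store: EntryStore, max_rounds: int = 10
) -> int:
    """Repeat sync rounds until nothing is rejected; returns the number of
    rounds used. Converges because each round can only shrink the unsynced
    set and every parent eventually precedes its children."""
    for rounds in range(1, max_rounds + 1):
        result = sync_round(client_store, server_store)
        if result.counts["rejected"] == 0:
            return rounds
    raise RuntimeError(f"sync did not converge in {max_rounds} rounds")


# ---------------------------------------------------------------------------
# In-process submission/retrieval contract (the transport the server exposes)
# ---------------------------------------------------------------------------

class SyncServer:
    """In-process server endpoint: fetch a project definition by name,
    submit an entry batch. Stands in for the two-endpoint wire contract."""

    def __init__(self, projects: dict[str, Project] | None = None):
        self.projects: dict[str, Project] = dict(projects or {})
        self.stores: dict[str, EntryStore] = {
            name: EntryStore(p) for name, p in self.projects.items()
        }

    def add_project(self, project: Project) -> None:
        self.projects[project.name] = project
        self.stores[project.name] = EntryStore(project)

    def fetch_project(self, name: str):
        from .project_io import write_project

        if name not in self.projects:
            raise KeyError(f"no project {name!r} on this server")
        return write_project(self.projects[name])

    def submit(self, name: str, batch: SyncBatch) -> SyncResult:
        if name not in self.stores:
            raise KeyError(f"no project {name!r} on this server")
        return apply_batch(self.stores[name], batch)
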