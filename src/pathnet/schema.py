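"""Repository-document schema and validation.

The on-disk store is a single UTF-8 JSON document with a fixed
``format_version`` and nine record collections::

    format_version     "1.0"
    organisms          [{id, name}]
    entity_types       [{id, label}]
    interaction_types  [{id, label, is_regulatory}]
    cell_locations     [{id, name, parent}]          parent: id | null
    pathway_classes    [{id, name, parent}]
    entities           [{id, name, entity_type, organism, synonyms}]
    local_entities     [{id, entity, location}]
    interactions       [{id, interaction_type, organism, participants}]
    pathways           [{id, name, organism, pathway_class, interactions}]

Participants are ``{local_entity, role, modifier_effect?, stoichiometry?}``
with ``role`` in {input, output, modifier}.

:func:`validate_document` checks structure and field types and reports the
first violation with a JSON-pointer-style path (``/interactions/3/
participants/0/role``).  Referential integrity (every cross-reference
resolves) is a separate pass, :func:`check_references`, so callers can
defer it.
"""

from __future__ import annotations

from typing import Any

from .errors import IntegrityError, ValidationError
from .model import MODIFIER_EFFECTS, ROLES

FORMAT_VERSION = "1.0"

#: collection name -> (required fields, optional fields)
_RECORD_FIELDS: dict[str, tuple[dict[str, type], dict[str, Any]]] = {
    "organisms": ({"id": str, "name": str}, {}),
    "entity_types": ({"id": str, "label": str}, {}),
    "interaction_types": ({"id": str, "label": str, "is_regulatory": bool}, {}),
    "cell_locations": ({"id": str, "name": str}, {"parent": (str, type(None))}),
    "pathway_classes": ({"id": str, "name": str}, {"parent": (str, type(None))}),
    "entities": (
        {"id": str, "name": str, "entity_type": str},
        {"organism": (str, type(None)), "synonyms": list},
    ),
    "local_entities": ({"id": str, "entity": str, "location": str}, {}),
    "interactions": (
        {"id": str, "interaction_type": str, "participants": list},
        {"organism": (str, type(None))},
    ),
    "pathways": (
        {"id": str, "name": str, "organism": str, "interactions": list},
        {"pathway_class": (str, type(None))},
    ),
}

COLLECTIONS = tuple(_RECORD_FIELDS)


def _fail(message: str, path: str):
    raise ValidationError(message, path)


def _check_type(value, expected, path: str):
    if isinstance(expected, tuple):
        ok = isinstance(value, expected)
        names = " or ".join(t.__name__ for t in expected)
    else:
        # bool is an int subclass; keep them distinct
        ok = isinstance(value, expected) and not (
            expected is not bool and isinstance(value, bool) and expected in (int, float)
        )
        if expected is bool:
            ok = isinstance(value, bool)
        names = expected.__name__
    if not ok:
        _fail(f"expected {names}, got {type(value).__name__}", path)


def _check_record(record, required, optional, path: str):
    if not isinstance(record, dict):
        _fail(f"expected object, got {type(record).__name__}", path)
    for key, typ in required.items():
        if key not in record:
            _fail(f"missing required field {key!r}", path)
        _check_type(record[key], typ, f"{path}/{key}")
    for key, typ in optional.items():
        if key in record and record[key] is not None:
            _check_type(record[key], typ, f"{path}/{key}")
    extra = set(record) - set(required) - set(optional)
    if extra:
        _fail(f"unknown field {sorted(extra)[0]!r}", path)


def _check_participant(part, path: str):
    _check_record(
        part,
        {"local_entity": str, "role": str},
        {"modifier_effect": (str, type(None)), "stoichiometry": (int, float)},
        path,
    )
    if part["role"] not in ROLES:
        _fail(f"role must be one of {list(ROLES)}", f"{path}/role")
    effect = part.get("modifier_effect")
    if part["role"] == "modifier":
        if effect not in MODIFIER_EFFECTS:
            _fail(
                f"modifier participant requires modifier_effect in {list(MODIFIER_EFFECTS)}",
                f"{path}/modifier_effect",
            )
    elif effect is not None:
        _fail("modifier_effect only allowed when role is 'modifier'", f"{path}/modifier_effect")
    stoich = part.get("stoichiometry", 1)
    if not stoich > 0:
        _fail("stoichiometry must be > 0", f"{path}/stoichiometry")


def validate_document(doc: Any) -> None:
    """Validate structure and types; raise :class:`ValidationError` at the
    first violation, with a JSON-pointer-style path."""
    if not isinstance(doc, dict):
        _fail(f"expected object, got {type(doc).__name__}", "")
    if doc.get("format_version") != FORMAT_VERSION:
        _fail(f"format_version must be {FORMAT_VERSION!r}", "/format_version")
    extra = set(doc) - {"format_version", *COLLECTIONS}
    if extra:
        _fail(f"unknown top-level key {sorted(extra)[0]!r}", "")
    for name in COLLECTIONS:
        if name not in doc:
            _fail(f"missing collection {name!r}", "")
        records = doc[name]
        if not isinstance(records, list):
            _fail(f"expected list, got {type(records).__name__}", f"/{name}")
        required, optional = _RECORD_FIELDS[name]
        seen_ids: set[str] = set()
        for i, record in enumerate(records):
            path = f"/{name}/{i}"
            _check_record(record, required, optional, path)
            rid = record["id"]
            if rid in seen_ids:
                _fail(f"duplicate id {rid!r}", f"{path}/id")
            if not rid:
                _fail("id must be non-empty", f"{path}/id")
            seen_ids.add(rid)
            if name == "interactions":
                parts = record["participants"]
                if not parts:
                    _fail("participants must be non-empty", f"{path}/participants")
                for j, part in enumerate(parts):
                    _check_participant(part, f"{path}/participants/{j}")
            if name == "pathways":
                for j, iid in enumerate(record["interactions"]):
                    if not isinstance(iid, str):
                        _fail("interaction ids must be strings", f"{path}/interactions/{j}")
                if len(set(record["interactions"])) != len(record["interactions"]):
                    _fail("pathway interaction list has duplicates", f"{path}/interactions")
            if name == "entities":
                for j, syn in enumerate(record.get("synonyms", [])):
                    if not isinstance(syn, str):
                        _fail("synonyms must be strings", f"{path}/synonyms/{j}")


def _check_forest(records, collection: str):
    """Parent links must resolve within the collection and contain no cycle."""
    ids = {r["id"] for r in records}
    parent = {r["id"]: r.get("parent") for r in records}
    for rid, pid in parent.items():
        if pid is not None and pid not in ids:
            raise IntegrityError(
                f"{collection}: {rid!r} has unknown parent {pid!r}"
            )
    for rid in parent:
        seen = set()
        node = rid
        while node is not None:
            if node in seen:
                raise IntegrityError(f"{collection}: cycle through {rid!r}")
            seen.add(node)
            node = parent[node]


def check_references(doc: dict) -> None:
    """Full referential-integrity pass over a structurally valid document.

    Raises :class:`IntegrityError` naming the first dangling reference.
    Operates on the raw document so it can run without materializing any
    model objects.
    """
    ids = {name: {r["id"] for r in doc[name]} for name in COLLECTIONS}

    def ref(kind: str, value, owner: str):
        if value is not None and value not in ids[kind]:
            raise IntegrityError(f"{owner} references unknown {kind[:-1]} {value!r}")

    _check_forest(doc["cell_locations"], "cell_locations")
    _check_forest(doc["pathway_classes"], "pathway_classes")

    for e in doc["entities"]:
        owner = f"entity {e['id']!r}"
        ref("entity_types", e["entity_type"], owner)
        ref("organisms", e.get("organism"), owner)
    seen_pairs: set[tuple[str, str]] = set()
    for le in doc["local_entities"]:
        owner = f"local entity {le['id']!r}"
        ref("entities", le["entity"], owner)
        ref("cell_locations", le["location"], owner)
        pair = (le["entity"], le["location"])
        if pair in seen_pairs:
            raise IntegrityError(f"duplicate (entity, location) pair {pair!r}")
        seen_pairs.add(pair)
    transport_type_ids = {
        t["id"] for t in doc["interaction_types"] if t["label"] == "transport"
    }
    le_by_id = {le["id"]: le for le in doc["local_entities"]}
    for it in doc["interactions"]:
        owner = f"interaction {it['id']!r}"
        ref("interaction_types", it["interaction_type"], owner)
        ref("organisms", it.get("organism"), owner)
        for part in it["participants"]:
            ref("local_entities", part["local_entity"], owner)
        if it["interaction_type"] in transport_type_ids:
            # transport moves one species between compartments: every
            # input/output participant maps to the same entity, and the
            # locations on the two sides differ
            flow = [p for p in it["participants"] if p["role"] in ("input", "output")]
            ents = {le_by_id[p["local_entity"]]["entity"] for p in flow}
            if len(ents) > 1:
                raise IntegrityError(
                    f"{owner}: transport must move a single entity, got {sorted(ents)}"
                )
            locs_in = {
                le_by_id[p["local_entity"]]["location"]
                for p in flow
                if p["role"] == "input"
            }
            locs_out = {
                le_by_id[p["local_entity"]]["location"]
                for p in flow
                if p["role"] == "output"
            }
            if locs_in and locs_out and locs_in & locs_out:
                raise IntegrityError(
                    f"{owner}: transport input and output share a compartment"
                )
    for pw in doc["pathways"]:
        owner = f"pathway {pw['id']!r}"
        ref("organisms", pw["organism"], owner)
        ref("pathway_classes", pw.get("pathway_class"), owner)
        for iid in pw["interactions"]:
            ref("interactions", iid, owner)
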