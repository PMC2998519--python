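"""File-backed repository with layered, observable lazy retrieval.

The repository replaces a remote pathway database with a single JSON
document.  The original back end fetched collection-valued detail
(pathway interaction lists, interaction participant lists) only when a
navigation method was invoked; listing "all pathways" touched nothing but
scalar header fields.  That just-in-time contract is preserved — and made
testable — by an access-counting indirection layer:

* Vocabularies, entities, local entities and pathway *headers* (id, name,
  organism, class) are parsed eagerly at load.
* A pathway's interaction-id collection is materialized on first access
  and memoized (counted under ``interaction_lists``).
* An interaction's participant list is materialized on first access and
  memoized (counted under ``participant_lists``).

:meth:`Repository.access_stats` exposes the cumulative counters, so a
test can assert that enumerating every pathway header performs zero
participant materializations while k distinct collection accesses perform
exactly k.

Load-time validation (schema, referential integrity) scans the raw
document and deliberately does not touch the counters: the counters model
per-object retrieval through the API, not the initial parse.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from . import schema
from .errors import (
    ConflictError,
    IntegrityError,
    NotFoundError,
    UsageError,
    VocabularyError,
)
from .model import (
    CellLocation,
    Entity,
    EntityType,
    Interaction,
    InteractionType,
    LocalEntity,
    Network,
    Organism,
    Participant,
    Pathway,
    PathwayClass,
)


@dataclass(frozen=True)
class PathwayHeader:
    """Scalar pathway fields, loadable without touching interactions."""

    id: str
    name: str
    organism: str
    pathway_class: Optional[str] = None


@dataclass(frozen=True)
class QuerySpec:
    """Search criteria; every present criterion must match.

    ``name_pattern`` is a case-insensitive substring match; ``*`` acts as
    a wildcard (``"syn*ase"``).  ``location_filter`` matches entities
    localized at the given compartment or any descendant compartment.
    """

    name_pattern: Optional[str] = None
    type_filter: Optional[str] = None
    organism_filter: Optional[str] = None
    location_filter: Optional[str] = None

    def __post_init__(self):
        if not any(
            (
                self.name_pattern,
                self.type_filter,
                self.organism_filter,
                self.location_filter,
            )
        ):
            raise UsageError("QuerySpec requires at least one criterion")


def _name_matches(pattern: str, name: str) -> bool:
    # case-insensitive substring with '*' wildcards: anchoring is never
    # implied, so the pattern is wrapped in wildcards before globbing
    return fnmatch.fnmatchcase(name.lower(), f"*{pattern.lower()}*")


class Repository:
    """In-memory view over a repository document, with lazy collections.

    Construct via :func:`load_repository`.
    """

    def __init__(self, doc: dict, source: Optional[Path] = None):
        self._doc = doc
        self.source = source

        self._organisms = {r["id"]: Organism(r["id"], r["name"]) for r in doc["organisms"]}
        self._entity_types = {
            r["id"]: EntityType(r["id"], r["label"]) for r in doc["entity_types"]
        }
        self._interaction_types = {
            r["id"]: InteractionType(r["id"], r["label"], r["is_regulatory"])
            for r in doc["interaction_types"]
        }
        self._locations = {
            r["id"]: CellLocation(r["id"], r["name"], r.get("parent"))
            for r in doc["cell_locations"]
        }
        self._pathway_classes = {
            r["id"]: PathwayClass(r["id"], r["name"], r.get("parent"))
            for r in doc["pathway_classes"]
        }
        self._entities = {
            r["id"]: Entity(
                r["id"],
                r["name"],
                r["entity_type"],
                r.get("organism"),
                tuple(r.get("synonyms", ())),
            )
            for r in doc["entities"]
        }
        self._local_entities = {
            r["id"]: LocalEntity(r["id"], r["entity"], r["location"])
            for r in doc["local_entities"]
        }
        # raw records for the lazy layers
        self._interaction_records = {r["id"]: r for r in doc["interactions"]}
        self._pathway_records = {r["id"]: r for r in doc["pathways"]}
        self._pathway_headers = {
            r["id"]: PathwayHeader(
                r["id"], r["name"], r["organism"], r.get("pathway_class")
            )
            for r in doc["pathways"]
        }

        # memoization caches + fetch counters
        self._interactions: dict[str, Interaction] = {}
        self._pathway_interactions: dict[str, frozenset[str]] = {}
        self._stats = {"interaction_lists": 0, "participant_lists": 0}
        self._entity_interaction_index: Optional[dict[str, list[str]]] = None
        self._entity_pathway_index: Optional[dict[str, list[str]]] = None

    # -- vocabularies -------------------------------------------------

    def organism(self, organism_id: str) -> Organism:
        return self._get(self._organisms, organism_id, "organism")

    def entity_type(self, type_id: str) -> EntityType:
        return self._get(self._entity_types, type_id, "entity type")

    def interaction_type(self, type_id: str) -> InteractionType:
        return self._get(self._interaction_types, type_id, "interaction type")

    def cell_location(self, location_id: str) -> CellLocation:
        return self._get(self._locations, location_id, "cell location")

    def pathway_class(self, class_id: str) -> PathwayClass:
        return self._get(self._pathway_classes, class_id, "pathway class")

    def entity_type_by_label(self, label: str) -> EntityType:
        for t in self._entity_types.values():
            if t.label == label:
                return t
        raise VocabularyError(f"no entity type labelled {label!r}")

    def interaction_type_by_label(self, label: str) -> InteractionType:
        for t in self._interaction_types.values():
            if t.label == label:
                return t
        raise VocabularyError(f"no interaction type labelled {label!r}")

    @staticmethod
    def _get(mapping, key, kind):
        try:
            return mapping[key]
        except KeyError:
            raise NotFoundError(f"unknown {kind} {key!r}") from None

    # -- eager layers --------------------------------------------------

    def entity(self, entity_id: str) -> Entity:
        return self._get(self._entities, entity_id, "entity")

    def local_entity(self, local_entity_id: str) -> LocalEntity:
        return self._get(self._local_entities, local_entity_id, "local entity")

    def entities(self) -> Iterator[Entity]:
        return iter(self._entities.values())

    def local_entities(self) -> Iterator[LocalEntity]:
        return iter(self._local_entities.values())

    def local_entities_of_entity(self, entity_id: str) -> list[LocalEntity]:
        self.entity(entity_id)
        return sorted(
            (le for le in self._local_entities.values() if le.entity == entity_id),
            key=lambda le: le.id,
        )

    def counts(self) -> dict[str, int]:
        """Record count per layer/vocabulary collection."""
        return {name: len(self._doc[name]) for name in schema.COLLECTIONS}

    # -- lazy layers ---------------------------------------------------

    def interaction(self, interaction_id: str) -> Interaction:
        """Materialize (once) and return a full interaction.

        First access per interaction parses the participant list and
        increments the ``participant_lists`` counter; later accesses hit
        the memoized object.
        """
        cached = self._interactions.get(interaction_id)
        if cached is not None:
            return cached
        record = self._get(self._interaction_records, interaction_id, "interaction")
        participants = tuple(
            Participant(
                p["local_entity"],
                p["role"],
                p.get("modifier_effect"),
                p.get("stoichiometry", 1),
            )
            for p in record["participants"]
        )
        for p in participants:
            if p.local_entity not in self._local_entities:
                raise IntegrityError(
                    f"interaction {interaction_id!r} references unknown "
                    f"local entity {p.local_entity!r}"
                )
        interaction = Interaction(
            record["id"], record["interaction_type"], participants, record.get("organism")
        )
        self._interactions[interaction_id] = interaction
        self._stats["participant_lists"] += 1
        return interaction

    def interactions(self, ids: Optional[Iterable[str]] = None) -> list[Interaction]:
        if ids is None:
            ids = self._interaction_records
        return [self.interaction(i) for i in ids]

    def pathway_header(self, pathway_id: str) -> PathwayHeader:
        return self._get(self._pathway_headers, pathway_id, "pathway")

    def pathway_headers(self) -> list[PathwayHeader]:
        """All pathway headers; touches no lazy collection."""
        return sorted(self._pathway_headers.values(), key=lambda h: (h.name, h.id))

    def pathway_interaction_ids(self, pathway_id: str) -> frozenset[str]:
        """Materialize (once) a pathway's interaction-id collection."""
        cached = self._pathway_interactions.get(pathway_id)
        if cached is not None:
            return cached
        record = self._get(self._pathway_records, pathway_id, "pathway")
        ids = frozenset(record["interactions"])
        missing = [i for i in sorted(ids) if i not in self._interaction_records]
        if missing:
            raise IntegrityError(
                f"pathway {pathway_id!r} references unknown interaction {missing[0]!r}"
            )
        self._pathway_interactions[pathway_id] = ids
        self._stats["interaction_lists"] += 1
        return ids

    def pathway(self, pathway_id: str) -> Pathway:
        """Full pathway object (materializes its interaction list)."""
        h = self.pathway_header(pathway_id)
        return Pathway(
            h.id, h.name, h.organism, h.pathway_class,
            self.pathway_interaction_ids(pathway_id),
        )

    def pathway_interactions(self, pathway_id: str) -> list[Interaction]:
        return self.interactions(sorted(self.pathway_interaction_ids(pathway_id)))

    def access_stats(self) -> dict[str, int]:
        """Cumulative materialization counters (monotone non-decreasing)."""
        return dict(self._stats)

    # -- navigation ----------------------------------------------------

    def _descendant_locations(self, location_id: str) -> set[str]:
        self.cell_location(location_id)
        children: dict[Optional[str], list[str]] = {}
        for loc in self._locations.values():
            children.setdefault(loc.parent, []).append(loc.id)
        out, stack = set(), [location_id]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(children.get(node, ()))
        return out

    def _descendant_classes(self, class_id: str) -> set[str]:
        self.pathway_class(class_id)
        children: dict[Optional[str], list[str]] = {}
        for c in self._pathway_classes.values():
            children.setdefault(c.parent, []).append(c.id)
        out, stack = set(), [class_id]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(children.get(node, ()))
        return out

    def _ensure_indexes(self):
        """Invert participant membership: entity -> interactions -> pathways.

        Builds once; materializes every interaction and pathway collection
        (the counters record this honestly)."""
        if self._entity_interaction_index is not None:
            return
        e2i: dict[str, set[str]] = {}
        for iid in self._interaction_records:
            interaction = self.interaction(iid)
            for p in interaction.participants:
                eid = self.local_entity(p.local_entity).entity
                e2i.setdefault(eid, set()).add(iid)
        i2p: dict[str, set[str]] = {}
        for pid in self._pathway_records:
            for iid in self.pathway_interaction_ids(pid):
                i2p.setdefault(iid, set()).add(pid)
        e2p: dict[str, set[str]] = {}
        for eid, iids in e2i.items():
            for iid in iids:
                e2p.setdefault(eid, set()).update(i2p.get(iid, ()))
        self._entity_interaction_index = {k: sorted(v) for k, v in e2i.items()}
        self._entity_pathway_index = {k: sorted(v) for k, v in e2p.items()}

    def interactions_of_entity(self, entity_id: str) -> list[Interaction]:
        """All interactions with a participant mapping to the entity,
        regardless of compartment."""
        self.entity(entity_id)
        self._ensure_indexes()
        return [self.interaction(i) for i in self._entity_interaction_index.get(entity_id, [])]

    def pathways_of_entity(self, entity_id: str) -> list[Pathway]:
        """All pathways containing at least one interaction the entity
        participates in; sorted by id (upward navigation)."""
        self.entity(entity_id)
        self._ensure_indexes()
        return [self.pathway(p) for p in self._entity_pathway_index.get(entity_id, [])]

    def entities_of_pathway(self, pathway_id: str) -> set[str]:
        """Entity ids making up a pathway, compartment-collapsed
        (downward navigation)."""
        from .model import entities_of

        return entities_of(self.pathway_interactions(pathway_id), self)

    # -- search --------------------------------------------------------

    def search_entities(self, q: QuerySpec, include_synonyms: bool = False) -> list[Entity]:
        """Entities matching every present criterion, sorted by (name, id).

        ``include_synonyms`` extends the name match over synonym lists
        (opt-in; by default only primary names are searched).
        """
        if q.type_filter is not None:
            self.entity_type(q.type_filter)
        if q.organism_filter is not None:
            self.organism(q.organism_filter)
        locations: Optional[set[str]] = None
        if q.location_filter is not None:
            locations = self._descendant_locations(q.location_filter)
            localized = {
                le.entity
                for le in self._local_entities.values()
                if le.location in locations
            }
        out = []
        for e in self._entities.values():
            if q.name_pattern is not None:
                names = (e.name, *e.synonyms) if include_synonyms else (e.name,)
                if not any(_name_matches(q.name_pattern, n) for n in names):
                    continue
            if q.type_filter is not None and e.entity_type != q.type_filter:
                continue
            if q.organism_filter is not None and e.organism != q.organism_filter:
                continue
            if locations is not None and e.id not in localized:
                continue
            out.append(e)
        return sorted(out, key=lambda e: (e.name, e.id))

    def search_pathways(
        self, q: Optional[QuerySpec] = None, class_filter: Optional[str] = None
    ) -> list[PathwayHeader]:
        """Pathway headers matching name/organism criteria; ``class_filter``
        includes pathways classified at the node or any descendant."""
        if q is None and class_filter is None:
            raise UsageError("search_pathways requires a QuerySpec or class_filter")
        classes = self._descendant_classes(class_filter) if class_filter else None
        out = []
        for h in self._pathway_headers.values():
            if q is not None:
                if q.name_pattern is not None and not _name_matches(q.name_pattern, h.name):
                    continue
                if q.organism_filter is not None and h.organism != q.organism_filter:
                    continue
            if classes is not None and h.pathway_class not in classes:
                continue
            out.append(h)
        return sorted(out, key=lambda h: (h.name, h.id))

    # -- publication ---------------------------------------------------

    def save_pathway(
        self,
        net: Network,
        name: str,
        organism: str,
        pathway_class: Optional[str] = None,
        allow_empty: bool = False,
    ) -> Pathway:
        """Publish a network as a new pathway, appended to the document.

        The new record receives a fresh id; pre-existing records are not
        rewritten.  If the repository was loaded from a file, the file is
        updated on disk.  Raises :class:`ConflictError` when the organism
        already has a pathway of that name.
        """
        if not name:
            raise UsageError("pathway name must be non-empty")
        self.organism(organism)
        if pathway_class is not None:
            self.pathway_class(pathway_class)
        if not net.interactions and not allow_empty:
            raise UsageError("refusing to publish an empty network (allow_empty=False)")
        for iid in sorted(net.interactions):
            if iid not in self._interaction_records:
                raise IntegrityError(f"network references unknown interaction {iid!r}")
        for h in self._pathway_headers.values():
            if h.organism == organism and h.name == name:
                raise ConflictError(
                    f"organism {organism!r} already has a pathway named {name!r}"
                )
        seq = len(self._pathway_records)
        new_id = f"pw{seq:04d}"
        while new_id in self._pathway_records:
            seq += 1
            new_id = f"pw{seq:04d}"
        record = {
            "id": new_id,
            "name": name,
            "organism": organism,
            "pathway_class": pathway_class,
            "interactions": sorted(net.interactions),
        }
        self._doc["pathways"].append(record)
        self._pathway_records[new_id] = record
        self._pathway_headers[new_id] = PathwayHeader(new_id, name, organism, pathway_class)
        # publication invalidates memoized pathway membership
        self._entity_pathway_index = None
        self._entity_interaction_index = None
        if self.source is not None:
            save_document(self._doc, self.source)
        return self.pathway(new_id)

    # -- document access ----------------------------------------------

    def document(self) -> dict:
        """The raw underlying document (treat as read-only)."""
        return self._doc


def serialize_document(doc: dict) -> str:
    """Canonical, byte-stable JSON serialization of a repository document."""
    return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False) + "\n"


def save_document(doc: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(serialize_document(doc), encoding="utf-8")


def load_repository(
    source: Union[str, Path, dict],
    validate: bool = True,
    check_refs: str = "eager",
) -> Repository:
    """Load a repository document from a file path or an in-memory dict.

    ``validate=False`` skips schema validation; ``check_refs`` is
    ``"eager"`` (full referential-integrity pass at load) or ``"lazy"``
    (dangling references surface on first access).
    """
    if check_refs not in ("eager", "lazy"):
        raise UsageError("check_refs must be 'eager' or 'lazy'")
    if isinstance(source, dict):
        doc, path = source, None
    else:
        path = Path(source)
        doc = json.loads(path.read_text(encoding="utf-8"))
    if validate:
        schema.validate_document(doc)
    if check_refs == "eager":
        schema.check_references(doc)
    return Repository(doc, source=path)
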