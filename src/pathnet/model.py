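"""Domain types for the four-layer pathway data model.

The model mirrors how curated plant pathway databases organize their
content, in four layers of increasing aggregation:

1. **Entities** — molecular species: genes, RNAs, polypeptides, protein
   complexes, metabolites.  An entity may be organism-specific (a gene) or
   universal (a metabolite such as ATP or glucose).
2. **Localized entities** — an entity bound to a subcellular compartment.
   ATP present in the mitochondrion, nucleus, plastid and cytosol is one
   entity with four localized entities.
3. **Interactions** — typed transformations or influences (enzymatic
   reaction, transport, transcription, translation, activation,
   inhibition) over role-tagged localized participants.
4. **Pathways** — named, unordered collections of interactions with
   organism and ontology classification.

A :class:`Network` sits outside the curated layers: a user-defined,
mutable set of interactions that need not respect pathway boundaries.

Everything here is storage-agnostic.  Cross-references are opaque string
ids; operations that must follow a reference accept a *resolver* — any
object with ``local_entity(id)``, ``entity(id)`` and ``entity_type(id)``
accessors (a :class:`pathnet.repository.Repository` qualifies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol

from .errors import IntegrityError, VocabularyError

#: Closed vocabulary of participant roles.
ROLES = ("input", "output", "modifier")

#: Allowed effects for modifier participants.
MODIFIER_EFFECTS = ("catalysis", "activation", "inhibition")

#: Minimum entity-type vocabulary every repository provides.
CORE_ENTITY_TYPES = ("gene", "RNA", "polypeptide", "protein_complex", "metabolite")

#: Minimum interaction-type vocabulary, with the regulatory flag each
#: label carries.
CORE_INTERACTION_TYPES = (
    ("enzymatic_reaction", False),
    ("transport", False),
    ("transcription", False),
    ("translation", False),
    ("activation", True),
    ("inhibition", True),
)


@dataclass(frozen=True)
class Organism:
    id: str
    name: str


@dataclass(frozen=True)
class EntityType:
    id: str
    label: str


@dataclass(frozen=True)
class InteractionType:
    id: str
    label: str
    is_regulatory: bool = False


@dataclass(frozen=True)
class CellLocation:
    """A subcellular compartment; ``parent`` links form a forest."""

    id: str
    name: str
    parent: Optional[str] = None


@dataclass(frozen=True)
class PathwayClass:
    """A pathway-ontology term; ``parent`` links form a forest."""

    id: str
    name: str
    parent: Optional[str] = None


@dataclass(frozen=True)
class Entity:
    """A molecular species.  ``organism`` is ``None`` for universal
    entities (metabolites shared across organisms)."""

    id: str
    name: str
    entity_type: str
    organism: Optional[str] = None
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class LocalEntity:
    """An (entity, compartment) pair — the localization layer."""

    id: str
    entity: str
    location: str


@dataclass(frozen=True)
class Participant:
    """A role-tagged localized entity inside an interaction.

    ``modifier_effect`` is required when ``role == "modifier"`` and must be
    absent otherwise; ``stoichiometry`` is a positive multiplicity.
    """

    local_entity: str
    role: str
    modifier_effect: Optional[str] = None
    stoichiometry: float = 1.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise VocabularyError(
                f"unknown participant role {self.role!r}; expected one of {ROLES}"
            )
        if self.role == "modifier":
            if self.modifier_effect not in MODIFIER_EFFECTS:
                raise VocabularyError(
                    f"modifier participant requires modifier_effect in "
                    f"{MODIFIER_EFFECTS}, got {self.modifier_effect!r}"
                )
        elif self.modifier_effect is not None:
            raise VocabularyError(
                f"modifier_effect is only valid for modifier participants "
                f"(role={self.role!r})"
            )
        if not self.stoichiometry > 0:
            raise VocabularyError("stoichiometry must be > 0")


@dataclass(frozen=True)
class Interaction:
    """A typed transformation/influence with at least one participant."""

    id: str
    interaction_type: str
    participants: tuple[Participant, ...]
    organism: Optional[str] = None

    def __post_init__(self):
        if not self.participants:
            raise VocabularyError(f"interaction {self.id!r} has no participants")


@dataclass(frozen=True)
class Pathway:
    """A named, unordered, duplicate-free collection of interaction ids."""

    id: str
    name: str
    organism: str
    pathway_class: Optional[str] = None
    interactions: frozenset[str] = frozenset()


@dataclass
class Network:
    """A user-defined mutable set of interactions.

    Unlike a pathway, a network is not curated and not confined to
    pathway boundaries; it is the unit of filtering, analytics and
    export.  Interaction ids are kept duplicate-free by construction.
    """

    label: str = ""
    interactions: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.interactions)

    def __contains__(self, interaction_id: str) -> bool:
        return interaction_id in self.interactions

    def copy(self, label: Optional[str] = None) -> "Network":
        return Network(self.label if label is None else label, set(self.interactions))


class EntityResolver(Protocol):
    """Minimal lookup surface the model-level operations need."""

    def local_entity(self, local_entity_id: str) -> LocalEntity: ...

    def entity(self, entity_id: str) -> Entity: ...

    def entity_type(self, type_id: str) -> EntityType: ...


def participants_by_role(
    interaction: Interaction, role: Optional[str] = None
) -> list[Participant]:
    """Return the interaction's participants with the given role.

    ``role=None`` returns the full participant list.  Order follows the
    participant positions in the interaction, so concatenating the three
    role slices reproduces the original list up to permutation-free
    partitioning.
    """
    if role is None:
        return list(interaction.participants)
    if role not in ROLES:
        raise VocabularyError(f"unknown role {role!r}; expected one of {ROLES}")
    return [p for p in interaction.participants if p.role == role]


def entities_of(
    interactions: Iterable[Interaction], resolver: EntityResolver
) -> set[str]:
    """Deduplicated set of entity ids participating in the interactions.

    Localization is collapsed: an entity present in several compartments
    contributes a single id.  A participant whose localized entity cannot
    be resolved raises :class:`IntegrityError` naming the dangling id.
    """
    out: set[str] = set()
    for interaction in interactions:
        for p in interaction.participants:
            try:
                le = resolver.local_entity(p.local_entity)
            except Exception:
                raise IntegrityError(
                    f"interaction {interaction.id!r} references unknown "
                    f"local entity {p.local_entity!r}"
                ) from None
            out.add(le.entity)
    return out


def genes_of(interactions: Iterable[Interaction], resolver: EntityResolver) -> set[str]:
    """Entity ids of type ``gene`` participating in the interactions.

    Subset of :func:`entities_of`, restricted by the entity-type label.
    Used for the shared-gene pathway distance matrix.
    """
    gene_entities: set[str] = set()
    for eid in entities_of(interactions, resolver):
        ent = resolver.entity(eid)
        if resolver.entity_type(ent.entity_type).label == "gene":
            gene_entities.add(eid)
    return gene_entities
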