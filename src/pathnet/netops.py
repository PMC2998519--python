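"""Network construction, filtering, endpoints, neighbourhoods and
pathway-similarity matrices.

All operations are pure: they take a repository plus a network (or
pathway ids) and return new objects, leaving their inputs untouched.
Set semantics rule throughout — networks are duplicate-free sets of
interaction ids, and entity-level results collapse compartments (one
entity, however many localized copies it has).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import UsageError, VocabularyError
from .model import Network, genes_of
from .repository import Repository


@dataclass(frozen=True)
class Endpoints:
    """Start- and end-points of an interaction collection.

    ``sources`` are entities consumed (input role) but never produced;
    ``sinks`` are produced (output role) but never consumed.  Entities
    appearing only as modifiers (enzymes, regulators) belong to neither:
    endpoints describe mass flow, not influence.  The two sets are
    disjoint by construction.
    """

    sources: frozenset[str]
    sinks: frozenset[str]


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise shared-gene counts between pathways.

    ``values[i, j]`` is the number of gene entities common to pathways
    ``pathway_ids[i]`` and ``pathway_ids[j]``; the diagonal holds each
    pathway's own gene count.  Larger counts mean closer pathways — the
    quantity is a similarity stored under the field's customary
    "distance matrix" name.
    """

    pathway_ids: tuple[str, ...]
    values: np.ndarray  # square, int, symmetric

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.pathway_ids), len(self.pathway_ids)):
            raise UsageError("matrix shape does not match pathway list")


def _resolve_network(repo: Repository, net: Union[Network, str]) -> Network:
    """Accept a Network or a pathway id."""
    if isinstance(net, Network):
        return net
    return Network(label=net, interactions=set(repo.pathway_interaction_ids(net)))


def network_from_pathways(
    repo: Repository, pathways: Sequence[str], label: str = ""
) -> Network:
    """Union the interaction sets of the given pathways into a network."""
    ids: set[str] = set()
    for pid in pathways:
        ids |= repo.pathway_interaction_ids(pid)
    return Network(label=label, interactions=ids)


def network_edit(
    repo: Repository,
    net: Network,
    add: Iterable[str] = (),
    remove: Iterable[str] = (),
) -> Network:
    """Return ``(net ∪ add) \\ remove``; removing an absent id is a no-op."""
    add = list(add)
    for iid in add:
        repo.interaction(iid)  # raises on unresolvable id
    result = (net.interactions | set(add)) - set(remove)
    return Network(label=net.label, interactions=result)


def filter_interactions(
    repo: Repository,
    net: Union[Network, str],
    keep_types: Optional[Iterable[str]] = None,
    drop_types: Optional[Iterable[str]] = None,
    regulatory_only: bool = False,
) -> Network:
    """Restrict a network by interaction type.

    Exactly one criterion must be supplied: ``keep_types`` retains the
    listed type labels, ``drop_types`` removes them (e.g. stripping
    transcription/translation clutter to expose a core metabolic
    pathway), and ``regulatory_only`` retains activation/inhibition-like
    types flagged as regulatory.  Type arguments are vocabulary labels.
    """
    supplied = sum((keep_types is not None, drop_types is not None, bool(regulatory_only)))
    if supplied != 1:
        raise UsageError(
            "supply exactly one of keep_types, drop_types, regulatory_only"
        )
    net = _resolve_network(repo, net)

    if regulatory_only:
        predicate = lambda tid: repo.interaction_type(tid).is_regulatory
    else:
        labels = set(keep_types if keep_types is not None else drop_types)
        type_ids = {repo.interaction_type_by_label(lbl).id for lbl in labels}
        if keep_types is not None:
            predicate = lambda tid: tid in type_ids
        else:
            predicate = lambda tid: tid not in type_ids

    kept = {
        iid for iid in net.interactions if predicate(repo.interaction(iid).interaction_type)
    }
    return Network(label=net.label, interactions=kept)


def endpoints(repo: Repository, net: Union[Network, str]) -> Endpoints:
    """Sources and sinks of a network or pathway (compartment-collapsed)."""
    net = _resolve_network(repo, net)
    consumed: set[str] = set()
    produced: set[str] = set()
    for iid in net.interactions:
        for p in repo.interaction(iid).participants:
            eid = repo.local_entity(p.local_entity).entity
            if p.role == "input":
                consumed.add(eid)
            elif p.role == "output":
                produced.add(eid)
    return Endpoints(
        sources=frozenset(consumed - produced),
        sinks=frozenset(produced - consumed),
    )


def neighborhood(repo: Repository, entity: str, p: int) -> Network:
    """The p-neighbourhood of an entity.

    Level 1 contains every interaction the entity participates in;
    level k adds interactions sharing at least one entity with a
    level-(k−1) interaction.  Distance counts interaction steps on the
    entity–interaction bipartite graph.  Returns the union of levels
    1..p as a network (empty for an isolated entity).
    """
    if p < 1:
        raise UsageError("p must be >= 1")
    seed_interactions = {i.id for i in repo.interactions_of_entity(entity)}
    visited = set(seed_interactions)
    frontier = deque((iid, 1) for iid in sorted(seed_interactions))
    while frontier:
        iid, level = frontier.popleft()
        if level >= p:
            continue
        for part in repo.interaction(iid).participants:
            eid = repo.local_entity(part.local_entity).entity
            for nxt in repo.interactions_of_entity(eid):
                if nxt.id not in visited:
                    visited.add(nxt.id)
                    frontier.append((nxt.id, level + 1))
    return Network(label=f"{entity} p={p}", interactions=visited)


def pathway_gene_sets(
    repo: Repository, pathways: Sequence[str]
) -> dict[str, set[str]]:
    """Gene entity ids per pathway (compartment-collapsed)."""
    return {
        pid: genes_of(repo.pathway_interactions(pid), repo) for pid in pathways
    }


def shared_gene_matrix(repo: Repository, pathways: Sequence[str]) -> DistanceMatrix:
    """Square matrix of pairwise shared-gene counts between pathways.

    Cell (i, j) counts gene entities participating in both pathways;
    the diagonal holds each pathway's own gene count.  Row order follows
    the input order; duplicate pathway ids are rejected.
    """
    if len(set(pathways)) != len(pathways):
        raise UsageError("duplicate pathway ids in matrix request")
    gene_sets = pathway_gene_sets(repo, pathways)
    n = len(pathways)
    values = np.zeros((n, n), dtype=np.int64)
    for i, pi in enumerate(pathways):
        gi = gene_sets[pi]
        values[i, i] = len(gi)
        for j in range(i + 1, n):
            shared = len(gi & gene_sets[pathways[j]])
            values[i, j] = values[j, i] = shared
    return DistanceMatrix(tuple(pathways), values)


def entities_in_min_pathways(
    repo: Repository, entities: Sequence[str], k: int
) -> list[str]:
    """Sublist of entities participating in at least ``k`` pathways,
    input order preserved (e.g. which up-regulated genes act in two or
    more pathways)."""
    if k < 1:
        raise UsageError("k must be >= 1")
    return [e for e in entities if len(repo.pathways_of_entity(e)) >= k]
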