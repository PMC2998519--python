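"""Brute-force oracles computed directly from raw repository documents.

Everything here operates on the serialized JSON structure (plain dicts)
and never calls into the library's navigation, indexing or export code,
so tests can compare the implementation against an independent reading
of the same document.
"""

from __future__ import annotations

import networkx as nx


def le_entity_map(doc: dict) -> dict[str, str]:
    return {le["id"]: le["entity"] for le in doc["local_entities"]}


def entity_type_label(doc: dict) -> dict[str, str]:
    labels = {t["id"]: t["label"] for t in doc["entity_types"]}
    return {e["id"]: labels[e["entity_type"]] for e in doc["entities"]}


def interaction_entities(doc: dict) -> dict[str, set[str]]:
    """interaction id -> participating entity ids (compartment-collapsed)."""
    le2e = le_entity_map(doc)
    return {
        it["id"]: {le2e[p["local_entity"]] for p in it["participants"]}
        for it in doc["interactions"]
    }


def entities_of_pathway(doc: dict, pathway_id: str) -> set[str]:
    by_iid = interaction_entities(doc)
    (pw,) = [p for p in doc["pathways"] if p["id"] == pathway_id]
    out: set[str] = set()
    for iid in pw["interactions"]:
        out |= by_iid[iid]
    return out


def gene_sets(doc: dict) -> dict[str, set[str]]:
    """pathway id -> gene entity ids, by naive scan."""
    types = entity_type_label(doc)
    by_iid = interaction_entities(doc)
    out = {}
    for pw in doc["pathways"]:
        genes: set[str] = set()
        for iid in pw["interactions"]:
            genes |= {e for e in by_iid[iid] if types[e] == "gene"}
        out[pw["id"]] = genes
    return out


def pathways_of_entity(doc: dict, entity_id: str) -> set[str]:
    by_iid = interaction_entities(doc)
    return {
        pw["id"]
        for pw in doc["pathways"]
        if any(entity_id in by_iid[iid] for iid in pw["interactions"])
    }


def interactions_of_entity(doc: dict, entity_id: str) -> set[str]:
    return {iid for iid, ents in interaction_entities(doc).items() if entity_id in ents}


def endpoints_tally(doc: dict, interaction_ids) -> tuple[set[str], set[str]]:
    """(sources, sinks) by direct in/out role tally at entity level."""
    le2e = le_entity_map(doc)
    by_id = {it["id"]: it for it in doc["interactions"]}
    consumed, produced = set(), set()
    for iid in interaction_ids:
        for p in by_id[iid]["participants"]:
            ent = le2e[p["local_entity"]]
            if p["role"] == "input":
                consumed.add(ent)
            elif p["role"] == "output":
                produced.add(ent)
    return consumed - produced, produced - consumed


def bipartite_graph(doc: dict) -> nx.Graph:
    """Entity–interaction bipartite graph (entities tagged 'e:',
    interactions 'i:')."""
    le2e = le_entity_map(doc)
    g = nx.Graph()
    for e in doc["entities"]:
        g.add_node(f"e:{e['id']}")
    for it in doc["interactions"]:
        g.add_node(f"i:{it['id']}")
        for p in it["participants"]:
            g.add_edge(f"i:{it['id']}", f"e:{le2e[p['local_entity']]}")
    return g


def neighborhood_bfs(doc: dict, entity_id: str, p: int) -> set[str]:
    """p-neighbourhood by shortest paths on the bipartite graph: an
    interaction is at level k iff its bipartite distance from the entity
    is 2k - 1."""
    g = bipartite_graph(doc)
    dist = nx.single_source_shortest_path_length(g, f"e:{entity_id}", cutoff=2 * p - 1)
    return {node[2:] for node, d in dist.items() if node.startswith("i:") and d % 2 == 1}


def shared_gene_matrix(doc: dict, pathway_ids) -> list[list[int]]:
    sets = gene_sets(doc)
    return [
        [len(sets[a] & sets[b]) if a != b else len(sets[a]) for b in pathway_ids]
        for a in pathway_ids
    ]
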