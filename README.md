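# pathnet

A four-layer data model for curated metabolic and regulatory pathway
networks, backed by a single JSON repository file.

Curated plant pathway databases organize their content in four layers:
molecular **entities** (genes, RNAs, polypeptides, protein complexes,
metabolites), **localized entities** (an entity bound to a subcellular
compartment — ATP in the mitochondrion, nucleus, plastid and cytosol is
one entity with four localized copies), typed **interactions**
(enzymatic reactions, transport, transcription, translation, activation,
inhibition) over role-tagged localized participants, and **pathways** —
named, unordered collections of interactions with organism and ontology
classification. `pathnet` implements that model as a library + CLI for
researchers who want to script against such data: navigate up and down
the layers ("what entities make up this pathway?" / "what pathways does
this entity participate in?"), search and filter, assemble user-defined
networks that cross pathway boundaries, compute endpoints,
p-neighbourhoods and shared-gene pathway similarity, and export to SBML,
XGMML, GraphViz dot and CSV.

Core quantities:

* **Sources / sinks** of an interaction set `I` at entity level:
  `sources(I) = consumed(I) \ produced(I)`,
  `sinks(I) = produced(I) \ consumed(I)`,
  where consumed/produced tally input/output roles (modifiers excluded).
* **p-neighbourhood** of entity *e*: level 1 is every interaction
  containing *e*; level *k* adds interactions sharing ≥ 1 entity with a
  level-(k−1) interaction; the result is the union of levels 1..p.
* **Shared-gene distance matrix** over pathways `P₁..Pₙ`:
  `D[i,j] = |genes(Pᵢ) ∩ genes(Pⱼ)|`, with `D[i,i] = |genes(Pᵢ)|`
  (a similarity: larger = closer; dot rendering draws thicker edges for
  larger counts).

Repositories are loaded lazily the way a remote database would serve
them: listing pathway headers touches no interaction data; collection
detail (interaction lists, participant lists) is materialized on first
access and memoized, with observable counters (`Repository.access_stats`)
so the contract is testable.

## Worked example

```python
from pathnet import (builtin_fixture, load_repository, network_from_pathways,
                     filter_interactions, endpoints, shared_gene_matrix)

repo = load_repository(builtin_fixture("hormone_pair"))
print([h.name for h in repo.pathway_headers()])
# ['auxin biosynthesis', 'auxin signalling', 'auxin transport',
#  'brassinosteroid biosynthesis', 'brassinosteroid signalling']

m = shared_gene_matrix(repo, ["pw_bs_bio", "pw_bs_sig", "pw_ax_sig"])
print(m.values)
# [[3 1 1]
#  [1 2 0]
#  [1 0 3]]
```

The diagonal holds each pathway's gene count (brassinosteroid
biosynthesis carries 3 genes); off-diagonal cells count shared genes —
one gene shared between brassinosteroid biosynthesis and signalling,
one between brassinosteroid biosynthesis and auxin signalling, none
between the two signalling pathways.

The same flows are available from the shell:

```sh
pathnet fixture --name atp_localization -o atp.json
pathnet search --repo atp.json --layer local-entity --entity ATP
# {"entity": "atp", "id": "le_00000", "location": "loc_cytosol"}
# {"entity": "atp", "id": "le_00001", "location": "loc_mitochondrion"}
# {"entity": "atp", "id": "le_00002", "location": "loc_nucleus"}
# {"entity": "atp", "id": "le_00003", "location": "loc_plastid"}
pathnet network --repo atp.json --pathways pw_atp --format sbml -o atp.sbml
pathnet distmat --repo repo.json --out-csv matrix.csv --out-dot matrix.dot
```

Exit codes: 0 success, 1 usage error, 2 data/integrity error.

## Repository document format

A single UTF-8 JSON file with `format_version: "1.0"` and collections
`organisms`, `entity_types`, `interaction_types`, `cell_locations`,
`pathway_classes`, `entities`, `local_entities`, `interactions`,
`pathways`; compartment and pathway-ontology trees encode `parent` by id
(null for roots). The schema is documented in
`src/pathnet/repository.schema.json`; validation runs on load (disable
with `load_repository(..., validate=False)`).
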