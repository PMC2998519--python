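# Methods

## The data model

`pathnet` models curated biological network content in four layers.
An *entity* is a molecular species — gene, RNA, polypeptide, protein
complex or metabolite — optionally bound to an organism (genes are
organism-specific; common metabolites such as ATP or glucose are
universal and carry no organism). A *localized entity* is an (entity,
compartment) pair: localization is a separate layer so that one ATP
entity can have distinct localized copies in the mitochondrion, nucleus,
plastid and cytosol, and so that transport can be expressed as the same
entity changing compartment. An *interaction* is a typed
transformation or influence over role-tagged localized participants;
a *pathway* is a named, unordered, duplicate-free set of interaction
references with organism and pathway-ontology classification. A
*network* is the user-facing working set: a mutable, duplicate-free
collection of interactions that may freely cross pathway boundaries.

Participant roles are fixed to `{input, output, modifier}`, with
modifiers subtyped by effect (`catalysis`, `activation`, `inhibition`).
This is the minimal role vocabulary that supports endpoint detection
(mass flow), regulatory filtering, and a faithful mapping onto SBML
reactant/product/modifier lists. Participants are localized entities,
never bare entities — localization is mandatory at the participant
level — while every entity-level result (entity listings, gene sharing,
endpoints, neighbourhoods) collapses compartments back to the
underlying entity. Reversibility is not modelled: an interaction is
stored in one direction and exported with `reversible="false"`.

Two structural invariants are enforced at load beyond reference
resolution: compartment and pathway-ontology `parent` links must form
forests, and a transport interaction must move a single entity between
disjoint input/output compartment sets.

## Storage and the lazy-retrieval contract

The store is a single JSON document (desk-scale, diffable, no server),
validated on load by a hand-written structural validator that reports
the first violation with a JSON-pointer path; the format is additionally
documented as a JSON Schema in `src/pathnet/repository.schema.json`.
Referential integrity is a separate raw-document pass, run eagerly by
default or deferred to first access with `check_refs="lazy"`.

Retrieval mimics a remote database's just-in-time behaviour:
vocabularies, entities, localized entities and pathway *headers* (id,
name, organism, class) are parsed eagerly; a pathway's interaction-id
collection and an interaction's participant list are each materialized
on first access and memoized. The two counters exposed by
`Repository.access_stats()` (`interaction_lists`, `participant_lists`)
increment exactly once per distinct collection, which makes the
contract directly assertable: enumerating all pathway headers performs
zero materializations, k distinct collection accesses perform exactly
k, and repeated access performs none. Load-time validation scans the
raw document without touching the counters — the counters model
per-object retrieval through the API, not the initial parse.
Memoization is invalidated only by `save_pathway`, the single mutating
operation, which appends a new pathway record (fresh zero-padded id,
name unique per organism) and rewrites the document without altering
pre-existing records.

Search is case-insensitive substring matching with `*` wildcards and is
never anchored; synonym matching is opt-in
(`search_entities(..., include_synonyms=True)`), since primary-name
search is the conservative default. All result orderings are
lexicographic by (name, id): determinism is required for byte-stable
exports and golden tests. A location filter matches entities localized
at the given compartment or any descendant; a pathway-class filter
likewise includes descendant ontology nodes.

## Analytics

*Endpoints.* Sources are entities with at least one input role and no
output role across the collection; sinks the converse. Modifier-only
entities (enzymes, regulators) are excluded: start- and end-points
describe mass flow, and a catalyst is neither consumed nor produced.
With that exclusion sources and sinks are disjoint by construction.

*p-neighbourhood.* Distance counts interaction steps on the
entity–interaction bipartite graph: level 1 is every interaction
containing the seed entity, level k adds interactions sharing an entity
with level k−1. The implementation is a plain breadth-first expansion
over the repository's inverted entity→interaction index; tests compare
it against an independent `networkx` shortest-path oracle on the
bipartite graph (an interaction is within level p iff its bipartite
distance from the seed entity is an odd number ≤ 2p−1).

*Shared-gene matrix.* Cell (i, j) is the number of gene-typed entities
common to pathways i and j, computed at entity level
(compartment-collapsed); the diagonal holds each pathway's gene count.
The raw count is stored — it is a similarity, and the dot exporter maps
larger counts to thicker edges (`penwidth = 1 + count`, capped at 10)
with an edge drawn only when the count reaches `min_shared` (default 1).
Gene membership is taken from direct gene participants; no gene→RNA→
protein projection is attempted. No null model is provided: the matrix
is descriptive, not a significance statement.

## Exporters

All exporters are pure functions of (document, network, options) and
byte-stable: element order is sorted by id, attribute order fixed, no
timestamps. SBML Level 2 Version 4 was chosen for era-appropriate
compatibility with CellDesigner-generation tools; species are localized
entities (so ATP appears once per compartment, sharing a name),
compartments are the cell locations in use, and reactions carry
reactants/products/modifiers from participant roles with stoichiometry.
Information depth is deliberately minimal — names only, no kinetics or
annotations. Identifier sanitization maps non-alphanumerics to `_` with
role prefixes `s_`/`c_`/`r_`; collisions abort the export with the
colliding ids rather than renaming silently.

XGMML uses an explicit bipartite encoding — interaction nodes alongside
localized-entity nodes, edges input→interaction and interaction→output,
modifier edges attributed with their effect — because an edge-only
projection cannot represent multi-substrate reactions or modifiers.
The attribute vocabulary (`kind`, `entity_type`, `organism`,
`location`, `interaction_type`, `role`, `modifier_effect`) is this
package's own convention, sufficient for Cytoscape import.

## Synthetic repositories

The generator emulates the shape of a mid-size curated plant pathway
database. Defaults: 3 organisms (*Arabidopsis thaliana*, *Glycine
max*, *Vitis vinifera*); a two-level compartment tree (a `cell` root
with organelle children, 5 compartments total); a 6-term pathway
ontology; 3–8 interactions per pathway; an entity pool whose types are
drawn from a mix of 30 % genes, 20 % RNA, 20 % polypeptides, 5 %
complexes, 25 % metabolites; 15 % of interactions regulatory
(activation/inhibition); and a 30 % chance that a transcription event
reuses a gene already used by another pathway (`overlap_rate`), which
is what produces non-trivial shared-gene structure. Interaction
construction respects type semantics: transcription is gene→RNA (one
RNA per gene, memoized), translation RNA→polypeptide, enzymatic
reactions consume and produce metabolites with an optional polypeptide
catalyst, transport moves one metabolite between two distinct
compartments, and regulation attaches a polypeptide modifier with the
matching effect.

A single seeded `random.Random` stream with a documented draw order
(organisms, locations, classes, entity pool, then pathways interaction
by interaction) makes documents byte-identical for identical parameters
and seed; any change to the draw order is a breaking change. With
`overlap_rate=0` gene sets are pairwise disjoint by construction.

What the generator does *not* emulate: realistic stoichiometry,
regulation topology, pathway size distributions, or identifier
conventions of real databases (AraCyc/TAIR-style accessions). Passing
tests therefore demonstrate correctness of the data model, navigation,
analytics and exports over structurally faithful documents — not
biological realism of the generated content.

## Problem sizes and numerical choices

The test suite and acceptance script use a canonical 20-pathway
repository (seed 42) for oracle-equivalence checks, 50 seeded
repositories for navigation symmetry, 100 small repositories for
endpoint tallies, and one 403-pathway repository — the scale of a full
curated database — for the all-pathway distance matrix; the whole suite
runs in a few seconds. All matrix arithmetic is exact integer set
counting; there are no tolerances anywhere in the package. Degenerate
inputs are defined rather than accidental: an empty-but-valid document
loads and searches cleanly; an empty network may not be exported or
(by default) published; `neighborhood` requires p ≥ 1; a
`shared_gene_matrix` request with duplicate pathway ids is a usage
error; publishing an empty network requires `allow_empty=True`.

## Known limitations

No live/remote database connectivity, user accounts or concurrent
writers; no kinetics, sequences or cross-database identifier mapping;
no SBML import; no BioPAX/PSI output; no statistical model over gene
sharing. Whether regulatory subtypes beyond activation/inhibition
(e.g. allosteric or indirect regulation) deserve first-class types is
left open — the interaction-type vocabulary is extensible, and new
labels participate in filtering via their `is_regulatory` flag.
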