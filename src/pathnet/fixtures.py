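"""Deterministic repository-document generators.

Two kinds of fixture are provided:

* **Named fixtures** (:func:`builtin_fixture`) — tiny hand-built
  documents with known structure: the ATP-in-four-compartments
  localization example, a linear chain, a closed cycle, a pathway mixing
  metabolic core with transcription/translation clutter, and a set of
  five hormone pathways with overlapping gene content.
* **Random repositories** (:func:`generate_repository`) — parameterized,
  seeded documents emulating a curated plant pathway database: a few
  organisms, a two-level compartment tree (cell → organelles), a small
  pathway ontology, an entity pool drawn from a type mix, and pathways
  assembled from typed interactions (enzymatic reactions, transport,
  transcription, translation, activation, inhibition).

Generation uses a single seeded pseudo-random stream with a fixed draw
order, so the same parameters and seed always produce byte-identical
documents; any change to the draw order is a breaking change.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import schema
from .errors import UsageError
from .repository import serialize_document

BUILTIN_NAMES = ("atp_localization", "chain", "cycle", "clutter", "hormone_pair")

_ORGANISM_NAMES = ["Arabidopsis thaliana", "Glycine max", "Vitis vinifera"]
_ORGANELLES = [
    "cytosol", "mitochondrion", "nucleus", "plastid", "vacuole",
    "chloroplast", "peroxisome", "endoplasmic reticulum", "golgi", "cell wall",
]
_PATHWAY_CLASS_NAMES = [
    "biosynthesis", "degradation", "signalling", "transport", "regulation",
]


class _Builder:
    """Accumulates records for a repository document in insertion order."""

    def __init__(self):
        self.doc: dict = {"format_version": schema.FORMAT_VERSION}
        for name in schema.COLLECTIONS:
            self.doc[name] = []
        self._local_index: dict[tuple[str, str], str] = {}
        for label in ("gene", "RNA", "polypeptide", "protein_complex", "metabolite"):
            self.doc["entity_types"].append({"id": f"et_{label}", "label": label})
        for label, reg in (
            ("enzymatic_reaction", False),
            ("transport", False),
            ("transcription", False),
            ("translation", False),
            ("activation", True),
            ("inhibition", True),
        ):
            self.doc["interaction_types"].append(
                {"id": f"it_{label}", "label": label, "is_regulatory": reg}
            )

    def organism(self, oid: str, name: str) -> str:
        self.doc["organisms"].append({"id": oid, "name": name})
        return oid

    def location(self, lid: str, name: str, parent: Optional[str] = None) -> str:
        self.doc["cell_locations"].append({"id": lid, "name": name, "parent": parent})
        return lid

    def pathway_class(self, cid: str, name: str, parent: Optional[str] = None) -> str:
        self.doc["pathway_classes"].append({"id": cid, "name": name, "parent": parent})
        return cid

    def entity(
        self, eid: str, name: str, type_label: str,
        organism: Optional[str] = None, synonyms: tuple[str, ...] = (),
    ) -> str:
        self.doc["entities"].append(
            {
                "id": eid,
                "name": name,
                "entity_type": f"et_{type_label}",
                "organism": organism,
                "synonyms": list(synonyms),
            }
        )
        return eid

    def local(self, entity_id: str, location_id: str) -> str:
        key = (entity_id, location_id)
        if key not in self._local_index:
            lid = f"le_{len(self._local_index):05d}"
            self._local_index[key] = lid
            self.doc["local_entities"].append(
                {"id": lid, "entity": entity_id, "location": location_id}
            )
        return self._local_index[key]

    def interaction(
        self, iid: str, type_label: str, participants, organism: Optional[str] = None
    ) -> str:
        parts = []
        for p in participants:
            le, role = p[0], p[1]
            rec = {"local_entity": le, "role": role}
            if len(p) > 2 and p[2] is not None:
                rec["modifier_effect"] = p[2]
            parts.append(rec)
        self.doc["interactions"].append(
            {
                "id": iid,
                "interaction_type": f"it_{type_label}",
                "organism": organism,
                "participants": parts,
            }
        )
        return iid

    def pathway(
        self, pid: str, name: str, organism: str,
        pathway_class: Optional[str], interactions,
    ) -> str:
        self.doc["pathways"].append(
            {
                "id": pid,
                "name": name,
                "organism": organism,
                "pathway_class": pathway_class,
                "interactions": list(interactions),
            }
        )
        return pid

    def build(self) -> dict:
        schema.validate_document(self.doc)
        schema.check_references(self.doc)
        return self.doc


# ---------------------------------------------------------------------------
# named fixtures


def _atp_localization() -> dict:
    b = _Builder()
    b.organism("ath", "Arabidopsis thaliana")
    cell = b.location("loc_cell", "cell")
    compartments = {}
    for name in ("cytosol", "mitochondrion", "nucleus", "plastid"):
        compartments[name] = b.location(f"loc_{name}", name, parent=cell)
    atp = b.entity("atp", "ATP", "metabolite", organism=None,
                   synonyms=("adenosine triphosphate",))
    locals_ = {name: b.local(atp, lid) for name, lid in compartments.items()}
    # one transport per compartment pair, forming a shuttle cycle
    hops = [
        ("cytosol", "mitochondrion"),
        ("mitochondrion", "nucleus"),
        ("nucleus", "plastid"),
        ("plastid", "cytosol"),
    ]
    ids = []
    for i, (a, bb) in enumerate(hops):
        ids.append(
            b.interaction(
                f"tr{i}", "transport",
                [(locals_[a], "input"), (locals_[bb], "output")],
            )
        )
    b.pathway("pw_atp", "ATP shuttling", "ath", None, ids)
    return b.build()


def _linear(names, close_cycle: bool) -> dict:
    b = _Builder()
    b.organism("ath", "Arabidopsis thaliana")
    cell = b.location("loc_cell", "cell")
    cytosol = b.location("loc_cytosol", "cytosol", parent=cell)
    locals_ = {
        n: b.local(b.entity(f"m_{n}", n, "metabolite"), cytosol) for n in names
    }
    pairs = list(zip(names, names[1:]))
    if close_cycle:
        pairs.append((names[-1], names[0]))
    ids = [
        b.interaction(
            f"rx{i}", "enzymatic_reaction",
            [(locals_[a], "input"), (locals_[c], "output")],
        )
        for i, (a, c) in enumerate(pairs)
    ]
    b.pathway("pw0", "cycle" if close_cycle else "chain", "ath", None, ids)
    return b.build()


def _clutter() -> dict:
    """One pathway: 5 enzymatic steps plus 3 transcription and 2
    translation events (the removable clutter)."""
    b = _Builder()
    b.organism("ath", "Arabidopsis thaliana")
    cell = b.location("loc_cell", "cell")
    cytosol = b.location("loc_cytosol", "cytosol", parent=cell)
    nucleus = b.location("loc_nucleus", "nucleus", parent=cell)
    mets = [b.local(b.entity(f"m{i}", f"M{i}", "metabolite"), cytosol) for i in range(6)]
    ids = [
        b.interaction(
            f"rx{i}", "enzymatic_reaction",
            [(mets[i], "input"), (mets[i + 1], "output")],
        )
        for i in range(5)
    ]
    rna_ids = []
    for i in range(3):
        g = b.local(b.entity(f"g{i}", f"gene{i}", "gene", organism="ath"), nucleus)
        rna_ids.append(b.entity(f"r{i}", f"rna{i}", "RNA", organism="ath"))
        r = b.local(rna_ids[-1], nucleus)
        ids.append(b.interaction(f"tx{i}", "transcription", [(g, "input"), (r, "output")], "ath"))
    for i in range(2):
        r = b.local(rna_ids[i], cytosol)
        p = b.local(b.entity(f"p{i}", f"protein{i}", "polypeptide", organism="ath"), cytosol)
        ids.append(b.interaction(f"tl{i}", "translation", [(r, "input"), (p, "output")], "ath"))
    b.pathway("pw0", "cluttered pathway", "ath", None, ids)
    return b.build()


def _hormone_pair() -> dict:
    """Five pathways covering brassinosteroid and auxin metabolism and
    signalling, with overlapping gene sets."""
    b = _Builder()
    b.organism("ath", "Arabidopsis thaliana")
    cell = b.location("loc_cell", "cell")
    nucleus = b.location("loc_nucleus", "nucleus", parent=cell)
    root = b.pathway_class("pc_root", "plant hormone metabolism and signalling")
    pc_bio = b.pathway_class("pc_bio", "biosynthesis", parent=root)
    pc_sig = b.pathway_class("pc_sig", "signalling", parent=root)

    genes, rnas = {}, {}
    for i in range(1, 9):
        genes[i] = b.local(b.entity(f"g{i}", f"gene{i}", "gene", "ath"), nucleus)
        rnas[i] = b.local(b.entity(f"r{i}", f"rna{i}", "RNA", "ath"), nucleus)

    spec_ = [
        ("pw_bs_bio", "brassinosteroid biosynthesis", pc_bio, [1, 2, 3]),
        ("pw_bs_sig", "brassinosteroid signalling", pc_sig, [3, 4]),
        ("pw_ax_bio", "auxin biosynthesis", pc_bio, [5, 6]),
        ("pw_ax_sig", "auxin signalling", pc_sig, [6, 7, 1]),
        ("pw_ax_tr", "auxin transport", pc_sig, [7, 8]),
    ]
    seq = 0
    for pid, name, cls, gene_nums in spec_:
        ids = []
        for gn in gene_nums:
            ids.append(
                b.interaction(
                    f"tx{seq}", "transcription",
                    [(genes[gn], "input"), (rnas[gn], "output")], "ath",
                )
            )
            seq += 1
        b.pathway(pid, name, "ath", cls, ids)
    return b.build()


def builtin_fixture(name: str) -> dict:
    """Return a named, hand-built repository document."""
    if name == "atp_localization":
        return _atp_localization()
    if name == "chain":
        return _linear(["A", "B", "C"], close_cycle=False)
    if name == "cycle":
        return _linear(["A", "B", "C"], close_cycle=True)
    if name == "clutter":
        return _clutter()
    if name == "hormone_pair":
        return _hormone_pair()
    raise UsageError(f"unknown fixture {name!r}; choose from {BUILTIN_NAMES}")


# ---------------------------------------------------------------------------
# random repositories


@dataclass(frozen=True)
class FixtureParams:
    """Parameters for :func:`generate_repository`.

    Defaults emulate a small curated plant pathway database: three
    organisms, five compartments under a ``cell`` root, a modest mix of
    molecular entity types dominated by genes and metabolites, about one
    regulatory interaction in seven, and moderate gene sharing between
    pathways.
    """

    seed: int
    n_pathways: int
    n_organisms: int = 3
    interactions_per_pathway: tuple[int, int] = (3, 8)
    entity_type_mix: dict = field(
        default_factory=lambda: {
            "gene": 0.30,
            "RNA": 0.20,
            "polypeptide": 0.20,
            "protein_complex": 0.05,
            "metabolite": 0.25,
        }
    )
    regulatory_fraction: float = 0.15
    overlap_rate: float = 0.30
    n_locations: int = 5
    n_entities: Optional[int] = None

    def __post_init__(self):
        if self.n_pathways < 1:
            raise UsageError("n_pathways must be >= 1")
        if self.n_organisms < 1:
            raise UsageError("n_organisms must be >= 1")
        lo, hi = self.interactions_per_pathway
        if not (1 <= lo <= hi):
            raise UsageError("interactions_per_pathway must satisfy 1 <= lo <= hi")
        if abs(sum(self.entity_type_mix.values()) - 1.0) > 1e-9:
            raise UsageError("entity_type_mix proportions must sum to 1")
        if not 0 <= self.regulatory_fraction <= 1:
            raise UsageError("regulatory_fraction must be in [0, 1]")
        if not 0 <= self.overlap_rate <= 1:
            raise UsageError("overlap_rate must be in [0, 1]")
        if self.n_locations < 2:
            raise UsageError("n_locations must be >= 2 (a root plus organelles)")
        if self.n_entities is not None and self.n_entities < 1:
            raise UsageError("n_entities must be >= 1")


_NAME_PREFIX = {
    "gene": "g", "RNA": "r", "polypeptide": "p",
    "protein_complex": "cx", "metabolite": "m",
}


class _Generator:
    def __init__(self, params: FixtureParams):
        self.params = params
        self.rng = random.Random(params.seed)
        self.b = _Builder()
        self.next_entity = 0
        self.unused: dict[str, list[str]] = {t: [] for t in _NAME_PREFIX}
        self.rna_for_gene: dict[str, str] = {}
        self.protein_for_rna: dict[str, str] = {}
        self.gene_pathways: dict[str, set[str]] = {}

    # draw order is part of the contract: organisms, locations, classes,
    # entity pool, then pathways (interaction by interaction)

    def _mint(self, type_label: str, organism: Optional[str]) -> str:
        i = self.next_entity
        self.next_entity += 1
        return self.b.entity(
            f"ent{i:05d}", f"{_NAME_PREFIX[type_label]}{i:05d}", type_label, organism
        )

    def _take(self, type_label: str, organism: Optional[str]) -> str:
        pool = self.unused[type_label]
        if pool:
            return pool.pop()
        return self._mint(type_label, organism)

    def run(self) -> dict:
        p, rng, b = self.params, self.rng, self.b
        organisms = []
        for i in range(p.n_organisms):
            name = _ORGANISM_NAMES[i] if i < len(_ORGANISM_NAMES) else f"Organism {i}"
            organisms.append(b.organism(f"org{i:02d}", name))
        cell = b.location("loc000", "cell")
        locs = []
        for i in range(p.n_locations - 1):
            name = _ORGANELLES[i] if i < len(_ORGANELLES) else f"compartment {i}"
            locs.append(b.location(f"loc{i + 1:03d}", name, parent=cell))
        # transport may also use the root, so two compartments always exist
        self.transport_locs = [cell] + locs
        root_class = b.pathway_class("pc000", "metabolism and regulation")
        classes = [
            b.pathway_class(f"pc{i + 1:03d}", name, parent=root_class)
            for i, name in enumerate(_PATHWAY_CLASS_NAMES)
        ]

        lo, hi = p.interactions_per_pathway
        expected = p.n_pathways * (lo + hi) / 2
        n_entities = p.n_entities or max(40, int(2.5 * expected))
        labels = list(p.entity_type_mix)
        weights = [p.entity_type_mix[t] for t in labels]
        for _ in range(n_entities):
            t = rng.choices(labels, weights)[0]
            org = None if t == "metabolite" else rng.choice(organisms)
            self.unused[t].append(self._mint(t, org))
        for pool in self.unused.values():
            pool.reverse()  # pop() consumes in creation order

        for pi in range(p.n_pathways):
            pid = f"pw{pi:04d}"
            org = rng.choice(organisms)
            cls = rng.choice(classes)
            k = rng.randint(lo, hi)
            iids = []
            for ki in range(k):
                iid = f"ix{pi:04d}_{ki:02d}"
                if rng.random() < p.regulatory_fraction:
                    t = rng.choice(["activation", "inhibition"])
                else:
                    t = rng.choice(
                        ["enzymatic_reaction", "enzymatic_reaction",
                         "transport", "transcription", "translation"]
                    )
                iids.append(self._interaction(iid, t, pid, org, locs))
            b.pathway(pid, f"synthetic pathway {pi:04d}", org, cls, iids)
        return b.build()

    def _pick_gene(self, pathway_id: str, organism: Optional[str]) -> str:
        rng = self.rng
        shared_candidates = sorted(
            g for g, ps in self.gene_pathways.items() if ps and pathway_id not in ps
        )
        if shared_candidates and rng.random() < self.params.overlap_rate:
            gene = rng.choice(shared_candidates)
        else:
            gene = self._take("gene", organism)
        self.gene_pathways.setdefault(gene, set()).add(pathway_id)
        return gene

    def _interaction(self, iid, type_label, pathway_id, organism, locs) -> str:
        rng, b = self.rng, self.b
        loc = rng.choice(locs)
        parts = []
        if type_label == "transcription":
            gene = self._pick_gene(pathway_id, organism)
            rna = self.rna_for_gene.get(gene)
            if rna is None:
                rna = self.rna_for_gene[gene] = self._take("RNA", organism)
            parts = [(b.local(gene, loc), "input"), (b.local(rna, loc), "output")]
        elif type_label == "translation":
            rna = rng.choice(sorted(self.rna_for_gene.values())) if (
                self.rna_for_gene and rng.random() < 0.5
            ) else self._take("RNA", organism)
            protein = self.protein_for_rna.get(rna)
            if protein is None:
                protein = self.protein_for_rna[rna] = self._take("polypeptide", organism)
            parts = [(b.local(rna, loc), "input"), (b.local(protein, loc), "output")]
        elif type_label == "transport":
            met = self._take("metabolite", None)
            src, dst = rng.sample(self.transport_locs, 2)
            parts = [(b.local(met, src), "input"), (b.local(met, dst), "output")]
        elif type_label == "enzymatic_reaction":
            n_in = rng.randint(1, 2)
            n_out = rng.randint(1, 2)
            for _ in range(n_in):
                parts.append((b.local(self._take("metabolite", None), loc), "input"))
            for _ in range(n_out):
                parts.append((b.local(self._take("metabolite", None), loc), "output"))
            if rng.random() < 0.7:
                enz = self._take("polypeptide", organism)
                parts.append((b.local(enz, loc), "modifier", "catalysis"))
        else:  # activation / inhibition
            regulator = self._take("polypeptide", organism)
            target_in = self._take("metabolite", None)
            target_out = self._take("metabolite", None)
            parts = [
                (b.local(regulator, loc), "modifier", type_label),
                (b.local(target_in, loc), "input"),
                (b.local(target_out, loc), "output"),
            ]
        return b.interaction(iid, type_label, parts, organism)


def generate_repository(params: FixtureParams) -> dict:
    """Generate a schema-valid, referentially intact random repository
    document; byte-identical for identical parameters and seed."""
    return _Generator(params).run()


def manifest_for(doc: dict) -> dict:
    """Layer counts the generator declares alongside a document."""
    return {name: len(doc[name]) for name in schema.COLLECTIONS}


def write_fixture(
    doc: dict, path: Union[str, Path], with_manifest: bool = True
) -> Path:
    """Write a document (and a ``.manifest.json`` sidecar) to disk."""
    path = Path(path)
    path.write_text(serialize_document(doc), encoding="utf-8")
    if with_manifest:
        sidecar = path.with_suffix(path.suffix + ".manifest.json")
        sidecar.write_text(
            json.dumps(manifest_for(doc), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    return path
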