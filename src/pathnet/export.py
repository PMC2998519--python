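"""Deterministic exporters: SBML L2V4, XGMML, GraphViz dot, CSV.

Every exporter is a pure function of its inputs and emits byte-stable
UTF-8 text with LF line endings: element order is sorted, attribute
order is fixed, and no timestamps or environment data leak into the
output.

SBML (Level 2 Version 4) maps localized entities to species, used
compartments to compartments, and interactions to reactions with
reactants/products/modifiers taken from participant roles.  Depth of
information is deliberately minimal — names only, no kinetics or
annotations — which keeps the documents importable by the broadest
range of downstream tools (CellDesigner, Jarnac and kin).

XGMML uses an explicit bipartite encoding: one node per localized
entity, one node per interaction, directed edges input→interaction and
interaction→output, modifier edges carrying their effect.  Interaction
nodes keep multi-substrate reactions and modifiers representable, which
an edge-only projection cannot do.  Cytoscape imports the result
directly.

The distance-matrix exporters render shared-gene similarity: dot edges
appear for pairs sharing at least ``min_shared`` genes with penwidth
1 + count (capped at 10) so thicker lines mean closer pathways; CSV is
RFC 4180 with the pathway ids as header row and row labels.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from typing import Union
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

from .errors import ExportError, UsageError
from .model import Network
from .netops import DistanceMatrix, _resolve_network
from .repository import Repository

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
XGMML_NS = "http://www.cs.rpi.edu/XGMML"

_SANITIZE = re.compile(r"[^A-Za-z0-9]")


def sanitize_id(raw: str, prefix: str) -> str:
    """Deterministic SId-safe identifier: non-alphanumerics become ``_``
    and a role prefix (``s_``/``c_``/``r_``) is prepended."""
    return prefix + _SANITIZE.sub("_", raw)


def _sanitize_map(ids, prefix: str) -> dict[str, str]:
    out: dict[str, str] = {}
    seen: dict[str, str] = {}
    for raw in sorted(ids):
        sid = sanitize_id(raw, prefix)
        if sid in seen:
            raise ExportError(
                f"id sanitization collision: {seen[sid]!r} and {raw!r} both map to {sid!r}"
            )
        seen[sid] = raw
        out[raw] = sid
    return out


def _indent_xml(elem: ET.Element, level: int = 0):
    pad = "\n" + "  " * level
    if len(elem):
        if not (elem.text and elem.text.strip()):
            elem.text = pad + "  "
        for child in elem:
            _indent_xml(child, level + 1)
            if not (child.tail and child.tail.strip()):
                child.tail = pad + "  "
        if not (elem[-1].tail and elem[-1].tail.strip()):
            elem[-1].tail = pad
    elif level and not (elem.tail and elem.tail.strip()):
        elem.tail = pad


def _serialize_xml(root: ET.Element) -> str:
    _indent_xml(root)
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="UTF-8", xml_declaration=True)
    return buf.getvalue().decode("utf-8") + "\n"


def to_sbml(repo: Repository, net: Union[Network, str]) -> str:
    """Export a network (or pathway id) as an SBML L2V4 document."""
    net = _resolve_network(repo, net)
    if not net.interactions:
        raise UsageError("cannot export an empty network")

    interactions = [repo.interaction(i) for i in sorted(net.interactions)]
    local_entity_ids = sorted(
        {p.local_entity for it in interactions for p in it.participants}
    )
    location_ids = sorted(
        {repo.local_entity(le).location for le in local_entity_ids}
    )
    species_ids = _sanitize_map(local_entity_ids, "s_")
    compartment_ids = _sanitize_map(location_ids, "c_")
    reaction_ids = _sanitize_map([it.id for it in interactions], "r_")

    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "2", "version": "4"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": "network", "name": net.label or "network"})

    list_c = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for loc_id in location_ids:
        loc = repo.cell_location(loc_id)
        ET.SubElement(
            list_c,
            f"{{{SBML_NS}}}compartment",
            {"id": compartment_ids[loc_id], "name": loc.name},
        )

    list_s = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for le_id in local_entity_ids:
        le = repo.local_entity(le_id)
        entity = repo.entity(le.entity)
        ET.SubElement(
            list_s,
            f"{{{SBML_NS}}}species",
            {
                "id": species_ids[le_id],
                "name": entity.name,
                "compartment": compartment_ids[le.location],
            },
        )

    list_r = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for it in interactions:
        reaction = ET.SubElement(
            list_r,
            f"{{{SBML_NS}}}reaction",
            {
                "id": reaction_ids[it.id],
                "name": repo.interaction_type(it.interaction_type).label,
                "reversible": "false",
            },
        )
        by_role = {"input": [], "output": [], "modifier": []}
        for p in it.participants:
            by_role[p.role].append(p)
        if by_role["input"]:
            lst = ET.SubElement(reaction, f"{{{SBML_NS}}}listOfReactants")
            for p in by_role["input"]:
                ET.SubElement(
                    lst,
                    f"{{{SBML_NS}}}speciesReference",
                    {
                        "species": species_ids[p.local_entity],
                        "stoichiometry": _num(p.stoichiometry),
                    },
                )
        if by_role["output"]:
            lst = ET.SubElement(reaction, f"{{{SBML_NS}}}listOfProducts")
            for p in by_role["output"]:
                ET.SubElement(
                    lst,
                    f"{{{SBML_NS}}}speciesReference",
                    {
                        "species": species_ids[p.local_entity],
                        "stoichiometry": _num(p.stoichiometry),
                    },
                )
        if by_role["modifier"]:
            lst = ET.SubElement(reaction, f"{{{SBML_NS}}}listOfModifiers")
            for p in by_role["modifier"]:
                ET.SubElement(
                    lst,
                    f"{{{SBML_NS}}}modifierSpeciesReference",
                    {"species": species_ids[p.local_entity]},
                )
    return _serialize_xml(sbml)


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def to_xgmml(
    repo: Repository, net: Union[Network, str], include_localization: bool = True
) -> str:
    """Export a network as an XGMML bipartite graph.

    Emits one node per localized entity (label, entity type, organism
    and — unless ``include_localization=False`` — compartment), one node
    per interaction (its type), and directed edges from inputs into the
    interaction node and from it to outputs; modifier edges carry the
    modifier effect.  Output bytes are identical across runs.
    """
    net = _resolve_network(repo, net)
    if not net.interactions:
        raise UsageError("cannot export an empty network")

    interactions = [repo.interaction(i) for i in sorted(net.interactions)]
    local_entity_ids = sorted(
        {p.local_entity for it in interactions for p in it.participants}
    )
    # XGMML ids are numeric; assign deterministically: entities first
    node_num = {("le", le): i + 1 for i, le in enumerate(local_entity_ids)}
    for j, it in enumerate(interactions):
        node_num[("it", it.id)] = len(local_entity_ids) + j + 1

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<graph xmlns="{XGMML_NS}" directed="1" label={quoteattr(net.label or "network")}>',
    ]

    def att(name, value):
        return f'    <att name={quoteattr(name)} type="string" value={quoteattr(str(value))}/>'

    for le_id in local_entity_ids:
        le = repo.local_entity(le_id)
        entity = repo.entity(le.entity)
        lines.append(
            f'  <node id="{node_num[("le", le_id)]}" label={quoteattr(entity.name)}>'
        )
        lines.append(att("kind", "entity"))
        lines.append(att("local_entity", le_id))
        lines.append(att("entity", entity.id))
        lines.append(att("entity_type", repo.entity_type(entity.entity_type).label))
        if entity.organism:
            lines.append(att("organism", repo.organism(entity.organism).name))
        if include_localization:
            lines.append(att("location", repo.cell_location(le.location).name))
        lines.append("  </node>")
    for it in interactions:
        type_label = repo.interaction_type(it.interaction_type).label
        lines.append(
            f'  <node id="{node_num[("it", it.id)]}" label={quoteattr(type_label)}>'
        )
        lines.append(att("kind", "interaction"))
        lines.append(att("interaction", it.id))
        lines.append(att("interaction_type", type_label))
        lines.append("  </node>")

    for it in interactions:
        it_num = node_num[("it", it.id)]
        for p in it.participants:
            le_num = node_num[("le", p.local_entity)]
            if p.role == "input":
                src, tgt, role = le_num, it_num, "input"
            elif p.role == "output":
                src, tgt, role = it_num, le_num, "output"
            else:
                src, tgt, role = le_num, it_num, "modifier"
            lines.append(f'  <edge source="{src}" target="{tgt}">')
            lines.append(att("role", role))
            if p.modifier_effect:
                lines.append(att("modifier_effect", p.modifier_effect))
            lines.append("  </edge>")
    lines.append("</graph>")
    return "\n".join(lines) + "\n"


def to_dot_distance(matrix: DistanceMatrix, min_shared: int = 1) -> str:
    """Render a shared-gene matrix as an undirected GraphViz graph.

    One node per pathway; one edge per unordered pair sharing at least
    ``min_shared`` genes, drawn with penwidth ``min(1 + shared, 10)`` so
    thicker lines indicate closer pathways.
    """
    if min_shared < 0:
        raise UsageError("min_shared must be >= 0")
    lines = ["graph pathway_distance {"]
    for pid in matrix.pathway_ids:
        lines.append(f"  {_dot_id(pid)} [label={_dot_quote(pid)}];")
    n = len(matrix.pathway_ids)
    for i in range(n):
        for j in range(i + 1, n):
            shared = int(matrix.values[i, j])
            if shared >= min_shared:
                penwidth = min(1 + shared, 10)
                lines.append(
                    f"  {_dot_id(matrix.pathway_ids[i])} -- "
                    f"{_dot_id(matrix.pathway_ids[j])} "
                    f"[label={shared}, penwidth={penwidth}];"
                )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_id(raw: str) -> str:
    return _SANITIZE.sub("_", raw)


def _dot_quote(raw: str) -> str:
    return '"' + raw.replace('"', r"\"") + '"'


def to_csv_matrix(matrix: DistanceMatrix) -> str:
    """Render a shared-gene matrix as RFC 4180 CSV (header row of
    pathway ids, row labels in column 1, trailing newline)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["pathway", *matrix.pathway_ids])
    for i, pid in enumerate(matrix.pathway_ids):
        writer.writerow([pid, *(int(v) for v in matrix.values[i])])
    return buf.getvalue()


@dataclass(frozen=True)
class ExportOptions:
    """Bundle of exporter options for callers that route by format."""

    format: str = "sbml"
    include_localization: bool = True
    min_shared: int = 1

    def __post_init__(self):
        if self.format not in ("sbml", "xgmml", "dot", "csv"):
            raise UsageError(f"unknown export format {self.format!r}")
        if self.min_shared < 0:
            raise UsageError("min_shared must be >= 0")

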