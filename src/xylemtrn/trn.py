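"""Four-layer transcriptional regulatory network construction and export.

Layer assignment is rule-based, applied in order:

1. wood-associated NAC master switches (role WND) form layer 1 — identified
   by catalog role, never by scanning;
2. upregulated TFs whose promoter carries SNBE but not SMRE form layer 2;
3. upregulated TFs with SMRE (alone or together with SNBE) form layer 3;
4. cell wall biosynthetic and PCD genes form layer 4.

TFs carrying neither element are reported as unplaced.  Edges run strictly
downward (source layer < target layer) and are each mediated by a cis-element
present in the target's promoter: WND->SNBE targets, MYB->SMRE targets,
layer-3 WRKY->W-box layer-4 targets, and NAC072/NAC045-class orthologs ->
TGTG-carrying PCD genes.  Curated literature edges can be merged in from a
TSV and are tagged evidence=literature; a layer-override table lets users pin
named genes to layers to reproduce hand-curated placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.sax.saxutils import escape

import networkx as nx

from .catalog import EFFECTOR_ROLES, GeneCatalog
from .errors import ValidationError
from .motifs import ElementProfile

ELEMENTS = ("SNBE", "SMRE", "WBOX", "TGTG")


@dataclass(frozen=True, order=True)
class TrnNode:
    gene_id: str
    layer: int
    role: str
    family: str
    ortholog_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.layer not in (1, 2, 3, 4):
            raise ValidationError(f"{self.gene_id}: layer must be 1..4, got {self.layer}")
        if self.layer == 1 and self.role != "WND":
            raise ValidationError(f"{self.gene_id}: layer 1 is reserved for WND genes")
        if self.layer == 4 and self.role not in EFFECTOR_ROLES:
            raise ValidationError(f"{self.gene_id}: layer 4 is reserved for CW/PCD genes")


@dataclass(frozen=True, order=True)
class TrnEdge:
    source: str
    target: str
    element: str
    evidence: str = "predicted"

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValidationError(f"edge {self.source}->{self.target}: unknown element {self.element!r}")
        if self.evidence not in ("predicted", "literature"):
            raise ValidationError(f"edge {self.source}->{self.target}: unknown evidence {self.evidence!r}")


def assign_layers(
    profiles: Mapping[str, ElementProfile],
    catalog: GeneCatalog,
    upregulated: Iterable[str],
    overrides: Mapping[str, int] | None = None,
) -> tuple[list[TrnNode], list[str]]:
    """Assign network layers; returns (nodes, unplaced TF gene ids).

    *profiles* must cover the scanned genes (upregulated TFs and layer-4
    candidates); WND genes need no profile.  *overrides* pins gene ids to
    layers, taking precedence over the rules.
    """
    overrides = dict(overrides or {})
    upregulated = set(upregulated)
    nodes: list[TrnNode] = []
    unplaced: list[str] = []

    def _node(gene_id: str, layer: int) -> TrnNode:
        entry = catalog[gene_id]
        return TrnNode(
            gene_id=gene_id,
            layer=overrides.pop(gene_id, layer),
            role=entry.role,
            family=entry.family,
            ortholog_tags=entry.ortholog_tags,
        )

    for entry in catalog:
        if entry.role == "WND":
            nodes.append(_node(entry.gene_id, 1))
        elif entry.role == "TF":
            if entry.gene_id not in upregulated:
                continue
            prof = profiles.get(entry.gene_id)
            if prof is None:
                raise ValidationError(f"{entry.gene_id}: upregulated TF has no element profile")
            if prof.has_snbe and not prof.has_smre:
                nodes.append(_node(entry.gene_id, 2))
            elif prof.has_smre:
                nodes.append(_node(entry.gene_id, 3))
            elif entry.gene_id in overrides:
                nodes.append(_node(entry.gene_id, overrides[entry.gene_id]))
            else:
                unplaced.append(entry.gene_id)
        elif entry.role in EFFECTOR_ROLES:
            nodes.append(_node(entry.gene_id, 4))
    nodes.sort(key=lambda n: (n.layer, n.gene_id))
    return nodes, unplaced


def build_edges(
    nodes: Sequence[TrnNode],
    profiles: Mapping[str, ElementProfile],
    curated: Iterable[TrnEdge] = (),
) -> list[TrnEdge]:
    """Element-mediated regulator->target edges, strictly downward in layer.

    Rules: every layer-1 WND targets every lower gene with SNBE; every
    layer-2/3 MYB targets every strictly lower gene with SMRE; every layer-3
    WRKY targets every layer-4 gene with a W-box; every NAC072/NAC045-class
    ortholog targets every layer-4 PCD gene with the TGTG element.  Curated
    edges are merged in unchanged; duplicates collapse.
    """
    layer = {n.gene_id: n.layer for n in nodes}
    edges: set[TrnEdge] = set()

    def _prof_has(gene_id: str, motif: str) -> bool:
        prof = profiles.get(gene_id)
        return prof is not None and prof.has(motif)

    for src in nodes:
        for tgt in nodes:
            if layer[src.gene_id] >= layer[tgt.gene_id]:
                continue
            if src.role == "WND" and _prof_has(tgt.gene_id, "SNBE"):
                edges.add(TrnEdge(src.gene_id, tgt.gene_id, "SNBE"))
            if src.family == "MYB" and src.layer in (2, 3) and _prof_has(tgt.gene_id, "SMRE"):
                edges.add(TrnEdge(src.gene_id, tgt.gene_id, "SMRE"))
            if (
                src.family == "WRKY"
                and src.layer == 3
                and tgt.layer == 4
                and _prof_has(tgt.gene_id, "WBOX")
            ):
                edges.add(TrnEdge(src.gene_id, tgt.gene_id, "WBOX"))
            if (
                src.ortholog_tags & {"NAC072_class", "NAC045_class"}
                and tgt.layer == 4
                and tgt.role == "PCD"
                and _prof_has(tgt.gene_id, "TGTG")
            ):
                edges.add(TrnEdge(src.gene_id, tgt.gene_id, "TGTG"))
    for edge in curated:
        if edge.source not in layer or edge.target not in layer:
            raise ValidationError(f"curated edge {edge.source}->{edge.target} references unknown node")
        if layer[edge.source] >= layer[edge.target]:
            raise ValidationError(
                f"curated edge {edge.source}->{edge.target} does not run downward in layer"
            )
        edges.add(edge)
    return sorted(edges, key=lambda e: (layer[e.source], e.source, e.target, e.element))


def read_curated_edges(path: str | Path) -> list[TrnEdge]:
    """Curated literature edges from a TSV (source, target, element)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    edges = []
    for line in lines:
        if not line or line.startswith("#") or line.startswith("source\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}: curated edge rows need source, target, element")
        edges.append(TrnEdge(parts[0], parts[1], parts[2], evidence="literature"))
    return edges


def read_layer_overrides(path: str | Path) -> dict[str, int]:
    """Layer pinning table: TSV of (gene_id, layer)."""
    overrides = {}
    for line in Path(path).read_text().rstrip("\n").split("\n"):
        if not line or line.startswith("#") or line.startswith("gene_id\t"):
            continue
        gene_id, layer = line.split("\t")[:2]
        overrides[gene_id] = int(layer)
    return overrides


# ---------------------------------------------------------------- export


def export_network(
    nodes: Sequence[TrnNode],
    edges: Sequence[TrnEdge],
    path: str | Path,
    fmt: str = "edgelist",
) -> list[Path]:
    """Write the network; returns the file(s) written.

    ``edgelist`` writes <path> (edges TSV) plus a sibling ``.nodes.tsv`` so a
    round-trip read reproduces isolated nodes too; ``graphml`` and ``dot``
    write a single file with layer as a node attribute (DOT additionally
    ranks each layer on one row).
    """
    path = Path(path)
    nodes = sorted(nodes, key=lambda n: (n.layer, n.gene_id))
    layer = {n.gene_id: n.layer for n in nodes}
    edges = sorted(edges, key=lambda e: (layer[e.source], e.source, e.target, e.element))
    if fmt == "edgelist":
        lines = ["source\ttarget\telement\tevidence"]
        lines += [f"{e.source}\t{e.target}\t{e.element}\t{e.evidence}" for e in edges]
        path.write_text("\n".join(lines) + "\n")
        nodes_path = path.with_suffix(".nodes.tsv")
        nlines = ["gene_id\tlayer\trole\tfamily\tortholog_tags"]
        nlines += [
            f"{n.gene_id}\t{n.layer}\t{n.role}\t{n.family}\t{';'.join(sorted(n.ortholog_tags))}"
            for n in nodes
        ]
        nodes_path.write_text("\n".join(nlines) + "\n")
        return [path, nodes_path]
    if fmt == "graphml":
        g = to_networkx(nodes, edges)
        nx.write_graphml(g, str(path))
        return [path]
    if fmt == "dot":
        path.write_text(to_dot(nodes, edges))
        return [path]
    raise ValidationError(f"unknown export format {fmt!r}")


def read_network(path: str | Path) -> tuple[list[TrnNode], list[TrnEdge]]:
    """Round-trip read of an edgelist export (edges TSV + sibling nodes TSV)."""
    path = Path(path)
    nodes_path = path.with_suffix(".nodes.tsv")
    nodes = []
    for line in nodes_path.read_text().rstrip("\n").split("\n")[1:]:
        if not line:
            continue
        gene_id, layer, role, family, tags = line.split("\t")
        nodes.append(
            TrnNode(gene_id, int(layer), role, family, frozenset(t for t in tags.split(";") if t))
        )
    edges = []
    for line in path.read_text().rstrip("\n").split("\n")[1:]:
        if not line:
            continue
        source, target, element, evidence = line.split("\t")
        edges.append(TrnEdge(source, target, element, evidence))
    return nodes, edges


def to_networkx(nodes: Sequence[TrnNode], edges: Sequence[TrnEdge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in sorted(nodes, key=lambda n: (n.layer, n.gene_id)):
        g.add_node(
            n.gene_id,
            layer=n.layer,
            role=n.role,
            family=n.family,
            ortholog_tags=";".join(sorted(n.ortholog_tags)),
        )
    for e in edges:
        g.add_edge(e.source, e.target, element=e.element, evidence=e.evidence)
    return g


def to_dot(nodes: Sequence[TrnNode], edges: Sequence[TrnEdge]) -> str:
    """DOT rendering with one rank per layer (layer 1 on top)."""
    lines = ["digraph TRN {", "  rankdir=TB;"]
    by_layer: dict[int, list[TrnNode]] = {}
    for n in sorted(nodes, key=lambda n: (n.layer, n.gene_id)):
        by_layer.setdefault(n.layer, []).append(n)
    for layer in sorted(by_layer):
        members = " ".join(f'"{escape(n.gene_id)}"' for n in by_layer[layer])
        lines.append(f"  {{ rank=same; {members} }}  // layer {layer}")
    for n in sorted(nodes, key=lambda n: (n.layer, n.gene_id)):
        lines.append(f'  "{escape(n.gene_id)}" [layer={n.layer}, role="{n.role}"];')
    layer = {n.gene_id: n.layer for n in nodes}
    for e in sorted(edges, key=lambda e: (layer[e.source], e.source, e.target, e.element)):
        style = "solid" if e.evidence == "literature" else "dashed"
        lines.append(
            f'  "{escape(e.source)}" -> "{escape(e.target)}" '
            f'[label="{e.element}", style={style}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def summarize(
    nodes: Sequence[TrnNode],
    edges: Sequence[TrnEdge],
    unplaced: Sequence[str] = (),
    element_partition: Mapping[str, int] | None = None,
) -> dict:
    """Layer/category count report; totals are internally consistent."""
    per_layer: dict[int, int] = {1: 0, 2: 0, 3: 0, 4: 0}
    per_layer_family: dict[int, dict[str, int]] = {1: {}, 2: {}, 3: {}, 4: {}}
    per_layer_role: dict[int, dict[str, int]] = {1: {}, 2: {}, 3: {}, 4: {}}
    for n in nodes:
        per_layer[n.layer] += 1
        per_layer_family[n.layer][n.family] = per_layer_family[n.layer].get(n.family, 0) + 1
        per_layer_role[n.layer][n.role] = per_layer_role[n.layer].get(n.role, 0) + 1
    per_element: dict[str, int] = {}
    for e in edges:
        per_element[e.element] = per_element.get(e.element, 0) + 1
    report = {
        "n_nodes": len(nodes),
        "n_edges": len(edges),
        "per_layer": per_layer,
        "per_layer_family": per_layer_family,
        "per_layer_role": per_layer_role,
        "edges_per_element": per_element,
        "unplaced_tfs": list(unplaced),
        "n_unplaced": len(unplaced),
        "total_input_genes": len(nodes) + len(unplaced),
    }
    if element_partition is not None:
        report["element_partition"] = dict(element_partition)
    return report
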