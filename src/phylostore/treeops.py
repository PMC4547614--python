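"""Curation operations on tree records: rerooting, OTU mapping, export.

Published tree files frequently arrive unrooted or mis-rooted, and their tip
labels rarely match any reference taxonomy, so the two central curation
moves are (1) re-choosing the root — which flips the stored source→target
orientation of every edge on the path between old and new root — and
(2) recording a mapping from each OTU's original label to a taxon record,
without ever altering the original label itself.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import UnknownTargetError
from .model import (
    META_ORIGINAL_LABEL,
    META_TAXON_ID,
    META_TAXON_NAME,
    NexsonDocument,
    NexsonVersion,
    get_meta,
    iter_otu_groups,
    iter_otus,
    iter_tree_groups,
    iter_trees,
    iter_nodes,
    iter_edges,
    natural_key,
    node_is_root,
    set_meta,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonRecord:
    """One row of a reference taxonomy (a rooted tree of taxa)."""

    taxon_id: int
    name: str
    parent_id: int | None
    rank: str = ""


@dataclass(frozen=True)
class RootTarget:
    """Where to place the root: an existing node, or a point on an edge."""

    kind: str  # "node" | "edge"
    target_id: str
    edge_fraction: float = 0.5

    def __post_init__(self):
        if self.kind not in ("node", "edge"):
            raise ValueError(f"kind must be 'node' or 'edge', got {self.kind!r}")
        if not 0.0 <= self.edge_fraction <= 1.0:
            raise ValueError("edge_fraction must lie in [0, 1]")


@dataclass
class OtuRecord:
    otu_id: str
    original_label: str | None = None
    mapped_taxon_id: int | None = None
    mapped_taxon_name: str | None = None


@dataclass
class NodeRecord:
    node_id: str
    otu_ref: str | None = None
    is_root: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class EdgeRecord:
    edge_id: str
    source: str
    target: str
    length: float | int | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class TreeRecord:
    """A rooted tree as an arborescence: edges stored source→target."""

    tree_id: str
    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: dict[str, EdgeRecord] = field(default_factory=dict)
    root_node_id: str | None = None
    extra: dict = field(default_factory=dict)

    # -- structure helpers ---------------------------------------------------

    def children(self) -> dict[str, list[EdgeRecord]]:
        out: dict[str, list[EdgeRecord]] = {n: [] for n in self.nodes}
        for edge in self.edges.values():
            out[edge.source].append(edge)
        for edges in out.values():
            edges.sort(key=lambda e: natural_key(e.target))
        return out

    def undirected_edge_multiset(self) -> list[tuple]:
        """Orientation-free view: sorted (endpoint-pair, length) entries."""
        return sorted(
            (tuple(sorted((e.source, e.target))), e.length)
            for e in self.edges.values()
        )

    def tip_ids(self) -> list[str]:
        child_map = self.children()
        return sorted((n for n in self.nodes if not child_map[n]), key=natural_key)

    # -- NexSON round trip ---------------------------------------------------

    @classmethod
    def from_nexson(cls, tree_id: str, tree_obj: dict,
                    version: NexsonVersion) -> "TreeRecord":
        record = cls(tree_id=tree_id)
        for node_id, node in iter_nodes(tree_obj, version):
            extra = {k: v for k, v in node.items()
                     if k not in ("@id", "@otu", "@root")}
            record.nodes[node_id] = NodeRecord(
                node_id=node_id, otu_ref=node.get("@otu"),
                is_root=node_is_root(node), extra=copy.deepcopy(extra))
        for edge_id, edge in iter_edges(tree_obj, version):
            extra = {k: v for k, v in edge.items()
                     if k not in ("@id", "@source", "@target", "@length")}
            record.edges[edge_id] = EdgeRecord(
                edge_id=edge_id, source=edge.get("@source"),
                target=edge.get("@target"), length=edge.get("@length"),
                extra=copy.deepcopy(extra))
        record.root_node_id = next(
            (n.node_id for n in record.nodes.values() if n.is_root), None)
        keyed = ("nodeById", "edgeById") if version.is_keyed else ("node", "edge")
        record.extra = copy.deepcopy(
            {k: v for k, v in tree_obj.items() if k not in keyed})
        return record

    def write_into(self, tree_obj: dict, version: NexsonVersion) -> None:
        """Replace the node/edge structure of a NexSON tree object in place."""
        node_objs: dict[str, dict] = {}
        for node_id in sorted(self.nodes, key=natural_key):
            node = self.nodes[node_id]
            obj: dict = {}
            if node.otu_ref is not None:
                obj["@otu"] = node.otu_ref
            if node.is_root:
                obj["@root"] = True
            obj.update(copy.deepcopy(node.extra))
            node_objs[node_id] = obj
        edge_objs: dict[str, dict] = {}
        for edge_id in sorted(self.edges, key=natural_key):
            edge = self.edges[edge_id]
            obj = {"@source": edge.source, "@target": edge.target}
            if edge.length is not None:
                obj["@length"] = edge.length
            obj.update(copy.deepcopy(edge.extra))
            edge_objs[edge_id] = obj
        if version.is_keyed:
            tree_obj["nodeById"] = node_objs
            tree_obj["edgeById"] = edge_objs
            tree_obj.pop("node", None)
            tree_obj.pop("edge", None)
        else:
            tree_obj["node"] = [{"@id": i, **o} for i, o in node_objs.items()]
            tree_obj["edge"] = [{"@id": i, **o} for i, o in edge_objs.items()]
            tree_obj.pop("nodeById", None)
            tree_obj.pop("edgeById", None)


# ---------------------------------------------------------------------------
# document-level accessors
# ---------------------------------------------------------------------------


def otus_from_doc(doc: NexsonDocument) -> dict[str, OtuRecord]:
    """All OTU records in the document, keyed by otu id."""
    version = doc.syntax_version
    out: dict[str, OtuRecord] = {}
    for _, group in iter_otu_groups(doc.nexml, version):
        for otu_id, otu in iter_otus(group, version):
            out[otu_id] = OtuRecord(
                otu_id=otu_id,
                original_label=get_meta(otu, version, META_ORIGINAL_LABEL),
                mapped_taxon_id=get_meta(otu, version, META_TAXON_ID),
                mapped_taxon_name=get_meta(otu, version, META_TAXON_NAME),
            )
    return out


def tree_records(doc: NexsonDocument) -> dict[str, TreeRecord]:
    version = doc.syntax_version
    out: dict[str, TreeRecord] = {}
    for _, group in iter_tree_groups(doc.nexml, version):
        for tree_id, tree in iter_trees(group, version):
            out[tree_id] = TreeRecord.from_nexson(tree_id, tree, version)
    return out


def get_tree(doc: NexsonDocument, tree_id: str) -> TreeRecord:
    record = tree_records(doc).get(tree_id)
    if record is None:
        raise UnknownTargetError(f"no tree {tree_id!r} in document")
    return record


def replace_tree(doc: NexsonDocument, record: TreeRecord) -> NexsonDocument:
    """Write an edited tree record back into its document (in place)."""
    version = doc.syntax_version
    for _, group in iter_tree_groups(doc.nexml, version):
        for tree_id, tree in iter_trees(group, version):
            if tree_id == record.tree_id:
                record.write_into(tree, version)
                return doc
    raise UnknownTargetError(f"no tree {record.tree_id!r} in document")


# ---------------------------------------------------------------------------
# rerooting
# ---------------------------------------------------------------------------


def _fresh_id(base: str, taken) -> str:
    if base not in taken:
        return base
    k = 2
    while f"{base}{k}" in taken:
        k += 1
    return f"{base}{k}"


def reroot_tree(tree: TreeRecord, target: RootTarget) -> TreeRecord:
    """Return a copy of *tree* rerooted at *target*.

    The undirected edge multiset is preserved (up to merging the two edges
    of a former degree-2 root, whose lengths are summed) and exactly the
    edges on the old-root→new-root path reverse their source→target
    orientation.  Rerooting onto an edge subdivides it at ``edge_fraction``
    (measured from the stored source), splitting its length proportionally.
    """
    tree = copy.deepcopy(tree)
    old_root = tree.root_node_id

    if target.kind == "node":
        if target.target_id not in tree.nodes:
            raise UnknownTargetError(f"no node {target.target_id!r} in tree "
                                     f"{tree.tree_id!r}")
        if target.target_id == old_root:
            return tree
        if tree.nodes[target.target_id].otu_ref is not None:
            # A tip cannot become the root (its OTU would sit on an internal
            # node); root on the tip's edge instead.
            raise UnknownTargetError(
                f"node {target.target_id!r} is a tip; reroot on its edge")
        new_root = target.target_id
    else:
        edge = tree.edges.get(target.target_id)
        if edge is None:
            raise UnknownTargetError(f"no edge {target.target_id!r} in tree "
                                     f"{tree.tree_id!r}")
        new_root = _fresh_id(f"{tree.tree_id}_root", tree.nodes)
        tree.nodes[new_root] = NodeRecord(node_id=new_root)
        frac = target.edge_fraction
        length_a = length_b = None
        if edge.length is not None:
            length_a = edge.length * frac
            length_b = edge.length * (1.0 - frac)
        del tree.edges[edge.edge_id]
        id_a = _fresh_id(f"{edge.edge_id}a", tree.edges)
        tree.edges[id_a] = EdgeRecord(id_a, edge.source, new_root, length_a)
        id_b = _fresh_id(f"{edge.edge_id}b", tree.edges)
        tree.edges[id_b] = EdgeRecord(id_b, new_root, edge.target, length_b)

    # Re-orient every edge away from the new root (breadth-first sweep).
    adjacency: dict[str, list[str]] = {n: [] for n in tree.nodes}
    for edge in tree.edges.values():
        adjacency[edge.source].append(edge.edge_id)
        adjacency[edge.target].append(edge.edge_id)
    seen = {new_root}
    queue = [new_root]
    while queue:
        node = queue.pop(0)
        for edge_id in sorted(adjacency[node], key=natural_key):
            edge = tree.edges[edge_id]
            other = edge.target if edge.source == node else edge.source
            if other in seen:
                continue
            if edge.source != node:
                edge.source, edge.target = node, other
            seen.add(other)
            queue.append(other)

    # A former root left with degree 2 is an artifact of rooting, not a
    # real vertex: suppress it and merge its two incident edges.
    if old_root is not None and old_root != new_root and \
            len(adjacency[old_root]) == 2 and tree.nodes[old_root].otu_ref is None:
        in_edge = next(e for e in tree.edges.values() if e.target == old_root)
        out_edge = next(e for e in tree.edges.values() if e.source == old_root)
        keep, drop = sorted((in_edge, out_edge),
                            key=lambda e: natural_key(e.edge_id))
        lengths = [e.length for e in (in_edge, out_edge) if e.length is not None]
        keep.source = in_edge.source
        keep.target = out_edge.target
        keep.length = sum(lengths) if lengths else None
        del tree.edges[drop.edge_id]
        del tree.nodes[old_root]

    for node in tree.nodes.values():
        node.is_root = node.node_id == new_root
    tree.root_node_id = new_root
    return tree


# ---------------------------------------------------------------------------
# OTU mapping
# ---------------------------------------------------------------------------


def map_otu(doc: NexsonDocument, otu_id: str,
            taxon: TaxonRecord | None) -> NexsonDocument:
    """Record (or, with ``taxon=None``, clear) a taxonomy mapping for an OTU.

    Only the mapped-taxon fields change; the original label is immutable and
    is never touched by any curation operation.  Mutates and returns *doc*.
    """
    version = doc.syntax_version
    for _, group in iter_otu_groups(doc.nexml, version):
        for oid, otu in iter_otus(group, version):
            if oid == otu_id:
                if taxon is None:
                    set_meta(otu, version, META_TAXON_ID, None)
                    set_meta(otu, version, META_TAXON_NAME, None)
                else:
                    set_meta(otu, version, META_TAXON_ID, taxon.taxon_id)
                    set_meta(otu, version, META_TAXON_NAME, taxon.name)
                return doc
    raise UnknownTargetError(f"no otu {otu_id!r} in document")


# ---------------------------------------------------------------------------
# Newick / NEXUS export
# ---------------------------------------------------------------------------

_UNQUOTED_LABEL = re.compile(r"[A-Za-z0-9.|+-]+\Z")


def quote_newick_label(label: str) -> str:
    """Quote a label for Newick/NEXUS unless it is plainly safe.

    Anything outside alphanumerics and ``. | + -`` (including underscores,
    which unquoted Newick readers fold to spaces) is single-quoted, with
    internal quotes doubled.
    """
    if label and _UNQUOTED_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(length: float | int) -> str:
    if isinstance(length, int):
        return str(length)
    return repr(length)


def _newick(tree: TreeRecord, label_of: Callable[[NodeRecord], str | None]) -> str:
    child_map = tree.children()

    def render(node_id: str) -> str:
        edges = child_map[node_id]
        node = tree.nodes[node_id]
        if not edges:
            label = label_of(node)
            return quote_newick_label(label) if label is not None else ""
        parts = []
        for edge in edges:
            sub = render(edge.target)
            if edge.length is not None:
                sub += ":" + _format_length(edge.length)
            parts.append(sub)
        label = label_of(node)
        suffix = quote_newick_label(label) if label is not None else ""
        return "(" + ",".join(parts) + ")" + suffix

    if tree.root_node_id is None:
        raise UnknownTargetError(f"tree {tree.tree_id!r} has no root")
    return render(tree.root_node_id) + ";"


def _label_resolver(otus: Mapping[str, OtuRecord],
                    label_mode: str) -> Callable[[NodeRecord], str | None]:
    def resolve(node: NodeRecord) -> str | None:
        if node.otu_ref is None:
            return None  # internal nodes are emitted unlabeled
        otu = otus.get(node.otu_ref)
        if otu is None:
            return node.otu_ref
        if label_mode == "otu_id":
            return otu.otu_id
        original = otu.original_label if otu.original_label is not None else otu.otu_id
        if label_mode == "original":
            return original
        if label_mode == "mapped_name":
            if otu.mapped_taxon_name is None:
                log.warning("otu %s is unmapped; falling back to its original label",
                            otu.otu_id)
                return original
            return otu.mapped_taxon_name
        if label_mode == "mapped_id":
            if otu.mapped_taxon_id is None:
                log.warning("otu %s is unmapped; falling back to its original label",
                            otu.otu_id)
                return original
            return str(otu.mapped_taxon_id)
        raise ValueError(f"unknown label mode {label_mode!r}")

    return resolve


def export_newick(tree: TreeRecord, otus: Mapping[str, OtuRecord],
                  label_mode: str = "original") -> str:
    """Render a tree as a rooted Newick string (';'-terminated).

    Sibling order follows natural id order so exports are byte-stable.
    ``label_mode`` selects original labels, mapped taxon names/ids, or raw
    otu ids; mapped modes fall back to the original label (with a logged
    warning) for unmapped OTUs.
    """
    return _newick(tree, _label_resolver(otus, label_mode))


def export_nexus(doc: NexsonDocument, label_mode: str = "original") -> str:
    """Render every tree in the document as a NEXUS file.

    One TAXA block covers all OTUs in the document; the TREES block carries
    a TRANSLATE table mapping 1-based indices to labels, and one rooted TREE
    statement per tree, identical to :func:`export_newick` output modulo
    translation.
    """
    otus = otus_from_doc(doc)
    resolve = _label_resolver(otus, label_mode)
    otu_order = sorted(otus, key=natural_key)
    labels = {}
    for otu_id in otu_order:
        labels[otu_id] = resolve(NodeRecord(node_id="", otu_ref=otu_id))
    index_of = {otu_id: i + 1 for i, otu_id in enumerate(otu_order)}

    lines = ["#NEXUS", "", "BEGIN TAXA;",
             f" DIMENSIONS NTAX={len(otu_order)};", " TAXLABELS"]
    for otu_id in otu_order:
        lines.append("  " + quote_newick_label(labels[otu_id]))
    lines += [" ;", "END;", "", "BEGIN TREES;", " TRANSLATE"]
    translate = [f"  {index_of[o]} {quote_newick_label(labels[o])}"
                 for o in otu_order]
    lines.append(",\n".join(translate))
    lines.append(" ;")

    def translated(node: NodeRecord) -> str | None:
        if node.otu_ref is None:
            return None
        return str(index_of[node.otu_ref]) if node.otu_ref in index_of else node.otu_ref

    for tree_id, record in sorted(tree_records(doc).items(),
                                  key=lambda kv: natural_key(kv[0])):
        newick = _newick(record, translated)
        lines.append(f" TREE {tree_id} = [&R] {newick}")
    lines += ["END;", ""]
    return "\n".join(lines)
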