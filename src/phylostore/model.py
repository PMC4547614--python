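"""NexSON document model: syntax versions, structural access, validation.

A NexSON document is the JSON serialization of the NeXML data model used for
curated phylogenetic studies.  Three syntax versions coexist:

* ``0.0`` — a direct badgerfish conversion of NeXML.  XML attributes carry an
  ``@`` prefix, element text maps to ``$``, and ``meta`` annotation elements
  sit in arrays under the ``meta`` property.
* ``1.0`` — badgerfish plus *meta promotion*: each literal/resource ``meta``
  child becomes a single ``^property`` key on its parent, which keeps files
  smaller and property lookup O(1).
* ``1.2`` — additionally re-houses OTUs, trees, nodes and edges in objects
  keyed by entity id (``otusById``, ``otuById``, ``treesById``, ``treeById``,
  ``nodeById``, ``edgeById``), which makes lookup fast and lets the
  serializer order entities deterministically.

The in-memory representation is deliberately the parsed JSON tree itself,
wrapped by :class:`NexsonDocument`; unknown keys therefore round-trip
opaquely.  This module knows how to *read* any of the three versions
(version-agnostic accessors) and how to *validate* the structural and
referential invariants; interconversion lives in :mod:`phylostore.convert`.
"""

from __future__ import annotations

import copy
import enum
import json
import re
from dataclasses import dataclass, field
from typing import Any, Iterator

from .errors import ParseError, UnsupportedVersionError

# Property on the root "nexml" object that declares the syntax version.
VERSION_PROPERTY = "@nexml2json"

# Element names that may repeat and are therefore always list-housed in the
# badgerfish (0.0/1.0) representations.  Singleton objects are accepted on
# read for tolerance of hand-written input.
REPEATABLE_ELEMENTS = frozenset(
    {"meta", "otus", "otu", "trees", "tree", "node", "edge"}
)

# Local meta-property conventions used by the curation operations.  The
# original tip label and the taxonomy mapping follow the ot: vocabulary;
# rooting confirmation and ingroup designation are local conventions
# documented in docs/methods.md.
META_ORIGINAL_LABEL = "ot:originalLabel"
META_TAXON_ID = "ot:ottId"
META_TAXON_NAME = "ot:ottTaxonName"
META_ROOTING_CONFIRMED = "ot:rootingConfirmed"
META_INGROUP_CLADE = "ot:inGroupClade"


class NexsonVersion(enum.Enum):
    """The three NexSON syntax families, identified by major.minor."""

    V0_0 = "0.0"
    V1_0 = "1.0"
    V1_2 = "1.2"

    @classmethod
    def from_tag(cls, tag: object) -> "NexsonVersion":
        """Map a ``nexml2json`` property value to a version family.

        A patch component ("1.2.1") is ignored; only major.minor matters.
        """
        if not isinstance(tag, str):
            raise UnsupportedVersionError(tag)
        majmin = ".".join(tag.split(".")[:2])
        for member in cls:
            if member.value == majmin:
                return member
        raise UnsupportedVersionError(tag)

    @property
    def is_keyed(self) -> bool:
        return self is NexsonVersion.V1_2

    @property
    def has_caret_meta(self) -> bool:
        return self is not NexsonVersion.V0_0


def detect_version(raw_document: dict) -> NexsonVersion:
    """Return the syntax version declared by a parsed NexSON JSON tree.

    The marker is the ``nexml2json`` property on the root ``nexml`` object
    (also accepted un-prefixed at top level for tolerance).  Documents
    predating the marker are direct badgerfish conversions, so a missing
    property means version 0.0.
    """
    if not isinstance(raw_document, dict):
        raise ParseError("NexSON document must be a JSON object")
    nexml = raw_document.get("nexml")
    tag = None
    if isinstance(nexml, dict):
        tag = nexml.get(VERSION_PROPERTY, nexml.get("nexml2json"))
    if tag is None:
        tag = raw_document.get("nexml2json")
    if tag is None:
        return NexsonVersion.V0_0
    return NexsonVersion.from_tag(tag)


def natural_key(identifier: str) -> tuple:
    """Sort key that orders embedded integers numerically ("node9" < "node10")."""
    parts = re.split(r"(\d+)", identifier)
    # Type-tagged so int and str chunks never compare directly.
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts)


def as_list(value: Any) -> list:
    """Badgerfish tolerance: coerce a possibly-singleton child into a list."""
    if value is None:
        return []
    if isinstance(value, list):
        return value
    return [value]


# ---------------------------------------------------------------------------
# Version-agnostic entity access
# ---------------------------------------------------------------------------
# Each iterator yields (entity_id, entity_object) pairs regardless of whether
# the entities are list-housed (0.0/1.0, id in "@id") or keyed (1.2, id is the
# container key and the object carries no "@id").


def _iter_housed(parent: dict, element: str, version: NexsonVersion) -> Iterator[tuple[str, dict]]:
    if version.is_keyed:
        container = parent.get(element + "ById")
        if isinstance(container, dict):
            for key in sorted(container, key=natural_key):
                yield key, container[key]
    else:
        for obj in as_list(parent.get(element)):
            if isinstance(obj, dict):
                yield obj.get("@id"), obj


def iter_otu_groups(nexml: dict, version: NexsonVersion) -> Iterator[tuple[str, dict]]:
    return _iter_housed(nexml, "otus", version)


def iter_otus(group: dict, version: NexsonVersion) -> Iterator[tuple[str, dict]]:
    return _iter_housed(group, "otu", version)


def iter_tree_groups(nexml: dict, version: NexsonVersion) -> Iterator[tuple[str, dict]]:
    return _iter_housed(nexml, "trees", version)


def iter_trees(group: dict, version: NexsonVersion) -> Iterator[tuple[str, dict]]:
    return _iter_housed(group, "tree", version)


def iter_nodes(tree: dict, version: NexsonVersion) -> Iterator[tuple[str, dict]]:
    return _iter_housed(tree, "node", version)


def iter_edges(tree: dict, version: NexsonVersion) -> Iterator[tuple[str, dict]]:
    return _iter_housed(tree, "edge", version)


def iter_meta(obj: dict, version: NexsonVersion) -> Iterator[tuple[str, Any]]:
    """Yield (property-name, value) pairs for every meta annotation on *obj*.

    Values are normalized: a scalar for literal meta, a dict containing
    ``@href`` for resource meta.  Property names are yielded without the
    caret prefix.
    """
    if version.has_caret_meta:
        for key, value in obj.items():
            if not key.startswith("^"):
                continue
            prop = key[1:]
            for v in value if isinstance(value, list) else [value]:
                yield prop, v
    else:
        for m in as_list(obj.get("meta")):
            if not isinstance(m, dict):
                continue
            prop = m.get("@property") or m.get("@rel")
            if "@href" in m:
                yield prop, {"@href": m["@href"]}
            else:
                yield prop, m.get("$")


def get_meta(obj: dict, version: NexsonVersion, prop: str, default: Any = None) -> Any:
    for p, v in iter_meta(obj, version):
        if p == prop:
            return v
    return default


def set_meta(obj: dict, version: NexsonVersion, prop: str, value: Any) -> None:
    """Set, replace or (``value=None``) remove a meta annotation on *obj*."""
    if version.has_caret_meta:
        key = "^" + prop
        if value is None:
            obj.pop(key, None)
        else:
            obj[key] = value
        return
    metas = [m for m in as_list(obj.get("meta"))
             if (m.get("@property") or m.get("@rel")) != prop]
    if value is not None:
        if isinstance(value, dict) and "@href" in value:
            entry = {"@rel": prop, "@xsi:type": "nex:ResourceMeta", "@href": value["@href"]}
        else:
            entry = {"@property": prop, "@xsi:type": "nex:LiteralMeta", "$": value}
        metas.append(entry)
    if metas:
        obj["meta"] = metas
    else:
        obj.pop("meta", None)


def node_is_root(node: dict) -> bool:
    root = node.get("@root")
    return root is True or root == "true"


def find_root_node_id(tree: dict, version: NexsonVersion) -> str | None:
    for node_id, node in iter_nodes(tree, version):
        if node_is_root(node):
            return node_id
    return None


# ---------------------------------------------------------------------------
# Document wrapper
# ---------------------------------------------------------------------------


class NexsonDocument:
    """A NexSON study document: a thin wrapper over the parsed JSON tree.

    All structure, including keys this library does not recognize, lives in
    ``self.data`` and survives serialization untouched.
    """

    __slots__ = ("data",)

    def __init__(self, data: dict):
        if not isinstance(data, dict) or not isinstance(data.get("nexml"), dict):
            raise ParseError("NexSON document must be an object with a 'nexml' child")
        self.data = data

    # -- construction -------------------------------------------------------

    @classmethod
    def loads(cls, text: str) -> "NexsonDocument":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(str(exc.msg), line=exc.lineno, column=exc.colno) from exc
        return cls(data)

    @classmethod
    def load_path(cls, path) -> "NexsonDocument":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.loads(handle.read())

    # -- basic properties ----------------------------------------------------

    @property
    def nexml(self) -> dict:
        return self.data["nexml"]

    @property
    def syntax_version(self) -> NexsonVersion:
        return detect_version(self.data)

    def copy(self) -> "NexsonDocument":
        return NexsonDocument(copy.deepcopy(self.data))

    def dumps(self, pretty: bool = False) -> str:
        if pretty:
            return json.dumps(self.data, indent=1, ensure_ascii=False) + "\n"
        return json.dumps(self.data, ensure_ascii=False, separators=(",", ":"))

    # -- convenience ---------------------------------------------------------

    def study_meta(self) -> dict[str, Any]:
        """All study-level meta annotations as a property → value(s) map."""
        out: dict[str, Any] = {}
        for prop, value in iter_meta(self.nexml, self.syntax_version):
            if prop in out:
                prior = out[prop]
                out[prop] = (prior if isinstance(prior, list) else [prior]) + [value]
            else:
                out[prop] = value
        return out

    def validate(self) -> "ValidationReport":
        return validate_document(self)

    def model_equal(self, other: "NexsonDocument") -> bool:
        from .convert import model_equal

        return model_equal(self, other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n_otus = sum(1 for g in iter_otu_groups(self.nexml, self.syntax_version)
                     for _ in iter_otus(g[1], self.syntax_version))
        return f"<NexsonDocument v{self.syntax_version.value} otus={n_otus}>"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


class ErrorCode(enum.Enum):
    """Closed enumeration of validation error codes.

    Tests and callers assert on these codes, never on message text.
    """

    DUPLICATE_ID = "duplicate-id"
    DANGLING_OTU_REF = "dangling-otu-ref"
    DANGLING_NODE_REF = "dangling-node-ref"
    NOT_ARBORESCENT = "not-arborescent"
    BAD_ROOT = "bad-root"
    BAD_EDGE = "bad-edge"
    BAD_LENGTH = "bad-length"
    OTU_REF_ON_INTERNAL = "otu-ref-on-internal"
    MALFORMED_META = "malformed-meta"
    BAD_STRUCTURE = "bad-structure"
    MISSING_ID = "missing-id"


@dataclass(frozen=True)
class ValidationError:
    code: ErrorCode
    entity_id: str | None
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationError] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def codes(self) -> set[ErrorCode]:
        return {e.code for e in self.errors}

    def add(self, code: ErrorCode, entity_id: str | None, message: str) -> None:
        self.errors.append(ValidationError(code, entity_id, message))


def _check_meta(obj: dict, version: NexsonVersion, owner: str | None,
                report: ValidationReport) -> None:
    if version.has_caret_meta:
        for key, value in obj.items():
            if not key.startswith("^"):
                continue
            if len(key) < 2:
                report.add(ErrorCode.MALFORMED_META, owner, "empty meta property name")
            values = value if isinstance(value, list) else [value]
            for v in values:
                if isinstance(v, dict) and "@href" not in v and "$" not in v:
                    report.add(ErrorCode.MALFORMED_META, owner,
                               f"meta {key!r} is an object with neither @href nor $")
    else:
        for m in as_list(obj.get("meta")):
            if not isinstance(m, dict):
                report.add(ErrorCode.MALFORMED_META, owner, "meta entry is not an object")
                continue
            prop = m.get("@property") or m.get("@rel")
            if not prop:
                report.add(ErrorCode.MALFORMED_META, owner,
                           "meta element lacks a property/rel name")
            if "@href" in m and "$" in m:
                report.add(ErrorCode.MALFORMED_META, owner,
                           f"meta {prop!r} has both @href and literal content")


def _register_id(ids: dict[str, set], namespace: str, entity_id: str | None,
                 report: ValidationReport) -> None:
    if entity_id is None:
        report.add(ErrorCode.MISSING_ID, None, f"{namespace} entity lacks an id")
        return
    seen = ids.setdefault(namespace, set())
    if entity_id in seen:
        report.add(ErrorCode.DUPLICATE_ID, entity_id,
                   f"duplicate {namespace} id {entity_id!r}")
    seen.add(entity_id)


def _validate_tree(tree_id: str, tree: dict, version: NexsonVersion,
                   otu_ids: set, ids: dict[str, set], report: ValidationReport) -> None:
    node_ids: list[str] = []
    roots: list[str] = []
    for node_id, node in iter_nodes(tree, version):
        _register_id(ids, "node", node_id, report)
        if node_id is None:
            continue
        node_ids.append(node_id)
        if node_is_root(node):
            roots.append(node_id)
        _check_meta(node, version, node_id, report)
        otu_ref = node.get("@otu")
        if otu_ref is not None and otu_ref not in otu_ids:
            report.add(ErrorCode.DANGLING_OTU_REF, node_id,
                       f"node {node_id!r} references unknown otu {otu_ref!r}")
    node_set = set(node_ids)

    out_edges: dict[str, list[str]] = {n: [] for n in node_set}
    in_degree: dict[str, int] = {n: 0 for n in node_set}
    for edge_id, edge in iter_edges(tree, version):
        _register_id(ids, "edge", edge_id, report)
        _check_meta(edge, version, edge_id, report)
        source = edge.get("@source")
        target = edge.get("@target")
        ok = True
        for endpoint in (source, target):
            if endpoint not in node_set:
                report.add(ErrorCode.DANGLING_NODE_REF, edge_id,
                           f"edge {edge_id!r} endpoint {endpoint!r} is not a node "
                           f"of tree {tree_id!r}")
                ok = False
        if ok and source == target:
            report.add(ErrorCode.BAD_EDGE, edge_id,
                       f"edge {edge_id!r} is a self-loop on {source!r}")
            ok = False
        length = edge.get("@length")
        if length is not None:
            if not isinstance(length, (int, float)) or isinstance(length, bool):
                report.add(ErrorCode.BAD_LENGTH, edge_id,
                           f"edge {edge_id!r} length {length!r} is not a number")
            elif length < 0:
                report.add(ErrorCode.BAD_LENGTH, edge_id,
                           f"edge {edge_id!r} length {length!r} is negative")
        if ok:
            out_edges[source].append(target)
            in_degree[target] += 1

    # OTU refs belong on tips only.
    for node_id, node in iter_nodes(tree, version):
        if node_id in node_set and node.get("@otu") is not None and out_edges.get(node_id):
            report.add(ErrorCode.OTU_REF_ON_INTERNAL, node_id,
                       f"node {node_id!r} has an otu mapping but is not a tip")

    if not node_set:
        return
    if len(roots) != 1:
        report.add(ErrorCode.BAD_ROOT, tree_id,
                   f"tree {tree_id!r} flags {len(roots)} root nodes (want exactly 1)")
        return
    root = roots[0]
    arborescent = True
    if in_degree.get(root, 0) != 0:
        report.add(ErrorCode.NOT_ARBORESCENT, tree_id,
                   f"root {root!r} of tree {tree_id!r} has an in-edge")
        arborescent = False
    for node_id in node_set:
        if node_id != root and in_degree.get(node_id, 0) != 1:
            report.add(ErrorCode.NOT_ARBORESCENT, node_id,
                       f"node {node_id!r} has in-degree {in_degree.get(node_id, 0)}"
                       " (want 1)")
            arborescent = False
    # Reachability: every node must sit below the root.
    seen = {root}
    stack = [root]
    while stack:
        for child in out_edges.get(stack.pop(), []):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    if arborescent and seen != node_set:
        missing = sorted(node_set - seen, key=natural_key)
        report.add(ErrorCode.NOT_ARBORESCENT, tree_id,
                   f"nodes unreachable from root in tree {tree_id!r}: {missing[:5]}")


def validate_document(doc: NexsonDocument) -> ValidationReport:
    """Check every structural and referential invariant of the document.

    Validation is pure — the document is never mutated, and validating twice
    yields identical reports.  Problems are reported, not raised.
    """
    report = ValidationReport()
    try:
        version = doc.syntax_version
    except UnsupportedVersionError as exc:
        report.add(ErrorCode.BAD_STRUCTURE, None, str(exc))
        return report
    nexml = doc.nexml
    _check_meta(nexml, version, None, report)

    ids: dict[str, set] = {}
    otu_ids: set[str] = set()
    for group_id, group in iter_otu_groups(nexml, version):
        _register_id(ids, "otu-group", group_id, report)
        _check_meta(group, version, group_id, report)
        for otu_id, otu in iter_otus(group, version):
            _register_id(ids, "otu", otu_id, report)
            _check_meta(otu, version, otu_id, report)
            if otu_id is not None:
                otu_ids.add(otu_id)

    otu_group_ids = ids.get("otu-group", set())
    for group_id, group in iter_tree_groups(nexml, version):
        _register_id(ids, "tree-group", group_id, report)
        _check_meta(group, version, group_id, report)
        otus_ref = group.get("@otus")
        if otus_ref is not None and otus_ref not in otu_group_ids:
            report.add(ErrorCode.DANGLING_OTU_REF, group_id,
                       f"tree group {group_id!r} references unknown otu group "
                       f"{otus_ref!r}")
        for tree_id, tree in iter_trees(group, version):
            _register_id(ids, "tree", tree_id, report)
            _check_meta(tree, version, tree_id, report)
            _validate_tree(tree_id, tree, version, otu_ids, ids, report)
    return report
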