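"""Lossless interconversion among NeXML XML and NexSON 0.0 / 1.0 / 1.2.

The three JSON syntaxes carry identical information and differ only in
housing:

* meta annotations live in badgerfish ``meta`` arrays (0.0) or as
  caret-prefixed properties (1.0, 1.2);
* entity collections are arrays of objects carrying ``@id`` (0.0, 1.0) or
  objects keyed by entity id (1.2).

Conversion routes every pair through the 1.0 form as a hub, so any path
between two versions yields the same result.  ``measure_payload_reduction``
quantifies the byte savings of the terse 1.2 housing over the naive
badgerfish form, serialized under an identical whitespace policy.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import Any

from lxml import etree

from .errors import ConversionError, InvalidDocumentError, ParseError
from .model import (
    VERSION_PROPERTY,
    NexsonDocument,
    NexsonVersion,
    REPEATABLE_ELEMENTS,
    as_list,
    natural_key,
)

log = logging.getLogger(__name__)

# Prefix → URI map used when a document does not carry its own declarations.
DEFAULT_NAMESPACES = {
    "$": "http://www.nexml.org/2009",
    "nex": "http://www.nexml.org/2009",
    "xsi": "http://www.w3.org/2001/XMLSchema-instance",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "ot": "http://purl.org/opentree/nexson",
}

# Entity elements that can carry meta and house further entities.
_CHILD_ELEMENTS = {
    "nexml": ("otus", "trees"),
    "otus": ("otu",),
    "otu": (),
    "trees": ("tree",),
    "tree": ("node", "edge"),
    "node": (),
    "edge": (),
}

_INT_RE = re.compile(r"-?\d+$")


@dataclass
class ConversionOptions:
    """Options for NeXML → NexSON ingestion."""

    target_version: NexsonVersion = NexsonVersion.V1_2
    pretty: bool = False


# ---------------------------------------------------------------------------
# meta promotion / demotion (0.0 <-> 1.0)
# ---------------------------------------------------------------------------


def _meta_sort_key(meta: dict) -> tuple:
    prop = meta.get("@property") or meta.get("@rel") or ""
    return (prop, json.dumps(meta, sort_keys=True, ensure_ascii=False))


# Per-annotation XML plumbing that the caret syntaxes shed: the meta
# element's own id, its xsi:type discriminator and the XSD datatype tag are
# all derivable (ids are re-mintable, the type lives in the JSON value), so
# promotion drops them and demotion regenerates them deterministically.
_META_PLUMBING = ("@id", "@xsi:type", "@datatype")


def _promote_meta(obj: dict, element: str) -> None:
    """badgerfish ``meta`` array → ``^property`` keys, in place."""
    metas = as_list(obj.pop("meta", None))
    grouped: dict[str, list] = {}
    for m in sorted((m for m in metas if isinstance(m, dict)), key=_meta_sort_key):
        prop = m.get("@property") or m.get("@rel")
        if prop is None:
            # Malformed meta is preserved so validation can report it.
            obj.setdefault("meta", []).append(m)
            continue
        extras = {k: v for k, v in m.items()
                  if k not in ("@property", "@rel", "$") and k not in _META_PLUMBING}
        if "@href" in m:
            value: Any = {"@href": m["@href"],
                          **{k: v for k, v in extras.items() if k != "@href"}}
        elif extras:
            value = {"$": m.get("$"), **extras}
        else:
            value = m.get("$")
        grouped.setdefault(prop, []).append(value)
    for prop, values in grouped.items():
        obj["^" + prop] = values[0] if len(values) == 1 else values
    for child in _CHILD_ELEMENTS[element]:
        for sub in as_list(obj.get(child)):
            if isinstance(sub, dict):
                _promote_meta(sub, child)


def _xsd_datatype(value: Any) -> str | None:
    if isinstance(value, bool):
        return "xsd:boolean"
    if isinstance(value, int):
        return "xsd:integer"
    if isinstance(value, float):
        return "xsd:double"
    return None


def _demote_meta(obj: dict, element: str, counter: list[int]) -> None:
    """``^property`` keys → badgerfish ``meta`` array, in place.

    Each meta element is given a fresh sequential id and, for typed literal
    values, an XSD datatype tag — the full direct image of the NeXML
    annotation element.
    """
    carets = sorted(k for k in obj if k.startswith("^"))
    metas = as_list(obj.get("meta"))
    fresh: list[dict] = []
    for key in carets:
        prop = key[1:]
        values = obj.pop(key)
        for v in values if isinstance(values, list) else [values]:
            if isinstance(v, dict) and "@href" in v:
                entry = {"@rel": prop, "@xsi:type": "nex:ResourceMeta"}
                entry.update(v)
            elif isinstance(v, dict):
                entry = {"@property": prop, "@xsi:type": "nex:LiteralMeta"}
                entry.update(v)
            else:
                entry = {"@property": prop, "@xsi:type": "nex:LiteralMeta", "$": v}
            datatype = _xsd_datatype(entry.get("$"))
            if datatype and "@datatype" not in entry:
                entry["@datatype"] = datatype
            fresh.append(entry)
    for entry in sorted(fresh, key=_meta_sort_key):
        if "@id" not in entry:
            counter[0] += 1
            entry["@id"] = f"meta{counter[0]}"
        metas.append(entry)
    if metas:
        obj["meta"] = sorted(metas, key=_meta_sort_key)
    for child in _CHILD_ELEMENTS[element]:
        for sub in as_list(obj.get(child)):
            if isinstance(sub, dict):
                _demote_meta(sub, child, counter)


# ---------------------------------------------------------------------------
# keyed housing (1.0 <-> 1.2)
# ---------------------------------------------------------------------------


def _house(parent: dict, element: str) -> None:
    """Array of ``@id``-bearing objects → ``<element>ById`` keyed container.

    An absent collection stays absent; an empty one stays empty.
    """
    if element not in parent:
        return
    objs = as_list(parent.pop(element, None))
    container: dict[str, dict] = {}
    for obj in objs:
        obj = dict(obj)
        entity_id = obj.pop("@id", None)
        if entity_id is None:
            raise ConversionError(
                f"cannot key a {element!r} entity that has no @id")
        if entity_id in container:
            raise ConversionError(
                f"duplicate {element} id {entity_id!r} prevents keyed housing")
        container[entity_id] = obj
    parent[element + "ById"] = container


def _unhouse(parent: dict, element: str) -> list[dict]:
    if element + "ById" not in parent:
        return []
    container = parent.pop(element + "ById") or {}
    objs = []
    for entity_id in sorted(container, key=natural_key):
        obj = {"@id": entity_id}
        obj.update(container[entity_id])
        objs.append(obj)
    parent[element] = objs
    return objs


def _rehouse_1_2(nexml: dict) -> None:
    for group in as_list(nexml.get("otus")):
        _house(group, "otu")
    for group in as_list(nexml.get("trees")):
        for tree in as_list(group.get("tree")):
            _house(tree, "node")
            _house(tree, "edge")
        _house(group, "tree")
    _house(nexml, "otus")
    _house(nexml, "trees")


def _unhouse_1_2(nexml: dict) -> None:
    for group in _unhouse(nexml, "otus"):
        _unhouse(group, "otu")
    for group in _unhouse(nexml, "trees"):
        for tree in _unhouse(group, "tree"):
            _unhouse(tree, "node")
            _unhouse(tree, "edge")


# ---------------------------------------------------------------------------
# version conversion
# ---------------------------------------------------------------------------


def convert_version(doc: NexsonDocument, target: NexsonVersion) -> NexsonDocument:
    """Return *doc* re-housed in syntax *target*; the input is not mutated.

    Semantic content is preserved exactly: the multiset of
    (entity-id, property, value) triples is invariant, and converting along
    any path between two versions yields model-equal results.
    """
    report = doc.validate()
    if not report.is_valid:
        raise InvalidDocumentError(report)
    source = doc.syntax_version
    out = doc.copy()
    nexml = out.nexml
    if source is target:
        nexml[VERSION_PROPERTY] = target.value
        return out
    # Normalize to the 1.0 hub.
    if source is NexsonVersion.V0_0:
        _promote_meta(nexml, "nexml")
    elif source is NexsonVersion.V1_2:
        _unhouse_1_2(nexml)
    # Then to the target.
    if target is NexsonVersion.V0_0:
        _demote_meta(nexml, "nexml", [0])
    elif target is NexsonVersion.V1_2:
        _rehouse_1_2(nexml)
    nexml[VERSION_PROPERTY] = target.value
    return out


# ---------------------------------------------------------------------------
# model equality
# ---------------------------------------------------------------------------


def _normal(value: Any, caret: bool = False) -> Any:
    if isinstance(value, dict):
        # An empty entity collection is semantically absent (XML cannot
        # distinguish the two), and the version tag is housing, not content.
        return tuple(sorted(
            (k, _normal(v, caret=k.startswith("^"))) for k, v in value.items()
            if k != VERSION_PROPERTY
            and not (v in ({}, []) and not k.startswith(("@", "^", "$")))))
    if isinstance(value, list):
        items = [_normal(v) for v in value]
        if caret and len(items) == 1:
            return items[0]
        return ("#list",) + tuple(sorted(items, key=repr))
    if isinstance(value, bool):
        return ("#bool", value)
    return value


def normal_form(doc: NexsonDocument) -> Any:
    """A hashable normal form invariant under version conversion and
    semantic-preserving reordering."""
    return _normal(convert_version(doc, NexsonVersion.V1_2).data)


def model_equal(a: NexsonDocument, b: NexsonDocument) -> bool:
    """True when two documents carry identical information, regardless of
    syntax version, entity order or meta housing."""
    return normal_form(a) == normal_form(b)


# ---------------------------------------------------------------------------
# payload profiling
# ---------------------------------------------------------------------------


def measure_payload_reduction(doc: NexsonDocument) -> float:
    """Percent byte-size reduction of the 1.2 housing over badgerfish 0.0.

    Both serializations use the canonical whitespace policy, so the number
    reflects housing terseness only: ``100 * (1 - bytes(v1.2)/bytes(v0.0))``.
    """
    from .canonical import canonical_serialize

    v00 = canonical_serialize(convert_version(doc, NexsonVersion.V0_0))
    v12 = canonical_serialize(convert_version(doc, NexsonVersion.V1_2))
    b00 = len(v00.encode("utf-8"))
    b12 = len(v12.encode("utf-8"))
    return 100.0 * (1.0 - b12 / b00)


# ---------------------------------------------------------------------------
# NeXML (XML) ingestion and export
# ---------------------------------------------------------------------------

_DATATYPE_PARSERS = {
    "xsd:int": int, "xsd:integer": int, "xsd:long": int,
    "xsd:float": float, "xsd:double": float, "xsd:decimal": float,
    "xsd:boolean": lambda s: s in ("true", "1"),
}


def _prefix_for(uri: str, nsrev: dict[str, str]) -> str | None:
    return nsrev.get(uri)


def _attr_name(key: str, nsrev: dict[str, str]) -> str:
    if key.startswith("{"):
        uri, local = key[1:].split("}", 1)
        prefix = _prefix_for(uri, nsrev)
        return f"{prefix}:{local}" if prefix else local
    return key


def _coerce_attr(name: str, value: str) -> Any:
    if name == "@root":
        return value in ("true", "1")
    if name == "@length":
        return int(value) if _INT_RE.match(value) else float(value)
    return value


def _element_to_obj(el, nsrev: dict[str, str]) -> dict:
    obj: dict[str, Any] = {}
    for key, value in el.attrib.items():
        name = "@" + _attr_name(key, nsrev)
        obj[name] = _coerce_attr(name, value)
    children: dict[str, list] = {}
    has_children = False
    for child in el:
        if not isinstance(child.tag, str):
            log.warning("dropping XML comment/PI inside <%s>",
                        etree.QName(el).localname)
            continue
        has_children = True
        local = etree.QName(child).localname
        children.setdefault(local, []).append(_element_to_obj(child, nsrev))
    for local, objs in children.items():
        if local in REPEATABLE_ELEMENTS or len(objs) > 1:
            obj[local] = objs
        else:
            obj[local] = objs[0]
    text = (el.text or "").strip()
    if text:
        if has_children:
            log.warning("dropping mixed text content inside <%s>",
                        etree.QName(el).localname)
        else:
            obj["$"] = text
    if etree.QName(el).localname == "meta":
        if "@content" in obj and "$" not in obj:
            obj["$"] = obj.pop("@content")
        parser = _DATATYPE_PARSERS.get(obj.get("@datatype"))
        if parser is not None and "$" in obj and isinstance(obj["$"], str):
            try:
                obj["$"] = parser(obj["$"])
            except ValueError:
                pass  # unparsable: keep the raw text and declared datatype
    return obj


def nexml_to_nexson(xml_text: str, opts: ConversionOptions | None = None) -> NexsonDocument:
    """Ingest a NeXML document into the NexSON model.

    XML attributes become ``@``-prefixed properties, element text maps to
    ``$``, namespace declarations are carried on the root under ``@xmlns``,
    and the result is re-housed into ``opts.target_version``.
    """
    opts = opts or ConversionOptions()
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        line, column = (exc.position or (None, None))
        raise ParseError(str(exc.msg), line=line, column=column) from exc
    if etree.QName(root).localname != "nexml":
        raise ParseError(f"root element is <{etree.QName(root).localname}>, "
                         "expected <nexml>")
    nsmap = dict(root.nsmap)
    nsrev: dict[str, str] = {}
    for prefix, uri in nsmap.items():
        if prefix is not None:
            nsrev.setdefault(uri, prefix)
    for prefix, uri in DEFAULT_NAMESPACES.items():
        if prefix != "$":
            nsrev.setdefault(uri, prefix)
    obj = _element_to_obj(root, nsrev)
    xmlns: dict[str, str] = {}
    for prefix, uri in nsmap.items():
        xmlns["$" if prefix is None else prefix] = uri
    if xmlns:
        obj["@xmlns"] = xmlns
    # Coerce badgerfish singletons of structural elements into lists.
    for element in ("otus", "trees"):
        if element in obj:
            obj[element] = as_list(obj[element])
    for group in as_list(obj.get("otus")):
        if "otu" in group:
            group["otu"] = as_list(group["otu"])
    for group in as_list(obj.get("trees")):
        if "tree" in group:
            group["tree"] = as_list(group["tree"])
        for tree in as_list(group.get("tree")):
            for element in ("node", "edge"):
                if element in tree:
                    tree[element] = as_list(tree[element])
    doc = NexsonDocument({"nexml": obj})
    doc.nexml[VERSION_PROPERTY] = NexsonVersion.V0_0.value
    return convert_version(doc, opts.target_version)


def _xml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return json.dumps(value)
    return str(value)


def _resolve_attr(name: str, nsmap: dict) -> str:
    if ":" in name:
        prefix, local = name.split(":", 1)
        uri = nsmap.get(prefix)
        if uri:
            return f"{{{uri}}}{local}"
        return local
    return name


def _obj_to_element(tag: str, obj: dict, parent, nsmap: dict, default_uri: str):
    el = etree.SubElement(parent, f"{{{default_uri}}}{tag}")
    _fill_element(el, tag, obj, nsmap, default_uri)
    return el


def _fill_element(el, tag: str, obj: dict, nsmap: dict, default_uri: str) -> None:
    is_meta = tag == "meta"
    for key in sorted(obj):
        if key.startswith("@") and key not in ("@xmlns", VERSION_PROPERTY):
            value = obj[key]
            el.set(_resolve_attr(key[1:], nsmap), _xml_value(value))
    if is_meta and "$" in obj and "@datatype" not in obj:
        datatype = _xsd_datatype(obj["$"])
        if datatype:
            el.set("datatype", datatype)
    if "$" in obj:
        el.text = _xml_value(obj["$"])
    for child_tag in ("meta", "otu", "node", "edge", "tree", "otus", "trees"):
        for child in as_list(obj.get(child_tag)):
            if isinstance(child, dict):
                _obj_to_element(child_tag, child, el, nsmap, default_uri)


def nexson_to_nexml(doc: NexsonDocument) -> str:
    """Export a NexSON document as NeXML XML text (inverse of ingestion).

    Re-ingesting the output reproduces a model-equal document.  Invalid
    documents are refused with their validation report attached.
    """
    report = doc.validate()
    if not report.is_valid:
        raise InvalidDocumentError(report)
    flat = convert_version(doc, NexsonVersion.V0_0)
    nexml_obj = flat.nexml
    xmlns = nexml_obj.get("@xmlns") or {}
    nsmap_decl: dict[str | None, str] = {}
    for prefix, uri in DEFAULT_NAMESPACES.items():
        nsmap_decl[None if prefix == "$" else prefix] = uri
    for prefix, uri in xmlns.items():
        nsmap_decl[None if prefix == "$" else prefix] = uri
    default_uri = nsmap_decl[None]
    prefix_map = {p: u for p, u in nsmap_decl.items() if p is not None}
    root = etree.Element(f"{{{default_uri}}}nexml", nsmap=nsmap_decl)
    _fill_element(root, "nexml", nexml_obj, prefix_map, default_uri)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")
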