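"""Canonical, diff-friendly NexSON serialization.

Study files live under version control, and git's diff machinery is
line-based, so the serializer emits one field per line with a deterministic
ordering of keys and entities.  Two model-equal documents — even ones that
differ by OTU-list order or by rotation of the children of internal nodes —
serialize to byte-identical text, so semantically trivial edits produce
empty diffs and a one-field edit touches a single line.

Policy (all deterministic):

* LF newlines, UTF-8, trailing newline, one space of indentation per depth;
* key order within an object: ``@id`` first, other ``@`` attributes
  lexicographically, then ``^`` meta lexicographically, then ``$``, then
  containers in natural (number-aware) order;
* keys of ``...ById`` containers and entity arrays ordered by natural id;
* arrays sorted by the canonical dump of their elements (entity order and
  child rotation carry no meaning in the data model);
* numbers in shortest round-trip decimal form.
"""

from __future__ import annotations

import json
from typing import Any

from .errors import InvalidDocumentError
from .model import NexsonDocument, natural_key


def _key_rank(key: str) -> tuple:
    if key == "@id":
        return (0,)
    if key.startswith("@"):
        return (1, key)
    if key.startswith("^"):
        return (2, key)
    if key == "$":
        return (3,)
    return (4, natural_key(key))


def _sorted_keys(obj: dict) -> list[str]:
    return sorted(obj.keys(), key=_key_rank)


def _scalar(value: Any) -> str:
    return json.dumps(value, ensure_ascii=False, allow_nan=False)


def _element_sort_key(value: Any) -> str:
    # Stable ordering for array elements: entity objects order by @id,
    # everything else by its own canonical dump.
    if isinstance(value, dict) and "@id" in value:
        return _scalar(value["@id"])
    return _dump_compact(value)


def _dump_compact(value: Any) -> str:
    if isinstance(value, dict):
        inner = ",".join(f"{_scalar(k)}:{_dump_compact(value[k])}"
                         for k in _sorted_keys(value))
        return "{" + inner + "}"
    if isinstance(value, list):
        return "[" + ",".join(sorted((_dump_compact(v) for v in value))) + "]"
    return _scalar(value)


def _write(value: Any, depth: int, out: list[str]) -> None:
    pad = " " * (depth + 1)
    if isinstance(value, dict):
        if not value:
            out.append("{}")
            return
        out.append("{\n")
        keys = _sorted_keys(value)
        for i, key in enumerate(keys):
            out.append(f"{pad}{_scalar(key)}: ")
            _write(value[key], depth + 1, out)
            out.append(",\n" if i < len(keys) - 1 else "\n")
        out.append(" " * depth + "}")
    elif isinstance(value, list):
        if not value:
            out.append("[]")
            return
        out.append("[\n")
        elements = sorted(value, key=_element_sort_key)
        for i, element in enumerate(elements):
            out.append(pad)
            _write(element, depth + 1, out)
            out.append(",\n" if i < len(elements) - 1 else "\n")
        out.append(" " * depth + "]")
    else:
        out.append(_scalar(value))


def canonical_serialize(doc: NexsonDocument) -> str:
    """Serialize *doc* to canonical text; refuses invalid documents.

    Byte-identical output for any two model-equal documents of the same
    syntax version, and idempotent: parsing the output and re-serializing
    reproduces it byte for byte.
    """
    report = doc.validate()
    if not report.is_valid:
        raise InvalidDocumentError(report)
    out: list[str] = []
    _write(doc.data, 0, out)
    out.append("\n")
    return "".join(out)


def canonical_parse(text: str) -> NexsonDocument:
    """Parse canonical (or any) NexSON JSON text back into a document."""
    return NexsonDocument.loads(text)
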