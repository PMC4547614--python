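"""Searchable study index with incremental, event-driven reindexing.

A flat-file git store offers no fast lookup, so an in-memory index is built
once over the whole corpus and then kept current by reindexing exactly the
study ids named in change events (the file name of every changed study path
is its id).  Two query shapes are supported: exact single-property match
over study-level metadata, and taxonomic scope — all trees containing at
least one OTU mapped to a given taxon or to any of its descendants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import NotFoundError, PhylostoreError, UnknownTaxonError
from .model import (
    META_TAXON_ID,
    NexsonDocument,
    get_meta,
    iter_nodes,
    iter_otu_groups,
    iter_otus,
    iter_tree_groups,
    iter_trees,
)
from .docstore import DocStore, StudyId, process_change_event, _git
from .treeops import TaxonRecord

log = logging.getLogger(__name__)


@dataclass
class IndexRecord:
    """Per-study searchable state: flattened study-level properties plus the
    mapped taxon-id set of every tree."""

    study_id: StudyId
    properties: dict = field(default_factory=dict)
    trees: dict[str, frozenset[int]] = field(default_factory=dict)


@dataclass
class StudyIndex:
    records: dict[str, IndexRecord] = field(default_factory=dict)
    build_errors: list[str] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyIndex):
            return NotImplemented
        return self.records == other.records

    # -- persistence (optional JSON snapshot) --------------------------------

    def to_json(self) -> str:
        payload = {
            str(sid): {
                "properties": record.properties,
                "trees": {t: sorted(taxa) for t, taxa in record.trees.items()},
            }
            for sid, record in self.records.items()
        }
        return json.dumps(payload, indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "StudyIndex":
        index = cls()
        for sid, entry in json.loads(text).items():
            index.records[sid] = IndexRecord(
                study_id=StudyId.parse(sid),
                properties=entry["properties"],
                trees={t: frozenset(taxa) for t, taxa in entry["trees"].items()},
            )
        return index


def _record_for(sid: StudyId, doc: NexsonDocument) -> IndexRecord:
    version = doc.syntax_version
    properties = dict(doc.study_meta())
    # Resource-valued meta indexes by its target URI.
    for key, value in list(properties.items()):
        if isinstance(value, dict) and "@href" in value:
            properties[key] = value["@href"]
    otu_taxon: dict[str, int] = {}
    for _, group in iter_otu_groups(doc.nexml, version):
        for otu_id, otu in iter_otus(group, version):
            taxon_id = get_meta(otu, version, META_TAXON_ID)
            if isinstance(taxon_id, int):
                otu_taxon[otu_id] = taxon_id
    trees: dict[str, frozenset[int]] = {}
    for _, group in iter_tree_groups(doc.nexml, version):
        for tree_id, tree in iter_trees(group, version):
            taxa = {otu_taxon[node.get("@otu")]
                    for _, node in iter_nodes(tree, version)
                    if node.get("@otu") in otu_taxon}
            trees[tree_id] = frozenset(taxa)
    return IndexRecord(study_id=sid, properties=properties, trees=trees)


def _primary_study_ids(store: DocStore) -> list[StudyId]:
    ids: set[StudyId] = set()
    for shard in store.shards:
        _, listing, _ = _git(shard, "ls-tree", "-r", "--name-only",
                             store.primary, "study", check=False)
        ids |= process_change_event(listing.splitlines())
    return sorted(ids)


def build_index(store: DocStore) -> StudyIndex:
    """Index every study on the primary branch (WIP-only studies excluded).

    Unparsable studies are logged, skipped and reported in
    ``index.build_errors``; they never abort the build.
    """
    index = StudyIndex()
    for sid in _primary_study_ids(store):
        try:
            doc, _ = store.fetch_study(sid)
            index.records[str(sid)] = _record_for(sid, doc)
        except PhylostoreError as exc:
            log.warning("skipping unparsable study %s: %s", sid, exc)
            index.build_errors.append(f"{sid}: {exc}")
    return index


def reindex_studies(index: StudyIndex, store: DocStore,
                    study_ids: Iterable[StudyId | str]) -> StudyIndex:
    """Re-read the listed studies from the primary branch, updating,
    adding or removing their records; all other records are untouched."""
    for sid in study_ids:
        sid = StudyId.parse(sid) if isinstance(sid, str) else sid
        try:
            doc, _ = store.fetch_study(sid)
        except NotFoundError:
            index.records.pop(str(sid), None)
            continue
        try:
            index.records[str(sid)] = _record_for(sid, doc)
        except PhylostoreError as exc:
            log.warning("skipping unparsable study %s: %s", sid, exc)
            index.records.pop(str(sid), None)
    return index


def search_studies_by_property(index: StudyIndex, property_name: str,
                               value) -> list[StudyId]:
    """Exact-match (case-sensitive) single-property search; a list-valued
    property (e.g. a multi-author list) matches on any element."""
    hits = []
    for record in index.records.values():
        stored = record.properties.get(property_name)
        if stored == value or (isinstance(stored, list) and value in stored):
            hits.append(record.study_id)
    return sorted(hits)


def taxon_closure(taxonomy: Sequence[TaxonRecord], taxon_id: int) -> set[int]:
    """The taxon plus all of its descendants in the taxonomy."""
    by_id = {t.taxon_id: t for t in taxonomy}
    if taxon_id not in by_id:
        raise UnknownTaxonError(f"taxon {taxon_id} is not in the taxonomy")
    children: dict[int, list[int]] = {}
    for taxon in taxonomy:
        if taxon.parent_id is not None:
            children.setdefault(taxon.parent_id, []).append(taxon.taxon_id)
    closure = {taxon_id}
    stack = [taxon_id]
    while stack:
        for child in children.get(stack.pop(), []):
            if child not in closure:
                closure.add(child)
                stack.append(child)
    return closure


def search_trees_by_taxon(index: StudyIndex, taxonomy: Sequence[TaxonRecord],
                          taxon_id: int) -> list[tuple[StudyId, str]]:
    """All (study, tree) pairs with >= 1 OTU mapped inside the given taxon's
    subtree of the taxonomy."""
    scope = taxon_closure(taxonomy, taxon_id)
    hits = []
    for record in index.records.values():
        for tree_id, taxa in record.trees.items():
            if taxa & scope:
                hits.append((record.study_id, tree_id))
    return sorted(hits)


def load_taxonomy_table(path) -> list[TaxonRecord]:
    """Read a taxonomy from a tab-separated table: id, parent_id, name, rank
    (empty parent_id marks the root; a header line is permitted)."""
    records = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.lower().startswith(("id\t", "#")):
                continue
            taxon_id, parent_id, name, rank = (line.split("\t") + [""])[:4]
            records.append(TaxonRecord(
                taxon_id=int(taxon_id),
                parent_id=int(parent_id) if parent_id else None,
                name=name, rank=rank))
    return records


def dump_taxonomy_table(taxonomy: Sequence[TaxonRecord]) -> str:
    lines = ["id\tparent_id\tname\trank"]
    for taxon in taxonomy:
        parent = "" if taxon.parent_id is None else str(taxon.parent_id)
        lines.append(f"{taxon.taxon_id}\t{parent}\t{taxon.name}\t{taxon.rank}")
    return "\n".join(lines) + "\n"
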