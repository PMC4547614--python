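"""Seeded synthetic generators: studies, taxonomies, corruptions, sessions.

Every module in this package is testable offline: the generators below
stand in for curated published studies, for the reference taxonomy tips are
mapped to, and for multi-curator editing sessions.  All outputs are
bit-reproducible for a fixed seed.  Generated tip labels deliberately carry
the punctuation, underscore and annotation noise of real published trees
("Homo_sapiens_x23", "Rattus sp. nov."), which exercises Newick quoting and
label-mapping code paths.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .convert import DEFAULT_NAMESPACES, convert_version
from .errors import CorruptionError
from .model import (
    META_INGROUP_CLADE,
    META_ORIGINAL_LABEL,
    META_ROOTING_CONFIRMED,
    META_TAXON_ID,
    META_TAXON_NAME,
    VERSION_PROPERTY,
    ErrorCode,
    NexsonDocument,
    NexsonVersion,
    iter_edges,
    iter_nodes,
    iter_tree_groups,
    iter_trees,
    set_meta,
)
from .treeops import TaxonRecord, get_tree, map_otu, replace_tree, RootTarget, reroot_tree

_SYLLABLES = ["ba", "ce", "dro", "fu", "gi", "lo", "mi", "nus", "pho", "ra",
              "sa", "the", "ul", "vex", "zo"]
_RANKS = ["domain", "kingdom", "phylum", "class", "order", "family",
          "genus", "species"]
_WORDS = ["alpine", "coastal", "type", "reference", "holotype", "revised",
          "draft", "sequenced", "vouchered", "published"]


@dataclass(frozen=True)
class StudyGenParams:
    """Knobs of the synthetic-study generator; defaults give a small,
    meta-bearing study with one binary tree."""

    n_otus: int = 20
    n_trees: int = 1
    meta_per_otu: int = 0
    meta_per_study: int = 0
    mapped_fraction: float = 0.5
    branch_length_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_otus < 1:
            raise ValueError("n_otus must be >= 1")
        if self.n_trees < 0 or self.meta_per_otu < 0 or self.meta_per_study < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.mapped_fraction <= 1.0:
            raise ValueError("mapped_fraction must lie in [0, 1]")
        if self.branch_length_scale <= 0:
            raise ValueError("branch_length_scale must be positive")


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _species_label(rng: random.Random, index: int) -> str:
    genus = _word(rng, rng.randint(2, 3)).capitalize()
    species = _word(rng, rng.randint(2, 3))
    style = rng.random()
    if style < 0.35:
        label = f"{genus}_{species}"            # underscore-joined
    elif style < 0.65:
        label = f"{genus} {species}"            # plain binomial with space
    elif style < 0.80:
        label = f"{genus} sp. nov."             # periods and spaces
    else:
        label = f"{genus}_{species}_x{rng.randint(1, 99)}"  # accession noise
    return f"{label} {index}" if rng.random() < 0.1 else label


def generate_taxonomy(n_taxa: int, depth: int = 5, seed: int = 0) -> list[TaxonRecord]:
    """A single-rooted synthetic taxonomy of *n_taxa* records.

    Each non-root taxon attaches to a uniformly chosen existing taxon whose
    depth is below *depth*; ranks follow depth.  Deterministic per seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = random.Random(seed)
    records = [TaxonRecord(100001, "Biota", None, "domain")]
    depths = {100001: 0}
    names = {"Biota"}
    for i in range(1, n_taxa):
        taxon_id = 100001 + i
        eligible = [r for r in records if depths[r.taxon_id] < depth]
        parent = rng.choice(eligible)
        level = depths[parent.taxon_id] + 1
        rank = _RANKS[min(level, len(_RANKS) - 1)]
        name = _word(rng, rng.randint(2, 4)).capitalize()
        if name in names:
            name = f"{name} {i}"
        names.add(name)
        records.append(TaxonRecord(taxon_id, name, parent.taxon_id, rank))
        depths[taxon_id] = level
    return records


def _grow_tree(rng: random.Random, tip_otus: list[str], tree_index: int,
               counter: list[int], scale: float) -> dict:
    """Random rooted binary tree over the given OTUs by uniform edge
    attachment; returns a V1_2 tree object."""

    def new_node() -> str:
        counter[0] += 1
        return f"node{counter[0]}"

    def new_edge() -> str:
        counter[1] += 1
        return f"edge{counter[1]}"

    def length() -> float:
        return round(rng.expovariate(1.0 / scale), 6)

    nodes: dict[str, dict] = {}
    edges: dict[str, dict] = {}
    root = new_node()
    nodes[root] = {"@root": True}
    if len(tip_otus) == 1:
        nodes[root]["@otu"] = tip_otus[0]
    else:
        order = list(tip_otus)
        rng.shuffle(order)
        for otu in order[:2]:
            tip = new_node()
            nodes[tip] = {"@otu": otu}
            edges[new_edge()] = {"@source": root, "@target": tip,
                                 "@length": length()}
        for otu in order[2:]:
            host_id = rng.choice(sorted(edges))
            host = edges[host_id]
            mid = new_node()
            nodes[mid] = {}
            edges[new_edge()] = {"@source": mid, "@target": host["@target"],
                                 "@length": round(host["@length"] / 2, 6)}
            host["@target"] = mid
            host["@length"] = round(host["@length"] / 2, 6)
            tip = new_node()
            nodes[tip] = {"@otu": otu}
            edges[new_edge()] = {"@source": mid, "@target": tip,
                                 "@length": length()}
    internal = [n for n in nodes if "@otu" not in nodes[n] and n != root]
    tree = {
        "@label": f"tree {tree_index} from synthetic study",
        "@xsi:type": "nex:FloatTree",
        "^" + META_ROOTING_CONFIRMED: True,
        "nodeById": nodes,
        "edgeById": edges,
    }
    if internal:
        tree["^" + META_INGROUP_CLADE] = rng.choice(sorted(internal))
    return tree


def generate_study(params: StudyGenParams) -> NexsonDocument:
    """A valid synthetic V1_2 study document, deterministic per seed."""
    rng = random.Random(params.seed)
    taxonomy = generate_taxonomy(max(4, 2 * params.n_otus), depth=5,
                                 seed=params.seed + 104729)
    taxa_pool = [t for t in taxonomy if t.parent_id is not None] or taxonomy

    otu_by_id: dict[str, dict] = {}
    labels_seen: set[str] = set()
    otu_ids = [f"otu{i + 1}" for i in range(params.n_otus)]
    n_mapped = round(params.mapped_fraction * params.n_otus)
    mapped_set = set(rng.sample(otu_ids, n_mapped))
    for i, otu_id in enumerate(otu_ids):
        label = _species_label(rng, i + 1)
        if label in labels_seen:
            label = f"{label}_{i + 1}"
        labels_seen.add(label)
        otu = {"^" + META_ORIGINAL_LABEL: label}
        if otu_id in mapped_set:
            taxon = rng.choice(taxa_pool)
            otu["^" + META_TAXON_ID] = taxon.taxon_id
            otu["^" + META_TAXON_NAME] = taxon.name
        for j in range(params.meta_per_otu):
            otu[f"^ot:otuNote{j + 1}"] = rng.choice(_WORDS)
        otu_by_id[otu_id] = otu

    counter = [0, 0]  # node, edge counters shared across trees
    tree_by_id = {
        f"tree{t + 1}": _grow_tree(rng, otu_ids, t + 1, counter,
                                   params.branch_length_scale)
        for t in range(params.n_trees)
    }

    nexml: dict = {
        "@id": f"study-seed{params.seed}",
        "@version": "0.9",
        "@xmlns": dict(DEFAULT_NAMESPACES),
        VERSION_PROPERTY: NexsonVersion.V1_2.value,
        "^ot:studyYear": rng.randint(1995, 2024),
        "^ot:studyAuthor": sorted({_word(rng, 2).capitalize()
                                   for _ in range(rng.randint(1, 3))}),
        "^ot:curatorName": _word(rng, 3).capitalize(),
        "^ot:studyPublication": {
            "@href": f"https://doi.org/10.{rng.randint(1000, 9999)}/synth.{params.seed}"},
        "otusById": {"otus1": {"otuById": otu_by_id}},
        "treesById": {"trees1": {"@otus": "otus1", "treeById": tree_by_id}},
    }
    for j in range(params.meta_per_study):
        nexml[f"^ot:studyNote{j + 1}"] = rng.choice(_WORDS)
    return NexsonDocument({"nexml": nexml})


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

CORRUPTION_KINDS = ("dangling-edge", "duplicate-id", "orphan-otu-ref", "cycle")

# Which validation code each corruption is guaranteed to trigger.
CORRUPTION_CODES = {
    "dangling-edge": ErrorCode.DANGLING_NODE_REF,
    "duplicate-id": ErrorCode.DUPLICATE_ID,
    "orphan-otu-ref": ErrorCode.DANGLING_OTU_REF,
    "cycle": ErrorCode.NOT_ARBORESCENT,
}


def _trees_of(doc: NexsonDocument):
    version = doc.syntax_version
    for _, group in iter_tree_groups(doc.nexml, version):
        for _, tree in iter_trees(group, version):
            yield tree


def corrupt_study(doc: NexsonDocument, corruption_kind: str,
                  seed: int = 0) -> NexsonDocument:
    """Inject exactly one defect of the named kind into a copy of *doc*.

    ``duplicate-id`` returns the copy in V1_0 housing, where a duplicated
    id is representable (keyed V1_2 containers cannot hold one).
    """
    if corruption_kind not in CORRUPTION_KINDS:
        raise CorruptionError(f"unknown corruption kind {corruption_kind!r}")
    rng = random.Random(seed)

    if corruption_kind == "duplicate-id":
        out = convert_version(doc, NexsonVersion.V1_0)
        for tree in _trees_of(out):
            nodes = tree.get("node") or []
            if len(nodes) >= 2:
                victim, donor = rng.sample(range(len(nodes)), 2)
                nodes[victim]["@id"] = nodes[donor]["@id"]
                return out
        raise CorruptionError("no tree with >= 2 nodes to duplicate an id in")

    out = doc.copy()
    version = out.syntax_version
    if corruption_kind == "dangling-edge":
        for tree in _trees_of(out):
            edges = dict(iter_edges(tree, version))
            if edges:
                edge_id = rng.choice(sorted(edges))
                edges[edge_id]["@target"] = "node_missing_999999"
                return out
        raise CorruptionError("document has no edges")

    if corruption_kind == "orphan-otu-ref":
        for tree in _trees_of(out):
            tips = [(nid, n) for nid, n in iter_nodes(tree, version)
                    if n.get("@otu") is not None]
            if tips:
                _, node = rng.choice(sorted(tips))
                node["@otu"] = "otu_missing_999999"
                return out
        raise CorruptionError("document has no otu-bearing nodes")

    # cycle: re-point a descendant's out-edge back at its grandparent.
    for tree in _trees_of(out):
        edges = dict(iter_edges(tree, version))
        by_source: dict[str, list[str]] = {}
        for edge_id, edge in edges.items():
            by_source.setdefault(edge["@source"], []).append(edge_id)
        candidates = []
        for edge_id, edge in edges.items():
            for child_edge in by_source.get(edge["@target"], []):
                candidates.append((child_edge, edge["@source"]))
        if candidates:
            child_edge, ancestor = rng.choice(sorted(candidates))
            edges[child_edge]["@target"] = ancestor
            return out
    raise CorruptionError("no two-edge path available to bend into a cycle")


# ---------------------------------------------------------------------------
# curation sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionEvent:
    index: int
    curator: str
    action: str
    study_id: object
    response: object


@dataclass
class SessionLog:
    study_id: object
    events: list[SessionEvent] = field(default_factory=list)

    @property
    def merged_count(self) -> int:
        return sum(1 for e in self.events if e.response.merged)


def simulate_curation_session(store, n_curators: int, n_edits: int,
                              seed: int = 0) -> SessionLog:
    """Replay a randomized multi-curator editing session against a store.

    One study is deposited, then *n_edits* random edits (metadata change,
    OTU mapping, reroot) are applied by *n_curators* with randomized
    fetch/save interleaving: a curator sometimes keeps editing from a stale
    parent, which is exactly what produces deferred (merged=False) saves.
    Deterministic per seed.
    """
    rng = random.Random(seed)
    doc = generate_study(StudyGenParams(n_otus=8, n_trees=1, mapped_fraction=0.5,
                                        seed=rng.randrange(2**31)))
    taxonomy = generate_taxonomy(24, seed=rng.randrange(2**31))
    sid, response = store.create_study(doc, author_id="curator0",
                                       message="initial deposit")
    log = SessionLog(study_id=sid)
    log.events.append(SessionEvent(0, "curator0", "create", sid, response))

    state: dict[str, tuple[NexsonDocument, str]] = {}
    for k in range(1, n_edits + 1):
        curator = f"curator{rng.randrange(n_curators)}"
        if curator not in state or rng.random() < 0.7:
            state[curator] = store.fetch_study(sid)
        local, parent_sha = state[curator]
        local = local.copy()
        action = rng.choice(["meta", "map", "reroot"])
        version = local.syntax_version
        # Every edit bumps a session counter, so the file always changes.
        set_meta(local.nexml, version, "ot:sessionEdit", k)
        if action == "meta":
            set_meta(local.nexml, version, "ot:studyYear", rng.randint(1995, 2024))
        elif action == "map":
            otu_id = f"otu{rng.randint(1, 8)}"
            map_otu(local, otu_id, rng.choice(taxonomy))
        else:
            tree = get_tree(local, "tree1")
            internal = sorted(n for n in tree.nodes
                              if tree.nodes[n].otu_ref is None)
            target = rng.choice(internal)
            tree = reroot_tree(tree, RootTarget(kind="node", target_id=target))
            replace_tree(local, tree)
        response = store.save_study(sid, local, parent_sha=parent_sha,
                                    author_id=curator,
                                    message=f"edit {k}: {action}")
        log.events.append(SessionEvent(k, curator, action, sid, response))
        if response.merged:
            state[curator] = (local, response.new_sha)
        else:
            state.pop(curator, None)
    return log
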