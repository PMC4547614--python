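# Methods

This note records the data model, the conventions this package fixes where
the NexSON ecosystem leaves a choice open, the synthetic-data conditions
under which the test suite runs, and the numerical/engineering decisions a
maintainer would want to know.

## Data model

A study document is the NeXML data model serialized as JSON: top-level
study metadata, OTU groups, and tree groups of rooted trees whose edges
are stored with an explicit source→target orientation (an arborescence:
every non-root node has exactly one in-edge, the root none, and all nodes
are reachable from the root). Character data is out of scope by design —
the store holds phylogenetic *estimates* and their curation metadata, not
alignments or MCMC/bootstrap tree sets.

Three syntax versions coexist and interconvert losslessly:

| version | meta annotations | entity housing |
|---|---|---|
| 0.0 | badgerfish `meta` arrays, full XML image | arrays of `@id`-bearing objects |
| 1.0 | `^property` keys | arrays of `@id`-bearing objects |
| 1.2 | `^property` keys | `<element>ById` objects keyed by id |

A document's version is declared by the `nexml2json` property; only the
major.minor prefix is significant, and a missing property means 0.0, the
direct badgerfish image that predates the marker.

**What conversion preserves and what it sheds.** The invariant content is
the multiset of (entity-id, property, value) annotation triples plus the
entity/edge structure. The 0.0 image additionally carries per-annotation
XML plumbing — each `meta` element's own `id`, its `xsi:type`
discriminator and its XSD `datatype` tag. These are derivable (ids are
re-mintable, the datatype is the JSON value's type), so promotion to the
caret syntaxes drops them and demotion regenerates them deterministically
(sequential `meta1`, `meta2`, … in document walk order; `xsd:integer` /
`xsd:double` / `xsd:boolean` inferred from the value). This asymmetry is
the entire payload saving of the terse syntaxes. Two further
representational notes: an *empty* entity collection is treated as
equivalent to an absent one (XML cannot distinguish them), and in 1.2 the
housed objects drop their inner `@id` — the container key carries it.
Unrecognized keys at any level round-trip opaquely.

**Local meta conventions.** Curation state is recorded under the `ot:`
vocabulary: `ot:originalLabel` (immutable deposit-time tip label),
`ot:ottId` / `ot:ottTaxonName` (the recorded taxonomy mapping), and two
tree-level flags this package defines as local convention because no
standard name exists: `ot:rootingConfirmed` (boolean; a curator vouched
for the root) and `ot:inGroupClade` (node id of the ingroup ancestor).

## Canonical serialization

Study files live under line-based version control, so the serializer is
deterministic to the byte: LF newlines, trailing newline, one space of
indentation per depth, one primitive field per line. Key order inside an
object is `@id`, other `@` attributes lexicographically, `^` meta
lexicographically, `$`, then containers in natural (number-aware) order, so
`node9` sorts before `node10` and insertion order never matters. Arrays
sort by the canonical dump of their elements (entity order and child
rotation carry no meaning in this data model; multi-valued meta is a
multiset). Numbers print in Python's shortest round-trip decimal form.
Consequences: two model-equal documents serialize byte-identically,
serialization is idempotent, and a one-field edit changes one line of the
stored file.

## Tree operations

*Rerooting* re-orients edges away from the new root with a breadth-first
sweep, so exactly the edges on the old→new root path flip. Rooting on an
edge subdivides it at a fraction measured from the stored source, splitting
the length proportionally; the new node id derives from the tree id. A
former root left with undirected degree 2 is a rooting artifact, not a
vertex of the unrooted topology, so it is suppressed and its two incident
edge lengths summed (two absent lengths merge to absent). A tip cannot be
made the root directly — that would strand its OTU on an internal node —
the operation refuses and points the caller at the tip's edge. Branch
lengths are non-negative reals; *absent* is permitted and distinct from
zero.

*Export.* Newick sibling order follows natural child-node-id order, making
exports byte-stable. Labels are single-quoted (internal quotes doubled)
unless they consist solely of alphanumerics and `. | + -`; underscores are
quoted too, because unquoted underscores read back as spaces. Mapped-label
modes fall back to the original label for unmapped OTUs with a logged
warning rather than failing mid-curation. NEXUS export emits one TAXA
block for the whole document and a TRANSLATE table of 1-based indices.

## Document store

Each shard is an ordinary git repository; the primary branch is `main`.
Study `ot_211` lives at `study/ot_11/ot_211/ot_211.json`: bucket = prefix
plus the last two digits of the numeric suffix, zero-padded for short
suffixes (`pg_5` → `pg_05`). Ids are minted as max existing suffix + 1,
where "existing" scans every branch **and** every path ever added, so an
id parked on an unmerged branch or belonging to a deleted study is never
reused (a recycled id would inherit a stranger's history).

A save validates and size-checks first (default cap 20 MiB, configurable),
then commits on a WIP branch named `<study>_<author>_<parent7>` forked
from the client's parent SHA. If the study's blob on the primary branch
still equals its blob at the parent, the branch merges (fast-forward where
possible) and is deleted; otherwise the branch survives and the response
says `merged=false` — a normal outcome, the data are saved and a human
resolves the merge later. The unchanged-since-parent test is per study
file, so edits to other studies never block a merge. All commit-creating
operations on a shard serialize behind an in-process lock, guaranteeing
that every commit's parent is the head observed when the operation began.
Pushing to a remote goes through a separate mirror clone, so the working
repository keeps accepting saves while a slow or failing push is in
flight. Change events are lists of changed paths; the file-name portion of
a study path *is* its id, which is what makes incremental reindexing
trivial.

## Index

In-memory records (with an optional JSON snapshot) rather than a database
service: one record per primary-branch study holding all study-level meta
(flattened; resource meta indexes by its URI, curator names included) plus
each tree's set of mapped taxon ids. Property search is exact and
case-sensitive; list-valued properties match on any element. Taxon-scope
search computes the descendant closure of the query taxon in a supplied
taxonomy table and returns trees intersecting it. Reindexing the ids named
in change events reproduces a fresh full build (tested with randomized
multi-curator sessions).

## Synthetic data: what it emulates and what it does not

The generator produces valid 1.2 studies: uniform-edge-attachment random
binary trees (shape-agnostic and seedable; root degree 2), exponential
branch lengths (default scale 0.1 substitutions/site, typical of published
molecular trees), and tip labels that deliberately reproduce the
punctuation, underscore and accession noise of real deposits, which is
what exercises quoting and mapping code. A synthetic single-rooted
taxonomy with ranked levels stands in for a reference taxonomy; mapped
OTUs point at it. Default densities: every OTU carries its original label;
`mapped_fraction` (default 0.5) of OTUs carry a taxon mapping; study-level
meta includes year, author list, curator and a DOI-style resource link.
The meta-dense reference condition used for the payload measurement is 200
OTUs, one tree, `mapped_fraction=1.0`, generator seed 42.

What the generator does **not** emulate: real estimation artifacts
(polytomies, support values, zero-length terminal branches), label
collisions across studies, taxonomies with synonymy or rank gaps, and
corpus-scale statistics of a production deployment. Passing tests
therefore demonstrate the contracts — losslessness, determinism, merge
semantics, index consistency — on realistic document *shapes*, not
performance or curation quality on any real corpus.

Session simulation replays seeded random edits (metadata change, OTU
mapping, reroot) by n curators, each edit bumping a session counter so the
file always changes; curators sometimes keep editing from a stale parent,
which is what produces deferred merges. Test problem sizes (studies of
2–20 OTUs, sessions of 5–50 edits, 100–200 property-test repetitions) were
chosen to exercise every code path at desk scale.

## Known limitations

* Deferred WIP branches accumulate until resolved by hand; no
  object-model diff/merge tool is provided.
* The in-process lock serializes mutations per shard within one process;
  cross-process writers would need a file lock.
* Mixed XML content and comments inside NeXML are dropped with a warning;
  NeXML character blocks and XSD validation are out of scope.
* Index persistence is a snapshot, not a transactional store; search is
  exact-match only.
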