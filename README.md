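# phylostore

A git-backed, sharded document store and curation toolkit for published
phylogenetic estimates, serialized as NexSON (NeXML-in-JSON).

## The problem

Published tree files are rarely reusable as deposited: they arrive
unrooted or mis-rooted, their tip labels are idiosyncratic
(`Homo_sapiens_x23`, `Rattus sp. nov.`), and the metadata needed to
interpret them is missing. Fixing these things after publication —
*curation* — is error-prone itself, so every edit needs provenance: who
changed what, when, and why. phylostore treats a corpus of study documents
as files in git repositories ("shards") and implements the standard
create/read/update/delete operations **as commits**, so the full edit
history of every tree comes for free from version control, and anyone can
clone, inspect, or fork the entire corpus with ordinary git tools.

It is aimed at maintainers of community-curated tree collections and at
bioinformaticians who want a transparent, diff-able, zero-service database
for document-scale phylogenetic data.

## What is inside

* **Document model & validation** (`model`) — NexSON studies in three
  syntax versions: 0.0 (direct badgerfish image of NeXML: `@` for XML
  attributes, `$` for text, `meta` arrays), 1.0 (badgerfish plus `^property`
  meta promotion) and 1.2 (entities re-housed in id-keyed containers).
  Validation checks every structural and referential invariant — duplicate
  ids, dangling OTU/node references, non-arborescent edge sets — against a
  fixed error-code enumeration.
* **Lossless conversion** (`convert`) — NeXML ↔ any NexSON version; the
  terse 1.2 housing cuts a meta-dense study's payload by ≥ 50 % relative to
  the naive 0.0 image (`measure_payload_reduction`).
* **Canonical serialization** (`canonical`) — one field per line, stable
  key and entity order, so shuffling an OTU list or rotating children
  produces an *empty* git diff and a one-field edit touches one line.
* **Tree curation** (`treeops`) — rerooting at a node or at a fractional
  position on an edge (edges on the old→new root path reverse their
  source→target orientation; a leftover degree-2 root is suppressed);
  OTU-to-taxonomy mapping that never touches the original label; Newick and
  NEXUS export with correct label quoting.
* **Document store** (`docstore`) — sharded id minting (`ot_`/`pg_`
  prefixes; study `ot_211` lives at `study/ot_11/ot_211/ot_211.json`),
  a 20 MiB commit-size gate, and work-in-progress merge semantics: a save
  commits onto a WIP branch forked from the parent SHA the client fetched;
  it merges to the primary branch only if that study's file has not changed
  since, otherwise the branch is kept for manual resolution
  (`merged=false`). A mirror clone handles pushing to a remote so saves are
  never blocked by a slow push.
* **Search index** (`indexing`) — exact property search and taxonomic-scope
  search (all trees with an OTU mapped inside a given taxon's subtree),
  kept current by reindexing exactly the study ids named in change events.
* **Fixtures** (`fixtures`) — seeded generators for studies, taxonomies,
  targeted corruptions and multi-curator editing sessions; every test input
  is synthesized, no downloads.

## Worked example

```sh
$ phylostore fixture study --otus 8 --seed 11 --mapped-fraction 0.5 -o study.json
$ phylostore store init corpus
$ phylostore store create corpus study.json --author mholder -m "deposit seed-11 study"
{"study_id": "ot_1", "merged": true, "sha": "6ee49782e47e002ef6975375cb9ee9a1810283da"}
```

The store minted the first `ot_`-prefixed id, wrote the study in canonical
form at `corpus/shard/study/ot_01/ot_1/ot_1.json`, and committed it
authored by `mholder`; `merged: true` says the deposit reached the primary
branch, and the SHA is what a later `store save --parent <sha>` must hand
back so concurrent edits can be detected. Export the tree and profile the
serialization:

```sh
$ phylostore export study.json --format newick
(('Sagi basace':0.007228,((('Mice_miceba_x1':0.019562,...):0.000772):0.007228,...);
```

```python
>>> import phylostore as ps
>>> doc = ps.NexsonDocument.load_path("study.json")
>>> print("payload reduction: %.1f%%" % ps.measure_payload_reduction(doc))
payload reduction: 46.5%
```

That last number is the byte saving of the 1.2 id-keyed housing over the
naive badgerfish image for this small, half-mapped study; denser
annotation pushes it past 50 % (see below). Labels with spaces or
underscores come back single-quoted in Newick, so they survive an
independent parser unchanged.

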