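"""Shared fixtures: every test input is generated programmatically."""

from __future__ import annotations

import pytest

import phylostore as ps


def make_tiny_doc() -> ps.NexsonDocument:
    """Smallest interesting study: 2 OTUs, one 3-node/2-edge rooted tree."""
    return ps.NexsonDocument({
        "nexml": {
            "@id": "tiny",
            "@nexml2json": "1.2",
            "^ot:studyYear": 2010,
            "otusById": {
                "otus1": {"otuById": {
                    "otu1": {"^ot:originalLabel": "Homo_sapiens_x23"},
                    "otu2": {"^ot:originalLabel": "Pan troglodytes"},
                }},
            },
            "treesById": {
                "trees1": {"@otus": "otus1", "treeById": {
                    "tree1": {
                        "nodeById": {
                            "node1": {"@root": True},
                            "node2": {"@otu": "otu1"},
                            "node3": {"@otu": "otu2"},
                        },
                        "edgeById": {
                            "edge1": {"@source": "node1", "@target": "node2",
                                      "@length": 1.5},
                            "edge2": {"@source": "node1", "@target": "node3",
                                      "@length": 0.5},
                        },
                    },
                }},
            },
        },
    })


@pytest.fixture
def tiny_doc() -> ps.NexsonDocument:
    return make_tiny_doc()


@pytest.fixture
def study_doc() -> ps.NexsonDocument:
    return ps.generate_study(ps.StudyGenParams(n_otus=20, n_trees=2,
                                               mapped_fraction=0.7, seed=42))


@pytest.fixture
def store(tmp_path) -> ps.DocStore:
    return ps.DocStore.init(tmp_path / "store")
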