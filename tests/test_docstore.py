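"""Sharded git-backed store: paths, minting, CRUD commits, WIP merges."""

from __future__ import annotations

import subprocess
import threading

import pytest

import phylostore as ps
from phylostore.docstore import StudyId, _git, _git_out


def tiny(seed: int = 0, n_otus: int = 4) -> ps.NexsonDocument:
    return ps.generate_study(ps.StudyGenParams(n_otus=n_otus, n_trees=1,
                                               seed=seed))


def edit_year(doc: ps.NexsonDocument, year: int) -> ps.NexsonDocument:
    out = doc.copy()
    out.nexml["^ot:studyYear"] = year
    return out


class TestShardPath:
    @pytest.mark.parametrize("study_id,expected", [
        ("ot_211", "study/ot_11/ot_211/ot_211.json"),
        ("ot_1000", "study/ot_00/ot_1000/ot_1000.json"),
        ("pg_5", "study/pg_05/pg_5/pg_5.json"),
    ])
    def test_bucketing_rule(self, study_id, expected):
        assert ps.shard_path(study_id) == expected

    @pytest.mark.parametrize("bad", ["OT_1", "ot1", "ot_", "_5", "ot_-3", ""])
    def test_malformed_ids_rejected(self, bad):
        with pytest.raises(ps.StoreError):
            ps.shard_path(bad)

    def test_roundtrip_parse(self):
        sid = StudyId.parse("pg_4077")
        assert (sid.prefix, sid.numeric_suffix) == ("pg_", 4077)
        assert str(sid) == "pg_4077"


class TestChangeEvents:
    def test_paths_map_to_ids(self):
        payload = ["study/ot_11/ot_211/ot_211.json", "README.md",
                   "study/ot_11/ot_211/ot_211.json",
                   "study/pg_05/pg_5/pg_5.json",
                   "study/ot_11/notes.txt"]
        assert {str(s) for s in ps.process_change_event(payload)} == \
            {"ot_211", "pg_5"}

    def test_empty_payload(self):
        assert ps.process_change_event([]) == set()


class TestMinting:
    def test_empty_store_starts_at_one(self, store):
        assert str(store.mint_study_id()) == "ot_1"

    def test_mint_skips_gaps_to_max_plus_one(self, store):
        shard = store.shards[0]
        for sid in ("ot_1", "ot_2", "ot_7"):
            rel = ps.shard_path(sid)
            target = shard / rel
            target.parent.mkdir(parents=True)
            target.write_text("{}\n")
            _git(shard, "add", rel)
        _git(shard, "commit", "-q", "-m", "seed ids")
        assert str(store.mint_study_id()) == "ot_8"

    def test_concurrent_creates_yield_distinct_ids_and_linear_history(self, store):
        ids, errors = [], []

        def worker(seed):
            try:
                sid, _ = store.create_study(tiny(seed), f"curator{seed}")
                ids.append(str(sid))
            except Exception as exc:  # pragma: no cover - diagnostic
                errors.append(exc)

        threads = [threading.Thread(target=worker, args=(i,)) for i in range(12)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        assert not errors
        assert len(set(ids)) == 12
        # Linear parentage: every commit has exactly one parent.
        out = _git_out(store.shards[0], "log", "--format=%P", store.primary)
        parents = [line.split() for line in out.splitlines()]
        assert all(len(p) == 1 for p in parents[:-1])


class TestCrud:
    def test_create_fetch_roundtrip(self, store):
        doc = tiny(1)
        sid, response = store.create_study(doc, "alice", "deposit")
        assert response.merged and response.wip_branch is None
        fetched, sha = store.fetch_study(sid)
        assert ps.model_equal(fetched, doc)
        assert sha == response.new_sha

    def test_two_creates_distinct_ids(self, store):
        sid1, _ = store.create_study(tiny(1), "alice")
        sid2, _ = store.create_study(tiny(2), "bob")
        assert sid1 != sid2
        assert len(store.study_history(sid1)) == 1

    def test_fetch_unknown_id(self, store):
        with pytest.raises(ps.NotFoundError):
            store.fetch_study("ot_999")

    def test_invalid_document_rejected_without_commit(self, store):
        sid, r0 = store.create_study(tiny(1), "alice")
        doc, sha = store.fetch_study(sid)
        broken = ps.corrupt_study(doc, "dangling-edge")
        with pytest.raises(ps.InvalidDocumentError):
            store.save_study(sid, broken, sha, "alice")
        assert store.fetch_study(sid)[1] == r0.new_sha

    def test_happy_path_save_advances_primary(self, store):
        sid, _ = store.create_study(tiny(1), "alice")
        doc, sha = store.fetch_study(sid)
        response = store.save_study(sid, edit_year(doc, 2001), sha, "alice",
                                    "fix year")
        assert response.merged
        assert store.fetch_study(sid)[1] == response.new_sha

    def test_unknown_parent_sha(self, store):
        sid, _ = store.create_study(tiny(1), "alice")
        doc, _ = store.fetch_study(sid)
        with pytest.raises(ps.StoreError):
            store.save_study(sid, doc, "0" * 40, "alice")


class TestMergeSemantics:
    def test_concurrent_same_study_saves(self, store):
        """Two curators save the same study from one parent: the first
        merges, the second is parked on a surviving WIP branch."""
        sid, _ = store.create_study(tiny(1), "alice")
        doc, sha = store.fetch_study(sid)
        first = store.save_study(sid, edit_year(doc, 2001), sha, "alice")
        second = store.save_study(sid, edit_year(doc, 2002), sha, "bob")
        assert first.merged
        assert not second.merged
        assert second.wip_branch is not None
        branches = _git_out(store.shards[0], "branch", "--list",
                            "--format=%(refname:short)")
        assert second.wip_branch in branches.split()
        # The deferred edit is reachable from its branch (no data loss) ...
        assert _git_out(store.shards[0], "rev-parse",
                        second.wip_branch) == second.new_sha
        # ... but the primary branch still carries the first edit.
        current, _ = store.fetch_study(sid)
        assert current.nexml["^ot:studyYear"] == 2001

    def test_concurrent_different_study_saves_both_merge(self, store):
        sid1, _ = store.create_study(tiny(1), "alice")
        sid2, _ = store.create_study(tiny(2), "bob")
        doc1, sha1 = store.fetch_study(sid1)
        doc2, sha2 = store.fetch_study(sid2)
        r1 = store.save_study(sid1, edit_year(doc1, 2001), sha1, "alice")
        r2 = store.save_study(sid2, edit_year(doc2, 2002), sha2, "bob")
        assert r1.merged and r2.merged

    def test_wip_commit_not_in_primary_history(self, store):
        sid, _ = store.create_study(tiny(1), "alice")
        doc, sha = store.fetch_study(sid)
        store.save_study(sid, edit_year(doc, 2001), sha, "alice")
        parked = store.save_study(sid, edit_year(doc, 2002), sha, "bob")
        history_shas = {record.sha for record in store.study_history(sid)}
        assert parked.new_sha not in history_shas

    def test_no_op_save_is_merged_without_commit(self, store):
        sid, r0 = store.create_study(tiny(1), "alice")
        doc, sha = store.fetch_study(sid)
        response = store.save_study(sid, doc, sha, "alice")
        assert response.merged and response.new_sha == r0.new_sha


class TestDelete:
    def test_delete_then_fetch_not_found_history_kept(self, store):
        sid, _ = store.create_study(tiny(1), "alice")
        doc, sha = store.fetch_study(sid)
        store.save_study(sid, edit_year(doc, 2001), sha, "alice")
        _, sha = store.fetch_study(sid)
        response = store.delete_study(sid, sha, "carol", "withdrawn")
        assert response.merged
        with pytest.raises(ps.NotFoundError):
            store.fetch_study(sid)
        history = store.study_history(sid)
        assert len(history) == 3
        assert history[0].author_id == "carol"

    def test_stale_delete_is_parked(self, store):
        sid, _ = store.create_study(tiny(1), "alice")
        doc, sha = store.fetch_study(sid)
        store.save_study(sid, edit_year(doc, 2001), sha, "alice")
        response = store.delete_study(sid, sha, "bob")
        assert not response.merged
        assert response.wip_branch is not None
        store.fetch_study(sid)  # still present on primary

    def test_delete_never_existing(self, store):
        with pytest.raises(ps.NotFoundError):
            store.delete_study("ot_404", "HEAD", "alice")

    def test_deleted_id_is_never_reminted(self, store):
        sid, _ = store.create_study(tiny(1), "alice")
        _, sha = store.fetch_study(sid)
        store.delete_study(sid, sha, "alice")
        assert store.mint_study_id().numeric_suffix == sid.numeric_suffix + 1


class TestHistory:
    def test_create_plus_two_saves(self, store):
        sid, _ = store.create_study(tiny(1), "alice", "deposit")
        for k, author in enumerate(["bob", "carol"], start=1):
            doc, sha = store.fetch_study(sid)
            store.save_study(sid, edit_year(doc, 2000 + k), sha, author,
                            f"edit {k}")
        history = store.study_history(sid)
        assert [h.author_id for h in history] == ["carol", "bob", "alice"]
        assert [h.message for h in history] == ["edit 2", "edit 1", "deposit"]
        assert history[-1].parent_sha == "" or len(history[-1].parent_sha) == 40

    def test_unknown_id_has_no_history(self, store):
        with pytest.raises(ps.NotFoundError):
            store.study_history("ot_12345")


class TestSizeGate:
    def test_small_limit_rejects_oversize_create(self, tmp_path):
        store = ps.DocStore.init(tmp_path / "s", max_file_bytes=4096)
        small = tiny(1, n_otus=2)
        sid, _ = store.create_study(small, "alice")
        big = small.copy()
        big.nexml["^ot:studyNote1"] = "x" * 8192
        head = store.fetch_study(sid)[1]
        with pytest.raises(ps.SizeLimitError):
            store.create_study(big, "alice")
        with pytest.raises(ps.SizeLimitError):
            store.save_study(sid, big, head, "alice")
        # Repository unchanged by the rejections.
        assert store.fetch_study(sid)[1] == head


class TestMirror:
    def test_sync_pushes_working_head_to_remote(self, store, tmp_path):
        bare = tmp_path / "remote.git"
        subprocess.run(["git", "init", "-q", "--bare", "-b", "main", str(bare)],
                       check=True)
        sid, response = store.create_study(tiny(1), "alice")
        result = store.sync_mirror_and_push(str(bare))
        assert result.ok
        remote_head = subprocess.run(
            ["git", "-C", str(bare), "rev-parse", "main"],
            capture_output=True, text=True, check=True).stdout.strip()
        assert remote_head == response.new_sha
        # Idempotent second sync.
        assert store.sync_mirror_and_push(str(bare)).ok

    def test_failed_push_leaves_working_repo_usable(self, store, tmp_path):
        store.create_study(tiny(1), "alice")
        result = store.sync_mirror_and_push(str(tmp_path / "missing.git"))
        assert not result.ok
        sid, response = store.create_study(tiny(2), "bob")
        assert response.merged  # saving was never blocked by pushing


class TestReconstructibility:
    def test_independent_clone_sees_identical_content(self, store, tmp_path):
        sid, _ = store.create_study(tiny(1), "alice")
        clone = tmp_path / "independent"
        subprocess.run(["git", "clone", "-q", str(store.shards[0]), str(clone)],
                       check=True)
        text = (clone / ps.shard_path(sid)).read_text(encoding="utf-8")
        doc, _ = store.fetch_study(sid)
        assert text == ps.canonical_serialize(doc)
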