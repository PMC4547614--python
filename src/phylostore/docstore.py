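"""Sharded, git-backed document store: CRUD as commits.

Every create/update/delete is a git commit authored by the curator, so the
full provenance of each study — who changed what, when, and why — is
carried by ordinary version control.  A save lands first on a
work-in-progress (WIP) branch forked from the parent SHA the client was
given at fetch time; if the study's file is unchanged on the primary branch
since that parent, the branch is merged immediately and deleted, otherwise
it is retained (merged=False) for manual resolution.  Studies are bucketed
on disk by id prefix plus the last two digits of the numeric suffix, e.g.
study ``ot_211`` lives at ``study/ot_11/ot_211/ot_211.json``.

All commit-creating operations on one shard are serialized behind a
per-repository lock, so the parent of every commit equals the branch head
observed when the operation began.
"""

from __future__ import annotations

import json
import re
import subprocess
import threading
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path, PurePosixPath

from .canonical import canonical_serialize
from .errors import (
    InvalidDocumentError,
    NotFoundError,
    SizeLimitError,
    StoreError,
)
from .model import NexsonDocument

PRIMARY_BRANCH = "main"
DEFAULT_MAX_FILE_BYTES = 20 * 2**20  # 20 MiB commit-size cap
SHARD_CONFIG_NAME = "shard_config.json"

_STUDY_ID_RE = re.compile(r"([a-z]+(?:_[a-z]+)*_)(\d+)\Z")

# One lock per repository path; serializes all mutating git operations.
_REPO_LOCKS: dict[str, threading.RLock] = {}
_REPO_LOCKS_GUARD = threading.Lock()


def _lock_for(repo: Path) -> threading.RLock:
    key = str(repo.resolve())
    with _REPO_LOCKS_GUARD:
        return _REPO_LOCKS.setdefault(key, threading.RLock())


# ---------------------------------------------------------------------------
# identifiers and paths
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class StudyId:
    """Prefixed study identifier, e.g. ``ot_211`` or ``pg_5``."""

    prefix: str
    numeric_suffix: int

    def __post_init__(self):
        if not re.fullmatch(r"[a-z]+(?:_[a-z]+)*_", self.prefix):
            raise StoreError(f"malformed id prefix {self.prefix!r}")
        if self.numeric_suffix < 0:
            raise StoreError("numeric suffix must be non-negative")

    def __str__(self) -> str:
        return f"{self.prefix}{self.numeric_suffix}"

    @classmethod
    def parse(cls, text: str) -> "StudyId":
        match = _STUDY_ID_RE.fullmatch(text)
        if not match:
            raise StoreError(f"malformed study id {text!r}")
        return cls(match.group(1), int(match.group(2)))


def shard_path(study_id: StudyId | str) -> str:
    """Deterministic repository-relative path of a study's file.

    The bucket directory is the id prefix plus the last two digits of the
    numeric suffix, zero-padded for suffixes shorter than two digits:
    ``ot_211`` → ``study/ot_11/ot_211/ot_211.json``.
    """
    sid = StudyId.parse(study_id) if isinstance(study_id, str) else study_id
    bucket = f"{sid.prefix}{sid.numeric_suffix % 100:02d}"
    return str(PurePosixPath("study") / bucket / str(sid) / f"{sid}.json")


def process_change_event(payload) -> set[StudyId]:
    """Study ids named by a push-event payload of changed file paths.

    The file-name portion of each study path is the study id, so extracting
    the affected ids needs no repository access; non-study paths are
    ignored and duplicates collapse.
    """
    out: set[StudyId] = set()
    for path in payload:
        parts = PurePosixPath(path).parts
        if len(parts) != 4 or parts[0] != "study" or not parts[3].endswith(".json"):
            continue
        stem = parts[3][: -len(".json")]
        if stem != parts[2]:
            continue
        try:
            out.add(StudyId.parse(stem))
        except StoreError:
            continue
    return out


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommitRecord:
    sha: str
    parent_sha: str
    author_id: str
    message: str
    timestamp: datetime


@dataclass(frozen=True)
class StoreResponse:
    """Outcome of a mutating operation: whether it reached the primary
    branch, the SHA a client should use as the next parent, and — for
    deferred merges — the surviving WIP branch name."""

    merged: bool
    new_sha: str
    wip_branch: str | None = None


@dataclass(frozen=True)
class PushResult:
    ok: bool
    detail: str = ""


@dataclass
class StoreConfig:
    shard_paths: list[str] = field(default_factory=list)
    id_prefix: str = "ot_"
    max_file_bytes: int = DEFAULT_MAX_FILE_BYTES
    mirror_path: str | None = None
    primary_branch: str = PRIMARY_BRANCH

    @classmethod
    def load(cls, path) -> "StoreConfig":
        with open(path, "r", encoding="utf-8") as handle:
            return cls(**json.load(handle))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.__dict__, handle, indent=1)
            handle.write("\n")


# ---------------------------------------------------------------------------
# git plumbing
# ---------------------------------------------------------------------------


def _git(repo, *args, check: bool = True, ok_codes=(0,)) -> tuple[int, str, str]:
    cmd = ["git", "-C", str(repo),
           "-c", "user.name=phylostore", "-c", "user.email=phylostore@localhost",
           *args]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if check and proc.returncode not in ok_codes:
        raise StoreError(
            f"git {' '.join(args)} failed ({proc.returncode}): {proc.stderr.strip()}")
    return proc.returncode, proc.stdout, proc.stderr


def _git_out(repo, *args) -> str:
    return _git(repo, *args)[1].strip()


def _rev_parse(repo, ref: str) -> str | None:
    code, out, _ = _git(repo, "rev-parse", "--verify", "--quiet", ref, check=False)
    return out.strip() if code == 0 else None


class DocStore:
    """The document store over one or more shard repositories.

    The first shard mints ids for ``config.id_prefix``; reads locate a study
    in whichever shard holds it.
    """

    def __init__(self, config: StoreConfig):
        if not config.shard_paths:
            raise StoreError("store config names no shard repositories")
        self.config = config
        self.shards = [Path(p) for p in config.shard_paths]
        for shard in self.shards:
            if not (shard / ".git").exists():
                raise StoreError(f"{shard} is not a git repository")

    # -- setup ---------------------------------------------------------------

    @classmethod
    def init(cls, root, id_prefix: str = "ot_",
             max_file_bytes: int = DEFAULT_MAX_FILE_BYTES) -> "DocStore":
        """Create a fresh single-shard store under *root*."""
        root = Path(root)
        shard = root / "shard"
        shard.mkdir(parents=True, exist_ok=True)
        _git(shard, "init", "-q", "-b", PRIMARY_BRANCH)
        (shard / "study").mkdir(exist_ok=True)
        with open(shard / SHARD_CONFIG_NAME, "w", encoding="utf-8") as handle:
            json.dump({"id_prefix": id_prefix}, handle)
            handle.write("\n")
        _git(shard, "add", SHARD_CONFIG_NAME)
        _git(shard, "commit", "-q", "-m", "initialize shard")
        config = StoreConfig(shard_paths=[str(shard)], id_prefix=id_prefix,
                             max_file_bytes=max_file_bytes,
                             mirror_path=str(root / "mirror"))
        return cls(config)

    # -- internals -----------------------------------------------------------

    @property
    def primary(self) -> str:
        return self.config.primary_branch

    def _shard_of(self, sid: StudyId) -> Path | None:
        path = shard_path(sid)
        for shard in self.shards:
            if _rev_parse(shard, f"{self.primary}:{path}"):
                return shard
        return None

    def _checkout_primary(self, shard: Path) -> None:
        head = _git_out(shard, "symbolic-ref", "--quiet", "--short", "HEAD")
        if head != self.primary:
            _git(shard, "checkout", "-q", self.primary)

    def _prepare_text(self, doc: NexsonDocument) -> str:
        # Rejection (invalid or oversize) precedes any commit.
        report = doc.validate()
        if not report.is_valid:
            raise InvalidDocumentError(report)
        text = canonical_serialize(doc)
        size = len(text.encode("utf-8"))
        if size > self.config.max_file_bytes:
            raise SizeLimitError(size, self.config.max_file_bytes)
        return text

    @staticmethod
    def _author(author_id: str) -> str:
        return f"{author_id} <{author_id}@curators.invalid>"

    def _known_study_ids(self) -> dict[str, set[StudyId]]:
        """All study ids present on any branch, grouped by prefix.

        WIP-only studies count — an id parked on an unmerged branch must
        never be re-minted — and so do ids of deleted studies, whose history
        would otherwise be inherited by an unrelated new study.
        """
        out: dict[str, set[StudyId]] = {}
        for shard in self.shards:
            _, refs, _ = _git(shard, "for-each-ref", "--format=%(refname:short)",
                              "refs/heads")
            for ref in refs.split():
                code, listing, _ = _git(shard, "ls-tree", "-r", "--name-only",
                                        ref, "study", check=False)
                if code != 0:
                    continue
                for sid in process_change_event(listing.splitlines()):
                    out.setdefault(sid.prefix, set()).add(sid)
            # Every path ever added on any branch (catches deleted studies).
            _, added, _ = _git(shard, "log", "--all", "--diff-filter=A",
                               "--name-only", "--format=", check=False)
            for sid in process_change_event(added.splitlines()):
                out.setdefault(sid.prefix, set()).add(sid)
        return out

    # -- operations ----------------------------------------------------------

    def mint_study_id(self) -> StudyId:
        """Next unused id for the configured prefix (max existing + 1).

        Inspecting the shards, including WIP branches, is what guarantees
        uniqueness; :meth:`create_study` mints under the store lock so
        concurrent creates cannot collide.
        """
        with _lock_for(self.shards[0]):
            known = self._known_study_ids().get(self.config.id_prefix, set())
            top = max((sid.numeric_suffix for sid in known), default=0)
            return StudyId(self.config.id_prefix, top + 1)

    def create_study(self, doc: NexsonDocument, author_id: str,
                     message: str | None = None) -> tuple[StudyId, StoreResponse]:
        """Mint an id and commit the study to the primary branch."""
        shard = self.shards[0]
        with _lock_for(shard):
            text = self._prepare_text(doc)
            sid = self.mint_study_id()
            self._checkout_primary(shard)
            rel = shard_path(sid)
            target = shard / rel
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_text(text, encoding="utf-8")
            _git(shard, "add", rel)
            _git(shard, "commit", "-q", "--no-verify",
                 "--author", self._author(author_id),
                 "-m", message or f"create study {sid}")
            return sid, StoreResponse(merged=True,
                                      new_sha=_rev_parse(shard, "HEAD"))

    def fetch_study(self, study_id: StudyId | str) -> tuple[NexsonDocument, str]:
        """Read a study from the primary branch.

        Returns the document and the primary-branch head SHA, which the
        client must hand back as ``parent_sha`` on a later save.
        """
        sid = StudyId.parse(study_id) if isinstance(study_id, str) else study_id
        shard = self._shard_of(sid)
        if shard is None:
            raise NotFoundError(f"study {sid} not found on branch {self.primary}")
        text = _git_out(shard, "show", f"{self.primary}:{shard_path(sid)}")
        return NexsonDocument.loads(text), _rev_parse(shard, self.primary)

    def _wip_save(self, sid: StudyId, parent_sha: str, author_id: str,
                  message: str, mutate) -> StoreResponse:
        """Shared WIP-branch commit/merge machinery for save and delete.

        *mutate(shard, rel)* applies the change to the checked-out WIP
        branch and returns False when there is nothing to commit.
        """
        shard = self._shard_of(sid) or self.shards[0]
        rel = shard_path(sid)
        with _lock_for(shard):
            if _rev_parse(shard, f"{parent_sha}^{{commit}}") is None:
                raise StoreError(f"unknown parent SHA {parent_sha!r}")
            wip = f"{sid}_{author_id}_{parent_sha[:7]}"
            suffix = 2
            while _rev_parse(shard, f"refs/heads/{wip}") is not None:
                wip = f"{sid}_{author_id}_{parent_sha[:7]}_{suffix}"
                suffix += 1
            _git(shard, "branch", wip, parent_sha)
            _git(shard, "checkout", "-q", wip)
            try:
                changed = mutate(shard, rel)
                if not changed:
                    _git(shard, "checkout", "-q", self.primary)
                    _git(shard, "branch", "-D", wip)
                    return StoreResponse(merged=True,
                                         new_sha=_rev_parse(shard, self.primary))
                _git(shard, "commit", "-q", "--no-verify",
                     "--author", self._author(author_id), "-m", message)
                wip_sha = _rev_parse(shard, "HEAD")
                blob_at_parent = _rev_parse(shard, f"{parent_sha}:{rel}")
                blob_on_primary = _rev_parse(shard, f"{self.primary}:{rel}")
                _git(shard, "checkout", "-q", self.primary)
                if blob_at_parent == blob_on_primary:
                    _git(shard, "merge", "-q", "--no-edit", wip)
                    _git(shard, "branch", "-d", wip)
                    return StoreResponse(merged=True,
                                         new_sha=_rev_parse(shard, self.primary))
                return StoreResponse(merged=False, new_sha=wip_sha, wip_branch=wip)
            except Exception:
                self._checkout_primary(shard)
                raise

    def save_study(self, study_id: StudyId | str, doc: NexsonDocument,
                   parent_sha: str, author_id: str,
                   message: str | None = None) -> StoreResponse:
        """Commit an edited study on a WIP branch and merge it if safe.

        The merge happens only when the study's file is unchanged on the
        primary branch since ``parent_sha``; concurrent edits to *other*
        studies never block a merge.  A deferred merge is a normal outcome,
        not an error: the data are saved on the retained WIP branch.
        """
        sid = StudyId.parse(study_id) if isinstance(study_id, str) else study_id
        text = self._prepare_text(doc)

        def mutate(shard: Path, rel: str) -> bool:
            target = shard / rel
            target.parent.mkdir(parents=True, exist_ok=True)
            if target.exists() and target.read_text(encoding="utf-8") == text:
                return False
            target.write_text(text, encoding="utf-8")
            _git(shard, "add", rel)
            return True

        return self._wip_save(sid, parent_sha, author_id,
                              message or f"update study {sid}", mutate)

    def delete_study(self, study_id: StudyId | str, parent_sha: str,
                     author_id: str, message: str | None = None) -> StoreResponse:
        """Remove a study with a commit; its history remains retrievable."""
        sid = StudyId.parse(study_id) if isinstance(study_id, str) else study_id
        if self._shard_of(sid) is None:
            raise NotFoundError(f"study {sid} not found on branch {self.primary}")

        def mutate(shard: Path, rel: str) -> bool:
            code, _, _ = _git(shard, "rm", "-q", "-r", str(PurePosixPath(rel).parent),
                              check=False)
            return code == 0

        return self._wip_save(sid, parent_sha, author_id,
                              message or f"delete study {sid}", mutate)

    def study_history(self, study_id: StudyId | str) -> list[CommitRecord]:
        """Newest-first commits that touched the study's file on the primary
        branch, each carrying the curator id and message."""
        sid = StudyId.parse(study_id) if isinstance(study_id, str) else study_id
        rel = shard_path(sid)
        records: list[CommitRecord] = []
        for shard in self.shards:
            _, out, _ = _git(shard, "log", self.primary,
                             "--format=%H%x1f%P%x1f%an%x1f%aI%x1f%s",
                             "--", rel, check=False)
            for line in out.splitlines():
                sha, parents, author, stamp, subject = line.split("\x1f")
                records.append(CommitRecord(
                    sha=sha, parent_sha=parents.split(" ")[0] if parents else "",
                    author_id=author, message=subject,
                    timestamp=datetime.fromisoformat(stamp)))
            if records:
                return records
        raise NotFoundError(f"study {sid} has no history in any shard")

    # -- mirroring -----------------------------------------------------------

    def sync_mirror_and_push(self, remote: str) -> PushResult:
        """Fast-forward the mirror clone to the working head, then push.

        Pushing happens only from the mirror, so the working repository
        keeps accepting saves while a (possibly slow or failing) push is in
        flight.  *remote* may be a configured remote name or a git URL/path
        (a local bare repository in tests).
        """
        shard = self.shards[0]
        mirror = Path(self.config.mirror_path or f"{shard}_mirror")
        if not (mirror / ".git").exists():
            mirror.parent.mkdir(parents=True, exist_ok=True)
            code, _, err = _git(shard.parent, "clone", "-q", "-b", self.primary,
                                str(shard), str(mirror), check=False)
            if code != 0:
                return PushResult(False, f"mirror clone failed: {err.strip()}")
        code, _, err = _git(mirror, "fetch", "-q", "origin", check=False)
        if code != 0:
            return PushResult(False, f"mirror fetch failed: {err.strip()}")
        code, _, err = _git(mirror, "merge", "-q", "--ff-only",
                            f"origin/{self.primary}", check=False)
        if code != 0:
            return PushResult(False, f"mirror fast-forward failed: {err.strip()}")
        code, _, err = _git(mirror, "push", "-q", remote,
                            f"{self.primary}:{self.primary}", check=False)
        if code != 0:
            return PushResult(False, f"push failed: {err.strip()}")
        return PushResult(True, "")
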