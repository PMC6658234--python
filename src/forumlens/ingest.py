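"""Reading comment archives and building the per-forum indices.

The input format is the JSON-lines schema of public comment-archive dumps:
one JSON object per line carrying at least an author name, a forum
(subreddit) name, a thread link id, a UTC timestamp and the comment body.
Field names are remapped through :class:`SchemaConfig`, so dumps with other
spellings can be ingested unchanged.

Inclusion rules applied here:

* a fixed calendar-month date window (both ends inclusive, UTC);
* platform service accounts (``AutoModerator``) and deleted-account
  placeholders (``[deleted]``) are dropped before any counting;
* forums enter the analysis only when matched by a search-term scan of
  their name/description and not private, and only when at least
  ``min_commenters`` distinct accounts commented within the window.

Forum names are compared case-insensitively (display names vary in case);
commenter names are case-sensitive identities.
"""

from __future__ import annotations

import calendar
import csv
import gzip
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set

log = logging.getLogger(__name__)

#: Accounts excluded from every count and every downstream structure.
DEFAULT_EXCLUDED_AUTHORS = frozenset({"AutoModerator", "[deleted]"})

#: Forums below this many distinct commenters are dropped from the analysis.
DEFAULT_MIN_COMMENTERS = 500

# Type aliases for the two indices every later stage consumes.
CommenterIndex = Dict[str, Set[str]]
ThreadIndex = Dict[str, Dict[str, List[str]]]


@dataclass(frozen=True, slots=True)
class CommentRecord:
    """One comment event from the archive."""

    author: str
    forum: str
    thread_id: str
    created_utc: int
    body: str


@dataclass(frozen=True, slots=True)
class ForumMeta:
    """Forum metadata row: name, short description, privacy flag."""

    name: str
    description: str = ""
    is_private: bool = False


@dataclass(frozen=True, slots=True)
class SchemaConfig:
    """Maps source field names in the dump to :class:`CommentRecord` fields.

    Defaults match public Reddit comment archives.
    """

    author: str = "author"
    forum: str = "subreddit"
    thread_id: str = "link_id"
    created_utc: str = "created_utc"
    body: str = "body"


class ArchiveReader:
    """Iterable over :class:`CommentRecord` parsed from a JSON-lines file.

    Malformed lines (bad JSON, missing mapped fields, empty key fields) are
    skipped with a warning and tallied in :attr:`skipped`; an unreadable
    file raises. Files ending in ``.gz`` are decompressed transparently.
    """

    def __init__(self, path: str | Path, schema: SchemaConfig | None = None):
        self.path = Path(path)
        self.schema = schema or SchemaConfig()
        self.skipped = 0
        self.read = 0
        if not self.path.exists():
            raise FileNotFoundError(self.path)

    def _open(self):
        if self.path.suffix == ".gz":
            return gzip.open(self.path, "rt", encoding="utf-8")
        return open(self.path, "rt", encoding="utf-8")

    def __iter__(self) -> Iterator[CommentRecord]:
        s = self.schema
        with self._open() as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    rec = CommentRecord(
                        author=str(obj[s.author]),
                        forum=str(obj[s.forum]),
                        thread_id=str(obj[s.thread_id]),
                        created_utc=int(obj[s.created_utc]),
                        body=str(obj[s.body]),
                    )
                    if not rec.author or not rec.forum or not rec.thread_id:
                        raise ValueError("empty key field")
                except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                    self.skipped += 1
                    log.warning("skipping line %d of %s: %s", lineno, self.path, exc)
                    continue
                self.read += 1
                yield rec


def read_comment_archive(
    path: str | Path, schema_config: SchemaConfig | None = None
) -> ArchiveReader:
    """Open a JSON-lines comment archive for streaming.

    Returns an :class:`ArchiveReader`; consume it to stream records, then
    inspect ``.skipped`` for the count of malformed lines.
    """
    return ArchiveReader(path, schema_config)


def _month_epoch_bounds(start_month: str, end_month: str) -> tuple[int, int]:
    """Epoch seconds of the first second of ``start_month`` and the last
    second of ``end_month`` (both "YYYY-MM", UTC)."""
    try:
        sy, sm = (int(p) for p in start_month.split("-"))
        ey, em = (int(p) for p in end_month.split("-"))
    except ValueError as exc:
        raise ValueError(f"month must be 'YYYY-MM': {exc}") from exc
    if (ey, em) < (sy, sm):
        raise ValueError(
            f"window end {end_month!r} precedes window start {start_month!r}"
        )
    lo = int(datetime(sy, sm, 1, tzinfo=timezone.utc).timestamp())
    last_day = calendar.monthrange(ey, em)[1]
    hi = int(
        datetime(ey, em, last_day, 23, 59, 59, tzinfo=timezone.utc).timestamp()
    )
    return lo, hi


def filter_records(
    records: Iterable[CommentRecord],
    window_start: str,
    window_end: str,
    excluded_authors: Iterable[str] = DEFAULT_EXCLUDED_AUTHORS,
) -> List[CommentRecord]:
    """Keep records inside the calendar-month window with includable authors.

    ``window_start``/``window_end`` are "YYYY-MM"; both months are included
    in full (UTC). Author comparison against ``excluded_authors`` is exact
    and case-sensitive.
    """
    lo, hi = _month_epoch_bounds(window_start, window_end)
    excluded = set(excluded_authors)
    return [
        r
        for r in records
        if lo <= r.created_utc <= hi and r.author not in excluded
    ]


def discover_forums(
    forum_metas: Iterable[ForumMeta],
    search_terms: Sequence[str],
    manual_exclusions: Iterable[str] = (),
) -> List[str]:
    """Forums whose name or description matches any search term.

    Matching is case-insensitive substring over name and description.
    Private forums and manually excluded names (topically unrelated hits)
    are removed. Result is deterministic: sorted by name.
    """
    if not search_terms:
        raise ValueError("search_terms must be non-empty")
    terms = [t.casefold() for t in search_terms]
    excluded = {e.casefold() for e in manual_exclusions}
    hits = []
    for meta in forum_metas:
        if meta.is_private or meta.name.casefold() in excluded:
            continue
        text = f"{meta.name} {meta.description}".casefold()
        if any(t in text for t in terms):
            hits.append(meta.name)
    return sorted(hits)


def apply_min_commenter_threshold(
    commenter_index: CommenterIndex, min_commenters: int = DEFAULT_MIN_COMMENTERS
) -> List[str]:
    """Forums with at least ``min_commenters`` distinct included commenters."""
    if min_commenters < 1:
        raise ValueError("min_commenters must be >= 1")
    return sorted(
        f for f, s in commenter_index.items() if len(s) >= min_commenters
    )


def build_indices(
    records: Iterable[CommentRecord],
    forum_whitelist: Optional[Iterable[str]] = None,
) -> tuple[CommenterIndex, ThreadIndex]:
    """Build the commenter and thread indices from (already filtered) records.

    ``forum_whitelist`` restricts to the given forums (case-insensitive
    name match); without it every forum observed in the records appears.
    """
    allowed = (
        {f.casefold() for f in forum_whitelist}
        if forum_whitelist is not None
        else None
    )
    commenters: CommenterIndex = {}
    threads: ThreadIndex = {}
    for rec in records:
        if allowed is not None and rec.forum.casefold() not in allowed:
            continue
        commenters.setdefault(rec.forum, set()).add(rec.author)
        threads.setdefault(rec.forum, {}).setdefault(rec.thread_id, []).append(
            rec.body
        )
    return commenters, threads


def read_forum_metadata_csv(path: str | Path) -> List[ForumMeta]:
    """Read forum metadata from CSV with columns name, description, is_private."""
    metas = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            metas.append(
                ForumMeta(
                    name=row["name"],
                    description=row.get("description", "") or "",
                    is_private=str(row.get("is_private", "")).strip().lower()
                    in {"1", "true", "yes"},
                )
            )
        names = [m.name.casefold() for m in metas]
        if len(names) != len(set(names)):
            raise ValueError("forum names not unique under case-folding")
    return metas


def write_commenter_index_csv(index: CommenterIndex, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["forum", "commenter"])
        for forum in sorted(index):
            for name in sorted(index[forum]):
                w.writerow([forum, name])


def write_thread_index_csv(index: ThreadIndex, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["forum", "thread_id", "n_comments"])
        for forum in sorted(index):
            for tid in sorted(index[forum]):
                w.writerow([forum, tid, len(index[forum][tid])])
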