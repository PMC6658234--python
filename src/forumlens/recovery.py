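"""Recovery-focus text mining.

A forum's recovery focus is the percentage of its comment threads in which
at least one comment mentions a recovery term (``recovery``, ``recover``,
``recovers``, ``recovered``, ``recovering``). Matching is whole-word and
case-insensitive, with words delimited by non-alphanumeric characters: the
term list enumerates inflections explicitly, so ``irrecoverable`` must not
count while ``Recovery!`` must.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

from ._util import pct2

DEFAULT_RECOVERY_TERMS = (
    "recovery",
    "recover",
    "recovers",
    "recovered",
    "recovering",
)


def _term_pattern(terms: Sequence[str]) -> re.Pattern:
    if not terms:
        raise ValueError("term list must be non-empty")
    alts = "|".join(re.escape(t) for t in terms)
    # custom boundaries: underscores and other punctuation delimit words
    return re.compile(rf"(?<![A-Za-z0-9])(?:{alts})(?![A-Za-z0-9])", re.IGNORECASE)


@dataclass(frozen=True, slots=True)
class RecoveryEntry:
    """Per-forum recovery-focus result."""

    forum: str
    threads_total: int
    threads_with_term: int
    percentage: float  # 100 * ratio at 2 decimals, half-up


def recovery_focus(
    forum: str,
    threads: Mapping[str, Sequence[str]],
    term_list: Sequence[str] = DEFAULT_RECOVERY_TERMS,
) -> RecoveryEntry:
    """Score one forum from its thread -> comment-bodies mapping.

    A thread counts if any of its comments contains any term as a whole
    word, case-insensitively. Raises for a forum with no threads (the
    percentage is undefined).
    """
    if not threads:
        raise ValueError(f"forum {forum!r} has no threads; percentage undefined")
    pat = _term_pattern(term_list)
    hits = sum(
        1
        for bodies in threads.values()
        if any(pat.search(body) for body in bodies)
    )
    return RecoveryEntry(
        forum=forum,
        threads_total=len(threads),
        threads_with_term=hits,
        percentage=pct2(hits, len(threads)),
    )


def recovery_report(
    thread_index: Mapping[str, Mapping[str, Sequence[str]]],
    term_list: Sequence[str] = DEFAULT_RECOVERY_TERMS,
) -> List[RecoveryEntry]:
    """Recovery focus for every forum in a thread index, sorted by name."""
    return [
        recovery_focus(forum, thread_index[forum], term_list)
        for forum in sorted(thread_index)
    ]


def recovery_focus_difference(
    report_a: RecoveryEntry, report_b: RecoveryEntry
) -> float:
    """Signed percentage-point difference (a minus b)."""
    return report_a.percentage - report_b.percentage


def write_recovery_csv(entries: Sequence[RecoveryEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["forum", "threads_total", "threads_with_term", "percentage"])
        for e in entries:
            w.writerow(
                [e.forum, e.threads_total, e.threads_with_term, f"{e.percentage:.2f}"]
            )
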