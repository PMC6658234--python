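"""Commenter-overlap accounting between detected communities.

Once forums are partitioned into communities, each community has a
commenter set (everyone who posted on at least one of its forums) and
those sets overlap. This module computes the exhaustive Venn-style region
counts (how many commenters belong to exactly each subset of communities),
exclusive/both summaries for two groups of communities, per-community
participation percentages, and the coverage of a subtype's commenters by a
selected forum list. A bot-name prevalence report supports the
conservative "flag, don't filter" treatment of automated accounts.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass
from itertools import chain, combinations
from pathlib import Path
from typing import Dict, FrozenSet, Hashable, Iterable, List, Mapping, Sequence, Set

from ._util import pct2, round2


@dataclass
class VennPartition:
    """Disjoint region counts over the union of the community sets.

    ``regions`` maps each non-empty subset of community labels to the
    number of commenters belonging to exactly that subset; the counts sum
    to ``universe_size`` (the union's size).
    """

    universe_size: int
    regions: Dict[FrozenSet[Hashable], int]

    def count(self, *labels: Hashable) -> int:
        return self.regions[frozenset(labels)]

    def _key(self, region: FrozenSet[Hashable]) -> str:
        return "&".join(str(l) for l in sorted(region, key=str))

    def to_json(self, path: str | Path) -> None:
        data = {
            self._key(r): c
            for r, c in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), self._key(kv[0])))
        }
        Path(path).write_text(
            json.dumps({"universe_size": self.universe_size, "regions": data}, indent=2)
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "count"])
            for r in sorted(self.regions, key=lambda r: (len(r), self._key(r))):
                w.writerow([self._key(r), self.regions[r]])


def community_commenter_sets(
    partition_membership: Mapping[str, Hashable],
    commenter_index: Mapping[str, Set[str]],
) -> Dict[Hashable, Set[str]]:
    """Community label -> union of its member forums' commenter sets."""
    sets: Dict[Hashable, Set[str]] = {}
    for forum, label in partition_membership.items():
        sets.setdefault(label, set()).update(commenter_index[forum])
    return sets


def venn_partition(
    community_sets: Mapping[Hashable, Set[str]]
) -> VennPartition:
    """Exact counts for all 2^k - 1 membership regions.

    Classifies every commenter in the union by the exact subset of
    communities they posted in. Intended for k <= 6 (a drawable Venn);
    larger k still yields the table.
    """
    labels = sorted(community_sets, key=str)
    if not labels:
        raise ValueError("need at least one community")
    universe = set().union(*community_sets.values())
    regions: Dict[FrozenSet[Hashable], int] = {
        frozenset(sub): 0
        for r in range(1, len(labels) + 1)
        for sub in combinations(labels, r)
    }
    for member in universe:
        key = frozenset(l for l in labels if member in community_sets[l])
        regions[key] += 1
    return VennPartition(universe_size=len(universe), regions=regions)


@dataclass(frozen=True, slots=True)
class GroupOverlap:
    """Exclusive/shared commenter counts for two groups of communities."""

    only_a: int
    only_b: int
    both: int
    neither: int
    universe_size: int
    pct_only_a: float
    pct_only_b: float
    pct_both: float


def group_exclusive_counts(
    community_sets: Mapping[Hashable, Set[str]],
    group_a: Sequence[Hashable],
    group_b: Sequence[Hashable],
) -> GroupOverlap:
    """Commenters exclusive to each community group versus shared by both.

    The universe is the union of *all* community sets; percentages are of
    the universe at 2 decimals, half-up. Group definitions must not share
    a community label.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint lists of community labels")
    for label in chain(group_a, group_b):
        if label not in community_sets:
            raise KeyError(f"unknown community label {label!r}")
    universe = set().union(*community_sets.values())
    in_a = set().union(*(community_sets[l] for l in group_a)) if group_a else set()
    in_b = set().union(*(community_sets[l] for l in group_b)) if group_b else set()
    only_a = len(in_a - in_b)
    only_b = len(in_b - in_a)
    both = len(in_a & in_b)
    n = len(universe)
    return GroupOverlap(
        only_a=only_a,
        only_b=only_b,
        both=both,
        neither=n - only_a - only_b - both,
        universe_size=n,
        pct_only_a=pct2(only_a, n),
        pct_only_b=pct2(only_b, n),
        pct_both=pct2(both, n),
    )


def community_participation(
    community_sets: Mapping[Hashable, Set[str]], universe: Set[str]
) -> Dict[Hashable, float]:
    """Per-community percentage of the universe that posted in it.

    Membership is non-exclusive, so the percentages can sum past 100.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    return {
        label: pct2(len(s), len(universe)) for label, s in community_sets.items()
    }


def coverage(
    subtype_set: Set[str], selected_forum_sets: Iterable[Set[str]]
) -> float:
    """Percentage of the subtype's commenters found on the selected forums."""
    if not subtype_set:
        raise ValueError("subtype commenter set is empty")
    union: Set[str] = set()
    for s in selected_forum_sets:
        union |= s
    return pct2(len(subtype_set & union), len(subtype_set))


@dataclass
class BotNameReport:
    """Prevalence of bot-named accounts and their activity summary.

    Accounts whose name contains "bot" (case-insensitive substring) are
    flagged for reporting only — never removed from the analysis.
    """

    n_accounts: int
    n_flagged: int
    percentage: float
    flagged: List[str]
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    min: int | None = None
    max: int | None = None


def bot_name_report(commenter_activity_counts: Mapping[str, int]) -> BotNameReport:
    """Flag bot-named accounts and summarize their comment counts.

    SD is the sample standard deviation (n-1 denominator); mean/SD/median
    are None when no account is flagged.
    """
    flagged = sorted(
        name for name in commenter_activity_counts if "bot" in name.casefold()
    )
    n = len(commenter_activity_counts)
    report = BotNameReport(
        n_accounts=n,
        n_flagged=len(flagged),
        percentage=pct2(len(flagged), n) if n else 0.0,
        flagged=flagged,
    )
    if flagged:
        counts = [commenter_activity_counts[name] for name in flagged]
        report.mean = round2(statistics.fmean(counts))
        report.sd = round2(statistics.stdev(counts)) if len(counts) > 1 else 0.0
        report.median = float(statistics.median(counts))
        report.min = min(counts)
        report.max = max(counts)
    return report
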