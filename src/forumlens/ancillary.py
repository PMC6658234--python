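"""Ancillary-forum profiling for a forum subtype.

Given a subtype (a labelled group of forums) and the full commenter index,
this module finds the *ancillary* forums its commenters also contribute to,
applies the 1% inclusion rule, ranks candidates jointly by subtype-commenter
count and by the proportion of the forum's own commenters that come from
the subtype, selects the top K by mean rank, and builds the
restricted-commenter overlap network (overlaps computed over subtype
commenters only).

The dual ranking balances two failure modes of either criterion alone:
ranking by raw count favours huge general-interest forums where the
subtype is a drop in the ocean, while ranking by proportion favours tiny
forums. The mean of the two ranks (rank 1 = best on each criterion,
fractional ranks for ties) selects forums that are both large and
subtype-dense; "top K" therefore means the K numerically smallest mean
ranks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import pandas as pd

from .overlap import OverlapMatrix, build_overlap_matrix

log = logging.getLogger(__name__)

DEFAULT_INCLUSION_PERCENT = 1.0
DEFAULT_TOP_K = 50


@dataclass
class SubtypeDefinition:
    """A labelled subtype: its member forums and their pooled commenters."""

    label: str
    forums: List[str]
    commenters: Set[str]

    def __post_init__(self):
        if not self.forums:
            raise ValueError("a subtype needs at least one member forum")

    @classmethod
    def from_index(
        cls, label: str, forums: Sequence[str], commenter_index: Mapping[str, Set[str]]
    ) -> "SubtypeDefinition":
        pooled: Set[str] = set()
        for f in forums:
            if f not in commenter_index:
                raise KeyError(f"subtype forum {f!r} missing from commenter index")
            pooled |= commenter_index[f]
        return cls(label=label, forums=list(forums), commenters=pooled)


def ancillary_inclusion_threshold(
    n_subtype_commenters: int, percent: float = DEFAULT_INCLUSION_PERCENT
) -> int:
    """Smallest contributor count meeting the inclusion percentage.

    The smallest integer n with n / n_subtype_commenters >= percent/100,
    i.e. the ceiling of percent% of the subtype size (82 for a subtype of
    8166 at 1%; 16 for 1580).
    """
    if n_subtype_commenters < 1:
        raise ValueError("subtype must have at least one commenter")
    frac = Decimal(str(percent)) / 100
    return int(math.ceil(Decimal(n_subtype_commenters) * frac))


def find_ancillary_forums(
    commenter_index_all: Mapping[str, Set[str]],
    subtype: SubtypeDefinition,
    percent: float = DEFAULT_INCLUSION_PERCENT,
) -> pd.DataFrame:
    """Candidate ancillary forums with contribution counts and proportions.

    Every forum outside the subtype where at least ``percent``% of the
    subtype's commenters contributed. Columns: forum,
    n_subtype_commenters, forum_total_commenters, proportion.
    """
    members = {f.casefold() for f in subtype.forums}
    threshold = ancillary_inclusion_threshold(len(subtype.commenters), percent)
    rows = []
    for forum in sorted(commenter_index_all):
        if forum.casefold() in members:
            continue
        commenters = commenter_index_all[forum]
        n_sub = len(commenters & subtype.commenters)
        if n_sub >= threshold:
            rows.append(
                {
                    "forum": forum,
                    "n_subtype_commenters": n_sub,
                    "forum_total_commenters": len(commenters),
                    "proportion": n_sub / len(commenters),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "forum",
            "n_subtype_commenters",
            "forum_total_commenters",
            "proportion",
        ],
    )


def rank_ancillary_forums(candidates: pd.DataFrame) -> pd.DataFrame:
    """Dual descending ranks and their mean; rank 1 = largest.

    Ties receive the average of the tied rank positions (fractional
    ranking), keeping the mean rank on a stable scale. Output is sorted
    ascending by mean rank, ties broken by forum name.
    """
    if candidates.empty:
        raise ValueError("candidate list is empty")
    df = candidates.copy()
    df["rank_by_count"] = df["n_subtype_commenters"].rank(
        ascending=False, method="average"
    )
    df["rank_by_proportion"] = df["proportion"].rank(ascending=False, method="average")
    df["mean_rank"] = (df["rank_by_count"] + df["rank_by_proportion"]) / 2.0
    df = df.sort_values(["mean_rank", "forum"], kind="mergesort").reset_index(
        drop=True
    )
    return df


def select_top_k(ranking: pd.DataFrame, k: int = DEFAULT_TOP_K) -> List[str]:
    """First ``k`` forums of the sorted ranking (best mean rank first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    forums = list(ranking["forum"])
    if len(forums) < k:
        log.warning(
            "only %d candidates available for top-%d selection; returning all",
            len(forums),
            k,
        )
        return forums
    return forums[:k]


def restricted_overlap_matrix(
    commenter_index_all: Mapping[str, Set[str]],
    forums: Sequence[str],
    subtype_commenters: Set[str],
) -> OverlapMatrix:
    """Overlap matrix over ``forums`` using subtype commenters only.

    Each forum's commenter set is intersected with the subtype's before
    the pairwise mean overlaps are computed, so commenters with no
    connection to the subtype cannot inflate (or dilute) the weights.
    """
    if not subtype_commenters:
        raise ValueError("subtype commenter set is empty")
    restricted: Dict[str, Set[str]] = {}
    for f in forums:
        if f not in commenter_index_all:
            raise KeyError(f"forum {f!r} missing from commenter index")
        r = commenter_index_all[f] & subtype_commenters
        if not r:
            raise ValueError(
                f"forum {f!r} has no commenters from the subtype; "
                "cannot appear in a restricted overlap network"
            )
        restricted[f] = r
    return build_overlap_matrix(restricted, forums)


def write_ranking_tsv(ranking: pd.DataFrame, path) -> None:
    ranking.to_csv(path, sep="\t", index=False)
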