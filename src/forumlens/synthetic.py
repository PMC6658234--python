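"""Seeded synthetic comment archives with known ground truth.

The generator emits the same JSON-lines schema the ingest stage consumes
(author / subreddit / link_id / created_utc / body) together with a
record-exact :class:`GroundTruth`, so every pipeline stage can be tested
without real data. What it emulates:

* planted forum-community structure: each commenter has a home community
  and is active in each other community with probability ``ε``; within an
  active community they post in each forum with probability ``p_member``
  (crossing happens at the community level, so a visitor to a community
  contributes to most of its forums and overlap structure is preserved
  under commenter-set restriction);
* heavy-tailed per-forum activity (bounded Zipf comment counts, minimum
  one comment);
* per-forum recovery-term prevalence: each comment body carries a
  recovery term with the forum's configured probability;
* archive noise: bot-named accounts (ordinary behaviour, distinctive
  names), ``AutoModerator`` service comments and ``[deleted]``
  placeholders. Excluded-account noise is written only into threads that
  already hold a regular comment, with term-free bodies, so the ground
  truth is exact for the post-filter archive.

Identical config + seed produce a byte-identical archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Set, Union

import numpy as np

from .ingest import _month_epoch_bounds
from .recovery import DEFAULT_RECOVERY_TERMS

# Deliberately term-free filler vocabulary; "irrecoverable" exercises the
# whole-word matching rule without containing any term as a word.
_VOCAB = (
    "today meal plan week feeling photo progress thread gym water walk "
    "sleep done habit note goal check update maybe start irrecoverable "
    "coffee scale morning list again help thanks really honestly"
).split()


@dataclass
class CommunityConfig:
    """One planted forum community: its forums and its home commenters."""

    forums: List[str]
    n_commenters: int


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic archive; defaults give strong structure."""

    communities: List[CommunityConfig]
    cross_community_prob: float = 0.05  # ε: visit another community
    member_forum_prob: float = 0.9  # post in a forum of an active community
    activity_zipf_a: float = 2.5  # heavy-tailed extra comments per forum
    max_comments_per_forum: int = 50
    threads_per_forum: int = 40
    recovery_rate: Union[float, Dict[str, float]] = 0.1  # ρ, scalar or per forum
    bot_fraction: float = 0.01
    deleted_fraction: float = 0.01  # [deleted] records per regular record
    automod_per_forum: int = 2
    window_start: str = "2017-03"
    window_end: str = "2018-02"
    seed: int = 0

    def rho(self, forum: str) -> float:
        if isinstance(self.recovery_rate, dict):
            return float(self.recovery_rate.get(forum, 0.0))
        return float(self.recovery_rate)

    def validate(self) -> None:
        if not self.communities:
            raise ValueError("need at least one community")
        forums = [f for c in self.communities for f in c.forums]
        if not forums or len(forums) != len(set(forums)):
            raise ValueError("forums must be non-empty and globally unique")
        probs = [self.cross_community_prob, self.member_forum_prob,
                 self.bot_fraction, self.deleted_fraction]
        if isinstance(self.recovery_rate, dict):
            probs += list(self.recovery_rate.values())
        else:
            probs.append(self.recovery_rate)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(c.n_commenters < 0 for c in self.communities):
            raise ValueError("commenter counts must be >= 0")
        if self.threads_per_forum < 1 or self.max_comments_per_forum < 1:
            raise ValueError("thread and comment counts must be >= 1")
        if self.activity_zipf_a <= 1.0:
            raise ValueError("zipf exponent must exceed 1")
        _month_epoch_bounds(self.window_start, self.window_end)  # raises if bad


@dataclass
class GroundTruth:
    """Record-exact facts about the emitted archive (post-filter view)."""

    forum_community: Dict[str, int]
    forum_commenters: Dict[str, Set[str]]
    thread_recovery: Dict[str, Dict[str, bool]]  # forum -> thread -> has term
    bot_names: Set[str]
    commenter_home: Dict[str, int]
    monthly_counts: Dict[str, int]  # regular records per "YYYY-MM"
    n_regular_records: int
    n_records: int

    def to_json(self, path: str | Path) -> None:
        data = {
            "forum_community": self.forum_community,
            "forum_commenters": {f: sorted(s) for f, s in self.forum_commenters.items()},
            "thread_recovery": self.thread_recovery,
            "bot_names": sorted(self.bot_names),
            "commenter_home": self.commenter_home,
            "monthly_counts": self.monthly_counts,
            "n_regular_records": self.n_regular_records,
            "n_records": self.n_records,
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def _dump(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def generate_archive(config: GeneratorConfig) -> tuple[List[str], GroundTruth]:
    """Generate a JSON-lines archive (list of lines) and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = _month_epoch_bounds(config.window_start, config.window_end)
    terms = DEFAULT_RECOVERY_TERMS

    forums: List[str] = []
    forum_community: Dict[str, int] = {}
    for ci, comm in enumerate(config.communities):
        for f in comm.forums:
            forum_community[f] = ci
            forums.append(f)
    thread_ids = {
        f: [f"t3_{f.casefold()}{j:04d}" for j in range(config.threads_per_forum)]
        for f in forums
    }

    # commenter roster with home communities and bot names
    names: List[str] = []
    commenter_home: Dict[str, int] = {}
    bot_names: Set[str] = set()
    idx = 0
    for ci, comm in enumerate(config.communities):
        for _ in range(comm.n_commenters):
            name = f"user{idx:05d}"
            if rng.random() < config.bot_fraction:
                name += "_bot"
                bot_names.add(name)
            names.append(name)
            commenter_home[name] = ci
            idx += 1

    lines: List[str] = []
    forum_commenters: Dict[str, Set[str]] = {f: set() for f in forums}
    thread_recovery: Dict[str, Dict[str, bool]] = {f: {} for f in forums}
    monthly_counts: Dict[str, int] = {}

    def body_text(with_term: bool) -> str:
        words = [_VOCAB[k] for k in rng.integers(0, len(_VOCAB), size=6)]
        if with_term:
            words.insert(int(rng.integers(0, len(words) + 1)),
                         terms[int(rng.integers(0, len(terms)))])
        return " ".join(words)

    def emit(author: str, forum: str, thread: str, with_term: bool) -> None:
        ts = int(rng.integers(lo, hi + 1))
        lines.append(
            _dump(
                {
                    "author": author,
                    "subreddit": forum,
                    "link_id": thread,
                    "created_utc": ts,
                    "body": body_text(with_term),
                }
            )
        )
        if author not in ("AutoModerator", "[deleted]"):
            forum_commenters[forum].add(author)
            prev = thread_recovery[forum].get(thread, False)
            thread_recovery[forum][thread] = prev or with_term
            month = datetime.fromtimestamp(ts, timezone.utc).strftime("%Y-%m")
            monthly_counts[month] = monthly_counts.get(month, 0) + 1

    n_comm = len(config.communities)
    for name in names:
        home = commenter_home[name]
        active = [home] + [
            c
            for c in range(n_comm)
            if c != home and rng.random() < config.cross_community_prob
        ]
        for ci in active:
            comm = config.communities[ci]
            chosen = [
                f for f in comm.forums if rng.random() < config.member_forum_prob
            ]
            if ci == home and not chosen:
                chosen = [comm.forums[int(rng.integers(0, len(comm.forums)))]]
            for forum in chosen:
                extra = min(
                    int(rng.zipf(config.activity_zipf_a)) - 1,
                    config.max_comments_per_forum - 1,
                )
                rho = config.rho(forum)
                tids = thread_ids[forum]
                for _ in range(1 + extra):
                    thread = tids[int(rng.integers(0, len(tids)))]
                    emit(name, forum, thread, bool(rng.random() < rho))

    n_regular = len(lines)

    # excluded-account noise, only into threads that already exist
    for forum in forums:
        observed = sorted(thread_recovery[forum])
        if not observed:
            continue
        for _ in range(config.automod_per_forum):
            emit(
                "AutoModerator",
                forum,
                observed[int(rng.integers(0, len(observed)))],
                False,
            )
    n_deleted = int(round(config.deleted_fraction * n_regular))
    populated = [f for f in forums if thread_recovery[f]]
    for _ in range(n_deleted if populated else 0):
        forum = populated[int(rng.integers(0, len(populated)))]
        observed = sorted(thread_recovery[forum])
        emit(
            "[deleted]", forum, observed[int(rng.integers(0, len(observed)))], False
        )

    truth = GroundTruth(
        forum_community=forum_community,
        forum_commenters=forum_commenters,
        thread_recovery=thread_recovery,
        bot_names=bot_names,
        commenter_home=commenter_home,
        monthly_counts=monthly_counts,
        n_regular_records=n_regular,
        n_records=len(lines),
    )
    return lines, truth


def write_archive(lines: List[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
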