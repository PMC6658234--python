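import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forumlens.ancillary import (
    SubtypeDefinition,
    ancillary_inclusion_threshold,
    find_ancillary_forums,
    rank_ancillary_forums,
    restricted_overlap_matrix,
    select_top_k,
)


def fractional_ranks_desc(values):
    """Independent oracle: descending fractional (average) ranking."""
    order = sorted(range(len(values)), key=lambda i: -values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestInclusionThreshold:
    @pytest.mark.parametrize("n,expected", [(8166, 82), (1580, 16), (100, 1)])
    def test_printed_thresholds(self, n, expected):
        assert ancillary_inclusion_threshold(n) == expected

    @settings(derandomize=True, max_examples=200)
    @given(n=st.integers(1, 10**6))
    def test_smallest_count_reaching_one_percent(self, n):
        t = ancillary_inclusion_threshold(n)
        assert t / n >= 0.01
        assert (t - 1) / n < 0.01

    def test_configurable_percent(self):
        assert ancillary_inclusion_threshold(1000, percent=2.5) == 25

    def test_empty_subtype_rejected(self):
        with pytest.raises(ValueError):
            ancillary_inclusion_threshold(0)


def make_subtype(n=1580, forums=("edm1", "edm2")):
    commenters = {f"s{i}" for i in range(n)}
    return SubtypeDefinition(label="sub", forums=list(forums),
                             commenters=commenters)


class TestFindAncillaryForums:
    def test_threshold_boundary_and_member_exclusion(self):
        sub = make_subtype(1580)  # inclusion threshold: 16
        index = {
            "edm1": {f"s{i}" for i in range(1000)},
            "edm2": {f"s{i}" for i in range(900, 1580)},
            "below": {f"s{i}" for i in range(15)} | {"out1"},
            "exact": {f"s{i}" for i in range(16)} | {"out2"},
        }
        df = find_ancillary_forums(index, sub)
        assert list(df["forum"]) == ["exact"]
        row = df.iloc[0]
        assert row["n_subtype_commenters"] == 16
        assert row["forum_total_commenters"] == 17
        assert row["proportion"] == pytest.approx(16 / 17)

    def test_planted_candidate_set_matches_ground_truth(self):
        rng = np.random.default_rng(8)
        sub = make_subtype(200, forums=("home",))  # threshold: 2
        index = {"home": set(sub.commenters)}
        expected = set()
        for k in range(30):
            n_sub = int(rng.integers(0, 6))
            members = {f"s{i}" for i in rng.choice(200, n_sub, replace=False)}
            index[f"anc{k:02d}"] = members | {f"other{k}_{i}" for i in range(3)}
            if n_sub >= 2:
                expected.add(f"anc{k:02d}")
        df = find_ancillary_forums(index, sub)
        assert set(df["forum"]) == expected


class TestRanking:
    def test_hand_enumerated_dual_ranks(self):
        candidates = pd.DataFrame(
            {
                "forum": ["A", "B", "C"],
                "n_subtype_commenters": [100, 50, 10],
                "forum_total_commenters": [200, 56, 100],
                "proportion": [0.5, 0.9, 0.1],
            }
        )
        ranked = rank_ancillary_forums(candidates)
        by_forum = ranked.set_index("forum")
        assert by_forum.loc["A", "mean_rank"] == 1.5  # ranks 1 and 2
        assert by_forum.loc["B", "mean_rank"] == 1.5  # ranks 2 and 1
        assert by_forum.loc["C", "mean_rank"] == 3.0
        assert list(ranked["forum"]) == ["A", "B", "C"]  # name breaks the tie

    def test_identical_candidates_share_mean_rank(self):
        candidates = pd.DataFrame(
            {
                "forum": list("abcd"),
                "n_subtype_commenters": [5] * 4,
                "forum_total_commenters": [10] * 4,
                "proportion": [0.5] * 4,
            }
        )
        ranked = rank_ancillary_forums(candidates)
        assert set(ranked["mean_rank"]) == {2.5}

    def test_matches_independent_double_sort_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        counts = rng.integers(1, 400, size=n)
        totals = counts + rng.integers(1, 2000, size=n)
        candidates = pd.DataFrame(
            {
                "forum": [f"f{i:02d}" for i in range(n)],
                "n_subtype_commenters": counts,
                "forum_total_commenters": totals,
                "proportion": counts / totals,
            }
        )
        ranked = rank_ancillary_forums(candidates).set_index("forum")
        rc = fractional_ranks_desc(list(counts))
        rp = fractional_ranks_desc(list(counts / totals))
        for i in range(n):
            f = f"f{i:02d}"
            assert ranked.loc[f, "rank_by_count"] == rc[i]
            assert ranked.loc[f, "rank_by_proportion"] == rp[i]
            assert ranked.loc[f, "mean_rank"] == (rc[i] + rp[i]) / 2

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            rank_ancillary_forums(pd.DataFrame(columns=["forum"]))


class TestSelectTopK:
    def _ranking(self, n=10, seed=4):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 100, size=n)
        totals = counts + rng.integers(1, 500, size=n)
        return rank_ancillary_forums(
            pd.DataFrame(
                {
                    "forum": [f"f{i}" for i in range(n)],
                    "n_subtype_commenters": counts,
                    "forum_total_commenters": totals,
                    "proportion": counts / totals,
                }
            )
        )

    def test_fewer_candidates_than_k_returns_all_with_warning(self, caplog):
        ranking = self._ranking(3)
        with caplog.at_level("WARNING"):
            selected = select_top_k(ranking, 50)
        assert len(selected) == 3
        assert "top-50" in caplog.text

    def test_top_two_of_hand_example(self):
        candidates = pd.DataFrame(
            {
                "forum": ["A", "B", "C"],
                "n_subtype_commenters": [100, 50, 10],
                "forum_total_commenters": [200, 56, 100],
                "proportion": [0.5, 0.9, 0.1],
            }
        )
        assert select_top_k(rank_ancillary_forums(candidates), 2) == ["A", "B"]

    def test_nesting_under_growing_k(self):
        ranking = self._ranking(20)
        for k in range(1, 20):
            assert set(select_top_k(ranking, k)) <= set(
                select_top_k(ranking, k + 1)
            )

    def test_selection_matches_sort_oracle(self):
        ranking = self._ranking(200, seed=9)
        selected = select_top_k(ranking, 50)
        oracle = list(
            ranking.sort_values(["mean_rank", "forum"])["forum"][:50]
        )
        assert selected == oracle


class TestRestrictedOverlap:
    def test_forums_equal_to_subtype_give_all_ones(self):
        sub = {f"s{i}" for i in range(20)}
        index = {"a": set(sub), "b": set(sub), "home": set(sub)}
        m = restricted_overlap_matrix(index, ["a", "b"], sub)
        assert m.weight("a", "b") == 1.0

    def test_disjoint_restricted_sets_give_zero(self):
        sub = {"s1", "s2"}
        index = {"a": {"s1", "x"}, "b": {"s2", "x"}}
        m = restricted_overlap_matrix(index, ["a", "b"], sub)
        assert m.weight("a", "b") == 0.0

    def test_invariant_to_commenters_outside_subtype(self):
        rng = np.random.default_rng(5)
        sub = {f"s{i}" for i in range(30)}
        index = {
            f"f{k}": {f"s{i}" for i in rng.choice(30, 10, replace=False)}
            for k in range(4)
        }
        base = restricted_overlap_matrix(index, sorted(index), sub)
        noisy = {
            f: s | {f"noise{f}{i}" for i in range(int(rng.integers(1, 50)))}
            for f, s in index.items()
        }
        again = restricted_overlap_matrix(noisy, sorted(index), sub)
        assert np.array_equal(base.values, again.values)
        assert np.all(base.values <= 1.0)

    def test_matches_brute_force_on_intersected_sets(self):
        rng = np.random.default_rng(6)
        sub = {f"s{i}" for i in range(40)}
        index = {
            f"f{k}": (
                {f"s{i}" for i in rng.choice(40, int(rng.integers(5, 25)),
                                             replace=False)}
                | {f"o{k}{i}" for i in range(5)}
            )
            for k in range(5)
        }
        forums = sorted(index)
        m = restricted_overlap_matrix(index, forums, sub)
        for i, a in enumerate(forums):
            for j, b in enumerate(forums):
                if i < j:
                    ra, rb = index[a] & sub, index[b] & sub
                    inter = len(ra & rb)
                    expected = (inter / len(ra) + inter / len(rb)) / 2
                    assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_empty_restricted_set_names_forum(self):
        index = {"a": {"s1"}, "b": {"outsider"}}
        with pytest.raises(ValueError, match="'b'"):
            restricted_overlap_matrix(index, ["a", "b"], {"s1"})
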