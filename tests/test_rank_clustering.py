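"""Rank aggregation, FCC similarity, leader clustering and cluster rules."""

import itertools

import numpy as np
import pytest

from ternadock.errors import ConsistencyError
from ternadock.fcc import (
    Cluster,
    ContactSet,
    energy_cluster_filter,
    fcc_cluster,
    fcc_similarity,
    pair_similarity,
)
from ternadock.ranking import (
    aggregate_ranks,
    rank_clusters,
    select_top,
)
from ternadock.scoring import ScoreTable


def contact_set(pid, items):
    return ContactSet(pid, frozenset(("A", i, " ") for i in items))


def full_contact_set(pid, pairs):
    return ContactSet(pid, frozenset(pairs))


class TestAggregateRanks:
    def test_consensus_of_identical_orders(self):
        values = {
            "sasa": {"a": 3.0, "b": 2.0, "c": 1.0},
            "voromqa": {"a": 30.0, "b": 20.0, "c": 10.0},
        }
        assert aggregate_ranks(values).order == ["a", "b", "c"]

    def test_hand_computed_mean_ranks(self):
        # A: sasa-rank 1, quality-rank 3; B: 2, 1; C: 3, 2
        values = {
            "sasa": {"A": 30.0, "B": 20.0, "C": 10.0},
            "voromqa": {"A": 1.0, "B": 9.0, "C": 5.0},
        }
        ranked = aggregate_ranks(values)
        assert ranked.aggregate == {"A": 2.0, "B": 1.5, "C": 2.5}
        assert ranked.order == ["B", "A", "C"]

    def test_full_tie_falls_back_to_pose_id(self):
        values = {
            "sasa": {"z": 1.0, "a": 1.0, "m": 1.0},
            "voromqa": {"z": 2.0, "a": 2.0, "m": 2.0},
        }
        assert aggregate_ranks(values).order == ["a", "m", "z"]

    def test_missing_component_lists_pose_ids(self):
        values = {"sasa": {"a": 1.0, "b": 2.0}, "voromqa": {"a": 1.0}}
        with pytest.raises(ConsistencyError, match="b"):
            aggregate_ranks(values)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(4)
        ids = [f"p{i}" for i in range(25)]
        sasa = dict(zip(ids, rng.normal(size=25)))
        qual = dict(zip(ids, rng.normal(size=25)))
        base = aggregate_ranks({"sasa": sasa, "voromqa": qual}).order
        warped = aggregate_ranks(
            {
                "sasa": {k: np.exp(v) for k, v in sasa.items()},
                "voromqa": {k: v**3 for k, v in qual.items()},
            }
        ).order
        assert base == warped


class TestSelectTop:
    def _ranked(self, n):
        values = {
            "sasa": {f"p{i:04d}": float(n - i) for i in range(n)},
            "voromqa": {f"p{i:04d}": float(n - i) for i in range(n)},
        }
        return aggregate_ranks(values)

    def test_saturation(self):
        ranked = self._ranked(5)
        assert select_top(ranked, 100) == ranked.order

    def test_default_keeps_200(self):
        ranked = self._ranked(500)
        top = select_top(ranked)
        assert len(top) == 200
        assert top == ranked.order[:200]

    def test_head(self):
        assert select_top(self._ranked(5), 1) == ["p0000"]


class TestFccSimilarity:
    def test_identity_and_disjoint(self):
        a = contact_set("a", [1, 2, 3])
        b = contact_set("b", [4, 5])
        assert fcc_similarity(a, a) == 1.0
        assert fcc_similarity(a, b) == 0.0

    def test_asymmetry_and_min_symmetrisation(self):
        a = contact_set("a", ["p", "q", "r", "s"])
        b = contact_set("b", ["p", "q"])
        assert fcc_similarity(a, b) == 0.5
        assert fcc_similarity(b, a) == 1.0
        assert pair_similarity(a, b, "min") == 0.5
        assert pair_similarity(a, b, "max") == 1.0
        assert pair_similarity(a, b, "mean") == 0.75

    def test_empty_set_warns_and_returns_zero(self):
        a = contact_set("a", [])
        b = contact_set("b", [1])
        with pytest.warns(UserWarning):
            assert fcc_similarity(a, b) == 0.0


def brute_force_leader_clusters(sets, threshold, min_size):
    """Independent reference: naive leader clustering with explicit loops."""
    sims = {}
    for a in sets:
        for b in sets:
            inter_ab = len(a.contacts & b.contacts)
            fab = inter_ab / len(a.contacts) if a.contacts else 0.0
            fba = inter_ab / len(b.contacts) if b.contacts else 0.0
            sims[(a.pose_id, b.pose_id)] = min(fab, fba)
    unassigned = sorted(s.pose_id for s in sets)
    clusters = []
    while unassigned:
        best, best_n = None, None
        for pid in unassigned:
            n = [
                q for q in unassigned
                if q != pid and sims[(pid, q)] >= threshold
            ]
            if best is None or len(n) > len(best_n):
                best, best_n = pid, n
        members = [best] + sorted(best_n)
        for m in members:
            unassigned.remove(m)
        clusters.append(members)
    kept = [c for c in clusters if len(c) >= min_size]
    out = sorted(p for c in clusters if len(c) < min_size for p in c)
    return kept, out


class TestFccCluster:
    def test_mutual_clique_forms_single_cluster(self):
        sets = [contact_set(f"p{i}", [1, 2, 3, 4]) for i in range(5)]
        clusters, unclustered = fcc_cluster(sets)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == sorted(s.pose_id for s in sets)
        assert unclustered == []

    def test_all_dissimilar_everything_eliminated(self):
        sets = [contact_set(f"p{i}", [10 * i, 10 * i + 1]) for i in range(4)]
        clusters, unclustered = fcc_cluster(sets, threshold=0.5, min_size=2)
        assert clusters == []
        assert unclustered == [f"p{i}" for i in range(4)]

    def test_two_cliques_and_singleton(self):
        sets = (
            [contact_set(f"a{i}", [1, 2, 3, 4]) for i in range(3)]
            + [contact_set(f"b{i}", [10, 11, 12, 13]) for i in range(3)]
            + [contact_set("lone", [99, 100])]
        )
        clusters, unclustered = fcc_cluster(sets)
        expected, expected_out = brute_force_leader_clusters(sets, 0.5, 2)
        assert sorted(sorted(c.members) for c in clusters) == sorted(
            sorted(c) for c in expected
        )
        assert unclustered == expected_out == ["lone"]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        universe = list(range(12))
        sets = [
            contact_set(
                f"p{i:02d}",
                rng.choice(universe, size=rng.integers(2, 8), replace=False),
            )
            for i in range(20)
        ]
        clusters, unclustered = fcc_cluster(sets)
        labels = [p for c in clusters for p in c.members] + unclustered
        assert sorted(labels) == sorted(s.pose_id for s in sets)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = list(range(10))
        sets = [
            contact_set(
                f"p{i:02d}",
                rng.choice(universe, size=rng.integers(2, 9), replace=False),
            )
            for i in range(rng.integers(8, 30))
        ]
        clusters, unclustered = fcc_cluster(sets)
        expected, expected_out = brute_force_leader_clusters(sets, 0.5, 2)
        assert [sorted(c.members) for c in clusters] == [
            sorted(c) for c in expected
        ]
        assert unclustered == expected_out

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        universe = list(range(8))
        sets = [
            contact_set(
                f"p{i:02d}",
                rng.choice(universe, size=rng.integers(2, 7), replace=False),
            )
            for i in range(15)
        ]
        ref_clusters, ref_out = fcc_cluster(sets)
        for perm_seed in range(3):
            perm = list(sets)
            np.random.default_rng(perm_seed).shuffle(perm)
            clusters, out = fcc_cluster(perm)
            assert [c.members for c in clusters] == [
                c.members for c in ref_clusters
            ]
            assert out == ref_out


class TestEnergyClusterFilter:
    def _clusters(self, groups):
        return [
            Cluster(cluster_id=f"c{k}", members=tuple(g))
            for k, g in enumerate(groups)
        ]

    def test_global_minimum_cluster_always_kept(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            groups = [
                [f"g{k}m{i}" for i in range(rng.integers(2, 6))]
                for k in range(4)
            ]
            clusters = self._clusters(groups)
            pool = [p for g in groups for p in g]
            energies = dict(zip(pool, rng.normal(size=len(pool))))
            argmin = min(energies, key=energies.get)
            kept = energy_cluster_filter(clusters, energies, 0.25)
            assert any(argmin in c.members for c in kept)

    def test_quartile_selection_eliminates_unlucky_cluster(self):
        clusters = self._clusters([["a1", "a2", "a3"], ["b1", "b2", "b3"],
                                   ["c1", "c2"]])
        energies = {
            "a1": -10.0, "a2": 0.0, "a3": 1.0,
            "b1": -9.0, "b2": 2.0, "b3": 3.0,
            "c1": 4.0, "c2": 5.0,
        }
        # ceil(0.25 * 8) = 2 selected: a1 and b1 -> cluster c eliminated
        kept = energy_cluster_filter(clusters, energies, 0.25)
        assert [c.cluster_id for c in kept] == ["c0", "c1"]

    def test_fraction_one_keeps_everything(self):
        clusters = self._clusters([["a", "b"], ["c", "d"]])
        energies = {p: float(i) for i, p in enumerate("abcd")}
        assert energy_cluster_filter(clusters, energies, 1.0) == clusters


class TestRankClusters:
    def _table(self, values):
        table = ScoreTable()
        for pid, (sasa, qual) in values.items():
            table.add(pid, "sasa", sasa)
            table.add(pid, "voromqa", qual)
        return table

    def test_single_cluster_gets_rank_one(self):
        clusters = [Cluster("c1", ("a", "b"))]
        ranked = rank_clusters(clusters, self._table(
            {"a": (10.0, 1.0), "b": (20.0, 2.0)}
        ))
        assert ranked[0].final_rank == 1
        assert ranked[0].max_sasa == 20.0
        assert ranked[0].max_quality == 2.0

    def test_dominating_cluster_ranks_first(self):
        clusters = [Cluster("low", ("a",), ), Cluster("high", ("b", "c"))]
        table = self._table(
            {"a": (10.0, 5.0), "b": (30.0, 9.0), "c": (1.0, 1.0)}
        )
        ranked = rank_clusters(clusters, table)
        assert ranked[0].cluster_id == "high"
        assert ranked[0].final_rank == 1

    def test_three_cluster_mean_rank_oracle(self):
        # representatives: c1 (sasa-rank 1, qual-rank 3), c2 (2, 1), c3 (3, 2)
        clusters = [
            Cluster("c1", ("a",)), Cluster("c2", ("b",)), Cluster("c3", ("c",))
        ]
        table = self._table(
            {"a": (30.0, 1.0), "b": (20.0, 9.0), "c": (10.0, 5.0)}
        )
        ranked = rank_clusters(clusters, table)
        assert [c.cluster_id for c in ranked] == ["c2", "c1", "c3"]
        assert [c.final_rank for c in ranked] == [1, 2, 3]
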