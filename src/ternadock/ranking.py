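"""Rank aggregation of surface-area and interface-quality scores, top-N
selection, and final cluster ranking.

Candidates are ordered by a two-component Borda (mean-rank) consensus:
each component is ranked with higher values better (a large accessible
surface leaves room for the degrader linker; a high quality score keeps
the interface physically plausible), ties receive the average rank, and
the aggregate score is the mean of the component ranks.  Mean-rank
aggregation is scale-free: any strictly monotone transform of either
component leaves the consensus order unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ConsistencyError
from .fcc import Cluster
from .scoring import ScoreTable

DEFAULT_AGGREGATE_COMPONENTS = ("sasa", "voromqa")


@dataclass
class RankedList:
    order: list[str]  # pose ids, best first
    component_ranks: dict  # component -> {pose_id: rank}
    aggregate: dict  # pose_id -> mean rank

    def __len__(self) -> int:
        return len(self.order)


def aggregate_ranks(
    values_by_component: dict[str, dict[str, float]],
    weights: dict[str, float] | None = None,
) -> RankedList:
    """Borda/mean-rank consensus of per-component scores (higher = better).

    ``values_by_component`` maps each component name to a complete
    ``{pose_id: value}`` mapping over the same pose ids; a pose missing a
    component raises with the offending ids listed.
    """
    if not values_by_component:
        raise ConsistencyError("no components to aggregate")
    components = sorted(values_by_component)
    ids = sorted(set().union(*(values_by_component[c] for c in components)))
    missing = {
        c: [i for i in ids if i not in values_by_component[c]]
        for c in components
    }
    missing = {c: m for c, m in missing.items() if m}
    if missing:
        raise ConsistencyError(f"poses missing component values: {missing}")
    if weights is None:
        weights = {c: 1.0 for c in components}
    w = np.array([weights.get(c, 1.0) for c in components], dtype=float)
    if w.sum() <= 0:
        raise ConsistencyError("aggregate weights must sum to > 0")

    component_ranks: dict[str, dict[str, float]] = {}
    rank_matrix = np.empty((len(ids), len(components)))
    for k, comp in enumerate(components):
        arr = np.array([values_by_component[comp][i] for i in ids])
        ranks = rankdata(-arr, method="average")  # rank 1 = best
        component_ranks[comp] = dict(zip(ids, ranks))
        rank_matrix[:, k] = ranks
    aggregate = rank_matrix @ w / w.sum()
    order = [ids[i] for i in sorted(range(len(ids)), key=lambda i: (aggregate[i], ids[i]))]
    return RankedList(
        order=order,
        component_ranks=component_ranks,
        aggregate=dict(zip(ids, aggregate)),
    )


def aggregate_from_table(
    table: ScoreTable,
    pose_ids: list[str],
    components: tuple[str, ...] = DEFAULT_AGGREGATE_COMPONENTS,
    weights: dict[str, float] | None = None,
) -> RankedList:
    """Aggregate over the given poses using values stored in a score table."""
    values = {
        comp: {pid: table.value(pid, comp) for pid in pose_ids}
        for comp in components
    }
    return aggregate_ranks(values, weights)


def select_top(ranked: RankedList, n: int = 200) -> list[str]:
    """First ``min(n, len(ranked))`` pose ids, consensus order preserved."""
    if n < 1:
        raise ConsistencyError("selection count must be >= 1")
    return ranked.order[:n]


def rank_clusters(
    clusters: list[Cluster],
    table: ScoreTable,
    weights: dict[str, float] | None = None,
) -> list[Cluster]:
    """Assign final ranks to clusters via their representative maxima.

    Each cluster is represented by the maximum member surface area and the
    maximum member quality score; the same mean-rank consensus as for
    poses orders the representatives.  Returns clusters sorted by final
    rank (1 = best); ``min_energy`` is refreshed when available.
    """
    if not clusters:
        return []
    reps_sasa: dict[str, float] = {}
    reps_quality: dict[str, float] = {}
    for cluster in clusters:
        reps_sasa[cluster.cluster_id] = max(
            table.value(p, "sasa") for p in cluster.members
        )
        reps_quality[cluster.cluster_id] = max(
            table.value(p, "voromqa") for p in cluster.members
        )
        cluster.max_sasa = reps_sasa[cluster.cluster_id]
        cluster.max_quality = reps_quality[cluster.cluster_id]
        if all(table.has(p, "energy") for p in cluster.members):
            cluster.min_energy = min(
                table.value(p, "energy") for p in cluster.members
            )
    ranked = aggregate_ranks(
        {"sasa": reps_sasa, "voromqa": reps_quality}, weights
    )
    position = {cid: i + 1 for i, cid in enumerate(ranked.order)}
    for cluster in clusters:
        cluster.final_rank = position[cluster.cluster_id]
    return sorted(clusters, key=lambda c: c.final_rank)
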