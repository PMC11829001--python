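"""Interface contacts, fraction-of-common-contacts (FCC) clustering, and
the energy-based cluster filtration.

Two candidate poses are compared through their sets of inter-protein
residue--residue contacts.  FCC is asymmetric by definition,
``fcc(a, b) = |a & b| / |a|``; for the clustering criterion the pair
similarity is symmetrised conservatively as the minimum of both
directions (configurable).  Clustering is greedy leader (Taylor--Butina)
clustering on the thresholded similarity graph: the unassigned pose with
the most unassigned neighbours becomes a cluster centre, ties going to
the lexicographically smallest pose id, and clusters below the minimum
size dissolve back to unclustered.  Unclustered poses are eliminated
from the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from .errors import ConsistencyError
from .structure import Pose, ResidueId, Structure, TernaryInput

DEFAULT_CONTACT_CUTOFF = 5.0  # Å, heavy-atom residue-contact definition


@dataclass(frozen=True)
class ContactSet:
    pose_id: str
    contacts: frozenset[tuple[ResidueId, ResidueId]]

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class Cluster:
    cluster_id: str
    members: tuple[str, ...]
    max_sasa: float | None = None
    max_quality: float | None = None
    min_energy: float | None = None
    final_rank: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def residue_contacts(
    receptor: Structure,
    mobile: Structure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> frozenset[tuple[ResidueId, ResidueId]]:
    """Residue pairs with any heavy-atom pair within ``cutoff`` Å.

    Receptor residue first in each pair.  Both structures are expected to
    be hydrogen-free already (preparation removes hydrogens).
    """
    if len(receptor) == 0 or len(mobile) == 0:
        return frozenset()
    pairs = receptor.kdtree.query_ball_tree(mobile.kdtree, r=cutoff)
    rec_res = [a.residue_id for a in receptor]
    mob_res = [a.residue_id for a in mobile]
    out = set()
    for i, js in enumerate(pairs):
        for j in js:
            out.add((rec_res[i], mob_res[j]))
    return frozenset(out)


def interface_contacts(
    inp: TernaryInput,
    pose: Pose,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactSet:
    """Contacts between the receptor and the posed mobile protein
    (moieties excluded on both sides)."""
    mobile = inp.mobile_protein
    placed = mobile.with_coords(pose.transform.apply(mobile.coords))
    return ContactSet(
        pose_id=pose.id,
        contacts=residue_contacts(inp.receptor_protein, placed, cutoff),
    )


def fcc_similarity(a: ContactSet, b: ContactSet) -> float:
    """|a & b| / |a| — the (asymmetric) fraction of a's contacts found in b."""
    if len(a) == 0:
        warnings.warn(
            f"FCC of empty contact set {a.pose_id!r} defined as 0", stacklevel=2
        )
        return 0.0
    return len(a.contacts & b.contacts) / len(a)


def pair_similarity(a: ContactSet, b: ContactSet, mode: str = "min") -> float:
    """Symmetrised FCC of a pose pair (min | mean | max of both directions)."""
    fab, fba = fcc_similarity(a, b), fcc_similarity(b, a)
    if mode == "min":
        return min(fab, fba)
    if mode == "mean":
        return 0.5 * (fab + fba)
    if mode == "max":
        return max(fab, fba)
    raise ConsistencyError(f"unknown FCC symmetrisation mode {mode!r}")


def fcc_cluster(
    contact_sets: list[ContactSet],
    threshold: float = 0.5,
    min_size: int = 2,
    mode: str = "min",
) -> tuple[list[Cluster], list[str]]:
    """Greedy leader clustering at the FCC similarity threshold.

    Returns ``(clusters, unclustered_ids)``.  Member tuples start with
    the cluster centre; clusters are emitted in formation order and the
    output is a partition of the input ids.
    """
    if not 0 < threshold <= 1:
        raise ConsistencyError("threshold must be in (0, 1]")
    if min_size < 1:
        raise ConsistencyError("min_size must be >= 1")
    by_id = {cs.pose_id: cs for cs in contact_sets}
    if len(by_id) != len(contact_sets):
        raise ConsistencyError("duplicate pose ids in contact sets")
    ids = sorted(by_id)
    # neighbour lists on the thresholded similarity graph
    neighbours: dict[str, set[str]] = {i: set() for i in ids}
    for i_pos, i in enumerate(ids):
        for j in ids[i_pos + 1 :]:
            if pair_similarity(by_id[i], by_id[j], mode) >= threshold:
                neighbours[i].add(j)
                neighbours[j].add(i)

    unassigned = set(ids)
    raw_clusters: list[tuple[str, list[str]]] = []
    while unassigned:
        # centre: most unassigned neighbours, ties -> smallest pose id
        centre = min(
            unassigned,
            key=lambda p: (-len(neighbours[p] & unassigned), p),
        )
        flock = sorted(neighbours[centre] & unassigned - {centre})
        members = [centre] + flock
        unassigned -= set(members)
        raw_clusters.append((centre, members))

    clusters: list[Cluster] = []
    unclustered: list[str] = []
    for centre, members in raw_clusters:
        if len(members) >= min_size:
            clusters.append(
                Cluster(
                    cluster_id=f"c{len(clusters) + 1:03d}",
                    members=tuple(members),
                )
            )
        else:
            unclustered.extend(members)
    return clusters, sorted(unclustered)


def energy_cluster_filter(
    clusters: list[Cluster],
    energies: dict[str, float],
    fraction: float = 0.25,
) -> list[Cluster]:
    """Keep clusters holding at least one of the lowest-energy poses.

    The selection pool is the ``ceil(fraction * N)`` lowest-energy poses
    over *all* clustered poses (not per cluster); a cluster survives iff
    it contains at least one selected pose.  The cluster holding the
    global minimum-energy pose therefore always survives.
    """
    if not 0 < fraction <= 1:
        raise ConsistencyError("fraction must be in (0, 1]")
    pool = [p for c in clusters for p in c.members]
    missing = sorted(p for p in pool if p not in energies)
    if missing:
        raise ConsistencyError(f"poses without energies: {missing[:5]} ...")
    n_select = int(np.ceil(fraction * len(pool)))
    selected = set(
        sorted(pool, key=lambda p: (energies[p], p))[:n_select]
    )
    return [c for c in clusters if selected & set(c.members)]
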