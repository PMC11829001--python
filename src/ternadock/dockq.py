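"""DockQ-family quality metrics for docked protein--protein models.

DockQ combines three classical CAPRI-style quantities into one score in
[0, 1]:

* ``fnat``  -- fraction of the native interface residue contacts (5 Å
  heavy-atom definition) reproduced by the model;
* ``iRMSD`` -- backbone RMSD over the native interface residues (any
  residue with a heavy atom within 10 Å of the partner protein) after
  superposing the model interface onto the native one;
* ``LRMSD`` -- backbone RMSD of the mobile (ligand) protein after
  superposing the model receptor onto the native receptor.

``DockQ = (fnat + 1/(1 + (iRMSD/1.5)^2) + 1/(1 + (LRMSD/8.5)^2)) / 3``

with quality classes Incorrect (< 0.23), Acceptable [0.23, 0.49),
Medium [0.49, 0.80) and High (>= 0.80).  Backbone means N, CA, C, O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ConsistencyError, ResidueMappingError
from .fcc import residue_contacts
from .structure import Pose, ResidueId, Structure, TernaryInput

BACKBONE_ATOMS = ("N", "CA", "C", "O")
IRMSD_SCALE = 1.5  # Å
LRMSD_SCALE = 8.5  # Å
FNAT_CUTOFF = 5.0  # Å
INTERFACE_CUTOFF = 10.0  # Å
ACCEPTABLE_THRESHOLD = 0.23
MEDIUM_THRESHOLD = 0.49
HIGH_THRESHOLD = 0.80


@dataclass(frozen=True)
class DockQResult:
    fnat: float
    irmsd: float
    lrmsd: float
    dockq: float
    quality_class: str


@dataclass(frozen=True)
class DockingModel:
    """A receptor+mobile protein pair (moieties already stripped)."""

    receptor: Structure
    mobile: Structure

    @classmethod
    def from_pose(cls, inp: TernaryInput, pose: Pose) -> "DockingModel":
        mobile = inp.mobile_protein
        return cls(
            receptor=inp.receptor_protein,
            mobile=mobile.with_coords(pose.transform.apply(mobile.coords)),
        )


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with the fitted map ``x -> R x + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ConsistencyError(
            f"coordinate shapes differ: {mobile.shape} vs {target.shape}"
        )
    if mobile.shape[0] < 3:
        raise ConsistencyError("superposition needs at least 3 points")
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(
        target - tgt_center, mobile - mob_center
    )
    R = rot.as_matrix()
    t = tgt_center - R @ mob_center
    rmsd = float(rssd / np.sqrt(mobile.shape[0]))
    return R, t, rmsd


def fnat(model_contacts: frozenset, native_contacts: frozenset) -> float:
    """Fraction of native contacts present in the model."""
    if not native_contacts:
        raise ConsistencyError("native interface has no contacts")
    return len(model_contacts & native_contacts) / len(native_contacts)


def _backbone_index(structure: Structure) -> dict[tuple[ResidueId, str], np.ndarray]:
    return {
        (a.residue_id, a.name): a.coordinates
        for a in structure
        if a.name in BACKBONE_ATOMS
    }


def _paired_backbone(
    model: Structure,
    native: Structure,
    residues: set[ResidueId] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model/native backbone coordinates in native order, residue-matched."""
    model_idx = _backbone_index(model)
    native_idx = _backbone_index(native)
    keys = [
        k
        for k in native_idx
        if residues is None or k[0] in residues
    ]
    missing = sorted({k[0] for k in keys if k not in model_idx})
    if missing:
        raise ResidueMappingError(
            f"model lacks backbone atoms for residues {missing}"
        )
    keys.sort()
    return (
        np.array([model_idx[k] for k in keys]),
        np.array([native_idx[k] for k in keys]),
    )


def lrmsd(model: DockingModel, native: DockingModel) -> float:
    """Mobile-protein backbone RMSD after receptor superposition, Å."""
    mod_rec, nat_rec = _paired_backbone(model.receptor, native.receptor)
    R, t, _ = kabsch_superpose(mod_rec, nat_rec)
    mod_mob, nat_mob = _paired_backbone(model.mobile, native.mobile)
    moved = mod_mob @ R.T + t
    return float(np.sqrt(((moved - nat_mob) ** 2).sum(axis=1).mean()))


def interface_residues(
    native: DockingModel, cutoff: float = INTERFACE_CUTOFF
) -> set[ResidueId]:
    """Native residues (either side) with a heavy atom within ``cutoff`` of
    the partner protein."""
    rec, mob = native.receptor, native.mobile
    if len(rec) == 0 or len(mob) == 0:
        raise ConsistencyError("empty structure in interface search")
    rec_tree, mob_tree = cKDTree(rec.coords), cKDTree(mob.coords)
    pairs = rec_tree.query_ball_tree(mob_tree, r=cutoff)
    residues: set[ResidueId] = set()
    for i, js in enumerate(pairs):
        if js:
            residues.add(rec.atoms[i].residue_id)
            for j in js:
                residues.add(mob.atoms[j].residue_id)
    if not residues:
        raise ConsistencyError("native interface is empty at the cutoff")
    return residues


def irmsd(
    model: DockingModel,
    native: DockingModel,
    cutoff: float = INTERFACE_CUTOFF,
) -> float:
    """Interface backbone RMSD after interface superposition, Å."""
    residues = interface_residues(native, cutoff)
    mod_rec, nat_rec = _paired_backbone(model.receptor, native.receptor, residues)
    mod_mob, nat_mob = _paired_backbone(model.mobile, native.mobile, residues)
    mod = np.vstack([mod_rec, mod_mob])
    nat = np.vstack([nat_rec, nat_mob])
    _, _, rmsd = kabsch_superpose(mod, nat)
    return rmsd


def quality_class(dockq: float) -> str:
    if dockq >= HIGH_THRESHOLD:
        return "High"
    if dockq >= MEDIUM_THRESHOLD:
        return "Medium"
    if dockq >= ACCEPTABLE_THRESHOLD:
        return "Acceptable"
    return "Incorrect"


def dockq_score(fnat_value: float, irmsd_value: float, lrmsd_value: float) -> DockQResult:
    """Combine fnat, iRMSD and LRMSD into the DockQ score and class."""
    if not 0 <= fnat_value <= 1:
        raise ConsistencyError("fnat must lie in [0, 1]")
    if irmsd_value < 0 or lrmsd_value < 0:
        raise ConsistencyError("RMSD values must be non-negative")
    score = (
        fnat_value
        + 1.0 / (1.0 + (irmsd_value / IRMSD_SCALE) ** 2)
        + 1.0 / (1.0 + (lrmsd_value / LRMSD_SCALE) ** 2)
    ) / 3.0
    return DockQResult(
        fnat=fnat_value,
        irmsd=irmsd_value,
        lrmsd=lrmsd_value,
        dockq=score,
        quality_class=quality_class(score),
    )


def evaluate_model(
    model: DockingModel, native: DockingModel
) -> DockQResult:
    """Full DockQ evaluation of a model against the native complex."""
    native_contacts = residue_contacts(
        native.receptor, native.mobile, FNAT_CUTOFF
    )
    model_contacts = residue_contacts(
        model.receptor, model.mobile, FNAT_CUTOFF
    )
    return dockq_score(
        fnat(model_contacts, native_contacts),
        irmsd(model, native),
        lrmsd(model, native),
    )


def near_native_percentage(dockq_values: list[float]) -> float:
    """Percentage of scores at or above the acceptable threshold (0.23)."""
    if not dockq_values:
        raise ConsistencyError("empty cluster in near-native computation")
    hits = sum(1 for v in dockq_values if v >= ACCEPTABLE_THRESHOLD)
    return 100.0 * hits / len(dockq_values)


def ranking_accuracy_curve(
    ranks: list[int], thresholds: list[int]
) -> list[float]:
    """accuracy(tau) = |{rank <= tau}| / |ranks| for each threshold."""
    if any(r < 1 for r in ranks):
        raise ConsistencyError("ranks must be positive")
    if not ranks:
        raise ConsistencyError("no ranks given")
    return [sum(1 for r in ranks if r <= t) / len(ranks) for t in thresholds]
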