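"""Deterministic toy ternary complexes and docking decoys.

The generator builds two non-overlapping pseudo-proteins — poly-alanine
five-atom residues (N, CA, C, O, CB) threaded on ideal helical lattices —
docked face to face with a genuine residue-contact interface, plus one
small hetero ligand per protein standing in for the anchor and warhead.
Decoys are rigid perturbations of the native placement with known
ground-truth transforms, emulating the output of a fast rigid docking
program at desk scale: most decoys scatter near the native pose, and a
configurable fraction is placed far outside the anchor–warhead distance
window to exercise the rough filtration.

Geometry is analytic and seeded, so every byte of the generated PDB text
is reproducible; no chemical realism is intended beyond heavy-atom
packing that the contact, surface-area and clash scores can act on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError
from .grid import EulerTriple, mass_center
from .structure import (
    AtomRecord,
    MoietyTag,
    Pose,
    RigidTransform,
    Structure,
    TernaryInput,
)

# helix lattice constants (Å / degrees); tuned once so that the native
# interface has >= 10 residue contacts at 5 Å and no heavy-atom clashes
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
MOBILE_PHASE = 50.0  # twist phase of the mobile helix: interdigitates faces
AXIS_SEPARATION = 9.0  # distance between the two helix axes
MOIETY_GAP = 6.0  # anchor–warhead mass-centre distance at the native pose


@dataclass(frozen=True)
class SyntheticSpec:
    n_residues: int = 12
    moiety_atoms: int = 4
    seed: int = 0
    n_decoys: int = 200
    max_translation: float = 4.5  # Å
    max_rotation: float = 15.0  # degrees
    far_fraction: float = 0.2

    def __post_init__(self):
        if self.n_residues < 4 or self.moiety_atoms < 1:
            raise ConsistencyError("toy proteins need >= 4 residues, >= 1 moiety atom")
        if self.max_translation < 0 or self.max_rotation < 0:
            raise ConsistencyError("perturbation bounds must be >= 0")
        if not 0 <= self.far_fraction <= 1:
            raise ConsistencyError("far_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """True decoy transforms relative to the native placement."""

    transforms: dict[str, RigidTransform]
    rotation_deg: dict[str, float]
    translation_ang: dict[str, float]
    far_ids: frozenset[str] = field(default_factory=frozenset)


def _helix_backbone(n_residues: int, chain: str, serial0: int,
                    mirror: bool, phase: float = 0.0) -> list[AtomRecord]:
    """Five heavy atoms per residue on an ideal helical lattice.

    ``mirror`` flips the radial direction so the second helix presents
    its side-chain face to the first; ``phase`` (degrees) rotates the
    lattice about its own axis so the faces interdigitate cleanly.
    """
    import gemmi

    masses = {el: gemmi.Element(el).weight for el in ("N", "C", "O")}
    atoms: list[AtomRecord] = []
    serial = serial0
    sign = -1.0 if mirror else 1.0
    for i in range(n_residues):
        angle = np.radians(HELIX_TWIST * i + phase)
        ca = np.array(
            [
                sign * HELIX_RADIUS * np.cos(angle),
                HELIX_RADIUS * np.sin(angle),
                HELIX_RISE * i,
            ]
        )
        u = np.array([sign * np.cos(angle), np.sin(angle), 0.0])  # radial out
        t = np.array([-sign * np.sin(angle), np.cos(angle), 0.0])  # tangent
        z = np.array([0.0, 0.0, 1.0])
        offsets = {
            "N": -1.2 * t + 0.4 * z,
            "CA": np.zeros(3),
            "C": 1.2 * t + 0.4 * z,
            "O": 1.4 * t + 1.5 * z,
            "CB": 1.5 * u,
        }
        for name in ("N", "CA", "C", "O", "CB"):
            element = name[0]
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name="ALA",
                    chain_id=chain,
                    residue_seq=i + 1,
                    insertion_code=" ",
                    coordinates=ca + offsets[name],
                    mass=masses[element],
                    is_hetero=False,
                )
            )
            serial += 1
    return atoms


def _moiety(center: np.ndarray, chain: str, serial0: int,
            n_atoms: int) -> list[AtomRecord]:
    """A compact hetero ligand: atoms on a small tetrahedral star."""
    import gemmi

    directions = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.4, 0.0, 0.0],
            [-0.7, 1.2, 0.0],
            [-0.7, -0.6, 1.1],
            [0.0, -1.3, -0.8],
            [0.7, 1.1, -0.9],
        ]
    )
    elements = ["C", "C", "N", "O", "C", "O"]
    atoms = []
    for k in range(n_atoms):
        d = directions[k % len(directions)] + 0.05 * (k // len(directions))
        el = elements[k % len(elements)]
        atoms.append(
            AtomRecord(
                serial=serial0 + k,
                name=f"{el}{k + 1}",
                element=el,
                residue_name="LIG",
                chain_id=chain,
                residue_seq=900,
                insertion_code=" ",
                coordinates=center + d,
                mass=gemmi.Element(el).weight,
                is_hetero=True,
            )
        )
    return atoms


def make_toy_complex(spec: SyntheticSpec = SyntheticSpec()) -> tuple[TernaryInput, Pose]:
    """Build the native toy complex and its (identity) native pose."""
    receptor_protein = _helix_backbone(spec.n_residues, "A", 1, mirror=False)
    mobile_protein = _helix_backbone(
        spec.n_residues, "B", 1001, mirror=True, phase=MOBILE_PHASE
    )
    # shift the mobile helix along +x so the CB faces of both helices meet
    shift = np.array([AXIS_SEPARATION, 0.0, 0.0])
    for a in mobile_protein:
        a.coordinates = a.coordinates + shift

    z_mid = HELIX_RISE * spec.n_residues / 2.0
    gap_center = np.array([AXIS_SEPARATION / 2.0, -6.5, z_mid])
    half = MOIETY_GAP / 2.0
    anchor = _moiety(
        gap_center - np.array([half, 0.0, 0.0]), "A", 500, spec.moiety_atoms
    )
    warhead = _moiety(
        gap_center + np.array([half, 0.0, 0.0]), "B", 1500, spec.moiety_atoms
    )

    inp = TernaryInput(
        receptor=Structure(receptor_protein + anchor),
        mobile=Structure(mobile_protein + warhead),
        receptor_moiety=MoietyTag(
            "anchor", frozenset(a.serial for a in anchor)
        ),
        mobile_moiety=MoietyTag(
            "warhead", frozenset(a.serial for a in warhead)
        ),
    )
    native = Pose(id="native", seed_id="native", transform=RigidTransform.identity())
    return inp, native


def _random_rotation(rng: np.random.Generator, max_deg: float) -> tuple[np.ndarray, float]:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.radians(max_deg))
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return R, float(np.degrees(angle))


def make_decoys(
    inp: TernaryInput,
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[list[Pose], GroundTruth]:
    """Seeded rigid decoys of the native placement.

    Decoy 0 is always the native placement.  ``round(far_fraction *
    n_decoys)`` decoys (taken from the end of the list) are translated far
    along the anchor->warhead axis, guaranteeing an anchor–warhead
    distance above any sensible window; the rest perturb the native pose
    by a uniform random rotation (<= max_rotation, about the mobile
    protein's mass centre) and translation (<= max_translation).
    """
    rng = np.random.default_rng(spec.seed)
    center = mass_center(inp.mobile_protein)
    anchor_c = mass_center(inp.anchor)
    warhead_c = mass_center(inp.warhead)
    away = warhead_c - anchor_c
    away /= np.linalg.norm(away)

    n_far = round(spec.far_fraction * spec.n_decoys)
    poses: list[Pose] = []
    truth = GroundTruth({}, {}, {}, frozenset())
    far_ids = set()
    for k in range(spec.n_decoys):
        pid = f"d{k:04d}"
        if k == 0:
            transform = RigidTransform.identity()
            rot_deg = trans_ang = 0.0
        elif k >= spec.n_decoys - n_far:
            R, rot_deg = _random_rotation(rng, spec.max_rotation)
            magnitude = rng.uniform(25.0, 40.0)
            transform = RigidTransform(R, away * magnitude, center)
            trans_ang = float(magnitude)
            far_ids.add(pid)
        else:
            R, rot_deg = _random_rotation(rng, spec.max_rotation)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            magnitude = rng.uniform(0.0, spec.max_translation)
            transform = RigidTransform(R, direction * magnitude, center)
            trans_ang = float(magnitude)
        poses.append(
            Pose(id=pid, seed_id=pid, transform=transform, provenance="seed")
        )
        truth.transforms[pid] = transform
        truth.rotation_deg[pid] = rot_deg
        truth.translation_ang[pid] = trans_ang
    truth.far_ids = frozenset(far_ids)
    return poses, truth


def grid_displaced_seed(
    inp: TernaryInput,
    offset: np.ndarray,
    euler: EulerTriple,
    pose_id: str = "displaced",
) -> Pose:
    """A seed pose whose exact grid correction is ``(offset, euler)``.

    Applying the translational offset and then the Euler rotation (about
    the translated mobile-protein centre, as the grid refinement does)
    maps this seed back onto the native placement exactly.
    """
    center = mass_center(inp.mobile_protein)
    return Pose(
        id=pose_id,
        seed_id=pose_id,
        transform=RigidTransform(
            rotation=euler.matrix().T,
            translation=-np.asarray(offset, dtype=float),
            rotation_center=center,
        ),
        provenance="seed",
    )
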