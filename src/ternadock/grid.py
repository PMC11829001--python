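"""Mass centres, the anchor--warhead distance, and grid refinements.

The local refinement explores a translational grid (default +-4.5 Å at
1.5 Å resolution on every axis) and, on the surviving candidates, a
rotational grid of Euler angles (default +-15 degrees at 5 degree
resolution on every axis).  Rotations use the extrinsic x -> y -> z
convention, ``R = Rz(psi) @ Ry(theta) @ Rx(phi)``, in degrees; the
convention is fixed here so that any reported grid triple identifies a
unique rotation matrix.  Rotations are applied about the mass centre of
the mobile protein in its current pose, so refinement never drags a
candidate away from its seed placement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConsistencyError, EmptyStructureError
from .structure import Pose, Structure, TernaryInput


@dataclass(frozen=True)
class GridSpec:
    translation_extent: float = 4.5  # Å
    translation_step: float = 1.5  # Å
    rotation_extent: float = 15.0  # degrees
    rotation_step: float = 5.0  # degrees

    def __post_init__(self):
        for extent, step, name in (
            (self.translation_extent, self.translation_step, "translation"),
            (self.rotation_extent, self.rotation_step, "rotation"),
        ):
            if step <= 0 or extent <= 0:
                raise ConsistencyError(f"{name} extent/step must be positive")
            ratio = extent / step
            if abs(ratio - round(ratio)) > 1e-9:
                raise ConsistencyError(
                    f"{name} extent must be an integer multiple of the step"
                )


class EulerTriple(NamedTuple):
    """Rotation angles in degrees about the x, y and z axes."""

    phi: float
    theta: float
    psi: float

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            "xyz", [self.phi, self.theta, self.psi], degrees=True
        ).as_matrix()


def _axis_values(extent: float, step: float) -> list[float]:
    n = round(extent / step)
    return [i * step for i in range(-n, n + 1)]


def mass_center(atoms: Structure | list) -> np.ndarray:
    """Mass-weighted mean position, Å."""
    if isinstance(atoms, Structure):
        if len(atoms) == 0:
            raise EmptyStructureError("mass centre of an empty structure")
        coords, masses = atoms.coords, atoms.masses
    else:
        if not atoms:
            raise EmptyStructureError("mass centre of an empty atom set")
        coords = np.array([a.coordinates for a in atoms], dtype=float)
        masses = np.array([a.mass for a in atoms], dtype=float)
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def moiety_distance(inp: TernaryInput, pose: Pose) -> float:
    """Euclidean distance between anchor and posed-warhead mass centres."""
    anchor_center = mass_center(inp.anchor)
    warhead = inp.warhead
    posed = pose.transform.apply(warhead.coords)
    masses = warhead.masses
    warhead_center = (masses[:, None] * posed).sum(axis=0) / masses.sum()
    return float(np.linalg.norm(anchor_center - warhead_center))


def translation_offsets(spec: GridSpec = GridSpec()) -> list[np.ndarray]:
    """All grid offsets, lexicographically ordered; includes the origin."""
    axis = _axis_values(spec.translation_extent, spec.translation_step)
    return [
        np.array(triple, dtype=float)
        for triple in itertools.product(axis, axis, axis)
    ]


def rotation_triples(spec: GridSpec = GridSpec()) -> list[EulerTriple]:
    """All grid Euler triples, lexicographically ordered; includes identity."""
    axis = _axis_values(spec.rotation_extent, spec.rotation_step)
    return [
        EulerTriple(*triple) for triple in itertools.product(axis, axis, axis)
    ]


def _fmt(value: float) -> str:
    return f"{value:g}"


def make_translated_pose(parent: Pose, offset: np.ndarray) -> Pose:
    """Child pose = parent placement followed by a grid translation."""
    offset = np.asarray(offset, dtype=float)
    label = ",".join(_fmt(v) for v in offset)
    return Pose(
        id=f"{parent.id}|t({label})",
        seed_id=parent.seed_id,
        transform=parent.transform.then_translation(offset),
        provenance="translated",
    )


def make_rotated_pose(
    inp: TernaryInput, parent: Pose, euler: EulerTriple
) -> Pose:
    """Child pose = parent placement rotated about its own mass centre.

    The rotation centre is the mass centre of the mobile *protein* (the
    warhead excluded) in the parent pose, which therefore stays fixed.
    """
    protein = inp.mobile_protein
    posed_center = _posed_mass_center(protein, parent)
    label = ",".join(_fmt(v) for v in euler)
    return Pose(
        id=f"{parent.id}|r({label})",
        seed_id=parent.seed_id,
        transform=parent.transform.then_rotation(euler.matrix(), posed_center),
        provenance="rotated",
    )


def _posed_mass_center(protein: Structure, pose: Pose) -> np.ndarray:
    posed = pose.transform.apply(protein.coords)
    masses = protein.masses
    return (masses[:, None] * posed).sum(axis=0) / masses.sum()


def posed_mobile_center(inp: TernaryInput, pose: Pose) -> np.ndarray:
    """Mass centre of the posed mobile protein (convenience for callers)."""
    return _posed_mass_center(inp.mobile_protein, pose)
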