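"""Domain types and PDB I/O for rigid ternary-complex modelling.

A candidate protein--protein complex (PPC) is represented as a fixed
*receptor* structure (the E3 ligase carrying its anchor ligand) plus a
*mobile* structure (the protein of interest carrying its warhead ligand)
that is repositioned by rigid-body poses.  Structures are flat lists of
:class:`AtomRecord`; residues are identified by ``(chain_id, residue_seq,
insertion_code)`` so that a write -> read round trip is lossless.

PDB parsing and writing go through :mod:`gemmi`; this module adds the
preparation rules of the pipeline (drop waters, hydrogens and alternate
conformers) and the rigid-transform plumbing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    ConsistencyError,
    EmptyStructureError,
    PDBFormatError,
)

logger = logging.getLogger(__name__)

_WATER_RESIDUES = {"HOH", "WAT"}
_HYDROGEN_ELEMENTS = {"H", "D"}
_CARBON_MASS = gemmi.Element("C").weight

#: residue identity: (chain_id, residue_seq, insertion_code)
ResidueId = tuple[str, int, str]


@dataclass(eq=False)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coordinates: np.ndarray
    mass: float
    is_hetero: bool

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in _HYDROGEN_ELEMENTS

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER_RESIDUES


class Structure:
    """An ordered collection of atoms with cached coordinate access."""

    def __init__(self, atoms: list[AtomRecord]):
        self.atoms = list(atoms)
        self._coords: np.ndarray | None = None
        self._kdtree = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float64 array of coordinates in Å."""
        if self._coords is None:
            self._coords = np.array(
                [a.coordinates for a in self.atoms], dtype=float
            ).reshape(len(self.atoms), 3)
        return self._coords

    @property
    def kdtree(self):
        """Cached cKDTree over the coordinates (structures are immutable)."""
        if self._kdtree is None:
            from scipy.spatial import cKDTree

            self._kdtree = cKDTree(self.coords)
        return self._kdtree

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def residue_ids(self) -> list[ResidueId]:
        """Residue identities in first-appearance order."""
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def subset(self, predicate) -> "Structure":
        return Structure([a for a in self.atoms if predicate(a)])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates (same order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ConsistencyError(
                f"coordinate array of shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            replace(a, coordinates=coords[i].copy())
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms)


@dataclass(frozen=True)
class MoietyTag:
    """Marks the anchor (on the E3 side) or warhead (on the POI side) atoms."""

    role: str  # "anchor" | "warhead"
    atom_serials: frozenset[int]

    def __post_init__(self):
        if self.role not in {"anchor", "warhead"}:
            raise ConsistencyError(f"unknown moiety role {self.role!r}")
        if not self.atom_serials:
            raise ConsistencyError(f"{self.role} moiety tag is empty")

    def resolve(self, structure: Structure) -> Structure:
        """Atoms of ``structure`` referenced by the tag, in structure order."""
        by_serial = {a.serial: a for a in structure}
        missing = sorted(s for s in self.atom_serials if s not in by_serial)
        if missing:
            raise ConsistencyError(
                f"{self.role} tag references missing serials {missing}"
            )
        non_het = sorted(
            s for s in self.atom_serials if not by_serial[s].is_hetero
        )
        if non_het:
            raise ConsistencyError(
                f"{self.role} tag references non-hetero serials {non_het}"
            )
        return structure.subset(lambda a: a.serial in self.atom_serials)


@dataclass(frozen=True)
class RigidTransform:
    """x -> R (x - c) + c + t with proper rotation R, both in Å."""

    rotation: np.ndarray
    translation: np.ndarray
    rotation_center: np.ndarray

    _TOL = 1e-9

    def __post_init__(self):
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, dtype=float)
        )
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        object.__setattr__(
            self, "rotation_center", np.asarray(self.rotation_center, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        R = self.rotation
        if R.shape != (3, 3):
            raise ConsistencyError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ConsistencyError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ConsistencyError("rotation matrix is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        c = self.rotation_center
        return (coords - c) @ self.rotation.T + c + self.translation

    def then_translation(self, offset: np.ndarray) -> "RigidTransform":
        """This transform followed by a pure translation."""
        return RigidTransform(
            self.rotation,
            self.translation + np.asarray(offset, dtype=float),
            self.rotation_center,
        )

    def then_rotation(
        self, rotation: np.ndarray, about: np.ndarray
    ) -> "RigidTransform":
        """This transform followed by a rotation about the point ``about``."""
        R1 = np.asarray(rotation, dtype=float)
        about = np.asarray(about, dtype=float)
        c0 = self.rotation_center
        t_new = R1 @ (c0 + self.translation - about) + about - c0
        return RigidTransform(R1 @ self.rotation, t_new, c0)


@dataclass(frozen=True)
class Pose:
    """A rigid placement of the mobile protein with provenance."""

    id: str
    seed_id: str
    transform: RigidTransform
    provenance: str = "seed"  # seed | translated | rotated

    def __post_init__(self):
        if self.provenance not in {"seed", "translated", "rotated"}:
            raise ConsistencyError(f"unknown provenance {self.provenance!r}")


@dataclass
class TernaryInput:
    """The two half-complexes of a ternary-structure prediction problem."""

    receptor: Structure
    mobile: Structure
    receptor_moiety: MoietyTag
    mobile_moiety: MoietyTag
    protac_file: str | None = None

    # caches; populated lazily
    _splits: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        shared = self.receptor.chain_ids & self.mobile.chain_ids
        if shared:
            raise ConsistencyError(
                f"receptor and mobile share chain ids {sorted(shared)}"
            )
        if self.receptor_moiety.role != "anchor":
            raise ConsistencyError("receptor moiety must have role 'anchor'")
        if self.mobile_moiety.role != "warhead":
            raise ConsistencyError("mobile moiety must have role 'warhead'")
        # fail fast if tags do not resolve
        self.receptor_moiety.resolve(self.receptor)
        self.mobile_moiety.resolve(self.mobile)

    @classmethod
    def from_structures(
        cls,
        receptor: Structure,
        mobile: Structure,
        protac_file: str | None = None,
    ) -> "TernaryInput":
        """Tag every HETATM atom of each structure as its bound moiety."""

        def het_serials(st: Structure, side: str) -> frozenset[int]:
            serials = frozenset(a.serial for a in st if a.is_hetero)
            if not serials:
                raise ConsistencyError(
                    f"{side} structure has no HETATM atoms to tag as moiety"
                )
            return serials

        return cls(
            receptor=receptor,
            mobile=mobile,
            receptor_moiety=MoietyTag("anchor", het_serials(receptor, "receptor")),
            mobile_moiety=MoietyTag("warhead", het_serials(mobile, "mobile")),
            protac_file=protac_file,
        )

    # -- protein / moiety views -------------------------------------------
    def _split(self, which: str):
        if which not in self._splits:
            st = self.receptor if which == "receptor" else self.mobile
            tag = (
                self.receptor_moiety
                if which == "receptor"
                else self.mobile_moiety
            )
            moiety = tag.resolve(st)
            protein = st.subset(lambda a: a.serial not in tag.atom_serials)
            self._splits[which] = (protein, moiety)
        return self._splits[which]

    @property
    def receptor_protein(self) -> Structure:
        return self._split("receptor")[0]

    @property
    def mobile_protein(self) -> Structure:
        return self._split("mobile")[0]

    @property
    def anchor(self) -> Structure:
        return self._split("receptor")[1]

    @property
    def warhead(self) -> Structure:
        return self._split("mobile")[1]


# ---------------------------------------------------------------------------
# PDB reading / preparation
# ---------------------------------------------------------------------------

def _validate_atom_lines(pdb_text: str) -> int:
    """Check coordinate fields of ATOM/HETATM records; return record count."""
    n = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n += 1
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi]
            try:
                value = float(fld)
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: unparseable {what} coordinate {fld!r}"
                ) from None
            if not math.isfinite(value):
                raise PDBFormatError(
                    f"line {lineno}: non-finite {what} coordinate {fld!r}"
                )
    return n


def read_structure(pdb_text: str) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    ATOM and HETATM records are both retained; insertion codes are part of
    the residue identity.  Only the first model is read and only the blank
    or ``A`` alternate-location indicator is kept, because the rigid-body
    pipeline needs exactly one conformer per atom.  A missing element
    column is inferred from the atom name; an unknown element falls back
    to the mass of carbon (with a warning) so that mass centres are always
    computable.
    """
    if _validate_atom_lines(pdb_text) == 0:
        raise EmptyStructureError("no ATOM/HETATM records in input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise PDBFormatError(str(exc)) from exc

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                element = atom.element
                if element.name in ("X", ""):
                    logger.warning(
                        "atom %s/%s: unknown element, using carbon mass",
                        residue.name,
                        atom.name,
                    )
                    mass = _CARBON_MASS
                    symbol = "C"
                else:
                    mass = element.weight
                    symbol = element.name
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=symbol,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_seq=residue.seqid.num,
                        insertion_code=residue.seqid.icode,
                        coordinates=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        ),
                        mass=mass,
                        is_hetero=residue.het_flag == "H",
                    )
                )
    if not atoms:
        raise EmptyStructureError("no atoms survived parsing")
    return Structure(atoms)


def prepare_structure(structure: Structure) -> Structure:
    """Drop waters and hydrogens; keep the remaining atom order. Idempotent."""
    return structure.subset(lambda a: not (a.is_water or a.is_hydrogen))


def strip_moieties(
    inp: TernaryInput,
) -> tuple[tuple[Structure, Structure], tuple[Structure, Structure]]:
    """Split both sides into (protein-only, moiety) structures."""
    return (
        (inp.receptor_protein, inp.mobile_protein),
        (inp.anchor, inp.warhead),
    )


def apply_pose(inp: TernaryInput, pose: Pose) -> Structure:
    """Place the mobile structure (protein + warhead) under the pose."""
    pose.transform.validate()
    return inp.mobile.with_coords(pose.transform.apply(inp.mobile.coords))


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _to_gemmi(structures: list[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    model = st[0]
    for source in structures:
        for atom in source:
            if len(model) == 0 or model[-1].name != atom.chain_id:
                model.add_chain(gemmi.Chain(atom.chain_id))
            chain = model[-1]
            res_tag = (atom.residue_seq, atom.insertion_code, atom.residue_name)
            if (
                len(chain) == 0
                or (
                    chain[-1].seqid.num,
                    chain[-1].seqid.icode,
                    chain[-1].name,
                )
                != res_tag
            ):
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(atom.residue_seq, atom.insertion_code)
                res.het_flag = "H" if atom.is_hetero else "A"
                chain.add_residue(res)
            residue = chain[-1]
            g_atom = gemmi.Atom()
            g_atom.name = atom.name
            g_atom.serial = atom.serial
            g_atom.element = gemmi.Element(atom.element)
            g_atom.pos = gemmi.Position(*atom.coordinates)
            g_atom.occ = 1.0
            g_atom.b_iso = 0.0
            residue.add_atom(g_atom)
    st.setup_entities()
    return st


def write_structures(structures: list[Structure]) -> str:
    """Serialise structures to PDB text (%8.3f coordinates, TER/END)."""
    non_empty = [s for s in structures if len(s)]
    if not non_empty:
        raise EmptyStructureError("nothing to write")
    seen: set[str] = set()
    for s in non_empty:
        overlap = seen & s.chain_ids
        if overlap:
            raise ConsistencyError(
                f"chain id collision across structures: {sorted(overlap)}"
            )
        seen |= s.chain_ids
    return _to_gemmi(non_empty).make_pdb_string()


def write_pose(inp: TernaryInput, pose: Pose) -> str:
    """Receptor chains followed by the placed mobile chains, as PDB text."""
    if len(inp.mobile) == 0:
        raise EmptyStructureError("mobile structure is empty")
    placed = apply_pose(inp, pose)
    return write_structures([inp.receptor, placed])
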