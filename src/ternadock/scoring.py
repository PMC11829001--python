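"""The rough ligand-based distance filter and the sequential protein-based
filtration chain, with pluggable score providers.

The sequential chain (default stability -> SASA -> energy -> interaction
z-score) is ordered fastest-first; at each stage a configurable top
fraction of candidates by that component survives.  Built-in providers
make the whole chain runnable with no third-party binaries:

* ``stability`` -- negated inter-protein heavy-atom clash count (<2.5 Å);
* ``sasa``      -- Shrake--Rupley solvent-accessible surface area of the
  complex (960 sphere points per atom, 1.4 Å probe);
* ``energy``    -- inter-protein Lennard-Jones 12-6 sum with per-element
  UFF well depths and radii, 8 Å cutoff (a documented surrogate for a
  full UFF force-field evaluation);
* ``pizsa``     -- interface-contact-count z-score over the current pose
  set (a monotone surrogate for an interaction z-score assessor);
* ``voromqa``   -- interface residue-contact count (a monotone surrogate
  for a Voronoi-based quality assessor; used for rank aggregation).

External tools can be substituted per component via
``provider="external:<command>"``; the adapter shells out with a written
complex PDB and parses the last number of the tool's output.  All scores
operate on protein-only structures: anchor and warhead are stripped
before protein-based scoring.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

import gemmi

from .errors import (
    ConfigurationError,
    ConsistencyError,
    PipelineStageError,
    ProviderError,
)
from .fcc import interface_contacts
from .grid import moiety_distance
from .structure import Pose, Structure, TernaryInput, write_structures

HIGHER_IS_BETTER = {
    "stability": True,
    "sasa": True,
    "energy": False,
    "pizsa": True,
    "voromqa": True,
}

CLASH_CUTOFF = 2.5  # Å, stability surrogate
ENERGY_CUTOFF = 8.0  # Å, Lennard-Jones pair cutoff
PROBE_RADIUS = 1.4  # Å, water probe
SASA_POINTS = 960  # sphere test points per atom

# UFF non-bonded parameters: element -> (x_i, Å; D_i, kcal/mol).
# x_i is the pair distance at the potential minimum, D_i the well depth;
# pair parameters combine by geometric means.
UFF_VDW = {
    "H": (2.886, 0.044),
    "C": (3.851, 0.105),
    "N": (3.660, 0.069),
    "O": (3.500, 0.060),
    "F": (3.364, 0.050),
    "P": (4.147, 0.305),
    "S": (4.035, 0.274),
    "CL": (3.947, 0.227),
    "BR": (4.189, 0.251),
    "I": (4.500, 0.339),
    "FE": (4.540, 0.013),
    "ZN": (4.045, 0.124),
    "MG": (3.021, 0.111),
    "NA": (2.983, 0.030),
    "K": (3.812, 0.035),
    "CA": (3.399, 0.238),
    "SE": (4.205, 0.291),
}


@dataclass(frozen=True)
class DistanceWindow:
    d_min: float = 3.0  # Å
    d_max: float = 20.0  # Å

    def __post_init__(self):
        if not 0 < self.d_min < self.d_max:
            raise ConsistencyError("require 0 < d_min < d_max")

    def contains(self, distance: float) -> bool:
        """Boundaries inclusive: poses at exactly d_min or d_max are kept."""
        return self.d_min <= distance <= self.d_max


@dataclass(frozen=True)
class ScoreRecord:
    pose_id: str
    component: str
    value: float

    @property
    def higher_is_better(self) -> bool:
        return HIGHER_IS_BETTER[self.component]


class ScoreTable:
    """Per-pose values for each score component, with derived ranks."""

    def __init__(self):
        self._values: dict[tuple[str, str], float] = {}

    def add(self, pose_id: str, component: str, value: float) -> None:
        if component not in HIGHER_IS_BETTER:
            raise ConsistencyError(f"unknown component {component!r}")
        if not math.isfinite(value):
            raise ConsistencyError(
                f"non-finite {component} value for {pose_id!r}"
            )
        self._values[(pose_id, component)] = float(value)

    def has(self, pose_id: str, component: str) -> bool:
        return (pose_id, component) in self._values

    def value(self, pose_id: str, component: str) -> float:
        try:
            return self._values[(pose_id, component)]
        except KeyError:
            raise ConsistencyError(
                f"no {component} value for pose {pose_id!r}"
            ) from None

    def component_values(self, component: str) -> dict[str, float]:
        return {
            pid: v
            for (pid, comp), v in self._values.items()
            if comp == component
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: pose_id, component, value, rank (1 = best).

        Ranks are per component over all poses scored for it, averaged on
        ties, best meaning highest value for higher-is-better components
        and lowest value otherwise.
        """
        rows = []
        for component in sorted({c for _, c in self._values}):
            values = self.component_values(component)
            ids = sorted(values)
            arr = np.array([values[i] for i in ids])
            ranks = rankdata(-arr if HIGHER_IS_BETTER[component] else arr)
            for pid, value, rank in zip(ids, arr, ranks):
                rows.append((pid, component, value, rank))
        return pd.DataFrame(
            rows, columns=["pose_id", "component", "value", "rank"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass(frozen=True)
class FilterConfig:
    """Sequential-filtration settings.

    ``retention`` keeps the top fraction per stage; absolute thresholds
    from any external protocol can be emulated by swapping providers and
    fractions via configuration.
    """

    components: tuple[str, ...] = ("stability", "sasa", "energy", "pizsa")
    retention: dict = field(
        default_factory=lambda: {
            "stability": 0.75,
            "sasa": 0.75,
            "energy": 0.75,
            "pizsa": 0.75,
        }
    )
    providers: dict = field(default_factory=dict)  # component -> "builtin" | "external:cmd"
    sasa_points: int = SASA_POINTS
    probe_radius: float = PROBE_RADIUS
    contact_cutoff: float = 5.0

    def __post_init__(self):
        for comp in self.components:
            if comp not in HIGHER_IS_BETTER:
                raise ConsistencyError(f"unknown filter component {comp!r}")
            frac = self.retention.get(comp, 0.75)
            if not 0 < frac <= 1:
                raise ConsistencyError(
                    f"retention fraction for {comp} must be in (0, 1]"
                )

    def fraction(self, component: str) -> float:
        return self.retention.get(component, 0.75)

    def provider(self, component: str) -> str:
        return self.providers.get(component, "builtin")


# ---------------------------------------------------------------------------
# Rough ligand-based filtration
# ---------------------------------------------------------------------------

def rough_ligand_filter(
    inp: TernaryInput,
    poses: list[Pose],
    window: DistanceWindow = DistanceWindow(),
) -> list[Pose]:
    """Keep poses whose anchor--warhead mass-centre distance lies in the
    window (boundaries inclusive); input order preserved."""
    kept = [p for p in poses if window.contains(moiety_distance(inp, p))]
    removed = len(poses) - len(kept)
    if removed:
        import logging

        logging.getLogger(__name__).info(
            "rough ligand filter removed %d of %d poses", removed, len(poses)
        )
    return kept


# ---------------------------------------------------------------------------
# Built-in score providers
# ---------------------------------------------------------------------------

def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _vdw_radius(element: str) -> float:
    r = gemmi.Element(element).vdw_r
    return r if r > 0 else 1.7


def sasa_score(
    structure: Structure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = SASA_POINTS,
) -> float:
    """Total solvent-accessible surface area (Å²), Shrake--Rupley method.

    Deterministic for a fixed point count; invariant (up to sphere-point
    discretisation) under rigid motion of the whole structure.
    """
    if len(structure) == 0:
        raise ConsistencyError("SASA of an empty structure")
    coords = structure.coords
    radii = np.array([_vdw_radius(a.element) for a in structure]) + probe_radius
    sphere = _unit_sphere(n_points)
    points = coords[:, None, :] + radii[:, None, None] * sphere
    buried = _self_buried(structure.kdtree, coords, radii, points)
    accessible = (~buried).sum(axis=1)
    return float((4.0 * math.pi * radii**2 * accessible / n_points).sum())


def _bury_points(
    buried: np.ndarray,
    points: np.ndarray,
    coords_b: np.ndarray,
    radii_b_sq: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
) -> None:
    """OR into ``buried`` the test points of side-A atoms ``pi`` falling
    inside the expanded spheres of side-B atoms ``pj`` (in place)."""
    if len(pi) == 0:
        return
    order = np.argsort(pi, kind="stable")
    pi, pj = pi[order], pj[order]
    n_points = points.shape[1]
    chunk = max(64, int(2_000_000 // n_points))
    start = 0
    while start < len(pi):
        stop = min(start + chunk, len(pi))
        # keep whole per-atom groups together (reduceat collapses them)
        while stop < len(pi) and pi[stop] == pi[stop - 1]:
            stop += 1
        i, j = pi[start:stop], pj[start:stop]
        pts = points[i]
        cb = coords_b[j]
        sq = (
            (pts**2).sum(axis=2)
            - 2.0 * np.einsum("epk,ek->ep", pts, cb)
            + (cb**2).sum(axis=1)[:, None]
        )
        mask = sq < radii_b_sq[j][:, None]
        starts = np.flatnonzero(np.r_[True, i[1:] != i[:-1]])
        buried[i[starts]] |= np.logical_or.reduceat(mask, starts, axis=0)
        start = stop


def _self_buried(
    tree, coords: np.ndarray, radii: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Burial mask of each atom's test points by its own structure."""
    buried = np.zeros(points.shape[:2], dtype=bool)
    pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
    if pairs.size:
        gap = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[gap < radii[pairs[:, 0]] + radii[pairs[:, 1]]]
        pi = np.concatenate([pairs[:, 0], pairs[:, 1]])
        pj = np.concatenate([pairs[:, 1], pairs[:, 0]])
        _bury_points(buried, points, coords, radii**2, pi, pj)
    return buried


class ComplexSASA:
    """Shrake--Rupley SASA of receptor+mobile complexes, one pose at a time.

    Exploits rigidity: each side's self-burial mask is pose-invariant (the
    mobile's test-point directions rotate with it), so per pose only the
    receptor<->mobile cross burial is recomputed.  Values agree with
    ``sasa_score`` on the assembled complex up to sphere-point
    discretisation (the mobile's sphere orientation co-rotates).
    """

    def __init__(
        self,
        inp: TernaryInput,
        probe_radius: float = PROBE_RADIUS,
        n_points: int = SASA_POINTS,
    ):
        self.n_points = n_points
        sphere = _unit_sphere(n_points)
        self._sides = {}
        for side, st in (
            ("receptor", inp.receptor_protein),
            ("mobile", inp.mobile_protein),
        ):
            radii = (
                np.array([_vdw_radius(a.element) for a in st]) + probe_radius
            )
            points = st.coords[:, None, :] + radii[:, None, None] * sphere
            self._sides[side] = {
                "structure": st,
                "radii": radii,
                "points": points,
                "self_buried": _self_buried(st.kdtree, st.coords, radii, points),
            }

    def score(self, pose: Pose) -> float:
        rec = self._sides["receptor"]
        mob = self._sides["mobile"]
        mob_coords = pose.transform.apply(mob["structure"].coords)
        # mobile test points co-rotate with the molecule, so the native
        # self-burial mask applies unchanged
        mob_points = pose.transform.apply(
            mob["points"].reshape(-1, 3)
        ).reshape(mob["points"].shape)
        rec_buried = rec["self_buried"].copy()
        mob_buried = mob["self_buried"].copy()
        tree = cKDTree(mob_coords)
        ball = rec["structure"].kdtree.query_ball_tree(
            tree, r=float(rec["radii"].max() + mob["radii"].max())
        )
        pairs = [(i, j) for i, js in enumerate(ball) for j in js]
        if pairs:
            ii = np.array([p[0] for p in pairs])
            jj = np.array([p[1] for p in pairs])
            gap = np.linalg.norm(
                rec["structure"].coords[ii] - mob_coords[jj], axis=1
            )
            near = gap < rec["radii"][ii] + mob["radii"][jj]
            ii, jj = ii[near], jj[near]
            _bury_points(
                rec_buried, rec["points"], mob_coords, mob["radii"] ** 2, ii, jj
            )
            _bury_points(
                mob_buried,
                mob_points,
                rec["structure"].coords,
                rec["radii"] ** 2,
                jj,
                ii,
            )
        total = 0.0
        for radii, buried in (
            (rec["radii"], rec_buried),
            (mob["radii"], mob_buried),
        ):
            accessible = (~buried).sum(axis=1)
            total += (
                4.0 * math.pi * radii**2 * accessible / self.n_points
            ).sum()
        return float(total)


def _uff_params(elements: list[str]) -> tuple[np.ndarray, np.ndarray]:
    xs, ds = [], []
    for el in elements:
        x, d = UFF_VDW.get(el.upper(), UFF_VDW["C"])
        xs.append(x)
        ds.append(d)
    return np.array(xs), np.array(ds)


def lennard_jones_energy(
    receptor: Structure,
    mobile: Structure,
    cutoff: float | None = ENERGY_CUTOFF,
) -> float:
    """Inter-protein UFF 12-6 energy, kcal/mol.

    ``E = sum_ij D_ij [ (x_ij / r)^12 - 2 (x_ij / r)^6 ]`` over receptor x
    mobile heavy-atom pairs within the cutoff (no cutoff if ``None``);
    geometric-mean combination for D_ij and x_ij.  A pair exactly at its
    minimum distance contributes ``-D_ij``.
    """
    if len(receptor) == 0 or len(mobile) == 0:
        return 0.0
    xa, da = _uff_params([a.element for a in receptor])
    xb, db = _uff_params([a.element for a in mobile])
    ca, cb = receptor.coords, mobile.coords
    if cutoff is None:
        ii, jj = np.meshgrid(
            np.arange(len(ca)), np.arange(len(cb)), indexing="ij"
        )
        ii, jj = ii.ravel(), jj.ravel()
    else:
        ball = receptor.kdtree.query_ball_tree(mobile.kdtree, r=cutoff)
        pairs = [(i, j) for i, js in enumerate(ball) for j in js]
        if not pairs:
            return 0.0
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
    r = np.linalg.norm(ca[ii] - cb[jj], axis=1)
    r = np.maximum(r, 1e-6)
    x_ij = np.sqrt(xa[ii] * xb[jj])
    d_ij = np.sqrt(da[ii] * db[jj])
    s6 = (x_ij / r) ** 6
    return float((d_ij * (s6**2 - 2.0 * s6)).sum())


def _placed_protein(inp: TernaryInput, pose: Pose) -> Structure:
    protein = inp.mobile_protein
    return protein.with_coords(pose.transform.apply(protein.coords))


def interaction_energy(
    inp: TernaryInput, pose: Pose, cutoff: float | None = ENERGY_CUTOFF
) -> float:
    """Inter-protein Lennard-Jones energy of the posed complex, kcal/mol."""
    return lennard_jones_energy(
        inp.receptor_protein, _placed_protein(inp, pose), cutoff
    )


def stability_score(inp: TernaryInput, pose: Pose) -> float:
    """Negated inter-protein clash count; 0 for a clash-free pose."""
    receptor = inp.receptor_protein
    placed = _placed_protein(inp, pose)
    ball = receptor.kdtree.query_ball_tree(placed.kdtree, r=CLASH_CUTOFF)
    return -float(sum(len(js) for js in ball))


def interface_quality(
    inp: TernaryInput, pose: Pose, cutoff: float = 5.0
) -> float:
    """Interface residue-contact count (higher is better).

    This is a monotone interface-size proxy standing in for an external
    structure-quality assessor; swap in one via an external provider to
    reproduce a published protocol exactly.
    """
    return float(len(interface_contacts(inp, pose, cutoff)))


def interaction_zscores(
    inp: TernaryInput, poses: list[Pose], cutoff: float = 5.0
) -> dict[str, float]:
    """Contact-count z-scores over the given pose set (population std).

    The z-score is set-relative by construction; a degenerate set (zero
    variance) yields all-zero scores with a warning.
    """
    counts = np.array(
        [len(interface_contacts(inp, p, cutoff)) for p in poses], dtype=float
    )
    std = counts.std()
    if std == 0:
        warnings.warn(
            "degenerate pose set for z-score (zero variance); all scores 0",
            stacklevel=2,
        )
        return {p.id: 0.0 for p in poses}
    mean = counts.mean()
    return {p.id: float((c - mean) / std) for p, c in zip(poses, counts)}


# ---------------------------------------------------------------------------
# External providers
# ---------------------------------------------------------------------------

def _external_score(command: str, inp: TernaryInput, pose: Pose) -> float:
    """Run an external scoring tool on the posed complex.

    The command receives the path of a written receptor+mobile PDB as its
    last argument; the last whitespace-separated number of its stdout is
    taken as the score.
    """
    exe = command.split()[0]
    if shutil.which(exe) is None:
        raise ConfigurationError(
            f"external scorer {exe!r} not found on PATH; "
            "configure provider 'builtin' to use the internal surrogate"
        )
    placed = inp.mobile.with_coords(pose.transform.apply(inp.mobile.coords))
    with tempfile.TemporaryDirectory() as tmp:
        pdb = Path(tmp) / "complex.pdb"
        pdb.write_text(write_structures([inp.receptor, placed]))
        proc = subprocess.run(
            command.split() + [str(pdb)],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:
        raise ProviderError(
            f"{exe} exited {proc.returncode}: {proc.stderr.strip()[:500]}"
        )
    numbers = [
        tok
        for tok in proc.stdout.split()
        if _is_number(tok)
    ]
    if not numbers:
        raise ProviderError(
            f"no numeric score in {exe} output: {proc.stdout.strip()[:500]}"
        )
    return float(numbers[-1])


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Sequential filtration
# ---------------------------------------------------------------------------

def _component_scores(
    component: str,
    provider: str,
    inp: TernaryInput,
    poses: list[Pose],
    config: FilterConfig,
) -> dict[str, float]:
    if provider.startswith("external:"):
        command = provider.split(":", 1)[1]
        return {p.id: _external_score(command, inp, p) for p in poses}
    if provider != "builtin":
        raise ConfigurationError(f"unknown provider {provider!r}")
    if component == "stability":
        return {p.id: stability_score(inp, p) for p in poses}
    if component == "sasa":
        scorer = ComplexSASA(inp, config.probe_radius, config.sasa_points)
        return {p.id: scorer.score(p) for p in poses}
    if component == "energy":
        return {p.id: interaction_energy(inp, p) for p in poses}
    if component == "pizsa":
        return interaction_zscores(inp, poses, config.contact_cutoff)
    if component == "voromqa":
        return {
            p.id: interface_quality(inp, p, config.contact_cutoff)
            for p in poses
        }
    raise ConsistencyError(f"unknown component {component!r}")


def _complex_protein(inp: TernaryInput, pose: Pose) -> Structure:
    """Protein-only receptor+mobile complex under the pose."""
    placed = _placed_protein(inp, pose)
    return Structure(inp.receptor_protein.atoms + placed.atoms)


def sequential_filter(
    inp: TernaryInput,
    poses: list[Pose],
    config: FilterConfig = FilterConfig(),
    table: ScoreTable | None = None,
) -> tuple[list[Pose], ScoreTable]:
    """Apply the configured component chain, keeping the top retention
    fraction at each stage (ceiling count, ties broken by pose id).

    Every computed score is retained in the returned table, including
    scores of poses dropped at a later stage; survivors therefore carry a
    value for every component of the chain.
    """
    if table is None:
        table = ScoreTable()
    survivors = list(poses)
    for component in config.components:
        if not survivors:
            raise PipelineStageError(
                f"no poses entering the {component} filtration stage"
            )
        values = _component_scores(
            component, config.provider(component), inp, survivors, config
        )
        for pid, value in values.items():
            table.add(pid, component, value)
        n_keep = math.ceil(config.fraction(component) * len(survivors))
        better = 1 if HIGHER_IS_BETTER[component] else -1
        ordered = sorted(
            survivors, key=lambda p: (-better * values[p.id], p.id)
        )
        keep_ids = {p.id for p in ordered[:n_keep]}
        survivors = [p for p in survivors if p.id in keep_ids]
    if not survivors:
        raise PipelineStageError("sequential filtration removed every pose")
    return survivors, table
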