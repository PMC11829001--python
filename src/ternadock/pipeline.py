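"""End-to-end orchestration: seeds -> filtration -> rank aggregation ->
grid refinement -> clustering -> cluster filtration -> final ranking.

The funnel mirrors a rigid ternary-complex screening protocol: a large
set of docking seed poses is cut down by the anchor–warhead distance
window and the sequential score filters, the consensus-ranked top
candidates are refined on the translational grid, re-filtered, the top
translated candidates are refined on the rotational grid, re-filtered,
and the surviving poses are clustered by fraction of common contacts.
Clusters are filtered by the lowest-energy-quartile rule, re-clustered,
and ranked by the consensus of their best member surface area and best
member interface quality.  Protein–protein docking itself is an external
concern: seeds are imported from a transform table, a directory of pose
PDBs, or the synthetic decoy generator.

Every stage is a pure function of its inputs; with a fixed configuration
and seed two runs produce byte-identical output tables.
"""

from __future__ import annotations

import logging
import subprocess
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .dockq import kabsch_superpose
from .errors import (
    ConfigurationError,
    ConsistencyError,
    PipelineStageError,
)
from .fcc import Cluster, energy_cluster_filter, fcc_cluster, interface_contacts
from .grid import (
    GridSpec,
    make_rotated_pose,
    make_translated_pose,
    rotation_triples,
    translation_offsets,
)
from .ranking import aggregate_from_table, select_top
from .ranking import rank_clusters as _rank_clusters
from .scoring import (
    DistanceWindow,
    FilterConfig,
    ScoreTable,
    interface_quality,
    rough_ligand_filter,
    sequential_filter,
)
from .structure import (
    Pose,
    RigidTransform,
    TernaryInput,
    prepare_structure,
    read_structure,
    write_pose,
)
from .synthetic import SyntheticSpec, make_decoys

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    pose_source: str = "synthetic"  # 'synthetic' | transform .tsv | pose dir
    n_seed_keep: int = 200
    n_translated_keep: int = 200
    window: DistanceWindow = field(default_factory=DistanceWindow)
    filters: FilterConfig = field(default_factory=FilterConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    fcc_threshold: float = 0.5
    fcc_mode: str = "min"
    min_cluster_size: int = 2
    energy_fraction: float = 0.25
    contact_cutoff: float = 5.0
    out_dir: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    protac_dock_command: str | None = None

    def __post_init__(self):
        if self.n_seed_keep < 1 or self.n_translated_keep < 1:
            raise ConsistencyError("selection counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "window" in raw:
            kwargs["window"] = DistanceWindow(**raw.pop("window"))
        if "filters" in raw:
            f = raw.pop("filters")
            if "components" in f:
                f["components"] = tuple(f["components"])
            kwargs["filters"] = FilterConfig(**f)
        if "grid" in raw:
            kwargs["grid"] = GridSpec(**raw.pop("grid"))
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticSpec(**raw.pop("synthetic"))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    seconds: float


@dataclass
class PipelineResult:
    input: TernaryInput
    clusters: list[Cluster]
    unclustered: list[str]
    reports: list[StageReport]
    table: ScoreTable
    poses: dict[str, Pose]
    artifacts: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Seed import
# ---------------------------------------------------------------------------

def write_transform_table(poses: list[Pose], path: str | Path) -> None:
    """Serialise poses as a tab-separated rigid-transform table."""
    lines = [
        "pose_id\tseed_id\tprovenance\t"
        + "\t".join(f"r{i}{j}" for i in range(3) for j in range(3))
        + "\ttx\tty\ttz\tcx\tcy\tcz"
    ]
    for p in poses:
        tr = p.transform
        nums = list(tr.rotation.flatten()) + list(tr.translation) + list(
            tr.rotation_center
        )
        lines.append(
            f"{p.id}\t{p.seed_id}\t{p.provenance}\t"
            + "\t".join(f"{v:.9f}" for v in nums)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_transform_table(path: str | Path) -> list[Pose]:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise PipelineStageError(f"transform table {path} contains no poses")
    poses = []
    for line in lines[1:]:
        fields = line.split("\t")
        pid, seed_id, provenance = fields[:3]
        nums = [float(v) for v in fields[3:]]
        poses.append(
            Pose(
                id=pid,
                seed_id=seed_id,
                transform=RigidTransform(
                    np.array(nums[:9]).reshape(3, 3),
                    np.array(nums[9:12]),
                    np.array(nums[12:15]),
                ),
                provenance=provenance,
            )
        )
    return poses


def _poses_from_pdb_dir(inp: TernaryInput, directory: Path) -> list[Pose]:
    """Derive rigid transforms from externally docked pose PDBs.

    Each file must contain the mobile chains with the same atoms as the
    input mobile structure; the pose transform is the least-squares rigid
    map from the input placement onto the file's placement.
    """
    files = sorted(directory.glob("*.pdb"))
    if not files:
        raise PipelineStageError(f"no pose PDBs in {directory}")
    ref = inp.mobile
    ref_keys = [(a.chain_id, a.residue_seq, a.insertion_code, a.name) for a in ref]
    poses = []
    for k, path in enumerate(files):
        st = prepare_structure(read_structure(path.read_text()))
        mobile = st.subset(lambda a: a.chain_id in ref.chain_ids)
        by_key = {
            (a.chain_id, a.residue_seq, a.insertion_code, a.name): a.coordinates
            for a in mobile
        }
        missing = [key for key in ref_keys if key not in by_key]
        if missing:
            raise ConsistencyError(
                f"{path.name} lacks mobile atoms, e.g. {missing[:3]}"
            )
        target = np.array([by_key[key] for key in ref_keys])
        R, t, _ = kabsch_superpose(ref.coords, target)
        poses.append(
            Pose(
                id=f"s{k:04d}",
                seed_id=f"s{k:04d}",
                transform=RigidTransform(R, t, np.zeros(3)),
                provenance="seed",
            )
        )
    return poses


def import_seed_poses(
    inp: TernaryInput, config: PipelineConfig
) -> list[Pose]:
    """Load seed poses from the configured source (provenance = seed)."""
    source = config.pose_source
    if source == "synthetic":
        poses, _ = make_decoys(inp, config.synthetic)
        return poses
    path = Path(source)
    if path.is_dir():
        return _poses_from_pdb_dir(inp, path)
    if path.is_file():
        return read_transform_table(path)
    raise PipelineStageError(f"unreadable pose source {source!r}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class _Recorder:
    def __init__(self):
        self.reports: list[StageReport] = []

    def record(self, stage: str, n_in: int, n_out: int, started: float):
        self.reports.append(
            StageReport(stage, n_in, n_out, time.perf_counter() - started)
        )
        logger.info("stage %-22s %6d -> %6d", stage, n_in, n_out)
        if n_out == 0:
            raise PipelineStageError(
                f"stage {stage!r} left no candidates "
                f"(input {n_in}); see stage reports"
            )


def _filter_and_rank(
    inp: TernaryInput,
    poses: list[Pose],
    config: PipelineConfig,
    table: ScoreTable,
    rec: _Recorder,
    label: str,
    keep: int | None,
) -> list[Pose]:
    """rough window -> sequential filters -> consensus top-N (if keep)."""
    t0 = time.perf_counter()
    kept = rough_ligand_filter(inp, poses, config.window)
    rec.record(f"{label}:rough_filter", len(poses), len(kept), t0)

    t0 = time.perf_counter()
    n_rough = len(kept)
    kept, _ = sequential_filter(inp, kept, config.filters, table)
    rec.record(f"{label}:sequential_filter", n_rough, len(kept), t0)

    if keep is not None:
        t0 = time.perf_counter()
        n_filtered = len(kept)
        for p in kept:
            if not table.has(p.id, "voromqa"):
                table.add(
                    p.id,
                    "voromqa",
                    interface_quality(inp, p, config.contact_cutoff),
                )
        ranked = aggregate_from_table(table, [p.id for p in kept])
        chosen = set(select_top(ranked, keep))
        kept = [p for p in kept if p.id in chosen]
        rec.record(f"{label}:rank_select", n_filtered, len(kept), t0)
    return kept


def run_pipeline(
    config: PipelineConfig,
    inp: TernaryInput | None = None,
    poses: list[Pose] | None = None,
) -> PipelineResult:
    """Execute the full candidate-generation and ranking funnel."""
    rec = _Recorder()
    table = ScoreTable()

    # (i) preparation
    t0 = time.perf_counter()
    if inp is None:
        if config.pose_source != "synthetic":
            raise ConfigurationError(
                "an input complex is required unless pose_source='synthetic'"
            )
        from .synthetic import make_toy_complex

        inp, _ = make_toy_complex(config.synthetic)
    n_raw = len(inp.receptor) + len(inp.mobile)
    inp = replace(
        inp,
        receptor=prepare_structure(inp.receptor),
        mobile=prepare_structure(inp.mobile),
        _splits={},
    )
    rec.record("prepare", n_raw, len(inp.receptor) + len(inp.mobile), t0)

    # (ii) seed import
    t0 = time.perf_counter()
    if poses is None:
        poses = import_seed_poses(inp, config)
    rec.record("import_seeds", len(poses), len(poses), t0)

    # (iii)-(iv) seed filtration and selection
    seeds = _filter_and_rank(
        inp, poses, config, table, rec, "seed", config.n_seed_keep
    )

    # (iv) translational grid
    t0 = time.perf_counter()
    offsets = translation_offsets(config.grid)
    translated = [
        make_translated_pose(parent, off) for parent in seeds for off in offsets
    ]
    rec.record("translate_grid", len(seeds), len(translated), t0)
    translated = _filter_and_rank(
        inp, translated, config, table, rec, "translated",
        config.n_translated_keep,
    )

    # (iv) rotational grid
    t0 = time.perf_counter()
    triples = rotation_triples(config.grid)
    rotated = [
        make_rotated_pose(inp, parent, triple)
        for parent in translated
        for triple in triples
    ]
    rec.record("rotate_grid", len(translated), len(rotated), t0)
    rotated = _filter_and_rank(
        inp, rotated, config, table, rec, "rotated", None
    )

    # (v) FCC clustering
    t0 = time.perf_counter()
    contact_sets = [
        interface_contacts(inp, p, config.contact_cutoff) for p in rotated
    ]
    clusters, unclustered = fcc_cluster(
        contact_sets,
        threshold=config.fcc_threshold,
        min_size=config.min_cluster_size,
        mode=config.fcc_mode,
    )
    rec.record("fcc_cluster", len(rotated), sum(c.size for c in clusters), t0)

    # (vi) energy-based cluster filtration
    t0 = time.perf_counter()
    energies = table.component_values("energy")
    kept_clusters = energy_cluster_filter(
        clusters, energies, config.energy_fraction
    )
    rec.record(
        "energy_cluster_filter",
        sum(c.size for c in clusters),
        sum(c.size for c in kept_clusters),
        t0,
    )

    # (vii) re-clustering of surviving poses
    t0 = time.perf_counter()
    surviving_ids = {p for c in kept_clusters for p in c.members}
    re_sets = [cs for cs in contact_sets if cs.pose_id in surviving_ids]
    clusters, re_unclustered = fcc_cluster(
        re_sets,
        threshold=config.fcc_threshold,
        min_size=config.min_cluster_size,
        mode=config.fcc_mode,
    )
    unclustered = sorted(set(unclustered) | set(re_unclustered))
    rec.record(
        "recluster", len(re_sets), sum(c.size for c in clusters), t0
    )

    # (viii) final cluster ranking
    t0 = time.perf_counter()
    pose_index = {p.id: p for p in rotated}
    for c in clusters:
        for pid in c.members:
            if not table.has(pid, "voromqa"):
                table.add(
                    pid,
                    "voromqa",
                    interface_quality(
                        inp, pose_index[pid], config.contact_cutoff
                    ),
                )
    clusters = _rank_clusters(clusters, table)
    rec.record("rank_clusters", len(clusters), len(clusters), t0)

    result = PipelineResult(
        input=inp,
        clusters=clusters,
        unclustered=unclustered,
        reports=rec.reports,
        table=table,
        poses=pose_index,
    )
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


# ---------------------------------------------------------------------------
# Outputs and the external docking adapter
# ---------------------------------------------------------------------------

def clusters_to_tsv(clusters: list[Cluster]) -> str:
    lines = [
        "cluster_id\tfinal_rank\tsize\tmax_sasa\tmax_quality\tmin_energy\tmembers"
    ]
    for c in sorted(clusters, key=lambda c: (c.final_rank or 0, c.cluster_id)):
        lines.append(
            f"{c.cluster_id}\t{c.final_rank}\t{c.size}\t"
            f"{c.max_sasa:.6f}\t{c.max_quality:.6f}\t{c.min_energy:.6f}\t"
            + ",".join(c.members)
        )
    return "\n".join(lines) + "\n"


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cluster_path = out / "clusters.tsv"
    cluster_path.write_text(clusters_to_tsv(result.clusters))
    result.artifacts["clusters"] = cluster_path

    report_path = out / "stage_reports.tsv"
    report_path.write_text(
        "stage\tn_in\tn_out\n"
        + "\n".join(
            f"{r.stage}\t{r.n_in}\t{r.n_out}" for r in result.reports
        )
        + "\n"
    )
    result.artifacts["stage_reports"] = report_path

    scores_path = out / "scores.tsv"
    result.table.to_tsv(scores_path)
    result.artifacts["scores"] = scores_path

    # stage (ix) inputs: one representative complex per cluster, ready for
    # external degrader docking
    for c in result.clusters:
        best = max(
            c.members,
            key=lambda pid: (result.table.value(pid, "voromqa"), pid),
        )
        pdb_path = out / f"cluster_{c.final_rank:03d}_{c.cluster_id}.pdb"
        pdb_path.write_text(write_pose(result.input, result.poses[best]))
        result.artifacts[c.cluster_id] = pdb_path

    if config.protac_dock_command:
        for c in result.clusters:
            external_dock_adapter(
                result.artifacts[c.cluster_id],
                result.input.protac_file,
                config.protac_dock_command,
            )
    else:
        logger.info(
            "no degrader docking command configured; stage (ix) skipped"
        )


@dataclass(frozen=True)
class InvocationRecord:
    command: tuple[str, ...]
    complex_file: str
    protac_file: str | None
    returncode: int
    stdout: str
    stderr: str


def external_dock_adapter(
    complex_pdb: str | Path,
    protac_file: str | Path | None,
    command: str,
) -> InvocationRecord:
    """Invoke an external small-molecule docking tool on a ranked complex.

    Pure pass-through: the command receives the complex PDB (and the
    degrader structure file when given) as trailing arguments; outputs
    are captured verbatim and never interpreted.
    """
    if not command:
        raise ConfigurationError("no docking command configured")
    argv = command.split() + [str(complex_pdb)]
    if protac_file is not None:
        argv.append(str(protac_file))
    import shutil

    if shutil.which(argv[0]) is None:
        raise ConfigurationError(
            f"docking command {argv[0]!r} not found on PATH"
        )
    proc = subprocess.run(argv, capture_output=True, text=True)
    record = InvocationRecord(
        command=tuple(argv),
        complex_file=str(complex_pdb),
        protac_file=None if protac_file is None else str(protac_file),
        returncode=proc.returncode,
        stdout=proc.stdout,
        stderr=proc.stderr,
    )
    if proc.returncode != 0:
        raise ConfigurationError(
            f"docking command failed ({proc.returncode}): "
            f"{proc.stderr.strip()[:500]}"
        )
    return record
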