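"""Bundled 22-case benchmark tables and the summary statistics over them.

The package ships per-case result tables for the 22 experimentally
solved PROTAC ternary complexes used to benchmark the pipeline against a
Bayesian-optimisation baseline (BOTCP):

* ``table3_dockq`` -- best-model fnat / iRMSD / LRMSD / DockQ / class per
  method, plus the maximum DockQ achievable by rigid docking;
* ``table4_best_rank`` -- rank, total cluster count and %near-native of
  the cluster holding the best-DockQ model;
* ``table5_first_acceptable`` -- the same three quantities for the first
  cluster holding an acceptable model (DockQ >= 0.23);
* ``table6_grid_improvement`` -- best-model DockQ at the seed, translated
  and rotated stages of the grid refinement, with percent improvement;
* ``table7_selected_transforms`` -- the selected grid translation (Å) and
  rotation (degrees) triples per case.

A checksum manifest guards the fixtures against silent edits.  The
statistics recomputed here (column means and medians, percent
improvements, win/loss/tie counts) are derived from the per-case values
only.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import ConsistencyError

TABLES = (
    "table3_dockq",
    "table4_best_rank",
    "table5_first_acceptable",
    "table6_grid_improvement",
    "table7_selected_transforms",
)


def _data_root():
    return resources.files("ternadock") / "data"


def verify_checksums() -> None:
    """Raise if any bundled table differs from its recorded checksum."""
    root = _data_root()
    manifest = {}
    for line in (root / "SHA256SUMS").read_text().splitlines():
        digest, name = line.split()
        manifest[name] = digest
    for name in TABLES:
        fname = f"{name}.tsv"
        if fname not in manifest:
            raise ConsistencyError(f"{fname} missing from checksum manifest")
        digest = hashlib.sha256((root / fname).read_bytes()).hexdigest()
        if digest != manifest[fname]:
            raise ConsistencyError(f"fixture {fname} fails its checksum")


def load_table(name: str, checked: bool = True) -> pd.DataFrame:
    """Load a bundled benchmark table by name."""
    if name not in TABLES:
        raise ConsistencyError(f"unknown benchmark table {name!r}")
    if checked:
        verify_checksums()
    with (_data_root() / f"{name}.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", na_values=["NA"])
    if frame["pdb_id"].duplicated().any() or len(frame) != 22:
        raise ConsistencyError(f"malformed fixture table {name}")
    return frame


def _column_stats(frame: pd.DataFrame) -> dict[str, dict[str, float]]:
    out = {}
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            continue
        values = frame[col].dropna()
        out[col] = {
            "mean": float(values.mean()),
            "median": float(values.median()),
            "n": int(values.size),
        }
    return out


def percent_improvement(before: float, after: float) -> float:
    """(after - before) / before * 100."""
    if before == 0:
        raise ConsistencyError("undefined improvement from a zero baseline")
    return (after - before) / before * 100.0


def benchmark_statistics() -> dict:
    """Recompute the benchmark summary statistics from the per-case tables.

    Returns a nested dict with, per table, the column means and medians;
    for the DockQ table additionally win/loss/tie counts between the two
    methods; for the grid table the per-case percent improvements and the
    improvement of the aggregate (mean/median) DockQ across grid stages.
    Absolute values are aggregated for the transform table, matching how
    displacement magnitudes are usually summarised.
    """
    stats: dict = {}
    t3 = load_table("table3_dockq")
    stats["table3_dockq"] = _column_stats(t3)
    wins = int((t3["pipeline_dockq"] > t3["botcp_dockq"]).sum())
    losses = int((t3["pipeline_dockq"] < t3["botcp_dockq"]).sum())
    stats["table3_dockq"]["comparison"] = {
        "wins": wins,
        "losses": losses,
        "ties": int(len(t3) - wins - losses),
        "win_pct": 100.0 * wins / len(t3),
    }

    for name in ("table4_best_rank", "table5_first_acceptable"):
        stats[name] = _column_stats(load_table(name, checked=False))

    t6 = load_table("table6_grid_improvement", checked=False)
    improvements = [
        percent_improvement(row.seed_dockq, row.rotated_dockq)
        for row in t6.itertuples()
    ]
    stats["table6_grid_improvement"] = _column_stats(t6)
    stats["table6_grid_improvement"]["recomputed_improvement_pct"] = {
        "per_case": improvements,
        "mean_of_aggregates": percent_improvement(
            float(t6["seed_dockq"].mean()), float(t6["rotated_dockq"].mean())
        ),
        "median_of_aggregates": percent_improvement(
            float(t6["seed_dockq"].median()),
            float(t6["rotated_dockq"].median()),
        ),
    }

    t7 = load_table("table7_selected_transforms", checked=False)
    stats["table7_selected_transforms"] = _column_stats(
        t7.assign(**{c: t7[c].abs() for c in t7.columns if c != "pdb_id"})
    )
    return stats


def format_report(stats: dict | None = None) -> str:
    """Human-readable benchmark summary."""
    if stats is None:
        stats = benchmark_statistics()
    lines = []
    for table, columns in stats.items():
        lines.append(table)
        for col, vals in columns.items():
            if col == "comparison":
                lines.append(
                    f"  DockQ wins/losses/ties: {vals['wins']}/"
                    f"{vals['losses']}/{vals['ties']}"
                    f" (win rate {vals['win_pct']:.3f}%)"
                )
            elif col == "recomputed_improvement_pct":
                lines.append(
                    "  grid improvement of mean DockQ: "
                    f"{vals['mean_of_aggregates']:.3f}%"
                )
                lines.append(
                    "  grid improvement of median DockQ: "
                    f"{vals['median_of_aggregates']:.3f}%"
                )
            else:
                lines.append(
                    f"  {col}: mean {vals['mean']:.3f}"
                    f" median {vals['median']:.3f} (n={vals['n']})"
                )
    return "\n".join(lines)
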