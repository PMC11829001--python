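# Methods

This note records the models, conventions and numerical choices behind
`ternadock`, and what its synthetic tests do and do not demonstrate.

## Problem setting

The package models the proteins-only stage of PROTAC ternary-complex
prediction. The receptor (E3 ligase with its bound anchor ligand) is
held fixed; the mobile protein (target protein with its bound warhead)
is repositioned by rigid transforms. A candidate PPC is therefore fully
described by a rotation, a rotation centre and a translation. Chemistry
is out of scope: hydrogens and waters are removed at preparation, all
scores act on heavy atoms, and the PROTAC itself only enters through the
geometric constraint its linker imposes and through the external docking
adapter at the end of the funnel.

## Conventions

* **Residue identity** is `(chain_id, residue_seq, insertion_code)`;
  atom order within residues is preserved from the input so PDB
  round-trips are lossless to the format's 0.001 Å precision.
* **Alternate locations**: only the blank or `A` conformer is kept — a
  rigid-body pipeline needs exactly one position per atom.
* **Masses and vdW radii** come from gemmi's element tables; an unknown
  element falls back to carbon's mass with a logged warning so mass
  centres are always computable.
* **Euler convention**: extrinsic x→y→z, `R = Rz(ψ)·Ry(θ)·Rx(φ)`,
  degrees. The convention is arbitrary but fixed and documented, so any
  reported grid triple identifies a unique rotation.
* **Rotation centre** for grid refinement is the mass centre of the
  mobile *protein* (warhead excluded) in its current, already-translated
  pose. Rotating about the current centre keeps every refined pose in
  the seed's neighbourhood; the alternative (the original seed centre)
  would couple rotation magnitude to translation distance.

## Filtration chain

* **Distance window** [3, 20] Å on the anchor–warhead mass-centre
  distance, boundaries inclusive. The lower bound excludes fused
  moieties; the upper bound exceeds typical anchor–warhead spacings by a
  wide margin so borderline linkers are not lost.
* **Stage order** stability → SASA → energy → z-score runs cheap scores
  first. Each stage keeps the top `ceil(f·n)` poses by that component
  (default f = 0.75), ties broken by pose id for determinism. Retention
  fractions, components, and per-component providers are configurable;
  absolute thresholds from a published protocol can be emulated by
  swapping providers via configuration.
* **Built-in score providers** are deliberately simple, monotone
  surrogates chosen so the whole funnel runs with no external binaries:
  * *stability* = −(# inter-protein heavy-atom pairs < 2.5 Å): a pure
    clash penalty, 0 for any physically sane pose.
  * *SASA* = Shrake–Rupley with 960 deterministic golden-spiral test
    points per atom and a 1.4 Å probe. For the pipeline's inner loop a
    rigid-body decomposition is used: each side's self-burial mask is
    pose-invariant (the mobile's test-point directions co-rotate with
    it), so only receptor↔mobile cross-burial is recomputed per pose.
    This agrees with the direct computation to <0.5 % (sphere-point
    discretisation) and is ~15× faster.
  * *energy* = inter-protein Lennard-Jones 12-6 sum with per-element UFF
    well depths and minimum distances (geometric-mean combination), 8 Å
    cutoff, kcal/mol. This is a surrogate for a full UFF force-field
    evaluation: it reproduces the dispersion/repulsion balance that
    drives the 25 %-lowest-energy cluster rule, not absolute energies.
  * *z-score* = population z-score of the interface contact count over
    the current pose set (zero-variance sets score 0 with a warning).
    Set-relative by construction, like the interaction z-scores it
    stands in for.
  * *quality* = interface residue-contact count at 5 Å. This is a
    monotone interface-size proxy, **not** a statistical-potential
    quality assessor; an external assessor can be wired in through the
    provider interface (`external:<command>`, which receives a written
    complex PDB and must print a number).

## Rank aggregation

The named components for consensus ranking are total SASA and interface
quality. Each is ranked descending (higher better) with average-rank
ties; the aggregate is the (optionally weighted) mean of component
ranks — a two-component Borda count. Mean-rank aggregation is invariant
under strictly monotone transforms of either component, which is exactly
the property needed when combining scores on incommensurable scales.
Final order is ascending aggregate, ties by pose id.

## Grid refinement

Translations: the Cartesian product of {−4.5, …, +4.5} Å at 1.5 Å per
axis (343 offsets, lexicographic order, origin included). Rotations: the
product of {−15°, …, +15°} at 5° per axis (343 triples, identity
included). The two stages run sequentially — translations exhaustively
on the selected seeds, rotations on the re-selected translated poses —
never as a combined 343×343 product per seed. An on-grid displacement is
recovered exactly: for a seed constructed as the inverse of a grid move,
some enumerated pose reproduces the native placement to <10⁻³ Å ligand
RMSD (verified by test).

## Clustering and cluster filtration

Contacts are residue pairs with any heavy-atom pair within 5 Å (the
conventional FCC contact definition). FCC is asymmetric,
`fcc(a,b) = |a∩b|/|a|`; the pair similarity used against the 0.5
criterion is `min(fcc(a,b), fcc(b,a))` — the conservative choice, with
`mean`/`max` available via configuration. Clustering is greedy leader
(Taylor–Butina): the unassigned pose with the most unassigned
neighbours becomes a centre (ties → lowest pose id), clusters under the
minimum size (default 2) dissolve, and unclustered poses are eliminated.
Energy-based cluster filtration selects the `ceil(0.25·N)` lowest-energy
poses over *all* clustered poses and keeps exactly the clusters holding
at least one selected pose — so the cluster containing the global
minimum-energy pose always survives. Survivors are re-clustered with
identical parameters, and clusters are finally ranked by the mean-rank
consensus of their representative maxima (max member SASA, max member
quality).

## DockQ evaluation

`DockQ = (fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²)) / 3` with
fnat on 5 Å native contacts, the interface defined by a 10 Å heavy-atom
shell, backbone = {N, CA, C, O}, and classes Incorrect < 0.23 ≤
Acceptable < 0.49 ≤ Medium < 0.80 ≤ High. Superpositions are
least-squares (Kabsch via scipy's `Rotation.align_vectors`); LRMSD
superposes receptors and reads the RMSD off the mobile backbone, iRMSD
superposes and scores the interface backbone itself.

## Bundled benchmark tables

Five per-case tables for the 22-complex benchmark are bundled as TSV
with a SHA-256 manifest checked at load. All summary statistics (column
means/medians, DockQ win counts, percent improvements) are recomputed
from the per-case values; the aggregate "% improvement" across grid
stages is the improvement *of the aggregates*
((mean_after − mean_before)/mean_before), which is how the summary rows
of the source tables are constructed — the mean of per-case
improvements is a different (much larger) number. During fixture
validation each DockQ row was cross-checked against the combination
formula; the baseline method's columns contain two rows (6W8I-FC,
7JTO-LB) whose tabulated DockQ contradicts its own metric triple, and
the baseline L-RMSD summary cells cannot be derived from the baseline
L-RMSD column (derived: 7.216/6.096). These values are kept verbatim and
the discrepancies are asserted by dedicated tests rather than silently
corrected.

## Synthetic data

The generator builds two pseudo-proteins — poly-alanine five-atom
residues (N, CA, C, O, CB) on ideal helical lattices (radius 2.3 Å,
rise 1.5 Å, twist 100°/residue, 12 residues by default) — docked face to
face 9 Å axis-to-axis with a 50° phase offset, tuned once so the native
interface has ≥10 residue contacts at 5 Å with no pair under 2.5 Å. One
four-atom hetero ligand per protein stands in for anchor and warhead,
placed 6 Å apart in the interface groove. Decoys perturb the native
placement by a uniform random rotation (≤15°, about the mobile protein
centre) and translation (≤4.5 Å) — mirroring the grid radii, so grid
refinement can plausibly correct them — plus a configurable far-off
fraction (default 20 %, 200 decoys by default) translated 25–40 Å along
the anchor→warhead axis to exercise the distance filter. Decoy 0 is
always the native placement, and all randomness flows from a single
seeded generator; pipeline stages themselves contain no randomness, so
fixed seed + fixed configuration ⇒ byte-identical outputs.

What the synthetic tests show: the geometry, filtration arithmetic,
aggregation, clustering and evaluation machinery are correct and
deterministic, and the funnel recovers near-native placements from
noisy decoys. What they do not show: performance on real protein
surfaces — toy interfaces are small and smooth, the score surrogates are
not the external assessors they stand in for, and no claim about
real-case DockQ distributions follows from a passing suite.

## Problem sizes and numerical choices

Tests run the pipeline at desk scale — tens of seeds, keep counts of
~6, and 60–240 SASA sphere points — chosen so the full suite completes
in about a minute while exercising every stage; the package defaults
(200 keeps, 960 points) are the production settings. Orthonormality of
rotations is enforced to 1e-8; pose application preserves intra-mobile
distances to 1e-6 Å; survivor counts use ceilings so a non-empty input
can never be filtered to zero by retention alone; every stage that could
still empty the candidate set raises an error naming the stage.

## Known limitations

* The linker is modelled only as a scalar distance window; moiety
  orientation (e.g. exit-vector angles) is ignored, so poses whose
  ligands point away from each other can survive to protein-based
  filtration.
* Built-in providers are ordinal surrogates: they order poses sensibly
  but their absolute values are not comparable to the external tools
  they replace.
* Rigid bodies throughout: no backbone or side-chain relaxation, no
  linker conformer sampling, no solvent model.
* Greedy leader clustering is order-independent only through its
  documented tie policy; a different similarity symmetrisation changes
  cluster boundaries near the 0.5 criterion.
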