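# ternadock

Rigid candidate generation, filtration and ranking for **PROTAC-mediated
ternary complexes**.

A PROTAC joins an E3-ligase-binding ligand (the *anchor*) to a ligand of a
protein of interest (the *warhead*) through a chemical linker. Whether a
PROTAC degrades its target depends on whether a productive **ternary
complex** — E3 ligase · PROTAC · target — can form, so screening
campaigns need to predict plausible protein–protein complexes (PPCs)
*before* docking the small molecule. `ternadock` implements the
candidate-processing funnel that sits between a fast rigid
protein–protein docking program (which supplies thousands of seed poses)
and PROTAC docking (which needs a handful of well-ranked complexes):

1. **Rough ligand-based filtration** — discard poses whose
   anchor–warhead mass-centre distance lies outside **[3, 20] Å**
   (boundaries inclusive), since no linker can bridge them.
2. **Sequential protein-based filtration** — fast scores first:
   clash-based stability, solvent-accessible surface area
   (Shrake–Rupley), inter-protein UFF Lennard-Jones energy, and an
   interface z-score; each stage retains a configurable top fraction
   (default 0.75).
3. **Rank aggregation** — a two-component Borda (mean-rank) consensus of
   total SASA and an interface-quality score selects the top 200
   candidates. Large SASA is rewarded deliberately: wider inter-protein
   gaps leave room for the PROTAC.
4. **Translational grid refinement** — every selected pose is displaced
   on a ±4.5 Å grid at 1.5 Å resolution per axis (7³ = 343 placements),
   re-filtered and re-ranked; the top 200 survive.
5. **Rotational grid refinement** — each survivor is rotated through a
   ±15° Euler grid at 5° resolution per axis (343 rotations, applied
   about the mobile protein's mass centre), then re-filtered.
6. **FCC clustering** — poses are clustered by **fraction of common
   contacts** (similarity ≥ 0.5, minimum cluster size 2, greedy leader
   algorithm); unclustered poses are eliminated.
7. **Energy-based cluster filtration** — the 25 % lowest-energy poses
   are marked; only clusters containing at least one marked pose are
   kept, then survivors are re-clustered.
8. **Cluster ranking** — each cluster is represented by its maximum
   member SASA and maximum member quality score; the same mean-rank
   consensus yields the final cluster ranking, and one representative
   complex per cluster is written out, ready for PROTAC docking.

Model quality is measured with the **DockQ** family:
`DockQ = (fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²)) / 3`, with
classes Incorrect < 0.23 ≤ Acceptable < 0.49 ≤ Medium < 0.80 ≤ High.

Protein–protein docking itself is *not* re-implemented: seed poses are
imported from a rigid-transform table, a directory of pose PDBs, or the
built-in synthetic decoy generator, which builds analytic toy complexes
with known ground truth so the whole funnel is testable offline.

## Worked example

Generate a toy complex with 60 docking decoys (20 % deliberately
"unpromising", far outside the distance window) and run the funnel:

```bash
ternadock synth --out-dir demo --seed 7 --n-decoys 60
cat > demo/config.yaml <<'YAML'
n_seed_keep: 6
n_translated_keep: 6
synthetic: {seed: 7, n_decoys: 60, far_fraction: 0.2}
filters: {sasa_points: 120}
YAML
ternadock run --config demo/config.yaml --out-dir demo/out
```

```
4 ranked clusters -> demo/out
  prepare                          128 ->     128
  import_seeds                      60 ->      60
  seed:rough_filter                 60 ->      47
  seed:sequential_filter            47 ->      16
  seed:rank_select                  16 ->       6
  translate_grid                     6 ->    2058
  translated:rough_filter         2058 ->    2018
  translated:sequential_filter    2018 ->     639
  translated:rank_select           639 ->       6
  rotate_grid                        6 ->    2058
  rotated:rough_filter            2058 ->    2058
  rotated:sequential_filter       2058 ->     652
  fcc_cluster                      652 ->     651
  energy_cluster_filter            651 ->     651
  recluster                        651 ->     651
  rank_clusters                      4 ->       4
```

The stage report shows the funnel at work: 13 of 60 seeds fail the
3–20 Å anchor–warhead window, the sequential filters cut each pose set
to its ceiling-chain size (47 → 16 is four rounds of keep-top-75 %), and
each of the 6 consensus-selected poses spawns 343 grid placements
(6 × 343 = 2058). The run ends with 4 ranked clusters in
`demo/out/clusters.tsv` plus one representative PDB per cluster.

Scoring the rank-1 representative against the known native placement:

```bash
ternadock evaluate --model demo/out/cluster_001_c001.pdb \
                   --native demo/native.pdb --receptor-chains A
fnat   0.167
iRMSD  2.424
LRMSD  5.368
DockQ  0.386  (Acceptable)
```

i.e. the top-ranked cluster contains an acceptable-quality pose (DockQ
≥ 0.23) recovered from noisy decoys without any knowledge of the native
placement.

`ternadock benchmark` recomputes the summary statistics of the bundled
22-case benchmark tables (per-case DockQ, cluster ranks, %near-native,
selected grid transforms) from their per-case values:

```
table3_dockq
  botcp_fnat: mean 0.519 median 0.488 (n=22)
  ...
  pipeline_dockq: mean 0.554 median 0.568 (n=22)
  DockQ wins/losses/ties: 16/6/0 (win rate 72.727%)
```

## Layout

```
src/ternadock/
  structure.py   PDB I/O, preparation, moiety tags, rigid transforms
  grid.py        mass centres, distance, translation/rotation grids
  scoring.py     distance window, SASA, LJ energy, stability, z-scores,
                 sequential filtration
  ranking.py     mean-rank aggregation, top-N selection, cluster ranking
  fcc.py         interface contacts, FCC similarity, leader clustering,
                 energy-based cluster filtration
  dockq.py       Kabsch superposition, fnat/iRMSD/LRMSD/DockQ, curves
  benchmark.py   bundled 22-case tables + recomputed statistics
  synthetic.py   toy complexes and decoys with known ground truth
  pipeline.py    stage orchestration, seed import, adapters
  cli.py         `ternadock` command (prepare/synth/run/evaluate/benchmark)
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
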