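# trajcontacts

Time-resolved profiling of ligand–receptor non-covalent interactions in
molecular-dynamics trajectories.

A single snapshot of a drug bound to its target tells you which contacts
exist at one instant; what distinguishes a stable binding mode from a
transient encounter is how long each contact *persists* over the simulation.
`trajcontacts` takes a multi-frame trajectory of a solvated ligand–receptor
system (protein, nucleic acid, or both), detects five classes of
non-covalent interactions in every frame with explicit geometric criteria,
and merges everything into one canonical table keyed by the atoms involved,

```
(bond type, ligand atom IDs, receptor atom IDs[, water ID])  →  {t₁, t₂, …}
```

from which occupancy ("permanence") statistics, per-residue time series and
contact timelines follow directly.  The per-frame analysis is embarrassingly
parallel: the time window *T* is split across *p* workers (*t′ = T/p* each),
every worker walks its interval in bounded chunks of at most `N_PDB` frames,
and the final merge is associative — the output is byte-identical for any
worker count.

## Interaction classes and geometric criteria

All thresholds are configurable (`GeometricCriteria`); defaults follow the
published criteria of the standard protein–ligand interaction profiler.
Comparisons are closed: geometry exactly at a cutoff counts.

| class | rule (defaults) |
|---|---|
| hydrogen bond | donor–acceptor ≤ 4.1 Å and ∠D–H–A ≥ 100°; without explicit H: D–A ≤ 3.5 Å |
| hydrophobic | ligand C···receptor C ≤ 4.0 Å, apolar carbons only; closest contact per residue |
| π-stacking | ring centroids ≤ 5.5 Å, in-plane offset ≤ 2.0 Å; parallel ≤ 30°, T-shaped ≥ 60° |
| salt bridge | opposite-sign charged-group centers ≤ 5.5 Å |
| water bridge | ligand and receptor polar atoms both 2.5–4.1 Å from one water oxygen, with donor/acceptor complementarity |

The native trajectory format is multi-model PDB (`MODEL`/`ENDMDL` blocks,
`TITLE … t=` timestamps honored, `CONECT` used for ligand ring and
charged-group perception).  Convert binary formats (XTC, DCD) upstream, e.g.
with `gmx trjconv` or MDAnalysis.

## Worked example

```python
from trajcontacts import (PipelineConfig, run_pipeline, read_bundle,
                          bond_type_counts, permanence_heatmap)
from trajcontacts.fixtures import build_trajectory, standard_schedule

# a synthetic 40-frame trajectory with four scheduled contacts
path, manifest = build_trajectory(standard_schedule(40), 40, "traj.pdb")

run_pipeline(PipelineConfig(trajectory="traj.pdb", ligand="LIG",
                            out_dir="out", n_workers=4))
table = read_bundle("out")
print(bond_type_counts(table))
print(permanence_heatmap(table).round(1))
```

prints

```
{'hbond': 20, 'hydrophobic': 30, 'pi_stack': 20, 'salt_bridge': 10, 'water_bridge': 0}
    SER10:A  LEU20:A  PHE30:A  ARG40:A
1      50.0      0.0      0.0      0.0
6       0.0     75.0      0.0      0.0
12      0.0      0.0     50.0      0.0
...
```

i.e. the hydrogen bond between ligand atom 1 and SER10 was present in 50 %
of the frames (20 of 40), the hydrophobic contact of atom 6 with LEU20 in
75 %, and the six ligand ring atoms each π-stack on PHE30 in every second
frame — exactly the schedule the fixture planted.

The same run from a shell:

```sh
trajcontacts traj.pdb --ligand LIG --workers 4 --out-dir out
```

Every run emits exactly eight files: `bonds_complete.json` (the full table
with provenance), `hbonds.csv`, `hydrophobic-interactions.csv`,
`pi-stacks.csv`, `water-bridge.csv`, `salt-bridges.csv` (one row per
interaction per frame), and the `LIG_ATOMS.csv` / `RCPT_ATOMS.csv` atom
tables.

## Analytics

`bond_type_counts`, `atom_permanence_histogram`, `permanence_heatmap`,
`residue_time_series` and `pair_timeline` each accept a `FilterSpec`
(bond types, ligand atoms, receptor residues, protein-only/nucleic-only
composition, time window) and return plot-ready tables; see
`docs/methods.md` for their exact definitions.

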