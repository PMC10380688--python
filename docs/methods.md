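# Methods

## Model of the data

A trajectory is an ordered sequence of frames; each frame holds the same
atoms (identical serial set — enforced, a mismatch is an error) with new
coordinates.  Atom identity is the 1-based PDB serial as read; serials are
never renumbered, because the merged interaction table keys are atom-serial
tuples and must be stable across frames and workers.  Frame *i* is stamped
`t_start + i·dt` (defaults 0 ps and 10 ps — the usual save interval of
production MD) unless the file carries explicit `TITLE … t=` records, which
win.  Analysis windows are half-open `[t_start, t_end)` so adjacent windows
compose without double counting.

Roles partition every atom exhaustively and exclusively: the ligand is
whatever the user's selection (`resname[:chain[:resnum]]`) matches — all
ligand atoms are treated as a single group; standard amino acids are
protein receptor, standard (deoxy)nucleotides nucleic receptor; HOH / WAT /
SOL / TIP3 are water; single-atom NA / CL / K / MG / ZN / CA residues are
ions; everything else is inert.  Only ligand↔receptor pairs (plus water
oxygens for bridges) can ever produce an interaction, so intra-ligand and
intra-receptor contacts are structurally impossible rather than filtered.

## Chemical perception

Receptor residues are perceived from templates — per-residue atom-name
lists for donors, acceptors, apolar carbons, aromatic rings and charged
groups reflecting their known covalent topology (e.g. ARG guanidinium
NE/CZ/NH1/NH2 as a +1 group, ASP CG/OD1/OD2 as −1, nucleotide phosphate as
−1, purine/pyrimidine ring systems).  Missing atoms in a residue simply
drop the affected feature; templates never guess coordinates.

The ligand's topology is not known a priori, so it is perceived from its
CONECT bond graph; if CONECT is absent, bonds are inferred from covalent
radii (+0.45 Å slack).  Donors are N/O with a bonded hydrogen; acceptors are
oxygens and under-substituted nitrogens; hydrophobic atoms are carbons
bonded only to C/H/S; rings are 5/6-cycles of the bond graph passing a
planarity test (max 0.3 Å out-of-plane, plane fit by SVD); charged groups
are matched as carboxylate, amidinium/guanidinium and quaternary-nitrogen
patterns.  A ligand with no derivable bonds triggers a warning and skips
ring/charge perception rather than failing the run.

Protonation is not predicted.  HIS counts as a neutral donor/acceptor
unless both ring nitrogens carry explicit hydrogens, in which case the
imidazolium is a +1 group.  When a frame has no hydrogens at all (crystal
structures), every polar atom is allowed to donate and hydrogen bonds fall
back to a tighter heavy-atom-only criterion.

## Detection criteria

Defaults (all configurable, echoed into the output metadata):

- hydrogen bond: D–A ≤ 4.1 Å and ∠D–H–A ≥ 100° over any bonded H (best
  angle reported); without explicit hydrogens D–A ≤ 3.5 Å.  A pair
  qualifying in both directions is recorded once, ligand-as-donor
  preferred, with a `protisdon` flag.
- hydrophobic: apolar C···C within 0.5–4.0 Å; per (ligand atom, receptor
  residue) only the closest contact is kept, so a methyl cluster cannot
  inflate counts.
- π-stacking: centroid distance ≤ 5.5 Å, interplanar angle folded to
  [0°, 90°]; ≤ 30° is parallel (P), ≥ 60° T-shaped (T), the 30–60° band
  yields nothing.  The offset is the smaller of the two in-plane
  projections of the centroid–centroid vector: for an edge-to-face
  geometry the projection onto the edge ring's plane equals the full
  centroid distance, so the larger projection carries no information and
  taking the maximum would forbid all realistic T-stacks.
- salt bridge: opposite-sign group centers (mean of member coordinates)
  within 0.5–5.5 Å.
- water bridge: one water oxygen within 2.5–4.1 Å of both a ligand and a
  receptor polar atom, the pair providing at least one donor and one
  acceptor; each (ligand, receptor, water) triple once, a water may bridge
  several pairs.

All comparisons are closed (≤ / ≥): geometry exactly at a threshold is
reported.  Detection is a pure function of coordinates, roles and criteria —
invariant under atom-record reordering and global rigid motion (verified to
1e-6 in the suite).  A clash guard (0.5 Å) rejects degenerate pairs.

## Parallel pipeline

The window's frames are divided across *p* workers balancing frame counts
(raw picoseconds would be ambiguous when the count is not a multiple of
*p*); the remainder goes to the lowest-ranked workers, so worker loads
differ by at most one frame.  Each worker walks its interval in chunks of at
most `n_pdb_per_chunk` frames (default 100, configurable down to the
low-memory value 10), materializing only one chunk at a time; an optional
wall-clock budget stops a worker at a chunk boundary, keeping completed
chunks and recording the covered sub-window in the table metadata.  Workers
share nothing; merging unions keys, concatenates and sorts timestamp lists,
and refuses overlapping windows (a double-counting guard).  The merge is
associative and commutative, so the final table — and every output byte —
is independent of worker count and backend (in-process serial or local
process pool; an MPI backend slot exists but requires mpi4py).

## Outputs

Eight files per run: `bonds_complete.json` holds the entry map (key →
time-sorted occurrences with their geometry metrics), the atom registry and
run provenance (criteria, dt, windows, frame count, selection, schema
version).  JSON serialization is canonical — sorted keys, integers for
frame-aligned times, fixed 3-decimal picoseconds otherwise — so equal
tables give byte-identical files; this is what the parallel-equivalence
guarantee is measured against.  The five per-type CSVs hold one row per
(interaction, frame); `LIG_ATOMS.csv` lists every ligand atom and
`RCPT_ATOMS.csv` every receptor atom referenced by at least one
interaction.  `read_bundle` reconstructs the table from the JSON alone and
is the exact inverse of `write_bundle`.

## Analytics definitions

Permanence is raw frame occupancy: `100 · n_frames_present /
n_frames_total`.  Gaps are not bridged; segments are maximal runs of
consecutive frames, reported as (first, last) frame times in ps, and an
optional `gap_bridge_frames` parameter (default 0) can close short
interruptions.  Bond-type counts tally (key, frame) occurrences.  Per-atom
histograms and heatmaps attribute multi-atom keys (rings, charged groups)
to every member ligand atom, and count a frame once per cell even when
several keys coincide there (frame-level OR).  Cumulative residue time is
`n_frames_present · dt`.  Filters (bond type, ligand atoms, residues,
protein/nucleic composition, time window) intersect occurrences and can
therefore only shrink counts.

## Synthetic fixtures

The generator plants each scheduled interaction at its own station, 25 Å
from its neighbors (well beyond every cutoff), with geometry ≥ 0.2 Å / 10°
inside the thresholds in scheduled frames and ≥ 0.2 Å outside otherwise;
schedules violating these margins are refused, as is coordinate jitter
large enough to endanger them (σ ≤ 0.04 Å).  Fixtures use real residue
names (SER, LEU, PHE, ARG, HOH) and a `LIG` ligand with CONECT records so
the template and bond-graph perception paths are exercised authentically.
Every manifest is itself validated against an independent brute-force
enumeration before other tests rely on it.

What the fixtures deliberately do not emulate: thermal motion beyond small
Gaussian jitter, conformational change, crowded binding sites where
interactions compete, periodic-boundary imaging, or solvent density.
Passing tests therefore demonstrate correctness of detection geometry and
pipeline bookkeeping, not robustness to force-field artifacts or to
structures with unusual chemistry.

Problem sizes in the suite and the reproduction script — a 200-frame
parallel-equivalence run, 100-frame occupancy fixtures, 100 random
≤ 200-atom micro-frames for oracle equivalence, 10 000-frame partition
checks — were chosen as the smallest sizes at which each property is
non-trivially exercised (multiple chunks per worker, uneven partitions,
every detector hit and missed).

## Known limitations

- No energetic scoring, pKa prediction or bond-order perception beyond
  templates + CONECT; π-cation, halogen and metal interactions are out of
  scope (the five classes above are the contract).
- Binary trajectory formats require upstream conversion to multi-model PDB.
- Residue templates cover the standard amino acids, their common
  protonation variants and (deoxy)nucleotides; exotic residues degrade to
  the inert role unless selected as the ligand.
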