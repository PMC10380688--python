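"""Permanence and timeline analytics over a merged interaction table.

Five plot-ready datasets, each with dynamic filtering: per-bond-type event
counts, per-ligand-atom permanence histograms, ligand-atom x receptor-residue
permanence heatmaps, per-residue time series with cumulative contact time,
and per-(ligand atom, residue) interaction timelines.

"Permanence" is raw frame occupancy: the fraction of trajectory frames in
which an interaction is present.  Gaps are not bridged by default; a
``gap_bridge_frames`` parameter can close short interruptions when computing
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trajcontacts.detect import BOND_TYPES
from trajcontacts.pipeline import InteractionTable, Key

__all__ = [
    "FilterSpec", "PermanenceRecord", "bond_type_counts",
    "atom_permanence_histogram", "permanence_heatmap",
    "residue_time_series", "pair_timeline", "permanence_records",
    "residue_label",
]

ResidueId = tuple[str, int, str]


def residue_label(residue: ResidueId) -> str:
    name, num, chain = residue
    return f"{name}{num}:{chain}" if chain else f"{name}{num}"


@dataclass(frozen=True)
class FilterSpec:
    """Dynamic filter over interaction occurrences.

    An empty spec filters nothing.  ``composition`` restricts the receptor
    side to ``protein_only``, ``nucleic_only`` or ``both``; the time window
    is half-open [t0, t1) in picoseconds.
    """

    bond_types: frozenset[str] | None = None
    ligand_serials: frozenset[int] | None = None
    receptor_residues: frozenset[ResidueId] | None = None
    composition: str | None = None  # protein_only | nucleic_only | both
    time_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.composition not in (None, "protein_only", "nucleic_only", "both"):
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.bond_types is not None:
            unknown = set(self.bond_types) - set(BOND_TYPES)
            if unknown:
                raise ValueError(f"unknown bond types: {sorted(unknown)}")


@dataclass(frozen=True)
class PermanenceRecord:
    """Occupancy statistics for one interaction key."""

    key: Key
    n_frames_present: int
    fraction_percent: float
    segments: tuple[tuple[float, float], ...]  # maximal runs, (start_ps, end_ps)


def _key_residue(table: InteractionTable, key: Key) -> ResidueId:
    rec = table.atoms[key[2][0]]
    return (rec["resname"], rec["resnum"], rec["chain"])


def _key_passes(table: InteractionTable, key: Key, spec: FilterSpec) -> bool:
    bond, lig, rcpt, _water = key
    if spec.bond_types is not None and bond not in spec.bond_types:
        return False
    if spec.ligand_serials is not None and not set(lig) & set(spec.ligand_serials):
        return False
    if spec.receptor_residues is not None and \
            _key_residue(table, key) not in spec.receptor_residues:
        return False
    if spec.composition in ("protein_only", "nucleic_only"):
        want = "receptor_protein" if spec.composition == "protein_only" \
            else "receptor_nucleic"
        if any(table.atoms[s]["role"] != want for s in rcpt):
            return False
    return True


def _iter_events(table: InteractionTable, spec: FilterSpec | None):
    """Yield (key, time_ps, metrics) for every occurrence passing the filter."""
    spec = spec or FilterSpec()
    for key, occ in table.entries.items():
        if not _key_passes(table, key, spec):
            continue
        for t, metrics in occ:
            if spec.time_window is not None and not \
                    (spec.time_window[0] <= t < spec.time_window[1]):
                continue
            yield key, t, metrics


def _segments(times: list[float], dt: float,
              gap_bridge_frames: int = 0) -> tuple[tuple[float, float], ...]:
    """Maximal runs of consecutive frames as (first_time, last_time) ps pairs."""
    if not times:
        return ()
    times = sorted(times)
    max_gap = (1 + gap_bridge_frames) * dt + 1e-6
    segs = []
    start = prev = times[0]
    for t in times[1:]:
        if t - prev > max_gap:
            segs.append((start, prev))
            start = t
        prev = t
    segs.append((start, prev))
    return tuple(segs)


def _n_frames_total(table: InteractionTable) -> int:
    n = table.meta.get("n_frames", 0)
    if n <= 0:
        raise ValueError("table meta lacks a positive n_frames")
    return n


def bond_type_counts(table: InteractionTable,
                     spec: FilterSpec | None = None) -> dict[str, int]:
    """Number of recorded (interaction, frame) occurrences per bond type."""
    counts = {b: 0 for b in BOND_TYPES}
    for key, _t, _m in _iter_events(table, spec):
        counts[key[0]] += 1
    return counts


def atom_permanence_histogram(table: InteractionTable,
                              spec: FilterSpec | None = None
                              ) -> dict[tuple[int, str], int]:
    """Frames of presence per (ligand atom serial, bond type).

    Multi-atom keys (rings, charged groups) attribute their presence to every
    member ligand atom.  A frame counts once per (atom, type) even when
    several keys of that type involve the atom in the same frame.
    """
    frames: dict[tuple[int, str], set[float]] = {}
    for key, t, _m in _iter_events(table, spec):
        for s in key[1]:
            frames.setdefault((s, key[0]), set()).add(t)
    return {k: len(v) for k, v in sorted(frames.items())}


def permanence_records(table: InteractionTable,
                       spec: FilterSpec | None = None,
                       gap_bridge_frames: int = 0) -> list[PermanenceRecord]:
    """Per-key occupancy: frame count, percentage, maximal presence segments."""
    dt = table.meta.get("dt", 10.0)
    total = _n_frames_total(table)
    by_key: dict[Key, list[float]] = {}
    for key, t, _m in _iter_events(table, spec):
        by_key.setdefault(key, []).append(t)
    out = []
    for key in sorted(by_key, key=repr):
        times = by_key[key]
        out.append(PermanenceRecord(
            key=key,
            n_frames_present=len(times),
            fraction_percent=100.0 * len(times) / total,
            segments=_segments(times, dt, gap_bridge_frames),
        ))
    return out


def permanence_heatmap(table: InteractionTable,
                       spec: FilterSpec | None = None) -> pd.DataFrame:
    """Ligand atom x receptor residue matrix of permanence percentages.

    A cell is the percentage of frames in which the ligand atom has at least
    one interaction (of any selected type) with the residue — several bond
    types in the same frame count once.
    """
    total = _n_frames_total(table)
    cell_frames: dict[tuple[int, ResidueId], set[float]] = {}
    for key, t, _m in _iter_events(table, spec):
        residue = _key_residue(table, key)
        for s in key[1]:
            cell_frames.setdefault((s, residue), set()).add(t)
    if not cell_frames:
        return pd.DataFrame(dtype=float)
    serials = sorted({s for s, _ in cell_frames})
    residues = sorted({r for _, r in cell_frames}, key=lambda r: (r[2], r[1], r[0]))
    data = np.zeros((len(serials), len(residues)))
    for (s, r), frames in cell_frames.items():
        data[serials.index(s), residues.index(r)] = 100.0 * len(frames) / total
    return pd.DataFrame(data, index=serials,
                        columns=[residue_label(r) for r in residues])


def residue_time_series(table: InteractionTable,
                        residues: list[ResidueId],
                        spec: FilterSpec | None = None) -> dict[ResidueId, dict]:
    """Per-residue frame-presence indicator and cumulative interaction time.

    Presence OR-composes over all the residue's interactions after filtering;
    cumulative time is n_frames_present * dt picoseconds.
    """
    dt = table.meta.get("dt", 10.0)
    t0 = table.meta.get("t_start", 0.0)
    total = _n_frames_total(table)
    times_axis = t0 + dt * np.arange(total)
    frames_by_res: dict[ResidueId, set[float]] = {r: set() for r in residues}
    want = set(residues)
    for key, t, _m in _iter_events(table, spec):
        residue = _key_residue(table, key)
        if residue in want:
            frames_by_res[residue].add(t)
    out = {}
    for r in residues:
        present = np.isin(np.round((times_axis - t0) / dt).astype(int),
                          np.round((np.array(sorted(frames_by_res[r])) - t0) / dt
                                   ).astype(int) if frames_by_res[r] else [])
        out[r] = {
            "times_ps": times_axis,
            "presence": present,
            "cumulative_ps": float(len(frames_by_res[r]) * dt),
        }
    return out


def pair_timeline(table: InteractionTable, ligand_serial: int,
                  residue: ResidueId, spec: FilterSpec | None = None,
                  gap_bridge_frames: int = 0) -> dict[str, dict]:
    """Presence segments and totals per bond type for one (atom, residue) pair.

    Segments are maximal consecutive-frame runs in picoseconds; the per-type
    total equals the corresponding atom-permanence entry restricted to the
    residue.
    """
    dt = table.meta.get("dt", 10.0)
    frames_by_type: dict[str, set[float]] = {}
    for key, t, _m in _iter_events(table, spec):
        if ligand_serial not in key[1]:
            continue
        if _key_residue(table, key) != residue:
            continue
        frames_by_type.setdefault(key[0], set()).add(t)
    return {
        bond: {
            "segments": _segments(sorted(frames), dt, gap_bridge_frames),
            "n_frames": len(frames),
            "total_ps": len(frames) * dt,
        }
        for bond, frames in sorted(frames_by_type.items())
    }
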