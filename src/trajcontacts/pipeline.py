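"""Map-reduce pipeline over trajectory frames.

The analysis window is split into per-worker intervals of (near-)equal frame
counts; each worker walks its interval in bounded chunks of at most
``n_pdb_per_chunk`` frames, profiles every frame, and folds the hits into an
interaction table; the per-worker tables are then merged into one canonical
table.  Workers share nothing: only the initial assignment and the final
tables cross the worker boundary, which is what makes the final result
independent of the worker count.
"""

from __future__ import annotations

import logging
import time as _time
import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path
from typing import Sequence

from trajcontacts.detect import GeometricCriteria, Interaction, profile_frame
from trajcontacts.structure_io import (
    Frame, LigandSelection, PdbTrajectory, Role, assign_roles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_VERSION", "PartitionPlan", "ChunkPlan", "InteractionTable",
    "PipelineConfig", "make_partition", "make_chunks", "run_worker",
    "merge_tables", "run_pipeline",
]

SCHEMA_VERSION = 1

Key = tuple  # (bond_type, ligand_serials, receptor_serials, water_serial|None)


class WindowOverlapError(ValueError):
    """Tables being merged cover overlapping time windows (double counting)."""


@dataclass(frozen=True)
class PartitionPlan:
    """Per-worker decomposition of the analysis window.

    ``intervals`` holds half-open picosecond windows, one per worker;
    ``frame_ranges`` the matching half-open frame-index ranges.  Worker frame
    counts differ by at most one; any remainder goes to the lowest-ranked
    workers.
    """

    t_start: float
    t_end: float
    n_workers: int
    intervals: tuple[tuple[float, float], ...]
    frame_ranges: tuple[tuple[int, int], ...]

    @property
    def frame_counts(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in self.frame_ranges)


@dataclass(frozen=True)
class ChunkPlan:
    """Bounded-memory sub-intervals (frame-index ranges) of one worker interval."""

    n_pdb_per_chunk: int
    chunks: tuple[tuple[int, int], ...]


def make_partition(t_start: float, t_end: float, dt: float, p: int,
                   strict: bool = False) -> PartitionPlan:
    """Split the half-open window [t_start, t_end) across p workers.

    Balances frame counts, not raw picoseconds: when the frame count is not a
    multiple of p, the first (count mod p) workers get one extra frame.  With
    more workers than frames the plan contains empty intervals (a warning, or
    an error under ``strict``).
    """
    if t_end <= t_start:
        raise ValueError(f"t_end ({t_end}) must be > t_start ({t_start})")
    if p < 1:
        raise ValueError("need at least one worker")
    n_frames = int(-((t_start - t_end) // dt))  # ceil((t_end - t_start) / dt)
    if n_frames < p:
        msg = f"{p} workers for {n_frames} frames: some intervals are empty"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    base, rem = divmod(n_frames, p)
    frame_ranges = []
    start = 0
    for rank in range(p):
        count = base + (1 if rank < rem else 0)
        frame_ranges.append((start, start + count))
        start += count
    intervals = tuple(
        (t_start + a * dt, t_start + b * dt) for a, b in frame_ranges
    )
    return PartitionPlan(
        t_start=t_start, t_end=t_end, n_workers=p,
        intervals=intervals, frame_ranges=tuple(frame_ranges),
    )


def make_chunks(frame_range: tuple[int, int], n_pdb_per_chunk: int = 100) -> ChunkPlan:
    """Tile one worker's frame range into chunks of at most n_pdb_per_chunk frames."""
    if n_pdb_per_chunk < 1:
        raise ValueError("n_pdb_per_chunk must be >= 1")
    a, b = frame_range
    chunks = tuple((i, min(i + n_pdb_per_chunk, b))
                   for i in range(a, b, n_pdb_per_chunk))
    return ChunkPlan(n_pdb_per_chunk=n_pdb_per_chunk, chunks=chunks)


@dataclass
class InteractionTable:
    """Canonical time-resolved interaction table.

    ``entries`` maps (bond_type, ligand_serials, receptor_serials,
    water_serial-or-None) to the time-sorted list of (time_ps, metrics)
    occurrences.  ``atoms`` records identity for every serial referenced by a
    key plus every ligand atom.  ``meta`` carries run provenance: criteria,
    dt, covered windows, frame counts, ligand selection and residue context.
    """

    entries: dict[Key, list[tuple[float, dict]]] = field(default_factory=dict)
    atoms: dict[int, dict] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, interaction: Interaction) -> None:
        occ = self.entries.setdefault(interaction.key, [])
        if occ and occ[-1][0] >= interaction.time_ps:
            if any(t == interaction.time_ps for t, _ in occ):
                raise ValueError(
                    f"duplicate occurrence for {interaction.key} at "
                    f"{interaction.time_ps} ps")
        occ.append((interaction.time_ps, dict(interaction.metrics)))
        occ.sort(key=lambda tm: tm[0])

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def register_atom(self, atom) -> None:
        self.atoms[atom.serial] = {
            "name": atom.name, "element": atom.element,
            "resname": atom.residue_name, "resnum": atom.residue_number,
            "chain": atom.chain_id, "role": atom.role.value,
        }

    def validate(self) -> None:
        dt = self.meta.get("dt")
        t0 = self.meta.get("t_start")
        for key, occ in self.entries.items():
            times = [t for t, _ in occ]
            if sorted(set(times)) != times:
                raise ValueError(f"timestamps not strictly increasing for {key}")
            if dt and t0 is not None:
                for t in times:
                    k = (t - t0) / dt
                    if abs(k - round(k)) > 1e-6:
                        raise ValueError(
                            f"timestamp {t} is not frame-aligned for {key}")


def _coalesce(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(windows):
        if merged and abs(a - merged[-1][1]) < 1e-9:
            merged[-1][1] = b
        elif merged and a < merged[-1][1]:
            raise WindowOverlapError(f"windows overlap at {a} ps")
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


class _ListSource:
    """Adapter presenting an in-memory frame list as a chunk-readable source."""

    def __init__(self, frames: Sequence[Frame]):
        self._frames = list(frames)

    def __len__(self) -> int:
        return len(self._frames)

    def read_frames(self, start: int, stop: int) -> list[Frame]:
        return self._frames[start:stop]


def run_worker(
    frames: Sequence[Frame] | PdbTrajectory | _ListSource,
    selection: LigandSelection,
    criteria: GeometricCriteria | None = None,
    *,
    frame_range: tuple[int, int] | None = None,
    n_pdb_per_chunk: int = 100,
    time_limit_s: float | None = None,
    dt: float = 10.0,
) -> InteractionTable:
    """Profile one worker interval chunk-by-chunk into an InteractionTable.

    At most ``n_pdb_per_chunk`` frames are materialized at a time.  A wall
    clock budget, when given, is honored at chunk boundaries: completed chunks
    are kept and ``meta['windows']`` records the sub-window actually covered.
    """
    criteria = criteria or GeometricCriteria()
    source = frames if hasattr(frames, "read_frames") else _ListSource(frames)
    if frame_range is None:
        frame_range = (0, len(source))
    plan = make_chunks(frame_range, n_pdb_per_chunk)
    table = InteractionTable(meta={
        "schema_version": SCHEMA_VERSION,
        "dt": dt,
        "criteria": criteria.to_dict(),
        "ligand": sorted(selection.residue_names),
        "windows": [],
        "n_frames": 0,
    })
    started = _time.monotonic()
    covered: list[tuple[float, float]] = []
    n_done = 0
    for a, b in plan.chunks:
        if time_limit_s is not None and (_time.monotonic() - started) >= time_limit_s:
            logger.warning("time limit reached after %d frames; stopping at "
                           "chunk boundary", n_done)
            break
        chunk = source.read_frames(a, b)
        for raw in chunk:
            try:
                frame = assign_roles(raw, selection)
            except Exception as exc:
                raise RuntimeError(
                    f"frame {raw.index} failed role assignment: {exc}") from exc
            for atom in frame.atoms_with_role(Role.LIGAND):
                table.register_atom(atom)
            for hit in profile_frame(frame, criteria):
                table.add(hit)
                for s in hit.receptor_serials:
                    table.register_atom(frame.by_serial[s])
                if hit.water_serial is not None:
                    table.register_atom(frame.by_serial[hit.water_serial])
        if chunk:
            covered.append((chunk[0].time_ps, chunk[-1].time_ps + dt))
            n_done += len(chunk)
    coalesced = _coalesce(covered)
    table.meta["windows"] = [list(w) for w in coalesced]
    table.meta["n_frames"] = n_done
    if coalesced:
        table.meta["t_start"] = coalesced[0][0]
        table.meta["t_end"] = coalesced[-1][1]
    table.validate()
    return table


def merge_tables(tables: Sequence[InteractionTable]) -> InteractionTable:
    """Union per-worker tables from disjoint windows into one canonical table.

    Associative and commutative: the result is independent of input order.
    Overlapping covered windows raise :class:`WindowOverlapError`.
    """
    merged = InteractionTable()
    windows: list[tuple[float, float]] = []
    n_frames = 0
    for t in tables:
        for key, occ in t.entries.items():
            merged.entries.setdefault(key, []).extend(occ)
        merged.atoms.update(t.atoms)
        windows.extend(tuple(w) for w in t.meta.get("windows", []))
        n_frames += t.meta.get("n_frames", 0)
        for field_name in ("dt", "criteria", "ligand", "schema_version"):
            if field_name in t.meta:
                prev = merged.meta.get(field_name)
                if prev is not None and prev != t.meta[field_name]:
                    raise ValueError(
                        f"cannot merge tables with differing {field_name}")
                merged.meta[field_name] = t.meta[field_name]
    coalesced = _coalesce(windows)
    for key in merged.entries:
        occ = sorted(merged.entries[key], key=lambda tm: tm[0])
        times = [tm[0] for tm in occ]
        if len(set(times)) != len(times):
            raise WindowOverlapError(
                f"duplicate timestamp for key {key} while merging")
        merged.entries[key] = occ
    merged.meta["windows"] = [list(w) for w in coalesced]
    merged.meta["n_frames"] = n_frames
    if coalesced:
        merged.meta["t_start"] = coalesced[0][0]
        merged.meta["t_end"] = coalesced[-1][1]
    merged.validate()
    return merged


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs; mirrors the CLI flags."""

    trajectory: str
    ligand: str
    out_dir: str
    start_ps: float | None = None  # analysis window start (default: whole file)
    end_ps: float | None = None
    traj_t_start: float = 0.0  # time of frame 0 when the file has no t= records
    dt: float = 10.0
    n_workers: int = 1
    n_pdb_per_chunk: int = 100
    time_limit_s: float | None = None
    backend: str = "serial"  # serial | pool | mpi
    criteria: GeometricCriteria = field(default_factory=GeometricCriteria)
    strict: bool = False


def _pool_worker(args: tuple) -> InteractionTable:
    (path, traj_t_start, dt, frame_range, sel_text, criteria_dict,
     n_pdb, time_limit_s) = args
    traj = PdbTrajectory(path, t_start=traj_t_start, dt=dt)
    return run_worker(
        traj, LigandSelection.parse(sel_text),
        GeometricCriteria.from_dict(criteria_dict),
        frame_range=frame_range, n_pdb_per_chunk=n_pdb,
        time_limit_s=time_limit_s, dt=dt,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run partition -> chunked workers -> merge -> output bundle.

    Returns the mapping of output filename to written path.  The merged table
    (and hence every output byte) is independent of ``n_workers`` and
    ``backend``.
    """
    from trajcontacts.outputs import write_bundle  # local import: avoid cycle

    selection = LigandSelection.parse(config.ligand)
    traj = PdbTrajectory(config.trajectory, t_start=config.traj_t_start,
                         dt=config.dt)
    times = traj.times
    if len(times) == 0:
        raise ValueError(f"{config.trajectory}: no frames found")
    ws = config.start_ps if config.start_ps is not None else float(times[0])
    we = config.end_ps if config.end_ps is not None else float(times[-1]) + config.dt
    in_window = [i for i, t in enumerate(times) if ws <= t < we]
    if not in_window:
        raise ValueError(
            f"window [{ws}, {we}) ps contains no trajectory frames "
            f"(trajectory spans [{times[0]}, {times[-1]}] ps)")
    first = in_window[0]
    plan = make_partition(ws, we, config.dt, config.n_workers,
                          strict=config.strict)
    logger.info("window [%s, %s) ps: %d frames over %d workers",
                ws, we, len(in_window), config.n_workers)

    jobs = []
    for (a, b) in plan.frame_ranges:
        jobs.append((first + a, first + b))

    t0 = _time.monotonic()
    if config.backend == "serial":
        tables = [
            run_worker(traj, selection, config.criteria, frame_range=rng,
                       n_pdb_per_chunk=config.n_pdb_per_chunk,
                       time_limit_s=config.time_limit_s, dt=config.dt)
            for rng in jobs
        ]
    elif config.backend == "pool":
        args = [
            (config.trajectory, config.traj_t_start, config.dt, rng,
             config.ligand, config.criteria.to_dict(),
             config.n_pdb_per_chunk, config.time_limit_s)
            for rng in jobs
        ]
        with ProcessPoolExecutor(max_workers=min(config.n_workers, 8)) as pool:
            tables = list(pool.map(_pool_worker, args))
    elif config.backend == "mpi":
        raise RuntimeError(
            "the MPI backend requires mpi4py, which is not installed; "
            "use --backend serial or pool")
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    logger.info("profiling done in %.2f s; merging %d tables",
                _time.monotonic() - t0, len(tables))

    merged = merge_tables(tables)
    merged.meta["ligand"] = sorted(selection.residue_names)
    out = write_bundle(merged, config.out_dir)
    logger.info("wrote %d files to %s (%d interaction events)",
                len(out), config.out_dir, merged.n_events)
    return out
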