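"""Serialization of the merged interaction table to the canonical file set.

One run emits exactly eight files: a JSON dictionary with every recorded
interaction plus provenance, five per-bond-type CSVs (one row per
interaction occurrence, i.e. per (interaction, frame)), and two atom tables
covering the ligand and the receptor atoms referenced by interactions.
JSON keys are serialized canonically (sorted, stable number formatting) so
identical tables produce byte-identical files regardless of worker count.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from trajcontacts.pipeline import InteractionTable, SCHEMA_VERSION

__all__ = ["OUTPUT_FILENAMES", "BOND_CSV", "write_bundle", "read_bundle",
           "SchemaVersionError"]

BOND_CSV = {
    "hbond": "hbonds.csv",
    "hydrophobic": "hydrophobic-interactions.csv",
    "pi_stack": "pi-stacks.csv",
    "water_bridge": "water-bridge.csv",
    "salt_bridge": "salt-bridges.csv",
}

OUTPUT_FILENAMES = (
    "bonds_complete.json",
    "hbonds.csv",
    "hydrophobic-interactions.csv",
    "pi-stacks.csv",
    "water-bridge.csv",
    "salt-bridges.csv",
    "LIG_ATOMS.csv",
    "RCPT_ATOMS.csv",
)

_METRIC_COLUMNS = {
    "hbond": ["da_dist", "dha_angle", "protisdon"],
    "hydrophobic": ["dist"],
    "pi_stack": ["centroid_dist", "angle", "offset", "stack_type"],
    "salt_bridge": ["center_dist", "ligand_sign"],
    "water_bridge": ["dist_lw", "dist_rw"],
}


class SchemaVersionError(ValueError):
    """The JSON on disk was written with an incompatible schema version."""


def _fmt_time(t: float) -> int | float:
    """Integers for frame-aligned times, else fixed 3-decimal picoseconds."""
    if abs(t - round(t)) < 1e-9:
        return int(round(t))
    return round(t, 3)


def _key_to_str(key: tuple) -> str:
    bond, lig, rcpt, water = key
    return "|".join([
        bond,
        ",".join(str(s) for s in lig),
        ",".join(str(s) for s in rcpt),
        "-" if water is None else str(water),
    ])


def _key_from_str(text: str) -> tuple:
    bond, lig, rcpt, water = text.split("|")
    return (
        bond,
        tuple(int(s) for s in lig.split(",")),
        tuple(int(s) for s in rcpt.split(",")),
        None if water == "-" else int(water),
    )


def write_bundle(table: InteractionTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the eight-file output set; returns filename -> path.

    An empty table is a valid run with zero interactions: the CSVs are
    written header-only and the JSON carries an empty entry map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.validate()
    written: dict[str, Path] = {}

    doc = {
        "schema_version": SCHEMA_VERSION,
        "meta": {k: v for k, v in sorted(table.meta.items())
                 if k != "schema_version"},
        "atoms": {str(s): rec for s, rec in sorted(table.atoms.items())},
        "entries": {
            _key_to_str(key): [[_fmt_time(t), metrics] for t, metrics in occ]
            for key, occ in sorted(table.entries.items(),
                                   key=lambda kv: _key_to_str(kv[0]))
        },
    }
    json_path = out_dir / "bonds_complete.json"
    json_path.write_text(
        json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n",
        encoding="utf-8",
    )
    written["bonds_complete.json"] = json_path

    by_type: dict[str, list[tuple]] = {b: [] for b in BOND_CSV}
    for key, occ in table.entries.items():
        by_type[key[0]].append((key, occ))
    for bond, filename in BOND_CSV.items():
        path = out_dir / filename
        metric_cols = _METRIC_COLUMNS[bond]
        header = ["time_ps", "ligand_serials", "receptor_serials"]
        if bond == "water_bridge":
            header.append("water_serial")
        header += ["receptor_resname", "receptor_resnum", "chain"] + metric_cols
        rows = []
        for key, occ in sorted(by_type[bond], key=lambda kv: _key_to_str(kv[0])):
            _, lig, rcpt, water = key
            atom = table.atoms.get(rcpt[0], {})
            for t, metrics in occ:
                row = [
                    _fmt_time(t),
                    "|".join(str(s) for s in lig),
                    "|".join(str(s) for s in rcpt),
                ]
                if bond == "water_bridge":
                    row.append(water)
                row += [atom.get("resname", ""), atom.get("resnum", ""),
                        atom.get("chain", "")]
                row += [metrics.get(c, "") for c in metric_cols]
                rows.append(row)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)
        written[filename] = path

    referenced: set[int] = set()
    for key in table.entries:
        referenced.update(key[1])
        referenced.update(key[2])
        if key[3] is not None:
            referenced.add(key[3])
    atom_header = ["serial", "name", "element", "resname", "resnum", "chain"]
    for filename, keep in (
        ("LIG_ATOMS.csv", lambda s, rec: rec["role"] == "ligand"),
        ("RCPT_ATOMS.csv", lambda s, rec: rec["role"].startswith("receptor")
         and s in referenced),
    ):
        path = out_dir / filename
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(atom_header)
            for s, rec in sorted(table.atoms.items()):
                if keep(s, rec):
                    w.writerow([s, rec["name"], rec["element"], rec["resname"],
                                rec["resnum"], rec["chain"]])
        written[filename] = path
    return written


def _reject_duplicate_keys(pairs):
    seen = {}
    for k, v in pairs:
        if k in seen:
            raise ValueError(f"duplicate key in JSON document: {k!r}")
        seen[k] = v
    return seen


def read_bundle(directory: str | Path) -> InteractionTable:
    """Reconstruct the interaction table from bonds_complete.json.

    The JSON is the single source of truth; the CSVs are derived views.
    read_bundle(write_bundle(t)) == t for any valid table.
    """
    directory = Path(directory)
    json_path = directory / "bonds_complete.json"
    if not json_path.exists():
        raise FileNotFoundError(f"{json_path} not found")
    doc = json.loads(json_path.read_text(encoding="utf-8"),
                     object_pairs_hook=_reject_duplicate_keys)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"file schema version {version!r} != supported {SCHEMA_VERSION}")
    table = InteractionTable()
    table.meta = dict(doc.get("meta", {}))
    table.meta["schema_version"] = version
    table.atoms = {int(s): rec for s, rec in doc.get("atoms", {}).items()}
    for keystr, occ in doc.get("entries", {}).items():
        key = _key_from_str(keystr)
        if key in table.entries:
            raise ValueError(f"duplicate interaction key: {keystr}")
        table.entries[key] = [(float(t), dict(metrics)) for t, metrics in occ]
    table.validate()
    return table
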