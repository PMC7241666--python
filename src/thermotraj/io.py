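"""Readers for PDB structures and trajectories; writers for result tables.

Two trajectory formats are supported, both plain text:

* ``pdb_multimodel`` — standard MODEL/ENDMDL blocks;
* ``xyz_frames`` — a minimal whitespace dialect: a header line
  ``natoms nframes``, then per frame one comment line followed by ``natoms``
  lines of ``x y z`` in topology order.

Frame indexing is 0-based throughout; trajectory times are stored in ps
(``index * stride * time_step``) and reported in ns in output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from thermotraj.model import (
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
    atomic_mass,
    element_from_name,
    vdw_radius,
)

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryFileSpec:
    path: str | Path
    format: str = "xyz_frames"  # or "pdb_multimodel"
    stride: int = 1
    time_step: float = 10.0  # ps per saved frame

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.format not in ("pdb_multimodel", "xyz_frames"):
            raise ValueError(f"unknown trajectory format {self.format!r}")


def _parse_pdb_atom_line(line: str) -> tuple[AtomRecord, np.ndarray, str]:
    """Parse one fixed-column ATOM/HETATM record -> (record, xyz, altLoc)."""
    serial = int(line[6:11])
    name = line[12:16].strip()
    alt_loc = line[16:17].strip()
    res_name = line[17:20].strip()
    chain_id = line[21:22].strip() or "A"
    res_seq = int(line[22:26])
    xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = element_from_name(name)
    record = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=res_name,
        residue_seq=res_seq,
        chain_id=chain_id,
        mass=atomic_mass(element),
        vdw_radius=vdw_radius(element),
    )
    return record, xyz, alt_loc


def read_pdb(path: str | Path) -> tuple[Topology, Frame]:
    """Read a PDB structure: atoms in file order, first MODEL's coordinates.

    Duplicate (chain, resSeq, name) records with alternate locations keep
    altLoc 'A' or blank, with a warning.  Raises if no ATOM/HETATM records
    are found.
    """
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    seen: set[tuple[str, int, str]] = set()
    in_first_model = True
    with open(path) as fh:
        for line in fh:
            tag = line[:6]
            if tag == "MODEL ":
                continue
            if tag == "ENDMDL":
                in_first_model = False
                continue
            if not in_first_model:
                continue
            if tag in ("ATOM  ", "HETATM"):
                record, xyz, alt_loc = _parse_pdb_atom_line(line)
                if alt_loc not in ("", "A"):
                    logger.warning(
                        "skipping altLoc %r of atom %s/%d %s",
                        alt_loc,
                        record.chain_id,
                        record.residue_seq,
                        record.name,
                    )
                    continue
                key = (record.chain_id, record.residue_seq, record.name)
                if key in seen:
                    logger.warning("duplicate atom %s, keeping first occurrence", key)
                    continue
                seen.add(key)
                records.append(record)
                coords.append(xyz)
    if not records:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    ref = np.array(coords)
    topology = Topology(records, ref)
    return topology, Frame(index=0, time=0.0, coords=ref)


def _read_pdb_models(path: str | Path) -> list[np.ndarray]:
    """All MODEL coordinate blocks of a multi-model PDB (file order)."""
    models: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    saw_model_tag = False
    with open(path) as fh:
        for line in fh:
            tag = line[:6]
            if tag == "MODEL ":
                saw_model_tag = True
                current = []
            elif tag == "ENDMDL":
                models.append(current)
                current = []
            elif tag in ("ATOM  ", "HETATM"):
                _, xyz, alt_loc = _parse_pdb_atom_line(line)
                if alt_loc in ("", "A"):
                    current.append(xyz)
    if not saw_model_tag and current:
        models.append(current)
    return [np.array(m) for m in models if m]


def _read_xyz_frames(path: str | Path) -> list[np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        n_atoms, n_frames = int(header[0]), int(header[1])
        frames = []
        for _ in range(n_frames):
            fh.readline()  # per-frame comment
            block = np.loadtxt(fh, max_rows=n_atoms, ndmin=2)
            frames.append(block[:, :3])
    return frames


def read_trajectory(spec: TrajectoryFileSpec, topology: Topology) -> Trajectory:
    """Read a trajectory file and bind it to an existing topology.

    Keeps every ``stride``-th frame; frame times are
    ``kept_index * stride * time_step`` ps.  Raises on any frame whose atom
    count differs from the topology.
    """
    if spec.format == "pdb_multimodel":
        raw = _read_pdb_models(spec.path)
    else:
        raw = _read_xyz_frames(spec.path)
    if not raw:
        raise ValueError(f"{spec.path}: no frames found")
    frames = []
    for out_index, file_index in enumerate(range(0, len(raw), spec.stride)):
        coords = raw[file_index]
        if coords.shape[0] != topology.n_atoms:
            raise ValueError(
                f"frame {file_index}: {coords.shape[0]} atoms, "
                f"topology has {topology.n_atoms}"
            )
        frames.append(
            Frame(
                index=out_index,
                time=out_index * spec.stride * spec.time_step,
                coords=coords,
            )
        )
    return Trajectory(topology=topology, frames=frames)


def write_pdb(path: str | Path, topology: Topology, frame: Frame) -> None:
    """Write a single-structure PDB (fixed columns, one chain block)."""
    with open(path, "w") as fh:
        for i, atom in enumerate(topology.atoms):
            x, y, z = frame.coords[i]
            tag = "HETATM" if topology.residues[topology.residue_of_atom[i]].is_water or topology.residues[topology.residue_of_atom[i]].is_ion else "ATOM  "
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            fh.write(
                f"{tag}{atom.serial:>5d} {name}{'':1s}{atom.residue_name:>3s} "
                f"{atom.chain_id}{atom.residue_seq:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}\n"
            )
        fh.write("END\n")


def write_xyz_frames(path: str | Path, trajectory: Trajectory) -> None:
    """Write the xyz_frames dialect (header, then per-frame blocks)."""
    with open(path, "w") as fh:
        fh.write(f"{trajectory.topology.n_atoms} {trajectory.n_frames}\n")
        for frame in trajectory.frames:
            fh.write(f"# frame {frame.index} time_ps {frame.time:.3f}\n")
            np.savetxt(fh, frame.coords, fmt="%.4f")


def write_records(records, path: str | Path, format: str = "csv",
                  sort_by: list[str] | None = None,
                  columns: list[str] | None = None) -> None:
    """Write homogeneous records (dataclasses, dicts, or a DataFrame).

    CSV output has a header row, floats at 4 decimals, and a deterministic
    row order (``sort_by`` columns when given, otherwise input order).
    ``columns`` supplies the header for an empty record list.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=columns) if columns else pd.DataFrame(rows)
    if sort_by and not df.empty:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.4f")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=float)
            fh.write("\n")
    else:
        raise ValueError(f"unknown output format {format!r}")
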