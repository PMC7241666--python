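"""Domain types for structures and trajectories, plus residue-chemistry tables.

The central containers are :class:`Topology` (atom identities, residues,
bonds, named selections) and :class:`Trajectory` (a frame sequence bound to
one topology).  Coordinates live in frames, never in atom records, so one
topology serves every frame of a trajectory.

Residue chemistry follows the brewing-enzyme thermostability convention:
charged = {Arg, Lys, Asp, Glu}, polar = {Gln, Asn, Ser, Thr, Tyr, Cys},
hydrophobic = {Ala, Ile, Leu, Phe, Val, Pro, Gly, Met, Trp}; everything
else (including His) is "other".  For surface-area partitioning,
"hydrophilic" means every protein residue that is not hydrophobic, so the
hydrophobic + hydrophilic areas add up to the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# Residue chemical classes.  His is deliberately in none of the three named
# sets: it is ionizable but its protonation is pH-dependent, so it is kept
# out of "charged" and lands in "other".
CHARGED_RESIDUES = frozenset({"ARG", "LYS", "ASP", "GLU"})
POLAR_RESIDUES = frozenset({"GLN", "ASN", "SER", "THR", "TYR", "CYS"})
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "ILE", "LEU", "PHE", "VAL", "PRO", "GLY", "MET", "TRP"}
)

WATER_NAMES = frozenset({"WAT", "HOH"})
ION_NAMES = frozenset({"NA", "CA", "CL", "MG", "ZN", "K"})

#: Catalytic residues of barley limit dextrinase: Asp473 (nucleophile),
#: Glu510 (general acid/base), Asp642 (transition-state stabilizer).
CATALYTIC_RESIDUES = frozenset({473, 510, 642})

# Bondi van der Waals radii (Angstrom) by element; 1.7 fallback for unknowns.
VDW_RADII = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "F": 1.47,
    "CL": 1.75,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "ZN": 1.39,
}
DEFAULT_VDW_RADIUS = 1.7

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,
    "CL": 35.45,
    "ZN": 65.38,
}
DEFAULT_MASS = 12.011

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})

# Bond-inference cutoffs (Angstrom).
_H_BOND_CUTOFF = 1.3
_HEAVY_BOND_CUTOFF = 1.9
_PEPTIDE_BOND_CUTOFF = 2.0


def classify_residue(residue_name: str) -> str:
    """Classify a 3-letter residue code as charged/polar/hydrophobic/other.

    Unknown names are classified "other" with a logged warning rather than
    raising, so chemically modified residues do not abort a run.
    """
    name = residue_name.upper().strip()
    if name in CHARGED_RESIDUES:
        return "charged"
    if name in POLAR_RESIDUES:
        return "polar"
    if name in HYDROPHOBIC_RESIDUES:
        return "hydrophobic"
    known = (
        CHARGED_RESIDUES
        | POLAR_RESIDUES
        | HYDROPHOBIC_RESIDUES
        | {"HIS", "ASN", "GLN"}
        | WATER_NAMES
        | ION_NAMES
    )
    if name not in known:
        logger.warning("unknown residue name %r classified as 'other'", residue_name)
    return "other"


def element_from_name(atom_name: str) -> str:
    """Infer the element from a PDB atom name (digit-stripped first letters)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in ("CL", "NA", "MG", "ZN", "BR", "FE") and len(
        atom_name.strip()
    ) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity (coordinates are held in frames, not here)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    mass: float
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdW radius must be positive")


@dataclass(frozen=True)
class Residue:
    name: str
    seq: int
    chain_id: str
    atom_start: int  # first atom index (inclusive)
    atom_stop: int  # last atom index (exclusive)

    @property
    def atom_indices(self) -> range:
        return range(self.atom_start, self.atom_stop)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_ion(self) -> bool:
        return self.name in ION_NAMES


class Topology:
    """Ordered atoms grouped into residues, with bonds and named selections.

    Parameters
    ----------
    atoms
        Atom records in file order.  (chain_id, residue_seq, name) must be
        unique; consecutive atoms sharing (chain_id, residue_seq,
        residue_name) form one residue.
    reference_coords
        (n_atoms, 3) coordinates used for geometric bond inference.  Bonds
        are needed for donor-hydrogen lookup in hydrogen-bond analysis.
    """

    def __init__(self, atoms: list[AtomRecord], reference_coords: np.ndarray):
        self.atoms: list[AtomRecord] = list(atoms)
        coords = np.asarray(reference_coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"reference coords shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a topology")
        keys = [(a.chain_id, a.residue_seq, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("(chain_id, residue_seq, name) must be unique")

        self.residues: list[Residue] = self._group_residues()
        self.bonds: list[tuple[int, int]] = self._infer_bonds(coords)
        self._bonded: dict[int, list[int]] = {}
        for i, j in self.bonds:
            self._bonded.setdefault(i, []).append(j)
            self._bonded.setdefault(j, []).append(i)
        self.selections: dict[str, np.ndarray] = build_selections(self)

        self.residue_of_atom = np.empty(len(self.atoms), dtype=int)
        for ri, res in enumerate(self.residues):
            self.residue_of_atom[res.atom_start : res.atom_stop] = ri

    def _group_residues(self) -> list[Residue]:
        residues: list[Residue] = []
        start = 0
        for i in range(1, len(self.atoms) + 1):
            if i == len(self.atoms) or (
                self.atoms[i].chain_id,
                self.atoms[i].residue_seq,
                self.atoms[i].residue_name,
            ) != (
                self.atoms[start].chain_id,
                self.atoms[start].residue_seq,
                self.atoms[start].residue_name,
            ):
                a = self.atoms[start]
                residues.append(
                    Residue(a.residue_name, a.residue_seq, a.chain_id, start, i)
                )
                start = i
        return residues

    def _infer_bonds(self, coords: np.ndarray) -> list[tuple[int, int]]:
        """Geometric bond inference on the reference coordinates.

        Hydrogens bond to the nearest heavy atom within 1.3 A (same residue).
        Heavy atoms within 1.9 A of each other in the same residue are
        bonded.  Across residues only the peptide C(i)-N(i+1) bond (within
        2.0 A, same chain, consecutive seq) is recognized, which keeps
        sterically crowded side chains from acquiring spurious bonds.
        """
        bonds: list[tuple[int, int]] = []
        for res in self.residues:
            idx = np.array(list(res.atom_indices))
            if len(idx) < 2:
                continue
            sub = coords[idx]
            is_h = np.array([self.atoms[i].element == "H" for i in idx])
            d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
            heavy_local = np.where(~is_h)[0]
            for hl in np.where(is_h)[0]:
                if heavy_local.size == 0:
                    continue
                nearest = heavy_local[np.argmin(d[hl, heavy_local])]
                if d[hl, nearest] <= _H_BOND_CUTOFF:
                    bonds.append((int(idx[min(hl, nearest)]), int(idx[max(hl, nearest)])))
            for a in range(len(idx)):
                if is_h[a]:
                    continue
                for b in range(a + 1, len(idx)):
                    if is_h[b]:
                        continue
                    if d[a, b] <= _HEAVY_BOND_CUTOFF:
                        bonds.append((int(idx[a]), int(idx[b])))
        # peptide bonds between consecutive residues of the same chain
        for r1, r2 in zip(self.residues, self.residues[1:]):
            if r1.chain_id != r2.chain_id or r2.seq != r1.seq + 1:
                continue
            c_idx = self._find_atom_in(r1, "C")
            n_idx = self._find_atom_in(r2, "N")
            if c_idx is None or n_idx is None:
                continue
            if np.linalg.norm(coords[c_idx] - coords[n_idx]) <= _PEPTIDE_BOND_CUTOFF:
                bonds.append((c_idx, n_idx))
        return sorted(set(bonds))

    def _find_atom_in(self, res: Residue, name: str) -> int | None:
        for i in res.atom_indices:
            if self.atoms[i].name == name:
                return i
        return None

    def bonded_to(self, atom_index: int) -> list[int]:
        return self._bonded.get(atom_index, [])

    def bonded_hydrogens(self, atom_index: int) -> list[int]:
        return [
            j for j in self.bonded_to(atom_index) if self.atoms[j].element == "H"
        ]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, residue_seq: int, atom_name: str, chain_id: str | None = None) -> int:
        """Look up an atom by (residue_seq, name); raises KeyError if absent."""
        for i, a in enumerate(self.atoms):
            if a.residue_seq == residue_seq and a.name == atom_name:
                if chain_id is None or a.chain_id == chain_id:
                    return i
        raise KeyError(f"atom {atom_name} of residue {residue_seq} not in topology")


def build_selections(topology: Topology) -> dict[str, np.ndarray]:
    """Compute the named index sets: protein, backbone, side_chain, water, ions.

    Backbone = atoms named N, CA, C, O in protein residues; side_chain is the
    protein complement (including hydrogens, so backbone and side chain
    partition the protein only over heavy backbone names plus everything
    else).  Raises if the protein selection is empty.
    """
    protein, backbone, side_chain, water, ions = [], [], [], [], []
    for res in topology.residues:
        if res.is_water:
            water.extend(res.atom_indices)
        elif res.is_ion:
            ions.extend(res.atom_indices)
        else:
            for i in res.atom_indices:
                protein.append(i)
                a = topology.atoms[i]
                if a.name in BACKBONE_ATOM_NAMES:
                    backbone.append(i)
                else:
                    side_chain.append(i)
    if not protein:
        raise ValueError("topology contains no protein atoms")
    return {
        "protein": np.array(protein, dtype=int),
        "backbone": np.array(backbone, dtype=int),
        "side_chain": np.array(side_chain, dtype=int),
        "water": np.array(water, dtype=int),
        "ions": np.array(ions, dtype=int),
    }


def is_backbone_participant(topology: Topology, atom_index: int) -> bool:
    """True if the atom is a backbone atom (N, CA, C, O) or a hydrogen bonded
    to a backbone atom — the main-chain side of MM/MS/SS classification."""
    atom = topology.atoms[atom_index]
    if atom.name in BACKBONE_ATOM_NAMES:
        return True
    if atom.element == "H":
        for j in topology.bonded_to(atom_index):
            if topology.atoms[j].name in BACKBONE_ATOM_NAMES:
                return True
    return False


@dataclass
class Frame:
    """Coordinates for every topology atom at one saved time point."""

    index: int
    time: float  # ps
    coords: np.ndarray  # (n_atoms, 3) Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")


@dataclass
class Trajectory:
    """A frame sequence bound to one topology, with a condition label."""

    topology: Topology
    frames: list[Frame]
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {f.index}: {f.coords.shape[0]} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if len(times) > 1 and not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def xyz(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([f.coords for f in self.frames])

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])
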