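"""Salt bridges, hydrophobic contacts, and named-pair distance monitoring.

A salt bridge is present in a frame when an acidic side-chain oxygen
(Asp OD1/OD2, Glu OE1/OE2) lies strictly within 4 Angstrom of a basic
side-chain nitrogen (Arg NE/NH1/NH2, Lys NZ).  Atom pairs between the same
residue pair are redundant: the unique record keeps the highest-occupancy
atom pair and reports its mean and standard deviation distance over the
frames where it is formed.

A hydrophobic contact joins two residues when any pair of designated carbon
atoms (backbone C/CA plus the side-chain carbons) is within 4 Angstrom
(inclusive); multiple in-range carbon pairs in a frame still count as one
contact ("without redundancy").  Same-residue and sequence-adjacent pairs
are excluded — neighboring backbones are always in range and would swamp
the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from thermotraj.model import HYDROPHOBIC_RESIDUES, Topology, Trajectory
from thermotraj.occupancy import occupancy as occupancy_pct

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # Angstrom, strict <
DEFAULT_CONTACT_CUTOFF = 4.0  # Angstrom, inclusive <=
LITERATURE_CONTACT_CUTOFF = 3.9  # alternative carbon-carbon cutoff

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}

#: PDB spellings of the designated hydrophobic carbon names.
HYDROPHOBIC_ATOM_NAMES = frozenset(
    {"C", "CA", "CB", "CD", "CD1", "CD2", "CE", "CE1", "CE2", "CE3",
     "CG", "CG1", "CG2", "CZ", "CZ2", "CZ3", "CH2"}
)


@dataclass
class PairSeries:
    """One atom pair's per-frame presence and distances."""

    atom_a: int
    atom_b: int
    presence: np.ndarray
    distances: np.ndarray

    @property
    def occupancy(self) -> float:
        return occupancy_pct(self.presence)


@dataclass
class SaltBridgeRecord:
    """A unique salt bridge (one per acidic/basic residue pair)."""

    acidic_residue: str  # e.g. "D317"
    basic_residue: str  # e.g. "R378"
    acidic_atom: str
    basic_atom: str
    occupancy: float  # best atom pair (primary number)
    union_occupancy: float  # any atom pair in range
    mean_distance: float
    sd_distance: float
    presence: np.ndarray = field(repr=False, default=None)

    @property
    def pair_label(self) -> str:
        return f"{self.acidic_residue}-{self.basic_residue}"


@dataclass
class HydrophobicContactRecord:
    residue_a: str
    residue_b: str
    atom_a: str
    atom_b: str
    occupancy: float
    presence: np.ndarray = field(repr=False, default=None)

    @property
    def pair_label(self) -> str:
        return f"{self.residue_a}-{self.residue_b}"


_ONE_LETTER = {"ASP": "D", "GLU": "E", "ARG": "R", "LYS": "K"}


def _residue_label(topology: Topology, atom_index: int) -> str:
    a = topology.atoms[atom_index]
    return f"{_ONE_LETTER.get(a.residue_name, a.residue_name)}{a.residue_seq}"


def detect_salt_bridges(
    trajectory: Trajectory,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> list[PairSeries]:
    """Per-frame salt-bridge events for every acidic-O/basic-N atom pair.

    An event is present when the distance is strictly below ``cutoff``.
    Returns one PairSeries per atom pair with at least one event.
    """
    if cutoff <= 0:
        raise ValueError("salt-bridge cutoff must be positive")
    topology = trajectory.topology
    acidic = [i for i, a in enumerate(topology.atoms)
              if a.name in ACIDIC_ATOMS.get(a.residue_name, ())]
    basic = [i for i, a in enumerate(topology.atoms)
             if a.name in BASIC_ATOMS.get(a.residue_name, ())]
    if not acidic or not basic:
        return []
    acidic_arr = np.array(acidic)
    basic_arr = np.array(basic)
    xyz = trajectory.xyz
    # (frames, acidic, basic) distances — the atom sets are small
    d = np.linalg.norm(
        xyz[:, acidic_arr, None, :] - xyz[:, basic_arr, None, :].transpose(0, 2, 1, 3),
        axis=-1,
    )
    present = d < cutoff
    out = []
    for ai in range(len(acidic)):
        for bi in range(len(basic)):
            bits = present[:, ai, bi]
            if bits.any():
                out.append(
                    PairSeries(
                        atom_a=int(acidic_arr[ai]),
                        atom_b=int(basic_arr[bi]),
                        presence=bits,
                        distances=d[:, ai, bi],
                    )
                )
    return out


def unique_salt_bridges(
    events: list[PairSeries], topology: Topology
) -> list[SaltBridgeRecord]:
    """Collapse atom pairs per residue pair, keeping the highest occupancy.

    The record carries both the best-atom-pair occupancy (primary) and the
    union occupancy (any atom pair in range in a frame), plus the best
    pair's mean and sd distance over the frames where it is formed.
    """
    res_of = topology.residue_of_atom
    by_pair: dict[tuple[int, int], list[PairSeries]] = {}
    for ev in events:
        key = (int(res_of[ev.atom_a]), int(res_of[ev.atom_b]))
        by_pair.setdefault(key, []).append(ev)
    records = []
    for key, group in sorted(by_pair.items()):
        group = sorted(group, key=lambda e: (-e.occupancy, e.atom_a, e.atom_b))
        best = group[0]
        union = np.zeros_like(best.presence)
        for ev in group:
            union |= ev.presence
        dists = best.distances[best.presence]
        aa = topology.atoms[best.atom_a]
        ba = topology.atoms[best.atom_b]
        records.append(
            SaltBridgeRecord(
                acidic_residue=_residue_label(topology, best.atom_a),
                basic_residue=_residue_label(topology, best.atom_b),
                acidic_atom=aa.name,
                basic_atom=ba.name,
                occupancy=best.occupancy,
                union_occupancy=occupancy_pct(union),
                mean_distance=float(dists.mean()) if dists.size else float("nan"),
                sd_distance=float(dists.std(ddof=0)) if dists.size else float("nan"),
                presence=best.presence,
            )
        )
    return records


def detect_hydrophobic_contacts(
    trajectory: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    restrict_to_hydrophobic_residues: bool = False,
) -> list[HydrophobicContactRecord]:
    """Residue-pair hydrophobic contacts over all frames.

    Presence in a frame means any whitelisted carbon pair across the two
    residues is within ``cutoff`` (inclusive); same-residue and
    sequence-adjacent (|delta seq| <= 1, same chain) pairs are excluded.
    The record names the atom pair most often in range.
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    topology = trajectory.topology
    water = set(topology.selections["water"].tolist())
    ions = set(topology.selections["ions"].tolist())
    carbons = [
        i
        for i, a in enumerate(topology.atoms)
        if a.name in HYDROPHOBIC_ATOM_NAMES
        and i not in water
        and i not in ions
        and (not restrict_to_hydrophobic_residues
             or a.residue_name in HYDROPHOBIC_RESIDUES)
    ]
    if len(carbons) < 2:
        return []
    carbon_arr = np.array(carbons)
    res_of = topology.residue_of_atom
    n_frames = trajectory.n_frames

    pair_presence: dict[tuple[int, int], np.ndarray] = {}
    atom_pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]] = {}
    for k, frame in enumerate(trajectory.frames):
        tree = cKDTree(frame.coords[carbon_arr])
        for li, lj in tree.query_pairs(cutoff):
            i, j = int(carbon_arr[li]), int(carbon_arr[lj])
            ri, rj = int(res_of[i]), int(res_of[j])
            if ri == rj:
                continue
            res_i, res_j = topology.residues[ri], topology.residues[rj]
            if res_i.chain_id == res_j.chain_id and abs(res_i.seq - res_j.seq) <= 1:
                continue
            key = (min(ri, rj), max(ri, rj))
            if key not in pair_presence:
                pair_presence[key] = np.zeros(n_frames, dtype=bool)
                atom_pair_counts[key] = {}
            pair_presence[key][k] = True
            akey = (min(i, j), max(i, j))
            atom_pair_counts[key][akey] = atom_pair_counts[key].get(akey, 0) + 1

    records = []
    for (ri, rj), bits in sorted(pair_presence.items()):
        counts = atom_pair_counts[(ri, rj)]
        (ai, aj), _ = max(sorted(counts.items()), key=lambda kv: kv[1])
        res_i, res_j = topology.residues[ri], topology.residues[rj]
        records.append(
            HydrophobicContactRecord(
                residue_a=f"{res_i.name}{res_i.seq}",
                residue_b=f"{res_j.name}{res_j.seq}",
                atom_a=topology.atoms[ai].name,
                atom_b=topology.atoms[aj].name,
                occupancy=occupancy_pct(bits),
                presence=bits,
            )
        )
    return records


@dataclass
class DistanceMonitor:
    series: pd.DataFrame  # frame, time_ns, distance
    fraction_below: float  # fraction of frames with distance <= threshold


def monitor_distance(
    trajectory: Trajectory,
    atom_a: tuple[int, str],
    atom_b: tuple[int, str],
    threshold: float = 3.5,
) -> DistanceMonitor:
    """Track the distance between two named atoms across the trajectory.

    ``atom_a`` / ``atom_b`` are (residue_seq, atom_name) pairs; raises
    KeyError naming the missing atom if either is absent.  Returns the
    per-frame distance series and the fraction of frames at or below
    ``threshold``.
    """
    topology = trajectory.topology
    ia = topology.atom_index(*atom_a)
    ib = topology.atom_index(*atom_b)
    xyz = trajectory.xyz
    d = np.linalg.norm(xyz[:, ia, :] - xyz[:, ib, :], axis=-1)
    series = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ns": trajectory.times_ps / 1000.0,
            "distance": d,
        }
    )
    return DistanceMonitor(
        series=series,
        fraction_below=float(np.count_nonzero(d <= threshold) / trajectory.n_frames),
    )
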