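"""Ground-truth fixture generator: toy topologies and designed trajectories.

Builds idealized extended-chain peptides (PDB-standard atom names, explicit
hydrogens on donors, optional water shell and divalent ion) and
multi-condition trajectories with:

* per-residue isotropic Gaussian jitter whose amplitude scales with a
  condition "temperature" factor — so RMSF recovers the designed sigmas;
* deterministic interaction schedules — for each scheduled hydrogen bond /
  salt bridge / hydrophobic contact, the partner atoms are placed at an
  in-range geometry in exactly round(occupancy * n_frames) frames (chosen
  by a seeded permutation) and well out of range (>= 5 A) otherwise, so the
  detectors recover the designed occupancy exactly rather than to within
  binomial noise.

The generated frames are not physically realistic (no force field, no
integrator, side-chain tips teleport between in-range and parked
positions); they exist to give every analysis stage a known ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from thermotraj.model import (
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
    atomic_mass,
    vdw_radius,
)

# Side-chain heavy-atom graph per residue: (atom_name, parent_name) in
# build order, parent "CA" starts the chain.  Geometry is idealized, not
# stereochemical: the chain zigzags away from the backbone at 1.5 A steps.
_SIDE_CHAINS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CB", "CA")],
    "VAL": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB")],
    "LEU": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
    "ILE": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")],
    "PRO": [("CB", "CA"), ("CG", "CB"), ("CD", "CG")],
    "MET": [("CB", "CA"), ("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
    "PHE": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
            ("CE1", "CD1"), ("CE2", "CD2"), ("CZ", "CE1")],
    "TRP": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
            ("NE1", "CD1"), ("CE2", "CD2"), ("CE3", "CD2"),
            ("CZ2", "CE2"), ("CZ3", "CE3"), ("CH2", "CZ2")],
    "SER": [("CB", "CA"), ("OG", "CB")],
    "THR": [("CB", "CA"), ("OG1", "CB"), ("CG2", "CB")],
    "CYS": [("CB", "CA"), ("SG", "CB")],
    "TYR": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
            ("CE1", "CD1"), ("CE2", "CD2"), ("CZ", "CE1"), ("OH", "CZ")],
    "ASN": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")],
    "GLN": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"),
            ("NE2", "CD")],
    "ASP": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
    "GLU": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"),
            ("OE2", "CD")],
    "LYS": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("CE", "CD"),
            ("NZ", "CE")],
    "ARG": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("NE", "CD"),
            ("CZ", "NE"), ("NH1", "CZ"), ("NH2", "CZ")],
    "HIS": [("CB", "CA"), ("CG", "CB"), ("ND1", "CG"), ("CD2", "CG"),
            ("CE1", "ND1"), ("NE2", "CD2")],
}

# Polar hydrogens placed on donor heavy atoms: residue -> {heavy: [H names]}
_POLAR_HYDROGENS: dict[str, dict[str, list[str]]] = {
    "SER": {"OG": ["HG"]},
    "THR": {"OG1": ["HG1"]},
    "CYS": {"SG": ["HG"]},
    "TYR": {"OH": ["HH"]},
    "ASN": {"ND2": ["HD21", "HD22"]},
    "GLN": {"NE2": ["HE21", "HE22"]},
    "LYS": {"NZ": ["HZ1", "HZ2", "HZ3"]},
    "ARG": {"NE": ["HE"], "NH1": ["HH11", "HH12"], "NH2": ["HH21", "HH22"]},
    "TRP": {"NE1": ["HE1"]},
    "HIS": {"ND1": ["HD1"]},
}

_CA_SPACING = 3.8  # Angstrom between consecutive alpha carbons
_STEP = 1.5  # heavy-atom bond step within side chains


@dataclass
class InteractionSchedule:
    """A designed interaction toggled to hit an exact target occupancy.

    kind: "hbond" (donor triple; acceptor is placed collinear at 2.9 A),
    "saltbridge" (basic N placed at 3.2 A from the acidic O), or "contact"
    (second carbon placed at 3.8 A).  ``atom_a`` stays with its residue's
    jittered position; ``atom_b`` (and the hydrogen for hbonds) is placed
    relative to it every frame.
    """

    kind: str  # hbond | saltbridge | contact
    atom_a: tuple[int, str]  # (residue_seq, atom_name) anchor
    atom_b: tuple[int, str]  # (residue_seq, atom_name) moved partner
    occupancy: float  # target percent in (0, 100]
    hydrogen: tuple[int, str] | None = None  # hbond only: donor's hydrogen

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 100.0:
            raise ValueError("target occupancy must be in (0, 100]")
        if self.kind not in ("hbond", "saltbridge", "contact"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "hbond" and self.hydrogen is None:
            raise ValueError("hbond schedules need the donor's hydrogen")


_IN_RANGE = {"hbond": 2.9, "saltbridge": 3.2, "contact": 3.8}
_OUT_OF_RANGE = 6.0


@dataclass
class ConditionSpec:
    """One simulated condition (a temperature / ion-presence system)."""

    label: str
    temperature_factor: float = 1.0  # scales every residue's jitter sigma
    schedules: list[InteractionSchedule] = field(default_factory=list)


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic multi-condition study."""

    sequence: list[str]
    n_frames: int = 500
    seed: int = 0
    base_sigma: float = 0.15  # Angstrom per-residue jitter at factor 1.0
    planted_regions: list[tuple[int, int, float]] = field(default_factory=list)
    # (start_seq, end_seq, sigma) ranges with elevated jitter
    n_waters: int = 0
    include_divalent_ion: bool = False
    conditions: list[ConditionSpec] = field(default_factory=list)
    time_step: float = 10.0  # ps between saved frames


@dataclass
class GroundTruth:
    """Designed quantities written alongside every generated fixture."""

    condition_label: str
    designed_occupancies: dict[str, float]
    sigma_per_residue: dict[int, float]
    temperature_factor: float
    planted_regions: list[tuple[int, int, float]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "condition_label": self.condition_label,
                    "designed_occupancies": self.designed_occupancies,
                    "sigma_per_residue": {
                        str(k): v for k, v in self.sigma_per_residue.items()
                    },
                    "temperature_factor": self.temperature_factor,
                    "planted_regions": self.planted_regions,
                },
                fh,
                indent=1,
            )
            fh.write("\n")


def build_toy_topology(
    sequence: list[str],
    n_waters: int = 0,
    include_divalent_ion: bool = False,
) -> tuple[Topology, Frame]:
    """Build an idealized extended-chain peptide topology + reference frame.

    Residues are spaced 3.8 A apart along x; side chains extend in -y with
    hydrogens offset in z so geometric bond inference is unambiguous.
    Waters sit on a grid at least 4 A from the protein; the optional
    divalent ion (Ca2+) is parked beyond the waters.
    """
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(name: str, element: str, res_name: str, res_seq: int,
            xyz: np.ndarray, chain: str = "A") -> None:
        nonlocal serial
        records.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_name=res_name,
                residue_seq=res_seq,
                chain_id=chain,
                mass=atomic_mass(element),
                vdw_radius=vdw_radius(element),
            )
        )
        coords.append(np.asarray(xyz, dtype=float))
        serial += 1

    for ri, res_name in enumerate(sequence):
        res_name = res_name.upper()
        if res_name not in _SIDE_CHAINS:
            raise ValueError(f"unknown residue {res_name!r} in sequence")
        seq = ri + 1
        ca = np.array([_CA_SPACING * ri, 0.0, 0.0])
        n_pos = ca + np.array([-1.45, 0.0, 0.0])
        c_pos = ca + np.array([1.0, 1.05, 0.0])
        o_pos = c_pos + np.array([0.65, 1.05, 0.0])
        add("N", "N", res_name, seq, n_pos)
        add("CA", "C", res_name, seq, ca)
        add("C", "C", res_name, seq, c_pos)
        add("O", "O", res_name, seq, o_pos)
        if res_name != "PRO":
            add("H", "H", res_name, seq, n_pos + np.array([0.0, -0.8, 0.6]))

        placed: dict[str, np.ndarray] = {"CA": ca}
        branch_sign = {}
        for name, parent in _SIDE_CHAINS[res_name]:
            base = placed[parent]
            # children of one parent fan out in +/-x; chain advances in -y
            n_children = branch_sign.get(parent, 0)
            branch_sign[parent] = n_children + 1
            dx = 0.0 if n_children == 0 else (0.9 if n_children == 1 else -0.9)
            dy = -np.sqrt(max(_STEP**2 - dx**2, 0.25))
            pos = base + np.array([dx, dy, 0.0])
            placed[name] = pos
            element = name[0] if name[0] in ("C", "N", "O", "S") else "C"
            add(name, element, res_name, seq, pos)
        for heavy, hnames in _POLAR_HYDROGENS.get(res_name, {}).items():
            if heavy not in placed:
                continue
            for hk, hname in enumerate(hnames):
                offset = {
                    0: np.array([0.0, 0.0, 1.0]),
                    1: np.array([0.0, 0.0, -1.0]),
                    2: np.array([0.0, -0.7, 0.71]),
                }[hk]
                add(hname, "H", res_name, seq, placed[heavy] + offset)

    # water grid in a plane well below the side chains
    protein_min_y = min(c[1] for c in coords) if coords else 0.0
    base_y = protein_min_y - 6.0
    per_row = max(1, int(np.ceil(np.sqrt(n_waters)))) if n_waters else 1
    for w in range(n_waters):
        seq = len(sequence) + 1 + w
        gx = 3.0 * (w % per_row)
        gz = 3.0 * (w // per_row)
        o = np.array([gx, base_y, gz])
        add("O", "O", "WAT", seq, o, chain="W")
        add("H1", "H", "WAT", seq, o + np.array([0.76, 0.59, 0.0]), chain="W")
        add("H2", "H", "WAT", seq, o + np.array([-0.76, 0.59, 0.0]), chain="W")
    if include_divalent_ion:
        seq = len(sequence) + n_waters + 1
        add("CA", "CA", "CA", seq, np.array([-8.0, base_y - 6.0, 0.0]), chain="I")

    ref = np.array(coords)
    topology = Topology(records, ref)
    return topology, Frame(index=0, time=0.0, coords=ref)


def _sigma_vector(
    topology: Topology,
    base_sigma: float,
    planted_regions: list[tuple[int, int, float]],
) -> tuple[np.ndarray, dict[int, float]]:
    """Per-atom sigma from the base value and planted elevated ranges."""
    per_residue: dict[int, float] = {}
    sigma = np.zeros(topology.n_atoms)
    for res in topology.residues:
        if res.is_water or res.is_ion:
            s = base_sigma
        else:
            s = base_sigma
            for lo, hi, elevated in planted_regions:
                if lo <= res.seq <= hi:
                    s = elevated
            per_residue[res.seq] = s
        sigma[res.atom_start : res.atom_stop] = s
    return sigma, per_residue


def generate_trajectory(
    topology: Topology,
    reference: Frame,
    spec: SyntheticSpec,
    condition: ConditionSpec,
    bernoulli: bool = False,
) -> tuple[Trajectory, GroundTruth]:
    """Generate one condition's trajectory with exact-count schedules.

    Jitter is isotropic Gaussian per atom with the residue's sigma times
    the condition's temperature factor.  Scheduled partner atoms are placed
    relative to their (jittered) anchor: in-range in exactly
    round(occupancy/100 * n_frames) frames chosen by a seeded permutation
    (or by independent Bernoulli draws when ``bernoulli=True``), parked at
    6 A otherwise.  Schedules sharing a moved atom are rejected.
    """
    n_frames = spec.n_frames
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    moved: set[int] = set()
    resolved = []
    for sched in condition.schedules:
        ia = topology.atom_index(*sched.atom_a)
        ib = topology.atom_index(*sched.atom_b)
        ih = topology.atom_index(*sched.hydrogen) if sched.hydrogen else None
        for m in ([ib, ih] if ih is not None else [ib]):
            if m in moved:
                raise ValueError(
                    f"infeasible schedule: atom index {m} moved by two schedules"
                )
            moved.add(m)
        resolved.append((sched, ia, ih, ib))

    label_digest = zlib.crc32(condition.label.encode("utf-8"))
    seed = (spec.seed * 1000003 + label_digest) % (2**31)
    rng = np.random.default_rng(seed)
    sigma_atoms, sigma_res = _sigma_vector(
        topology, spec.base_sigma, spec.planted_regions
    )
    sigma_atoms = sigma_atoms * condition.temperature_factor

    schedules_in: list[np.ndarray] = []
    designed: dict[str, float] = {}
    for sched, ia, ih, ib in resolved:
        n_in = int(round(sched.occupancy / 100.0 * n_frames))
        if bernoulli:
            bits = rng.random(n_frames) < sched.occupancy / 100.0
        else:
            bits = np.zeros(n_frames, dtype=bool)
            bits[rng.permutation(n_frames)[:n_in]] = True
        schedules_in.append(bits)
        key = f"{sched.kind}:{sched.atom_a[0]}{sched.atom_a[1]}-{sched.atom_b[0]}{sched.atom_b[1]}"
        designed[key] = 100.0 * n_in / n_frames if not bernoulli else sched.occupancy

    # unit directions per schedule, fixed across frames, pointing away from
    # the protein bulk so parked partners do not collide with anything
    directions = []
    for sched, ia, ih, ib in resolved:
        u = np.array([0.0, -1.0, 0.0]) + rng.normal(0, 0.05, 3)
        directions.append(u / np.linalg.norm(u))

    frames = []
    for k in range(n_frames):
        coords = reference.coords + rng.normal(0, 1.0, (topology.n_atoms, 3)) * (
            sigma_atoms[:, None]
        )
        for s_idx, (sched, ia, ih, ib) in enumerate(resolved):
            u = directions[s_idx]
            anchor = coords[ia]
            dist = _IN_RANGE[sched.kind] if schedules_in[s_idx][k] else _OUT_OF_RANGE
            if sched.kind == "hbond":
                # collinear donor-H-acceptor along u
                coords[ih] = anchor + u * 1.0
                coords[ib] = anchor + u * dist
            else:
                coords[ib] = anchor + u * dist
        frames.append(Frame(index=k, time=k * spec.time_step, coords=coords))

    truth = GroundTruth(
        condition_label=condition.label,
        designed_occupancies=designed,
        sigma_per_residue={
            seq: s * condition.temperature_factor for seq, s in sigma_res.items()
        },
        temperature_factor=condition.temperature_factor,
        planted_regions=list(spec.planted_regions),
    )
    return (
        Trajectory(topology=topology, frames=frames, condition_label=condition.label),
        truth,
    )


def generate_study(
    spec: SyntheticSpec,
) -> tuple[Topology, Frame, dict[str, Trajectory], dict[str, GroundTruth]]:
    """Build the topology and one trajectory per condition."""
    topology, reference = build_toy_topology(
        spec.sequence, spec.n_waters, spec.include_divalent_ion
    )
    trajectories: dict[str, Trajectory] = {}
    truths: dict[str, GroundTruth] = {}
    for condition in spec.conditions:
        traj, truth = generate_trajectory(topology, reference, spec, condition)
        trajectories[condition.label] = traj
        truths[condition.label] = truth
    return topology, reference, trajectories, truths
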