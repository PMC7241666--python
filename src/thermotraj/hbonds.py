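"""Geometric hydrogen-bond detection, deduplication and category bookkeeping.

A hydrogen bond is present in a frame when the donor-acceptor heavy-atom
distance is at most 3.5 Angstrom (inclusive) and the donor-hydrogen-acceptor
angle, measured at the hydrogen, exceeds 120 degrees (strict).  Donors are
N/O atoms carrying at least one bonded hydrogen (one candidate per
hydrogen); acceptors are all N/O atoms.  Intra-residue pairs are excluded;
backbone i/i+1 pairs are kept.

Candidates sharing the same (donor atom, acceptor atom) but different
hydrogens are redundant: deduplication keeps the highest-occupancy one.
Records are then classified three ways:

* backbone class MM / MS / SS — whether the donor side and acceptor side
  are main-chain (N, CA, C, O, or a hydrogen bonded to one) or side-chain;
* chemical class — from the two residues' classes: chr-chr, pho-pho,
  phi-phi (polar-polar), pho-phi; any pair involving "other" or a mixed
  charged pairing is "other";
* partner kind — protein-protein or protein-water (water-water pairs are
  never enumerated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from thermotraj.model import (
    Topology,
    Trajectory,
    classify_residue,
    is_backbone_participant,
)
from thermotraj.occupancy import occupancy as occupancy_pct

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_CUTOFF = 3.5  # Angstrom, donor-acceptor, inclusive
DEFAULT_ANGLE_CUTOFF = 120.0  # degrees at the hydrogen, strict


@dataclass
class HBondCandidate:
    """One donor-hydrogen-acceptor triple with its per-frame presence."""

    donor: int
    hydrogen: int
    acceptor: int
    presence: np.ndarray  # (n_frames,) bool
    distances: np.ndarray  # (n_frames,) donor-acceptor distance, Angstrom

    @property
    def occupancy(self) -> float:
        return occupancy_pct(self.presence)


@dataclass
class HBondRecord:
    """A deduplicated hydrogen bond with occupancy and category labels."""

    donor: int
    hydrogen: int
    acceptor: int
    donor_residue: str
    acceptor_residue: str
    donor_atom: str
    acceptor_atom: str
    occupancy: float
    presence: np.ndarray = field(repr=False)
    backbone_class: str = ""  # MM / MS / SS ("" for protein-water)
    chem_class: str = ""  # chr-chr / pho-pho / phi-phi / pho-phi / other
    partner_kind: str = "protein"  # protein / water
    water_class: str = ""  # M-water / S-water (protein-water records only)
    water_chem: str = ""  # chr-water / pho-water / phi-water / other-water


def enumerate_donors_acceptors(
    topology: Topology,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Donor (heavy atom, hydrogen) pairs and the acceptor atom list.

    Raises if no hydrogens are present at all: hydrogen-bond analysis needs
    a protonated input structure.
    """
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    any_h = any(a.element == "H" for a in topology.atoms)
    if not any_h:
        raise ValueError(
            "topology contains no hydrogens; hydrogen-bond analysis requires "
            "a protonated structure"
        )
    for i, atom in enumerate(topology.atoms):
        if atom.element not in ("N", "O"):
            continue
        acceptors.append(i)
        for h in topology.bonded_hydrogens(i):
            donors.append((i, h))
    return donors, acceptors


def detect_hbonds(
    trajectory: Trajectory,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    include_water: bool = True,
) -> list[HBondCandidate]:
    """Detect hydrogen bonds over all frames (neighbor-accelerated).

    Returns one candidate per donor-hydrogen-acceptor triple that is present
    in at least one frame.  ``include_water=False`` restricts both donors and
    acceptors to protein atoms; when water is included, water-water pairs
    are skipped.
    """
    if distance_cutoff <= 0 or angle_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    topology = trajectory.topology
    donors, acceptors = enumerate_donors_acceptors(topology)
    water_set = set(topology.selections["water"].tolist())
    if not include_water:
        donors = [(d, h) for d, h in donors if d not in water_set]
        acceptors = [a for a in acceptors if a not in water_set]
    ion_set = set(topology.selections["ions"].tolist())
    acceptors = [a for a in acceptors if a not in ion_set]
    acc_arr = np.array(acceptors, dtype=int)
    res_of = topology.residue_of_atom

    n_frames = trajectory.n_frames
    cos_cut = np.cos(np.deg2rad(angle_cutoff))
    found: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    donor_heavy = np.array([d for d, _ in donors], dtype=int)
    donor_h = np.array([h for _, h in donors], dtype=int)

    for k, frame in enumerate(trajectory.frames):
        coords = frame.coords
        acc_tree = cKDTree(coords[acc_arr])
        near = acc_tree.query_ball_point(coords[donor_heavy], distance_cutoff)
        for di in range(len(donors)):
            d, h = int(donor_heavy[di]), int(donor_h[di])
            for aj in near[di]:
                a = int(acc_arr[aj])
                if a == d or res_of[a] == res_of[d]:
                    continue
                if d in water_set and a in water_set:
                    continue
                dist = float(np.linalg.norm(coords[a] - coords[d]))
                if dist > distance_cutoff:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cos_angle = float(np.dot(v1, v2) / denom)
                # angle > cutoff  <=>  cos(angle) < cos(cutoff)
                if cos_angle < cos_cut:
                    key = (d, h, a)
                    if key not in found:
                        found[key] = (
                            np.zeros(n_frames, dtype=bool),
                            np.full(n_frames, np.nan),
                        )
                    found[key][0][k] = True
                    found[key][1][k] = dist
    return [
        HBondCandidate(donor=d, hydrogen=h, acceptor=a, presence=bits, distances=dists)
        for (d, h, a), (bits, dists) in sorted(found.items())
    ]


def dedupe_hbonds(candidates: list[HBondCandidate],
                  topology: Topology) -> list[HBondRecord]:
    """Collapse candidates sharing (donor, acceptor) to the max-occupancy one.

    Ties are broken by the lowest hydrogen index (logged), so results are
    deterministic.
    """
    by_pair: dict[tuple[int, int], list[HBondCandidate]] = {}
    for c in candidates:
        by_pair.setdefault((c.donor, c.acceptor), []).append(c)
    records = []
    for (d, a), group in sorted(by_pair.items()):
        group = sorted(group, key=lambda c: (-c.occupancy, c.hydrogen))
        best = group[0]
        if len(group) > 1 and group[1].occupancy == best.occupancy:
            logger.info(
                "hbond occupancy tie for donor %d acceptor %d: keeping hydrogen %d",
                d, a, best.hydrogen,
            )
        da = topology.atoms[d]
        aa = topology.atoms[a]
        records.append(
            HBondRecord(
                donor=d,
                hydrogen=best.hydrogen,
                acceptor=a,
                donor_residue=f"{da.residue_name}{da.residue_seq}",
                acceptor_residue=f"{aa.residue_name}{aa.residue_seq}",
                donor_atom=da.name,
                acceptor_atom=aa.name,
                occupancy=best.occupancy,
                presence=best.presence,
            )
        )
    return records


_CHEM_PAIRS = {
    frozenset(["charged"]): "chr-chr",
    frozenset(["hydrophobic"]): "pho-pho",
    frozenset(["polar"]): "phi-phi",
    frozenset(["hydrophobic", "polar"]): "pho-phi",
}

_CHEM_WATER = {"charged": "chr-water", "hydrophobic": "pho-water",
               "polar": "phi-water", "other": "other-water"}


def classify_hbonds(records: list[HBondRecord],
                    topology: Topology) -> list[HBondRecord]:
    """Fill backbone_class, chem_class, partner_kind (in place, returned)."""
    water_set = set(topology.selections["water"].tolist())
    for r in records:
        donor_is_water = r.donor in water_set
        acceptor_is_water = r.acceptor in water_set
        if donor_is_water or acceptor_is_water:
            r.partner_kind = "water"
            protein_atom = r.acceptor if donor_is_water else r.donor
            # main-chain side: for a protein donor the hydrogen sits on the
            # donor heavy atom, so the heavy atom decides in both directions
            r.water_class = (
                "M-water" if is_backbone_participant(topology, protein_atom)
                else "S-water"
            )
            res = topology.atoms[protein_atom]
            r.water_chem = _CHEM_WATER[classify_residue(res.residue_name)]
            continue
        r.partner_kind = "protein"
        donor_main = is_backbone_participant(topology, r.donor)
        acceptor_main = is_backbone_participant(topology, r.acceptor)
        if donor_main and acceptor_main:
            r.backbone_class = "MM"
        elif donor_main or acceptor_main:
            r.backbone_class = "MS"
        else:
            r.backbone_class = "SS"
        c1 = classify_residue(topology.atoms[r.donor].residue_name)
        c2 = classify_residue(topology.atoms[r.acceptor].residue_name)
        r.chem_class = _CHEM_PAIRS.get(frozenset([c1, c2]), "other")
    return records


PROTEIN_CATEGORIES = ("total", "MM", "MS", "SS",
                      "chr-chr", "pho-pho", "phi-phi", "pho-phi", "other")
WATER_CATEGORIES = ("total", "M-water", "S-water",
                    "chr-water", "pho-water", "phi-water", "other-water")


def mean_hbond_counts(records: list[HBondRecord]) -> dict[str, dict[str, float]]:
    """Mean per-frame hydrogen-bond counts by category.

    The mean count of a category is the sum over its records of
    frames-present, divided by the number of frames — i.e. the sum of the
    records' occupancy fractions.  Returns ``{"protein": {...}, "water":
    {...}}`` shaped like the intra-protein and protein-water count tables.
    """
    protein = {c: 0.0 for c in PROTEIN_CATEGORIES}
    water = {c: 0.0 for c in WATER_CATEGORIES}
    for r in records:
        frac = r.occupancy / 100.0
        if r.partner_kind == "water":
            water["total"] += frac
            water[r.water_class] += frac
            water[r.water_chem] += frac
        else:
            protein["total"] += frac
            protein[r.backbone_class] += frac
            protein[r.chem_class] += frac
    return {"protein": protein, "water": water}
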