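"""Hydrogen-bond geometry rules, dedup, classification, and count bookkeeping."""

import numpy as np
import pytest

from thermotraj import synthetic as syn
from thermotraj.hbonds import (
    classify_hbonds,
    dedupe_hbonds,
    detect_hbonds,
    enumerate_donors_acceptors,
    mean_hbond_counts,
)
from thermotraj.model import AtomRecord, Frame, Topology, Trajectory
from tests.conftest import make_trajectory
from tests.oracles import brute_force_hbonds


def _donor_acceptor_fixture(da_distance, dha_angle_deg):
    """A minimal O-H donor (residue 1) and O acceptor (residue 2) geometry.

    The hydrogen sits 1.0 A from the donor along +x; the acceptor is placed
    so that the donor-acceptor distance and the D-H-A angle at the hydrogen
    take the requested values.
    """
    donor = np.zeros(3)
    acceptor = np.array([da_distance, 0.0, 0.0])  # exact float distance
    # hydrogen 1.0 A from the donor, forming the requested D-H-A angle:
    # law of cosines gives |H-A|, then H's x from the two circle equations
    theta = np.deg2rad(dha_angle_deg)
    r = np.cos(theta) + np.sqrt(np.cos(theta) ** 2 - 1.0 + da_distance**2)
    hx = (1.0 + da_distance**2 - r**2) / (2.0 * da_distance)
    hydrogen = np.array([hx, np.sqrt(max(1.0 - hx**2, 0.0)), 0.0])
    atoms = [
        AtomRecord(1, "OG", "O", "SER", 1, "A", 15.999, 1.52),
        AtomRecord(2, "HG", "H", "SER", 1, "A", 1.008, 1.2),
        AtomRecord(3, "OD1", "O", "ASP", 2, "A", 15.999, 1.52),
        AtomRecord(4, "CA", "C", "ASP", 2, "A", 12.011, 1.7),
    ]
    coords = np.array([donor, hydrogen, acceptor, acceptor + [0, 0, 5.0]])
    topology = Topology(atoms, coords)
    return make_trajectory(topology, Frame(0, 0.0, coords), [coords])


@pytest.mark.parametrize(
    "distance,angle,expected",
    [
        (3.4, 150.0, True),  # inside both criteria
        (3.5, 121.0, True),  # boundary distance inclusive, angle just above
        (3.6, 179.0, False),  # exceeds the 3.5 A maximum
        (2.9, 180.0, True),  # collinear
        (2.9, 110.0, False),  # bent below the angle cutoff
        (2.9, 119.9, False),  # angle cutoff is strict: just below fails
    ],
)
def test_geometric_criteria(distance, angle, expected):
    traj = _donor_acceptor_fixture(distance, angle)
    candidates = detect_hbonds(traj)
    found = any(
        traj.topology.atoms[c.donor].name == "OG"
        and traj.topology.atoms[c.acceptor].name == "OD1"
        and c.presence[0]
        for c in candidates
    )
    assert found == expected


def test_detection_angle_value_is_as_constructed():
    traj = _donor_acceptor_fixture(3.0, 150.0)
    c = traj.frames[0].coords
    v1, v2 = c[0] - c[1], c[2] - c[1]
    angle = np.degrees(
        np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    )
    assert angle == pytest.approx(150.0, abs=1e-6)
    assert np.linalg.norm(c[2] - c[0]) == pytest.approx(3.0, abs=1e-9)


def test_donor_acceptor_enumeration(peptide):
    topology, _ = peptide
    donors, acceptors = enumerate_donors_acceptors(topology)
    donor_names = {
        (topology.atoms[d].residue_name, topology.atoms[d].name,
         topology.atoms[h].name)
        for d, h in donors
    }
    # SER OG donates via HG; LYS NZ has three donor hydrogens
    assert ("SER", "OG", "HG") in donor_names
    nz_pairs = [(d, h) for d, h in donors if topology.atoms[d].name == "NZ"
                and topology.atoms[d].residue_seq == 2]
    assert len(nz_pairs) == 3
    # water O is both donor (twice) and acceptor
    water_o = [i for i in topology.selections["water"]
               if topology.atoms[i].name == "O"]
    for o in water_o:
        assert sum(1 for d, _ in donors if d == o) == 2
        assert o in acceptors
    # every acceptor is N or O
    assert all(topology.atoms[a].element in ("N", "O") for a in acceptors)


def test_hydrogen_free_topology_rejected():
    atoms = [
        AtomRecord(1, "N", "N", "GLY", 1, "A", 14.0, 1.55),
        AtomRecord(2, "CA", "C", "GLY", 1, "A", 12.0, 1.7),
        AtomRecord(3, "C", "C", "GLY", 1, "A", 12.0, 1.7),
        AtomRecord(4, "O", "O", "GLY", 1, "A", 16.0, 1.52),
    ]
    coords = np.array([[0, 0, 0], [1.45, 0, 0], [2.4, 1, 0], [3, 2, 0]], float)
    topology = Topology(atoms, coords)
    with pytest.raises(ValueError, match="hydrogen"):
        enumerate_donors_acceptors(topology)


class TestDedup:
    def _schedule_traj(self, occ_a=60.0, occ_b=40.0, n_frames=100):
        """LYS NZ donates to GLU OE1 via two different hydrogens."""
        seq = ["LYS", "ALA", "GLU"]
        topology, reference = syn.build_toy_topology(seq)
        nz = topology.atom_index(1, "NZ")
        hz1 = topology.atom_index(1, "HZ1")
        hz2 = topology.atom_index(1, "HZ2")
        oe1 = topology.atom_index(3, "OE1")
        rng = np.random.default_rng(13)
        in_a = np.zeros(n_frames, dtype=bool)
        in_a[: int(occ_a)] = True
        in_b = np.zeros(n_frames, dtype=bool)
        in_b[int(occ_a) : int(occ_a) + int(occ_b)] = True
        coords_list = []
        u = np.array([0.0, -1.0, 0.0])
        for k in range(n_frames):
            c = reference.coords.copy()
            if in_a[k]:
                c[hz1] = c[nz] + u * 1.0
                c[oe1] = c[nz] + u * 2.9
            elif in_b[k]:
                c[hz2] = c[nz] + u * 1.0
                c[oe1] = c[nz] + u * 2.9
                c[hz1] = c[nz] + np.array([0.0, 1.0, 0.0])
            else:
                c[oe1] = c[nz] + u * 8.0
            coords_list.append(c)
        return make_trajectory(topology, reference, coords_list), nz, oe1

    def test_keeps_highest_occupancy_hydrogen(self):
        traj, nz, oe1 = self._schedule_traj()
        candidates = detect_hbonds(traj)
        ours = [c for c in candidates if c.donor == nz and c.acceptor == oe1]
        assert len(ours) >= 2  # two hydrogens produced separate candidates
        records = dedupe_hbonds(candidates, traj.topology)
        merged = [r for r in records if r.donor == nz and r.acceptor == oe1]
        assert len(merged) == 1
        assert merged[0].occupancy == pytest.approx(60.0)
        assert merged[0].occupancy == pytest.approx(
            max(c.occupancy for c in ours)
        )

    def test_dedup_never_increases_count(self):
        traj, _, _ = self._schedule_traj()
        candidates = detect_hbonds(traj)
        records = dedupe_hbonds(candidates, traj.topology)
        assert len(records) <= len(candidates)

    def test_exact_tie_keeps_lowest_hydrogen_index(self):
        traj, nz, oe1 = self._schedule_traj(occ_a=50.0, occ_b=50.0)
        records = dedupe_hbonds(detect_hbonds(traj), traj.topology)
        merged = [r for r in records if r.donor == nz and r.acceptor == oe1][0]
        assert merged.occupancy == pytest.approx(50.0)
        hz1 = traj.topology.atom_index(1, "HZ1")
        assert merged.hydrogen == hz1

    def test_single_candidate_unchanged(self):
        traj = _donor_acceptor_fixture(3.0, 170.0)
        candidates = detect_hbonds(traj)
        records = dedupe_hbonds(candidates, traj.topology)
        keyed = {(c.donor, c.acceptor): c for c in candidates}
        for r in records:
            assert r.occupancy == keyed[(r.donor, r.acceptor)].occupancy


class TestClassification:
    def _record_for(self, topology, traj, donor_name, acceptor_name):
        records = classify_hbonds(
            dedupe_hbonds(detect_hbonds(traj), topology), topology
        )
        for r in records:
            if r.donor_atom == donor_name and r.acceptor_atom == acceptor_name:
                return r
        raise AssertionError(
            f"no record {donor_name}->{acceptor_name} in "
            f"{[(r.donor_atom, r.acceptor_atom) for r in records]}"
        )

    def test_side_chain_charged_pair_is_SS_chr_chr(self):
        seq = ["ARG", "ALA", "ASP"]
        topology, reference = syn.build_toy_topology(seq)
        nh1 = topology.atom_index(1, "NH1")
        hh11 = topology.atom_index(1, "HH11")
        od1 = topology.atom_index(3, "OD1")
        c = reference.coords.copy()
        u = np.array([0.0, -1.0, 0.0])
        c[hh11] = c[nh1] + u
        c[od1] = c[nh1] + u * 2.9
        traj = make_trajectory(topology, reference, [c])
        r = self._record_for(topology, traj, "NH1", "OD1")
        assert r.backbone_class == "SS"
        assert r.chem_class == "chr-chr"
        assert r.partner_kind == "protein"

    def test_backbone_amide_to_carbonyl_is_MM(self):
        seq = ["GLY", "ALA", "GLY", "ALA", "GLY"]
        topology, reference = syn.build_toy_topology(seq)
        n5 = topology.atom_index(5, "N")
        h5 = topology.bonded_hydrogens(n5)[0]
        o1 = topology.atom_index(1, "O")
        c = reference.coords.copy()
        u = np.array([0.0, -1.0, 0.0])
        c[h5] = c[n5] + u
        c[o1] = c[n5] + u * 2.9
        traj = make_trajectory(topology, reference, [c])
        r = self._record_for(topology, traj, "N", "O")
        assert r.backbone_class == "MM"

    def test_serine_to_water_is_S_water(self):
        seq = ["ALA", "SER", "ALA"]
        topology, reference = syn.build_toy_topology(seq, n_waters=1)
        og = topology.atom_index(2, "OG")
        hg = topology.atom_index(2, "HG")
        water_o = topology.atom_index(4, "O")
        c = reference.coords.copy()
        u = np.array([0.0, -1.0, 0.0])
        c[hg] = c[og] + u
        c[water_o] = c[og] + u * 2.9
        # keep water hydrogens near their oxygen
        c[water_o + 1] = c[water_o] + np.array([0.76, 0.59, 0.0])
        c[water_o + 2] = c[water_o] + np.array([-0.76, 0.59, 0.0])
        traj = make_trajectory(topology, reference, [c])
        r = self._record_for(topology, traj, "OG", "O")
        assert r.partner_kind == "water"
        assert r.water_class == "S-water"
        assert r.water_chem == "phi-water"


class TestCounts:
    def test_designed_schedule_matches_hand_count(self):
        """Mean per-frame count equals frame-sum / n_frames on a designed set."""
        seq = ["LYS", "ALA", "ASP", "SER", "GLY", "GLU", "THR", "ALA", "ASN",
               "LEU"]
        topology, reference = syn.build_toy_topology(seq)
        schedules = [
            syn.InteractionSchedule("hbond", (4, "OG"), (3, "OD1"), 80.0,
                                    hydrogen=(4, "HG")),
            syn.InteractionSchedule("hbond", (7, "OG1"), (6, "OE1"), 50.0,
                                    hydrogen=(7, "HG1")),
            syn.InteractionSchedule("hbond", (9, "ND2"), (10, "N"), 30.0,
                                    hydrogen=(9, "HD21")),
        ]
        spec = syn.SyntheticSpec(sequence=seq, n_frames=200, seed=21,
                                 base_sigma=0.02,
                                 conditions=[syn.ConditionSpec("c", 1.0,
                                                               schedules)])
        traj, truth = syn.generate_trajectory(topology, reference, spec,
                                              spec.conditions[0])
        records = classify_hbonds(
            dedupe_hbonds(detect_hbonds(traj), topology), topology
        )
        counts = mean_hbond_counts(records)
        # independent bookkeeping: per-frame presence sums over all records
        per_frame = np.zeros(traj.n_frames)
        for r in records:
            if r.partner_kind == "protein":
                per_frame += r.presence
        assert counts["protein"]["total"] == pytest.approx(per_frame.mean())
        # category partition: MM + MS + SS = total
        assert (
            counts["protein"]["MM"] + counts["protein"]["MS"]
            + counts["protein"]["SS"]
        ) == pytest.approx(counts["protein"]["total"])
        chem_sum = sum(counts["protein"][c] for c in
                       ("chr-chr", "pho-pho", "phi-phi", "pho-phi", "other"))
        assert chem_sum == pytest.approx(counts["protein"]["total"])

    def test_simple_count_arithmetic(self):
        seq = ["SER", "ALA", "ASP"]
        topology, reference = syn.build_toy_topology(seq)
        sched = [syn.InteractionSchedule("hbond", (1, "OG"), (3, "OD1"), 50.0,
                                         hydrogen=(1, "HG"))]
        spec = syn.SyntheticSpec(sequence=seq, n_frames=100, seed=5,
                                 base_sigma=0.02,
                                 conditions=[syn.ConditionSpec("c", 1.0, sched)])
        traj, _ = syn.generate_trajectory(topology, reference, spec,
                                          spec.conditions[0])
        records = classify_hbonds(
            dedupe_hbonds(detect_hbonds(traj), topology), topology
        )
        counts = mean_hbond_counts(records)
        assert counts["protein"]["total"] == pytest.approx(0.5)


class TestBruteForceEquivalence:
    def test_neighbor_search_matches_all_pairs(self):
        """Accelerated detection = exhaustive scan, bit for bit."""
        rng = np.random.default_rng(30)
        seq_pool = list(syn._SIDE_CHAINS)
        for trial in range(6):
            seq = [seq_pool[i] for i in
                   rng.integers(0, len(seq_pool), size=8)]
            topology, reference = syn.build_toy_topology(seq, n_waters=3)
            coords = [
                reference.coords + rng.normal(0, 1.2, reference.coords.shape)
                for _ in range(3)
            ]
            traj = make_trajectory(topology, reference, coords)
            fast = {
                (c.donor, c.hydrogen, c.acceptor): c.presence
                for c in detect_hbonds(traj)
            }
            slow = brute_force_hbonds(traj)
            assert set(fast) == set(slow)
            for key in fast:
                np.testing.assert_array_equal(fast[key], slow[key])

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(31)
        seq = ["SER", "THR", "ASN", "LYS", "ASP", "GLN"]
        topology, reference = syn.build_toy_topology(seq)
        coords = [reference.coords + rng.normal(0, 1.0, reference.coords.shape)
                  for _ in range(4)]
        traj = make_trajectory(topology, reference, coords)
        tight = {(c.donor, c.hydrogen, c.acceptor): c.presence
                 for c in detect_hbonds(traj, 3.5, 120.0)}
        loose = {(c.donor, c.hydrogen, c.acceptor): c.presence
                 for c in detect_hbonds(traj, 4.0, 100.0)}
        for key, bits in tight.items():
            assert key in loose
            assert np.all(loose[key] >= bits)
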