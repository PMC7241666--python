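"""Salt-bridge and hydrophobic-contact rules, uniqueness, distance monitoring."""

import numpy as np
import pytest

from thermotraj import synthetic as syn
from thermotraj.interactions import (
    detect_hydrophobic_contacts,
    detect_salt_bridges,
    monitor_distance,
    unique_salt_bridges,
)
from thermotraj.model import Frame
from tests.conftest import make_trajectory
from tests.oracles import brute_force_contacts, brute_force_salt_bridges


def _place(topology, reference, placements):
    """Copy of the reference coords with (seq, name) -> absolute xyz edits."""
    c = reference.coords.copy()
    for (seq, name), xyz in placements.items():
        c[topology.atom_index(seq, name)] = xyz
    return c


@pytest.fixture(scope="module")
def charged_peptide():
    return syn.build_toy_topology(["ASP", "ALA", "ARG", "GLY", "GLU", "LYS"])


class TestSaltBridges:
    @pytest.mark.parametrize(
        "distance,expected",
        [(3.5, True), (3.99, True), (4.0, False), (4.2, False)],
    )
    def test_strict_four_angstrom_rule(self, charged_peptide, distance, expected):
        topology, reference = charged_peptide
        od1 = reference.coords[topology.atom_index(1, "OD1")]
        coords = _place(
            topology, reference,
            {(3, "NH1"): od1 + np.array([distance, 0.0, 0.0])},  # exact axis gap
        )
        traj = make_trajectory(topology, reference, [coords])
        events = detect_salt_bridges(traj)
        found = any(
            topology.atoms[e.atom_a].name == "OD1"
            and topology.atoms[e.atom_b].name == "NH1"
            and e.presence[0]
            for e in events
        )
        assert found == expected

    def test_all_atom_combinations_evaluated(self, charged_peptide):
        topology, reference = charged_peptide
        ne = reference.coords[topology.atom_index(3, "NE")]
        coords = _place(
            topology, reference,
            {(1, "OD2"): ne + np.array([3.0, 0.0, 0.0])},
        )
        traj = make_trajectory(topology, reference, [coords])
        pairs = {
            (topology.atoms[e.atom_a].name, topology.atoms[e.atom_b].name)
            for e in detect_salt_bridges(traj)
            if e.presence[0]
        }
        assert ("OD2", "NE") in pairs

    def test_uniqueness_keeps_best_atom_pair(self, charged_peptide):
        """Two atom pairs of one residue pair collapse to the higher occupancy."""
        topology, reference = charged_peptide
        od1 = topology.atom_index(1, "OD1")
        od2 = topology.atom_index(1, "OD2")
        nh1 = topology.atom_index(3, "NH1")
        ne = topology.atom_index(3, "NE")
        n_frames = 100
        coords_list = []
        for k in range(n_frames):
            c = reference.coords.copy()
            base = c[od1]
            c[nh1] = base + ([3.2, 0, 0] if k < 99 else [8.0, 0, 0])
            # OD2-NE in range in 70 frames via a separate basic atom
            c[ne] = c[od2] + ([0, 0, 3.5] if k < 70 else [0, 0, 8.0])
            coords_list.append(c)
        traj = make_trajectory(topology, reference, coords_list)
        records = unique_salt_bridges(detect_salt_bridges(traj), topology)
        ours = [r for r in records if r.pair_label == "D1-R3"]
        assert len(ours) == 1
        assert ours[0].acidic_atom == "OD1" and ours[0].basic_atom == "NH1"
        assert ours[0].occupancy == pytest.approx(99.0)
        assert ours[0].union_occupancy >= ours[0].occupancy

    def test_constant_bridge_statistics(self, charged_peptide):
        topology, reference = charged_peptide
        od1 = reference.coords[topology.atom_index(1, "OD1")]
        coords = _place(topology, reference,
                        {(3, "NH1"): od1 + np.array([2.85, 0.0, 0.0])})
        traj = make_trajectory(topology, reference, [coords] * 10)
        records = unique_salt_bridges(detect_salt_bridges(traj), topology)
        r = [x for x in records if x.pair_label == "D1-R3"][0]
        assert r.occupancy == pytest.approx(100.0)
        assert r.mean_distance == pytest.approx(2.85, abs=1e-9)
        assert r.sd_distance == pytest.approx(0.0, abs=1e-12)

    def test_glutamate_uses_epsilon_oxygens(self, charged_peptide):
        topology, reference = charged_peptide
        oe2 = reference.coords[topology.atom_index(5, "OE2")]
        coords = _place(topology, reference,
                        {(6, "NZ"): oe2 + np.array([0.0, 0.0, 3.0])})
        traj = make_trajectory(topology, reference, [coords])
        records = unique_salt_bridges(detect_salt_bridges(traj), topology)
        assert any(r.pair_label == "E5-K6" and r.acidic_atom in ("OE1", "OE2")
                   for r in records)

    def test_matches_brute_force(self, charged_peptide):
        topology, reference = charged_peptide
        rng = np.random.default_rng(40)
        coords = [reference.coords + rng.normal(0, 2.0, reference.coords.shape)
                  for _ in range(5)]
        traj = make_trajectory(topology, reference, coords)
        fast = {(e.atom_a, e.atom_b): e.presence
                for e in detect_salt_bridges(traj)}
        slow = brute_force_salt_bridges(traj)
        assert set(fast) == set(slow)
        for key in fast:
            np.testing.assert_array_equal(fast[key], slow[key])


class TestHydrophobicContacts:
    def test_contact_within_cutoff(self):
        seq = ["LEU", "GLY", "GLY", "VAL"]
        topology, reference = syn.build_toy_topology(seq)
        cd1 = reference.coords[topology.atom_index(1, "CD1")]
        coords = _place(topology, reference,
                        {(4, "CG1"): cd1 + np.array([3.8, 0.0, 0.0])})
        traj = make_trajectory(topology, reference, [coords])
        records = detect_hydrophobic_contacts(traj)
        ours = [r for r in records if r.pair_label == "LEU1-VAL4"]
        assert len(ours) == 1 and ours[0].occupancy == pytest.approx(100.0)

    def test_adjacent_residues_excluded(self):
        """Backbone carbons of sequence neighbors are always close but never count."""
        topology, reference = syn.build_toy_topology(["ALA", "ALA", "ALA"])
        traj = make_trajectory(topology, reference, [reference.coords])
        records = detect_hydrophobic_contacts(traj)
        for r in records:
            seq_a = int(r.residue_a[3:])
            seq_b = int(r.residue_b[3:])
            assert abs(seq_a - seq_b) > 1

    def test_multiple_atom_pairs_one_presence_bit(self):
        seq = ["LEU", "GLY", "GLY", "LEU"]
        topology, reference = syn.build_toy_topology(seq)
        cd1 = reference.coords[topology.atom_index(1, "CD1")]
        coords = _place(
            topology, reference,
            {
                (4, "CD1"): cd1 + np.array([3.0, 0.0, 0.0]),
                (4, "CD2"): cd1 + np.array([3.2, 0.0, 0.0]),
                (4, "CG"): cd1 + np.array([0.0, 3.4, 0.0]),
            },
        )
        traj = make_trajectory(topology, reference, [coords])
        records = [r for r in detect_hydrophobic_contacts(traj)
                   if r.pair_label == "LEU1-LEU4"]
        assert len(records) == 1  # one record, one presence bit per frame
        assert records[0].occupancy == pytest.approx(100.0)

    def test_cutoff_monotonicity(self):
        topology, reference = syn.build_toy_topology(
            ["LEU", "GLY", "VAL", "GLY", "ILE"]
        )
        rng = np.random.default_rng(41)
        coords = [reference.coords + rng.normal(0, 1.5, reference.coords.shape)
                  for _ in range(4)]
        traj = make_trajectory(topology, reference, coords)
        small = {r.pair_label: r.occupancy
                 for r in detect_hydrophobic_contacts(traj, cutoff=3.9)}
        large = {r.pair_label: r.occupancy
                 for r in detect_hydrophobic_contacts(traj, cutoff=4.0)}
        for pair, occ in small.items():
            assert large.get(pair, 0.0) >= occ

    def test_matches_brute_force(self):
        seq = ["LEU", "PHE", "GLY", "VAL", "ILE", "TRP"]
        topology, reference = syn.build_toy_topology(seq, n_waters=2)
        rng = np.random.default_rng(42)
        coords = [reference.coords + rng.normal(0, 1.5, reference.coords.shape)
                  for _ in range(4)]
        traj = make_trajectory(topology, reference, coords)
        fast = {(topology.residues[0].seq, r.pair_label): r.presence
                for r in detect_hydrophobic_contacts(traj)}
        slow = brute_force_contacts(traj)
        assert len(fast) == len(slow)
        fast_by_res = {}
        for r in detect_hydrophobic_contacts(traj):
            ri = next(i for i, res in enumerate(topology.residues)
                      if f"{res.name}{res.seq}" == r.residue_a)
            rj = next(i for i, res in enumerate(topology.residues)
                      if f"{res.name}{res.seq}" == r.residue_b)
            fast_by_res[(min(ri, rj), max(ri, rj))] = r.presence
        assert set(fast_by_res) == set(slow)
        for key in slow:
            np.testing.assert_array_equal(fast_by_res[key], slow[key])


class TestDistanceMonitor:
    def test_static_pair(self, charged_peptide):
        topology, reference = charged_peptide
        od1 = reference.coords[topology.atom_index(1, "OD1")]
        coords = _place(topology, reference,
                        {(3, "NE"): od1 + np.array([3.0, 0.0, 0.0])})
        traj = make_trajectory(topology, reference, [coords] * 8)
        mon = monitor_distance(traj, (1, "OD1"), (3, "NE"), threshold=3.5)
        assert np.allclose(mon.series["distance"], 3.0)
        assert mon.fraction_below == pytest.approx(1.0)

    def test_toggle_schedule_fraction(self, charged_peptide):
        topology, reference = charged_peptide
        n_frames = 200
        coords_list = []
        od1_idx = topology.atom_index(1, "OD1")
        ne_idx = topology.atom_index(3, "NE")
        for k in range(n_frames):
            c = reference.coords.copy()
            gap = 3.0 if k < 140 else 6.0  # 70% of frames in range
            c[ne_idx] = c[od1_idx] + np.array([gap, 0.0, 0.0])
            coords_list.append(c)
        traj = make_trajectory(topology, reference, coords_list)
        mon = monitor_distance(traj, (1, "OD1"), (3, "NE"), threshold=3.5)
        assert mon.fraction_below == pytest.approx(0.70)

    def test_zero_threshold_gives_zero_fraction(self, charged_peptide):
        topology, reference = charged_peptide
        traj = make_trajectory(topology, reference, [reference.coords])
        mon = monitor_distance(traj, (1, "OD1"), (3, "NE"), threshold=0.0)
        assert mon.fraction_below == 0.0

    def test_missing_atom_named_in_error(self, charged_peptide):
        topology, reference = charged_peptide
        traj = make_trajectory(topology, reference, [reference.coords])
        with pytest.raises(KeyError, match="OD9"):
            monitor_distance(traj, (1, "OD9"), (3, "NE"))
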