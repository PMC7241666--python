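"""Shared fixtures: small peptide topologies and designed trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from thermotraj import synthetic as syn
from thermotraj.model import Frame, Trajectory

MIXED_SEQUENCE = [
    "MET", "LYS", "ASP", "SER", "LEU", "ARG", "GLU", "VAL", "THR", "ALA",
    "GLY", "PHE", "ASN", "ILE", "ASP", "ARG", "SER", "LEU", "GLU", "LYS",
]


@pytest.fixture(scope="session")
def peptide():
    """A 20-residue mixed-chemistry peptide with waters and a Ca2+ ion."""
    topology, reference = syn.build_toy_topology(
        MIXED_SEQUENCE, n_waters=6, include_divalent_ion=True
    )
    return topology, reference


@pytest.fixture(scope="session")
def dry_peptide():
    """The same peptide without solvent or ions."""
    return syn.build_toy_topology(MIXED_SEQUENCE)


def make_trajectory(topology, reference, coords_list, time_step=10.0, label="test"):
    frames = [
        Frame(index=k, time=k * time_step, coords=np.asarray(c, dtype=float))
        for k, c in enumerate(coords_list)
    ]
    return Trajectory(topology=topology, frames=frames, condition_label=label)


@pytest.fixture(scope="session")
def static_trajectory(dry_peptide):
    topology, reference = dry_peptide
    return make_trajectory(topology, reference, [reference.coords.copy() for _ in range(5)])


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rotation = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    translation = rng.normal(scale=5.0, size=3)
    return rotation, translation
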