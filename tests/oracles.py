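"""Independent reference implementations used to check the package.

These are deliberately naive: exhaustive all-pairs scans and a grid-search
rigid-body minimizer.  They share no code with the implementation paths
they verify.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from thermotraj.hbonds import enumerate_donors_acceptors


def rmsd_plain(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def grid_search_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                         coarse_step_deg: float = 15.0) -> float:
    """Brute-force minimal RMSD over rotations: Euler grid + local refinement.

    Centers both point sets (the optimal translation always aligns
    centroids), scans a coarse Euler-angle grid, then polishes the best
    grid point with Nelder-Mead.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(angles):
        rot = Rotation.from_euler("zyx", angles, degrees=True)
        return rmsd_plain(rot.apply(mob), ref)

    grid = np.arange(-180.0, 180.0, coarse_step_deg)
    best_angles, best_val = None, np.inf
    for az in grid:
        for ay in np.arange(-90.0, 90.1, coarse_step_deg):
            for ax in grid:
                v = cost((az, ay, ax))
                if v < best_val:
                    best_val, best_angles = v, (az, ay, ax)
    res = minimize(cost, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    return float(min(best_val, res.fun))


def brute_force_hbonds(trajectory, distance_cutoff=3.5, angle_cutoff=120.0,
                       include_water=True):
    """All donor x acceptor pairs, no neighbor acceleration.

    Returns {(donor, hydrogen, acceptor): presence bool array} for triples
    present in at least one frame.
    """
    topology = trajectory.topology
    donors, acceptors = enumerate_donors_acceptors(topology)
    water = set(topology.selections["water"].tolist())
    ions = set(topology.selections["ions"].tolist())
    acceptors = [a for a in acceptors if a not in ions]
    if not include_water:
        donors = [(d, h) for d, h in donors if d not in water]
        acceptors = [a for a in acceptors if a not in water]
    res_of = topology.residue_of_atom
    n_frames = trajectory.n_frames
    out = {}
    for k, frame in enumerate(trajectory.frames):
        c = frame.coords
        for d, h in donors:
            for a in acceptors:
                if a == d or res_of[a] == res_of[d]:
                    continue
                if d in water and a in water:
                    continue
                dist = np.linalg.norm(c[a] - c[d])
                if dist > distance_cutoff:
                    continue
                v1 = c[d] - c[h]
                v2 = c[a] - c[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle > angle_cutoff:
                    key = (d, h, a)
                    if key not in out:
                        out[key] = np.zeros(n_frames, dtype=bool)
                    out[key][k] = True
    return out


def brute_force_salt_bridges(trajectory, cutoff=4.0):
    """All acidic-O x basic-N pairs: {(atom_a, atom_b): presence}."""
    from thermotraj.interactions import ACIDIC_ATOMS, BASIC_ATOMS

    topology = trajectory.topology
    acidic = [i for i, a in enumerate(topology.atoms)
              if a.name in ACIDIC_ATOMS.get(a.residue_name, ())]
    basic = [i for i, a in enumerate(topology.atoms)
             if a.name in BASIC_ATOMS.get(a.residue_name, ())]
    n_frames = trajectory.n_frames
    out = {}
    for k, frame in enumerate(trajectory.frames):
        c = frame.coords
        for i in acidic:
            for j in basic:
                if np.linalg.norm(c[i] - c[j]) < cutoff:
                    out.setdefault((i, j), np.zeros(n_frames, dtype=bool))[k] = True
    return out


def brute_force_contacts(trajectory, cutoff=4.0):
    """All whitelisted-carbon pairs -> residue-pair presence dict."""
    from thermotraj.interactions import HYDROPHOBIC_ATOM_NAMES

    topology = trajectory.topology
    water = set(topology.selections["water"].tolist())
    ions = set(topology.selections["ions"].tolist())
    carbons = [i for i, a in enumerate(topology.atoms)
               if a.name in HYDROPHOBIC_ATOM_NAMES
               and i not in water and i not in ions]
    res_of = topology.residue_of_atom
    n_frames = trajectory.n_frames
    out = {}
    for k, frame in enumerate(trajectory.frames):
        c = frame.coords
        for ii in range(len(carbons)):
            for jj in range(ii + 1, len(carbons)):
                i, j = carbons[ii], carbons[jj]
                ri, rj = int(res_of[i]), int(res_of[j])
                if ri == rj:
                    continue
                res_i = trajectory.topology.residues[ri]
                res_j = trajectory.topology.residues[rj]
                if res_i.chain_id == res_j.chain_id and abs(res_i.seq - res_j.seq) <= 1:
                    continue
                if np.linalg.norm(c[i] - c[j]) <= cutoff:
                    key = (min(ri, rj), max(ri, rj))
                    out.setdefault(key, np.zeros(n_frames, dtype=bool))[k] = True
    return out


def anova_sums_of_squares(groups):
    """Hand-computed one-way ANOVA decomposition -> (F, df1, df2)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return (ss_between / df1) / (ss_within / df2), df1, df2
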