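"""Superposition and deviation metrics: RMSD, RMSF, radius of gyration.

All metrics follow the conventions of the standard MD analysis tools:
RMSD is computed on an atom selection (default backbone) after optimal
rigid-body superposition onto a reference structure (Kabsch, unweighted);
RMSF is the per-atom root-mean-square fluctuation about the time-mean
position after frame-wise alignment, averaged per residue; the radius of
gyration is mass-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from thermotraj.model import Frame, Topology, Trajectory


@dataclass
class SuperpositionResult:
    """Optimal rigid transform: x_aligned = x_mobile @ rotation.T + translation."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd_after: float  # Angstrom


@dataclass
class PerResidueProfile:
    """A per-residue scalar profile (e.g. RMSF), indexed by residue_seq."""

    residue_seq: np.ndarray
    residue_name: list[str]
    values: np.ndarray
    selection: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_seq": self.residue_seq,
                "residue_name": self.residue_name,
                "value": self.values,
            }
        )


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm via SVD with reflection correction; requires >= 3
    non-collinear atoms in each set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()

    mob_c = mobile - wn @ mobile
    ref_c = reference - wn @ reference
    cov = (mob_c * wn[:, None]).T @ ref_c
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) atom configuration")
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = (wn @ reference) - rotation @ (wn @ mobile)
    aligned = mobile @ rotation.T + translation
    rmsd_after = float(np.sqrt(np.sum(wn[:, None] * (aligned - reference) ** 2)))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd_after=rmsd_after)


def _resolve_selection(topology: Topology, selection) -> np.ndarray:
    if isinstance(selection, str):
        sel = topology.selections[selection]
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    return sel


def rmsd_series(
    trajectory: Trajectory,
    selection="backbone",
    reference: Frame | None = None,
    window: tuple[float, float] = (0.25, 1.0),
) -> tuple[pd.DataFrame, float, float]:
    """Per-frame RMSD after superposition onto the reference selection.

    Returns ``(series, window_mean, window_sd)`` where ``series`` has
    columns frame, time_ns, rmsd and the summary statistics are taken over
    the fractional time window (default the converged 25-100% region).
    """
    sel = _resolve_selection(trajectory.topology, selection)
    if reference is None:
        reference = trajectory.frames[0]
    ref = reference.coords[sel]
    values = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory.frames):
        values[k] = kabsch_superpose(frame.coords[sel], ref).rmsd_after
    series = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ns": trajectory.times_ps / 1000.0,
            "rmsd": values,
        }
    )
    mean, sd = window_stats(values, window)
    return series, mean, sd


def window_stats(values: np.ndarray, window: tuple[float, float]) -> tuple[float, float]:
    """Mean and sd over a fractional index window (e.g. (0.25, 1.0))."""
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    n = len(values)
    start = int(np.floor(lo * n))
    stop = max(start + 1, int(np.ceil(hi * n)))
    chunk = np.asarray(values)[start:stop]
    return float(chunk.mean()), float(chunk.std(ddof=0))


def rmsf_profile(
    trajectory: Trajectory,
    selection="backbone",
    align_selection="backbone",
    reference_mode: str = "mean_position",
) -> PerResidueProfile:
    """Per-residue RMSF of the selected atoms after frame-wise alignment.

    Every frame is superposed onto the initial structure using
    ``align_selection``; the per-atom RMSF is then the root-mean-square
    deviation from the atom's time-mean position (``mean_position`` mode,
    the cpptraj atomicfluct convention) or from its initial position
    (``initial_structure`` mode).  Per-residue values are means over each
    residue's selected atoms.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if reference_mode not in ("mean_position", "initial_structure"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    topology = trajectory.topology
    sel = _resolve_selection(topology, selection)
    align_sel = _resolve_selection(topology, align_selection)

    ref_align = trajectory.frames[0].coords[align_sel]
    aligned = np.empty((trajectory.n_frames, sel.size, 3))
    for k, frame in enumerate(trajectory.frames):
        sup = kabsch_superpose(frame.coords[align_sel], ref_align)
        aligned[k] = frame.coords[sel] @ sup.rotation.T + sup.translation

    if reference_mode == "mean_position":
        ref_pos = aligned.mean(axis=0)
    else:
        ref_pos = trajectory.frames[0].coords[sel]
    atom_rmsf = np.sqrt(np.mean(np.sum((aligned - ref_pos) ** 2, axis=2), axis=0))

    res_of = topology.residue_of_atom[sel]
    res_ids = sorted(set(res_of.tolist()))
    seqs, names, values = [], [], []
    for ri in res_ids:
        mask = res_of == ri
        res = topology.residues[ri]
        seqs.append(res.seq)
        names.append(res.name)
        values.append(float(atom_rmsf[mask].mean()))
    return PerResidueProfile(
        residue_seq=np.array(seqs),
        residue_name=names,
        values=np.array(values),
        selection=str(selection),
    )


def radius_of_gyration(
    frame: Frame,
    topology: Topology,
    selection="protein",
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration (Angstrom) of a selection in one frame.

    Rg = sqrt( sum_i w_i |r_i - rbar|^2 / sum_i w_i ) with rbar the weighted
    centroid; mass-weighted by default (the VMD convention).
    """
    sel = _resolve_selection(topology, selection)
    coords = frame.coords[sel]
    if mass_weighted:
        w = np.array([topology.atoms[i].mass for i in sel])
    else:
        w = np.ones(sel.size)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight in radius_of_gyration")
    centroid = (w[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((w * np.sum((coords - centroid) ** 2, axis=1)).sum() / total))


def rg_series(
    trajectory: Trajectory,
    selection="protein",
    mass_weighted: bool = True,
    window: tuple[float, float] = (0.25, 1.0),
) -> tuple[pd.DataFrame, float, float]:
    """Per-frame radius of gyration plus converged-window mean and sd."""
    values = np.array(
        [
            radius_of_gyration(f, trajectory.topology, selection, mass_weighted)
            for f in trajectory.frames
        ]
    )
    series = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ns": trajectory.times_ps / 1000.0,
            "rg": values,
        }
    )
    mean, sd = window_stats(values, window)
    return series, mean, sd
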