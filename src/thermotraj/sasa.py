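"""Shrake-Rupley solvent-accessible surface area and its class aggregation.

Per-atom SASA is estimated by placing a deterministic golden-spiral point
set on each atom's solvent-expanded sphere (radius r_i + probe) and counting
the points not buried inside any neighbor's expanded sphere:

    SASA_i = (exposed points / total points) * 4 * pi * (r_i + probe)^2

Defaults: probe 1.4 Angstrom, 960 points.  Only protein atoms contribute to
the surface and to occlusion; waters and ions are excluded from both.
Aggregation sums per-residue areas into hydrophobic / hydrophilic classes
(hydrophilic = every non-hydrophobic protein residue, so the two classes
add to the total) and over the catalytic residue set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from thermotraj.geometry import PerResidueProfile, window_stats
from thermotraj.model import (
    CATALYTIC_RESIDUES,
    Frame,
    HYDROPHOBIC_RESIDUES,
    Topology,
    Trajectory,
)

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4  # Angstrom
DEFAULT_N_POINTS = 960


@lru_cache(maxsize=None)
def _warn_missing_catalytic(missing: tuple[int, ...]) -> None:
    # warn once per distinct missing set, not once per frame
    logger.warning("catalytic residues %s absent from topology", list(missing))


@dataclass
class SasaBreakdown:
    """Class-aggregated SASA; hydrophobic + hydrophilic = total (nm^2)."""

    total: float  # nm^2
    hydrophobic: float  # nm^2
    hydrophilic: float  # nm^2
    catalytic: float  # A^2 (three residues; reported on the atomic scale)
    per_residue: PerResidueProfile | None = None  # A^2 per residue


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    frame: Frame,
    topology: Topology,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    selection=None,
    include_hydrogens: bool = True,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2).

    Returns an array of length n_atoms with zeros outside the computed
    selection (default: protein atoms).  ``include_hydrogens=False`` drops
    hydrogens from both surface and occlusion, for comparison with tools
    run on heavy-atom structures.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    if n_sphere_points < 1:
        raise ValueError("n_sphere_points must be positive")
    if selection is None:
        sel = topology.selections["protein"]
    elif isinstance(selection, str):
        sel = topology.selections[selection]
    else:
        sel = np.asarray(selection, dtype=int)
    if not include_hydrogens:
        sel = np.array([i for i in sel if topology.atoms[i].element != "H"], dtype=int)
    if sel.size == 0:
        raise ValueError("empty SASA selection")

    coords = frame.coords[sel]
    radii = np.array([topology.atoms[i].vdw_radius for i in sel]) + probe_radius
    sphere = golden_spiral_points(n_sphere_points)

    max_r = radii.max()
    tree = cKDTree(coords)
    areas_sel = np.zeros(sel.size)
    for a in range(sel.size):
        neighbors = tree.query_ball_point(coords[a], radii[a] + max_r)
        neighbors = [b for b in neighbors if b != a]
        points = coords[a] + radii[a] * sphere
        if neighbors:
            nb = np.array(neighbors)
            d2 = np.sum(
                (points[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < radii[nb][None, :] ** 2, axis=1)
            exposed = int(np.count_nonzero(~buried))
        else:
            exposed = n_sphere_points
        areas_sel[a] = (exposed / n_sphere_points) * 4.0 * np.pi * radii[a] ** 2

    areas = np.zeros(topology.n_atoms)
    areas[sel] = areas_sel
    return areas


def aggregate_sasa(
    per_atom_areas: np.ndarray,
    topology: Topology,
    catalytic_set=CATALYTIC_RESIDUES,
) -> SasaBreakdown:
    """Sum per-atom areas into class totals (nm^2) and the catalytic set (A^2)."""
    hydrophobic = 0.0
    hydrophilic = 0.0
    catalytic = 0.0
    seqs, names, res_areas = [], [], []
    catalytic_found = set()
    for res in topology.residues:
        if res.is_water or res.is_ion:
            continue
        area = float(per_atom_areas[res.atom_start : res.atom_stop].sum())
        seqs.append(res.seq)
        names.append(res.name)
        res_areas.append(area)
        if res.name in HYDROPHOBIC_RESIDUES:
            hydrophobic += area
        else:
            hydrophilic += area
        if res.seq in catalytic_set:
            catalytic += area
            catalytic_found.add(res.seq)
    missing = set(catalytic_set) - catalytic_found
    if missing:
        _warn_missing_catalytic(tuple(sorted(missing)))
    profile = PerResidueProfile(
        residue_seq=np.array(seqs),
        residue_name=names,
        values=np.array(res_areas),
        selection="protein",
    )
    return SasaBreakdown(
        total=(hydrophobic + hydrophilic) / 100.0,
        hydrophobic=hydrophobic / 100.0,
        hydrophilic=hydrophilic / 100.0,
        catalytic=catalytic,
        per_residue=profile,
    )


def sasa_series(
    trajectory: Trajectory,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    catalytic_set=CATALYTIC_RESIDUES,
    window: tuple[float, float] = (0.25, 1.0),
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-frame SASA breakdown plus converged-window mean/sd per component."""
    rows = []
    for frame in trajectory.frames:
        areas = shrake_rupley(frame, trajectory.topology, probe_radius, n_sphere_points)
        bd = aggregate_sasa(areas, trajectory.topology, catalytic_set)
        rows.append(
            {
                "frame": frame.index,
                "time_ns": frame.time / 1000.0,
                "sasa_total": bd.total,
                "sasa_pho": bd.hydrophobic,
                "sasa_phil": bd.hydrophilic,
                "sasa_catalytic": bd.catalytic,
            }
        )
    series = pd.DataFrame(rows)
    summary = {
        col: window_stats(series[col].to_numpy(), window)
        for col in ("sasa_total", "sasa_pho", "sasa_phil", "sasa_catalytic")
    }
    return series, summary


@dataclass
class SasaDistribution:
    bin_centers: np.ndarray
    counts: np.ndarray
    peak_center: float
    peak_percent: float
    tie: bool


def sasa_distribution(values, bin_width: float = 2.0) -> SasaDistribution:
    """Histogram of a per-frame SASA series with odd-integer bin centers.

    Bins are anchored so that centers fall at odd multiples of half the bin
    width (for the default 2 nm^2 width: centers at ..., 347, 349, 351, ...).
    The major peak is the modal bin (% of frames); ties report the
    lowest-center bin and set ``tie``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("sasa_distribution requires at least one value")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # edges at even multiples of bin_width/2 -> centers at odd multiples
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = (np.floor(values.max() / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    centers = edges[:-1] + bin_width / 2
    peak_idx = int(np.argmax(counts))  # argmax takes the lowest index on ties
    tie = int(np.count_nonzero(counts == counts[peak_idx])) > 1
    return SasaDistribution(
        bin_centers=centers,
        counts=counts,
        peak_center=float(centers[peak_idx]),
        peak_percent=float(100.0 * counts[peak_idx] / values.size),
        tie=tie,
    )
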