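"""Thermal-sensitive region calling from RMSF profiles, and one-way ANOVA.

A thermal-sensitive region is a contiguous run of residues whose
fluctuation increase at elevated temperature (delta RMSF = test profile
minus reference profile) meets a threshold.  Two flag levels are used:
moderate (>= 0.5 Angstrom) and high (>= 1.0 Angstrom).  Runs separated by
short sub-threshold gaps are merged; very short runs are discarded; a few
residues at each chain terminus are ignored because the unrestrained
termini fluctuate for reasons unrelated to thermal sensitivity.

The one-way ANOVA compares per-frame metric values (RMSD, Rg, SASA)
between conditions; this treats frames as independent observations, which
overstates the effective sample size of a correlated time series — the
convention is kept for comparability and the caveat is documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from thermotraj.geometry import PerResidueProfile

DEFAULT_THRESHOLDS = (0.5, 1.0)  # Angstrom (moderate, high)
DEFAULT_MIN_LENGTH = 3  # residues
DEFAULT_MAX_GAP = 1  # residues
DEFAULT_EXCLUDE_TERMINI = 5  # residues


@dataclass
class RegionCall:
    start_residue_seq: int
    end_residue_seq: int
    mean_delta: float
    max_delta: float
    flag_level: str  # "moderate" or "high"


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    significant: bool  # at alpha = 0.05


def delta_rmsf(
    profile_test: PerResidueProfile, profile_reference: PerResidueProfile
) -> PerResidueProfile:
    """Per-residue RMSF difference (test - reference); negatives retained."""
    if not np.array_equal(profile_test.residue_seq, profile_reference.residue_seq):
        raise ValueError("profiles must cover identical residues")
    return PerResidueProfile(
        residue_seq=profile_test.residue_seq.copy(),
        residue_name=list(profile_test.residue_name),
        values=profile_test.values - profile_reference.values,
        selection=profile_test.selection,
    )


def call_regions(
    delta: PerResidueProfile,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
    exclude_termini: int = DEFAULT_EXCLUDE_TERMINI,
) -> list[RegionCall]:
    """Segment a delta-RMSF profile into flagged regions.

    Residues with delta >= thresholds[0] form maximal runs; runs separated
    by at most ``max_gap`` sub-threshold residues are merged; merged regions
    spanning fewer than ``min_length`` residues are discarded.  The first
    and last ``exclude_termini`` residues of the profile are ignored.  The
    flag level is "high" when the region's maximum delta reaches
    thresholds[1], else "moderate".
    """
    if len(delta.values) == 0:
        raise ValueError("empty delta profile")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    values = np.asarray(delta.values, dtype=float)
    seqs = np.asarray(delta.residue_seq)
    n = len(values)
    eligible = np.zeros(n, dtype=bool)
    if n > 2 * exclude_termini:
        eligible[exclude_termini : n - exclude_termini] = True
    above = (values >= thresholds[0]) & eligible

    # maximal runs of above-threshold residues
    runs: list[tuple[int, int]] = []
    start = None
    for i in range(n + 1):
        if i < n and above[i]:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    # merge runs separated by <= max_gap residues
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    calls = []
    for lo, hi in merged:
        if hi - lo + 1 < min_length:
            continue
        chunk = values[lo : hi + 1]
        calls.append(
            RegionCall(
                start_residue_seq=int(seqs[lo]),
                end_residue_seq=int(seqs[hi]),
                mean_delta=float(chunk.mean()),
                max_delta=float(chunk.max()),
                flag_level="high" if chunk.max() >= thresholds[1] else "moderate",
            )
        )
    return calls


def one_way_anova(groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across >= 2 groups of per-frame metric values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    f_stat, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    # identical groups give 0/0 in scipy; the F statistic is 0 by convention
    if np.isnan(f_stat):
        f_stat, p = 0.0, 1.0
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        significant=bool(p < alpha),
    )
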