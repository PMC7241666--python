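"""Occupancy statistics shared by all interaction types.

Occupancy is the percentage of trajectory frames in which an interaction
satisfies its geometric criterion.  Records are grouped into lifetime bins
(short-lived (0,10]%, substantially live (10,90]%, long-lived (90,100]%),
filtered at a strict >50% threshold for the "stable interaction" tables,
and compared across conditions (temperatures, ion presence) to classify
each interaction as maintained / comparable / weakened / lost / gained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LIFETIME_BINS = (
    ("short", 0.0, 10.0),
    ("substantial", 10.0, 90.0),
    ("long", 90.0, 100.0),
)

DIFFERENTIAL_CALLS = ("maintained", "comparable", "weakened", "variable", "lost", "gained")


def occupancy(presence, n_frames: int | None = None,
              window: tuple[float, float] | None = None) -> float:
    """Percent of frames in which the presence bits are set.

    ``presence`` is a boolean per-frame vector; ``window`` optionally
    restricts the count to a fractional frame window (e.g. the converged
    (0.25, 1.0) region).
    """
    bits = np.asarray(presence, dtype=bool)
    if n_frames is None:
        n_frames = bits.size
    if n_frames < 1:
        raise ValueError("occupancy requires at least one frame")
    if window is not None:
        lo, hi = window
        start = int(np.floor(lo * n_frames))
        stop = max(start + 1, int(np.ceil(hi * n_frames)))
        bits = bits[start:stop]
        n_frames = stop - start
    return 100.0 * int(np.count_nonzero(bits)) / n_frames


def lifetime_bin(occ: float) -> str:
    """Lifetime class of one occupancy value; bins are right-inclusive."""
    if not 0.0 < occ <= 100.0:
        raise ValueError(f"occupancy {occ} outside (0, 100]")
    for label, lo, hi in LIFETIME_BINS:
        if lo < occ <= hi:
            return label
    raise AssertionError("unreachable")


@dataclass
class LifetimeHistogram:
    coarse: dict[str, int]  # short / substantial / long
    fine_edges: np.ndarray  # 0, 10, ..., 100
    fine_counts: np.ndarray  # counts per (lo, hi] 10%-wide bin


def lifetime_histogram(occupancies) -> LifetimeHistogram:
    """Counts per lifetime bin plus a fine (0,10], (10,20], ... histogram."""
    occs = np.asarray(list(occupancies), dtype=float)
    coarse = {label: 0 for label, _, _ in LIFETIME_BINS}
    edges = np.arange(0.0, 101.0, 10.0)
    fine = np.zeros(10, dtype=int)
    for occ in occs:
        coarse[lifetime_bin(float(occ))] += 1
        # right-inclusive 10%-wide bins
        k = min(9, int(np.ceil(occ / 10.0)) - 1)
        fine[k] += 1
    return LifetimeHistogram(coarse=coarse, fine_edges=edges, fine_counts=fine)


def filter_by_occupancy(records, threshold: float = 50.0,
                        key=lambda r: r.occupancy):
    """Keep records with occupancy strictly above ``threshold`` percent."""
    if not 0.0 < threshold < 100.0:
        raise ValueError("occupancy threshold must be in (0, 100)")
    return [r for r in records if key(r) > threshold]


@dataclass
class DifferentialCall:
    """Cross-condition classification of one interaction."""

    interaction_id: str
    occupancies: dict[str, float | None]  # condition -> occupancy (None if absent)
    call: str

    def __post_init__(self) -> None:
        if self.call not in DIFFERENTIAL_CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def differential_classify(
    records_by_condition: dict[str, dict[str, float]],
    conditions: list[str] | None = None,
    comparability_tol: float = 10.0,
    maintained_floor: float = 80.0,
    presence_threshold: float = 50.0,
) -> list[DifferentialCall]:
    """Classify interactions across ordered conditions by occupancy pattern.

    ``records_by_condition`` maps condition -> {interaction_id: occupancy %}.
    An interaction is *present* in a condition when its occupancy exceeds
    ``presence_threshold``.  For interactions present in every condition
    ("common"), calls are assigned in precedence order:

    * comparable — max-min spread <= ``comparability_tol``;
    * maintained — minimum occupancy >= ``maintained_floor``;
    * weakened  — occupancy strictly decreasing along the condition order
      with total drop > ``comparability_tol`` points;
    * variable  — any other common pattern.

    Interactions present in the reference (first) condition but not common
    are *lost*; present only away from the reference are *gained*.
    """
    if conditions is None:
        conditions = list(records_by_condition)
    if len(conditions) < 2:
        raise ValueError("differential classification requires >= 2 conditions")
    for c in conditions:
        if c not in records_by_condition:
            raise ValueError(f"condition {c!r} has no records")
    reference = conditions[0]
    all_ids = sorted({i for c in conditions for i in records_by_condition[c]})
    calls = []
    for iid in all_ids:
        occs = {c: records_by_condition[c].get(iid) for c in conditions}
        present = {c: (occs[c] is not None and occs[c] > presence_threshold)
                   for c in conditions}
        if not any(present.values()):
            continue
        if all(present.values()):
            vals = [occs[c] for c in conditions]
            drops = all(b < a for a, b in zip(vals, vals[1:]))
            spread = max(vals) - min(vals)
            if spread <= comparability_tol:
                call = "comparable"
            elif min(vals) >= maintained_floor:
                call = "maintained"
            elif drops:
                call = "weakened"
            else:
                call = "variable"
        elif present[reference]:
            call = "lost"
        else:
            call = "gained"
        calls.append(DifferentialCall(interaction_id=iid, occupancies=occs, call=call))
    return calls
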