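"""Per-condition aggregation of insertion events and strain arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import InsertionEvent


@dataclass
class StrainMeasurement:
    l0: float  # um, pre-stretch length
    l1: float  # um, post-stretch length

    @property
    def strain(self) -> float:
        return strain(self.l0, self.l1)


@dataclass
class ConditionSummary:
    """One row of a per-condition statistics table.

    ``insertion_rate_percent`` is rounded half-away-from-zero for
    reporting; the exact fraction is retained in
    ``insertion_rate_fraction``.  Mean/SD statistics (sample SD, n-1)
    cover penetrated curves only and are ``None`` when no curve
    penetrated.
    """

    substrate_strain: float  # percent
    n_curves: int
    n_penetrated: int
    insertion_rate_fraction: float
    insertion_rate_percent: int
    mean_insertion_force: float | None  # nN
    sd_insertion_force: float | None
    mean_insertion_displacement: float | None  # um
    sd_insertion_displacement: float | None
    mean_insertion_time: float | None  # s
    sd_insertion_time: float | None
    indentation_speed: float  # um/s
    trigger_force: float  # nN


def strain(l0: float, l1: float) -> float:
    """Engineering strain (l1 - l0) / l0; negative values mean compression."""
    if l0 <= 0:
        raise ValueError("reference length l0 must be positive")
    return (l1 - l0) / l0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_condition(
    events_by_curve: list[list[InsertionEvent]],
    *,
    substrate_strain: float,
    indentation_speed: float,
    trigger_force: float,
) -> ConditionSummary:
    """Aggregate per-curve event lists for one strain condition.

    A curve counts as penetrated iff it carries at least one
    ``membrane_first`` event; the statistics are computed over the first
    event of each penetrated curve.
    """
    if len(events_by_curve) == 0:
        raise ValueError("events_by_curve must not be empty")
    firsts = [
        next(ev for ev in evs if ev.rank == "membrane_first")
        for evs in events_by_curve
        if any(ev.rank == "membrane_first" for ev in evs)
    ]
    n = len(events_by_curve)
    m = len(firsts)
    frac = m / n

    def stats(values):
        if m == 0:
            return None, None
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if m >= 2 else 0.0
        return float(np.mean(arr)), sd

    mf, sf = stats([e.insertion_force for e in firsts])
    md, sdd = stats([e.insertion_displacement for e in firsts])
    mt, st = stats([e.insertion_time for e in firsts])
    return ConditionSummary(
        substrate_strain=substrate_strain,
        n_curves=n,
        n_penetrated=m,
        insertion_rate_fraction=frac,
        insertion_rate_percent=_round_half_up(100.0 * frac),
        mean_insertion_force=mf,
        sd_insertion_force=sf,
        mean_insertion_displacement=md,
        sd_insertion_displacement=sdd,
        mean_insertion_time=mt,
        sd_insertion_time=st,
        indentation_speed=indentation_speed,
        trigger_force=trigger_force,
    )


def insertion_force_histogram(
    events: list[InsertionEvent] | np.ndarray,
    bin_edges=(0.0, 1.0, 2.0, 3.0),
) -> tuple[np.ndarray, int]:
    """Histogram of insertion forces with half-open bins [lo, hi).

    Returns ``(counts, overflow)`` where ``overflow`` counts forces at or
    above the last edge.  Forces below the first edge are not counted.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    if len(events) and isinstance(events[0], InsertionEvent):
        forces = np.array([e.insertion_force for e in events], dtype=float)
    else:
        forces = np.asarray(events, dtype=float)
    if forces.size == 0:
        return np.zeros(edges.size - 1, dtype=int), 0
    counts = np.zeros(edges.size - 1, dtype=int)
    inner = forces[(forces >= edges[0]) & (forces < edges[-1])]
    idx = np.searchsorted(edges, inner, side="right") - 1
    for i in idx:
        counts[i] += 1
    overflow = int(np.count_nonzero(forces >= edges[-1]))
    return counts, overflow
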