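"""From damage-count tracks to per-region repair time courses.

CPD-seq style data give, for each sampled time after UV irradiation, a count
of remaining lesions per genomic position.  For a region *a* the repaired
fraction at time t is the relative loss of signal against the 0-minute
sample,

    R_a(t) = (sum_i CPD_a^i(0) - sum_i CPD_a^i(t)) / sum_i CPD_a^i(0),

which is then rectified (clipped at zero and forced monotone non-decreasing,
since no new lesions arise once the UV source is removed).  Counts are
normalised by the number of available dipyrimidine sites; note the quotient
above cancels any per-region normalisation and length dependence, so the
normalisation only matters for cross-region comparability of intermediate
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import RepairTimeCourse

__all__ = [
    "SignalTrack",
    "RegionCounts",
    "UndamagedRegionError",
    "DataInconsistencyError",
    "count_dipyrimidines",
    "dipyrimidine_positions",
    "reverse_complement",
    "normalize_damage",
    "region_repair_fraction",
    "rectify",
    "empirical_repair_rate",
    "aggregate_region",
    "build_time_course",
    "merge_fraction_courses",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_PYRIMIDINES = frozenset("CT")


class UndamagedRegionError(ValueError):
    """The 0-minute signal in a region sums to zero; Eq-free fraction undefined."""


class DataInconsistencyError(ValueError):
    """Counts present where the sequence offers no dipyrimidine sites."""


@dataclass(frozen=True)
class SignalTrack:
    """A sparse per-position signal on one chromosome and strand."""

    chrom: str
    strand: str  # '+', '-' or 'both'
    positions: np.ndarray  # 0-based, strictly increasing
    values: np.ndarray  # counts or densities, >= 0
    time_label: float | None = None  # minutes post-irradiation

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or val.ndim != 1 or len(pos) != len(val):
            raise ValueError("positions and values must be 1-D and equally long")
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(val < 0):
            raise ValueError("signal values must be >= 0")
        if self.strand not in ("+", "-", "both"):
            raise ValueError(f"bad strand {self.strand!r}")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass
class RegionCounts:
    """Summed (optionally dipyrimidine-normalised) damage per sampled time."""

    region_id: str
    sums: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, s in self.sums.items():
            if s < 0:
                raise ValueError(f"negative damage sum {s} at t={t}")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def count_dipyrimidines(sequence: str, strand: str = "+") -> int:
    """Number of adjacent pyrimidine pairs (TT, TC, CT, CC) on a strand.

    For the '-' strand the count is taken on the reverse complement.
    Dinucleotides containing N (or any non-ACGT letter) are excluded; an
    empty or single-base sequence has no dinucleotides and yields 0.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = sequence.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    return sum(
        a in _PYRIMIDINES and b in _PYRIMIDINES for a, b in zip(seq, seq[1:])
    )


def dipyrimidine_positions(sequence: str, strand: str = "+") -> np.ndarray:
    """0-based start coordinates of dipyrimidine sites on a strand.

    A site at i covers forward-coordinate bases (i, i+1).  On the '-' strand
    a dipyrimidine corresponds to a purine pair on the forward sequence; the
    returned coordinates are always in forward orientation.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    members = (
        np.isin(seq, [b"C", b"T"]) if strand == "+"
        else np.isin(seq, [b"A", b"G"])
    )
    return np.flatnonzero(members[:-1] & members[1:])


def aggregate_region(
    tracks: Iterable[SignalTrack],
    chrom: str,
    start: int,
    end: int,
    strand: str = "both",
) -> float:
    """Sum track values falling in [start, end) on the requested strand.

    Strand 'both' pools '+', '-' and unstranded tracks; otherwise only tracks
    whose strand matches (or is itself 'both') contribute.
    """
    total = 0.0
    for tr in tracks:
        if tr.chrom != chrom:
            continue
        if strand != "both" and tr.strand not in (strand, "both"):
            continue
        lo = np.searchsorted(tr.positions, start, side="left")
        hi = np.searchsorted(tr.positions, end, side="left")
        total += float(tr.values[lo:hi].sum())
    return total


def normalize_damage(raw_sum: float, dipyr_count: int) -> float:
    """Damage sum per available dipyrimidine site.

    A region with zero dipyrimidine sites cannot carry CPDs; nonzero counts
    there indicate inconsistent inputs.
    """
    if dipyr_count == 0:
        if raw_sum > 0:
            raise DataInconsistencyError(
                f"{raw_sum} counts in a region with no dipyrimidine sites"
            )
        return 0.0
    return raw_sum / dipyr_count


def region_repair_fraction(counts: RegionCounts, t: float) -> float:
    """Repaired fraction at time t: (S(0) - S(t)) / S(0).

    May be negative before rectification (sampling noise); never exceeds 1.
    Raises :class:`UndamagedRegionError` when the 0-minute sum is zero.
    """
    if 0 not in counts.sums and 0.0 not in counts.sums:
        raise ValueError("RegionCounts lacks the 0-minute reference sample")
    s0 = counts.sums.get(0, counts.sums.get(0.0))
    if s0 == 0:
        raise UndamagedRegionError(
            f"region {counts.region_id!r} has no damage at t=0"
        )
    if t not in counts.sums:
        raise KeyError(f"time {t} not sampled for region {counts.region_id!r}")
    return (s0 - counts.sums[t]) / s0


def rectify(
    values: Sequence[float],
    times: Sequence[float],
    region_id: str = "",
) -> RepairTimeCourse:
    """Enforce non-negative, monotone non-decreasing repair fractions.

    The first value is clipped at 0, each later value at its predecessor's
    rectified value (no new lesions form after irradiation ends).  The
    operation is idempotent and leaves already-valid courses unchanged.
    """
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    prev = 0.0
    for i, x in enumerate(v):
        prev = max(x, prev)
        out[i] = prev
    return RepairTimeCourse(times=np.asarray(times, float), values=out,
                            region_id=region_id)


def empirical_repair_rate(tc: RepairTimeCourse) -> np.ndarray:
    """Data-derived rate surrogate: damage decrease per minute, per interval.

    Forward finite differences (R(t_i) - R(t_{i-1})) / (t_i - t_{i-1}) with
    R(0) = 0 prepended, so the first interval is (0, t_1].  On a rectified
    course every rate is >= 0.
    """
    t = np.concatenate(([0.0], tc.times))
    v = np.concatenate(([0.0], tc.values))
    return np.diff(v) / np.diff(t)


def build_time_course(
    counts: RegionCounts,
    times: Sequence[float] | None = None,
) -> RepairTimeCourse:
    """Repair fractions at all positive sampled times, rectified.

    ``times`` defaults to every sampled time > 0 in ascending order.
    """
    if times is None:
        times = sorted(t for t in counts.sums if t > 0)
    fracs = [region_repair_fraction(counts, t) for t in times]
    return rectify(fracs, times, region_id=counts.region_id)


def merge_fraction_courses(
    courses: Sequence[Mapping[float, float]],
    region_id: str = "",
) -> RepairTimeCourse:
    """Merge repair-fraction dictionaries from separate experimental courses.

    Each course is assumed to have been converted to fractions against its
    own 0-minute reference, which removes course-specific sequencing depth;
    times present in several courses are averaged.  The merged values are
    rectified before return.
    """
    pooled: dict[float, list[float]] = {}
    for course in courses:
        for t, v in course.items():
            if t > 0:
                pooled.setdefault(t, []).append(v)
    times = sorted(pooled)
    vals = [float(np.mean(pooled[t])) for t in times]
    return rectify(vals, times, region_id=region_id)
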