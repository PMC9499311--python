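"""End-to-end workflows: tracks in, region fits out.

Glue over the format readers, the segmentation, the repair transform and the
KJMA fitter, used both by the command-line interface and the narrative
examples.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import RepairTimeCourse, fit_many
from .segmentation import (
    GenomicRegion, TranscriptionUnit, build_region_set, classify_tcr,
    template_strand,
)
from .signal import (
    RegionCounts, SignalTrack, UndamagedRegionError, aggregate_region,
    build_time_course, count_dipyrimidines, normalize_damage,
    region_repair_fraction, rectify,
)

__all__ = [
    "region_counts",
    "region_time_courses",
    "segment_and_fit",
]

logger = logging.getLogger(__name__)


def _region_dipyr_count(
    region: GenomicRegion, sequences: Mapping[str, str]
) -> int:
    seq = sequences[region.chrom][region.start:region.end]
    n_frac = (seq.upper().count("N") / len(seq)) if seq else 1.0
    if n_frac > 0.5:
        logger.warning(
            "region %s is %.0f%% N; dropping", region.region_id, 100 * n_frac
        )
        return 0
    if region.strand == "both":
        return (count_dipyrimidines(seq, "+") + count_dipyrimidines(seq, "-"))
    return count_dipyrimidines(seq, region.strand)


def region_counts(
    tracks_by_time: Mapping[float, Sequence[SignalTrack]],
    region: GenomicRegion,
    sequences: Mapping[str, str] | None = None,
) -> RegionCounts:
    """Summed (dipyrimidine-normalised when sequence is given) damage per time."""
    dipyr = None
    if sequences is not None:
        dipyr = _region_dipyr_count(region, sequences)
    sums: dict[float, float] = {}
    for t, tracks in tracks_by_time.items():
        raw = aggregate_region(
            tracks, region.chrom, region.start, region.end, region.strand
        )
        sums[float(t)] = normalize_damage(raw, dipyr) if dipyr is not None else raw
    return RegionCounts(region_id=region.region_id, sums=sums)


def region_time_courses(
    tracks_by_time: Mapping[float, Sequence[SignalTrack]],
    regions: Iterable[GenomicRegion],
    sequences: Mapping[str, str] | None = None,
) -> tuple[dict[str, RepairTimeCourse], dict[str, dict[float, float]]]:
    """Rectified repair time courses for every damaged, fit-eligible region.

    Returns ``(courses, raw_fractions)``; undamaged regions (zero 0-minute
    signal) are skipped with a log note, and the pre-rectification fractions
    are returned alongside for transparency.
    """
    courses: dict[str, RepairTimeCourse] = {}
    raw: dict[str, dict[float, float]] = {}
    for region in regions:
        if not region.fit_eligible:
            continue
        counts = region_counts(tracks_by_time, region, sequences)
        try:
            times = sorted(t for t in counts.sums if t > 0)
            fracs = {t: region_repair_fraction(counts, t) for t in times}
        except UndamagedRegionError:
            logger.info("region %s undamaged at t=0; skipped", region.region_id)
            continue
        raw[region.region_id] = fracs
        courses[region.region_id] = rectify(
            [fracs[t] for t in times], times, region_id=region.region_id
        )
    return courses, raw


def segment_and_fit(
    tracks_by_time: Mapping[float, Sequence[SignalTrack]],
    tus: Sequence[TranscriptionUnit],
    chrom_sizes: Mapping[str, int],
    sequences: Mapping[str, str] | None = None,
    mode: str = "TCR",
    tcr_threshold: float = 0.2,
    theta_min_tcr: float = 0.5,
    theta_min_other: float = 0.4,
    theta_step: float = 0.01,
    m_range: tuple[float, float] = (0.5, 5.0),
    tau_range: tuple[float, float] = (20.0, 200.0),
):
    """The full analysis: classify TCR, build regions, transform, fit.

    TCR classification uses each TU's whole-TS rectified repair at 20
    minutes.  Returns ``(fits, regions, courses)`` where ``fits`` is the
    tidy fit table of :func:`repairkinetics.model.fit_many`.
    """
    # whole-TU transcribed-strand courses drive the TCR call
    ts_regions = [
        GenomicRegion(tu.chrom, tu.start, tu.end, template_strand(tu.strand),
                      "TS", tu.tu_id)
        for tu in tus
    ]
    ts_courses, _ = region_time_courses(tracks_by_time, ts_regions, sequences)
    repair20 = {
        rid.split("|")[0]: float(np.interp(20.0, tc.times, tc.values))
        for rid, tc in ts_courses.items()
        if 20.0 in tc.times
    }
    labels = classify_tcr(tus, repair20, threshold=tcr_threshold)
    regions = build_region_set(tus, labels, chrom_sizes, mode=mode)
    courses, _ = region_time_courses(tracks_by_time, regions, sequences)
    role_of = {r.region_id: r.role for r in regions}
    fits = fit_many(
        courses.values(),
        region_class=role_of,
        theta_min_tcr=theta_min_tcr,
        theta_min_other=theta_min_other,
        theta_step=theta_step,
        m_range=m_range,
        tau_range=tau_range,
    )
    return fits, regions, courses
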