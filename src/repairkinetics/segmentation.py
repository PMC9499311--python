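"""Genome segmentation for repair-kinetics fitting.

Two setups are supported.  The *TCR* setup singles out transcription units
(TUs) with evident transcription-coupled repair: their transcribed strand
(TS) and non-transcribed strand (NTS) are each divided into start, centre and
end thirds (six stranded subregions per TU), and all remaining genomic space
— including TUs without a TCR signature — is merged across strands into
non-TCR blocks.  The *gene* setup is the traditional partition into TS, NTS
and intergenic regions.

A TU is called TCR-supported when its TS shows more than a threshold fraction
of repair (default 20%) within the first 20 minutes after irradiation.

Strand convention: the TS of a '+'-strand TU is the template ('-') strand and
vice versa; "start" is always the transcriptionally first third, so for a
'-'-strand TU it is the rightmost third in genome coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptionUnit",
    "GenomicRegion",
    "ROLES",
    "classify_tcr",
    "subdivide",
    "build_region_set",
    "d_mere",
    "resolve_overlaps",
    "MIN_FIT_ELIGIBLE_NT",
]

logger = logging.getLogger(__name__)

ROLES = (
    "TS_start", "TS_centre", "TS_end",
    "NTS_start", "NTS_centre", "NTS_end",
    "nonTCR", "TS", "NTS", "intergenic",
)

#: thirds below this total size are too small to carry a meaningful count
MIN_FIT_ELIGIBLE_NT = 9


@dataclass(frozen=True)
class TranscriptionUnit:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    tu_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TU {self.tu_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TU {self.tu_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicRegion:
    """A stranded interval with its role in the segmentation."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or 'both'
    role: str
    parent_id: str | None = None
    fit_eligible: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.strand == "both" and self.role not in ("nonTCR", "intergenic"):
            raise ValueError("strand 'both' only for nonTCR/intergenic roles")

    @property
    def region_id(self) -> str:
        base = self.parent_id or f"{self.chrom}:{self.start}-{self.end}"
        return f"{base}|{self.role}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def template_strand(tu_strand: str) -> str:
    return "-" if tu_strand == "+" else "+"


def classify_tcr(
    tus: Sequence[TranscriptionUnit],
    ts_repair_at_20min: Mapping[str, float],
    threshold: float = 0.2,
) -> dict[str, bool]:
    """Label each TU TCR-supported or not from its early TS repair.

    A TU is TCR iff its (rectified) transcribed-strand repair fraction at
    20 minutes exceeds ``threshold``.  TUs missing a 20-minute value are
    labelled non-TCR with a logged note.
    """
    labels: dict[str, bool] = {}
    for tu in tus:
        val = ts_repair_at_20min.get(tu.tu_id)
        if val is None:
            logger.info("TU %s: no 20-min repair value; labelled non-TCR", tu.tu_id)
            labels[tu.tu_id] = False
        else:
            labels[tu.tu_id] = val > threshold
    return labels


def subdivide(
    chrom: str,
    start: int,
    end: int,
    tu_strand: str,
    region_strand: str,
    role_prefix: str,
    parent_id: str | None = None,
) -> list[GenomicRegion]:
    """Split an interval into transcriptional start/centre/end thirds.

    The thirds are contiguous, non-overlapping and tile [start, end) exactly;
    any remainder nucleotides go to the centre.  For a '-'-strand TU the
    start third is the rightmost in genome coordinates.  Intervals shorter
    than 3 nt cannot be split and fall back to a single flagged centre.
    """
    length = end - start
    eligible = length >= MIN_FIT_ELIGIBLE_NT
    if length < 3:
        return [GenomicRegion(chrom, start, end, region_strand,
                              f"{role_prefix}_centre", parent_id,
                              fit_eligible=False)]
    third = length // 3
    cuts = [start, start + third, end - third, end]
    genomic = [(cuts[0], cuts[1]), (cuts[1], cuts[2]), (cuts[2], cuts[3])]
    order = ("start", "centre", "end")
    if tu_strand == "-":
        genomic = genomic[::-1]
    return [
        GenomicRegion(chrom, lo, hi, region_strand, f"{role_prefix}_{part}",
                      parent_id, fit_eligible=eligible)
        for part, (lo, hi) in zip(order, genomic)
    ]


def resolve_overlaps(
    tus: Sequence[TranscriptionUnit],
) -> list[TranscriptionUnit]:
    """Drop same-strand TUs overlapped by a longer TU (longer one wins)."""
    kept: list[TranscriptionUnit] = []
    by_key = sorted(tus, key=lambda u: (u.chrom, u.strand, -u.length, u.start))
    for tu in by_key:
        clash = next(
            (k for k in kept
             if k.chrom == tu.chrom and k.strand == tu.strand
             and k.start < tu.end and tu.start < k.end),
            None,
        )
        if clash is None:
            kept.append(tu)
        else:
            logger.warning(
                "TU %s (%d nt) overlaps %s (%d nt) on %s%s; dropping the shorter",
                tu.tu_id, tu.length, clash.tu_id, clash.length, tu.chrom, tu.strand,
            )
    kept.sort(key=lambda u: (u.chrom, u.start))
    return kept


def _complement_blocks(
    intervals: list[tuple[int, int]], chrom_len: int
) -> list[tuple[int, int]]:
    """Gaps of [0, chrom_len) not covered by the (merged) intervals."""
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    blocks, cur = [], 0
    for lo, hi in merged:
        if lo > cur:
            blocks.append((cur, lo))
        cur = max(cur, hi)
    if cur < chrom_len:
        blocks.append((cur, chrom_len))
    return blocks


def build_region_set(
    tus: Sequence[TranscriptionUnit],
    tcr_labels: Mapping[str, bool],
    chrom_sizes: Mapping[str, int],
    mode: str = "TCR",
) -> list[GenomicRegion]:
    """Construct the full region set for one segmentation mode.

    mode='TCR': every TCR-labelled TU contributes six stranded subregions
    (TS/NTS x start/centre/end); everything else on the chromosome — gaps
    and non-TCR TUs alike — becomes strand-merged nonTCR blocks bounded by
    the TCR TUs.  mode='gene': every TU contributes whole-TU TS and NTS
    regions and the gaps become intergenic blocks.

    Same-strand overlapping TUs are resolved first (longer wins).  A TU
    extending beyond its chromosome raises ValueError.
    """
    if mode not in ("TCR", "gene"):
        raise ValueError(f"mode must be 'TCR' or 'gene', got {mode!r}")
    tus = resolve_overlaps(tus)
    for tu in tus:
        size = chrom_sizes.get(tu.chrom)
        if size is None:
            raise ValueError(f"TU {tu.tu_id}: unknown chromosome {tu.chrom}")
        if tu.end > size or tu.start < 0:
            raise ValueError(f"TU {tu.tu_id} exceeds bounds of {tu.chrom}")

    regions: list[GenomicRegion] = []
    covering: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for tu in tus:
        ts, nts = template_strand(tu.strand), tu.strand
        if mode == "gene":
            regions.append(GenomicRegion(tu.chrom, tu.start, tu.end, ts,
                                         "TS", tu.tu_id))
            regions.append(GenomicRegion(tu.chrom, tu.start, tu.end, nts,
                                         "NTS", tu.tu_id))
            covering[tu.chrom].append((tu.start, tu.end))
        elif tcr_labels.get(tu.tu_id, False):
            regions += subdivide(tu.chrom, tu.start, tu.end, tu.strand,
                                 ts, "TS", tu.tu_id)
            regions += subdivide(tu.chrom, tu.start, tu.end, tu.strand,
                                 nts, "NTS", tu.tu_id)
            covering[tu.chrom].append((tu.start, tu.end))

    gap_role = "intergenic" if mode == "gene" else "nonTCR"
    for chrom, size in chrom_sizes.items():
        for lo, hi in _complement_blocks(covering.get(chrom, []), size):
            regions.append(GenomicRegion(
                chrom, lo, hi, "both", gap_role,
                parent_id=f"{chrom}:{lo}-{hi}",
                fit_eligible=(hi - lo) >= MIN_FIT_ELIGIBLE_NT,
            ))
    return regions


def d_mere(x: float, centromere: float, telomere: float) -> float:
    """Relative distance to the nearer of centromere and telomere.

    d = 2 * min(|x - c|, |x - t|) / |c - t|; 0 at either landmark, 1 at
    their midpoint (dividing by half the span makes the midpoint maximal).
    """
    span = abs(centromere - telomere)
    if span == 0:
        raise ValueError("centromere and telomere coincide")
    return 2.0 * min(abs(x - centromere), abs(x - telomere)) / span
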