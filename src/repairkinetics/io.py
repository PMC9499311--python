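"""Readers and writers for the plain-text interchange formats.

Damage and excision tracks travel as 4-column bedGraph (one file per time
point per strand), annotations as BED6, sequence as FASTA, and tabular
results (time courses, fits, features, centromere/telomere landmarks) as
TSV.  All coordinates are 0-based half-open, BED-style.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import GenomicRegion, TranscriptionUnit, ROLES
from .signal import SignalTrack

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_bed6_tus",
    "write_regions_bed",
    "read_regions_bed",
    "write_fasta",
    "read_fasta",
    "read_meres_tsv",
    "write_fits_tsv",
    "write_time_courses_tsv",
]


def read_bedgraph(
    path: str | os.PathLike,
    strand: str = "both",
    time_label: float | None = None,
) -> dict[str, SignalTrack]:
    """Load a 4-column bedGraph into one per-base SignalTrack per chromosome.

    Multi-base intervals are expanded so each covered base carries the
    interval's value (count-per-base semantics); track files are expected to
    be position-resolved, so intervals are typically 1 bp.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "value": float},
    )
    tracks: dict[str, SignalTrack] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        widths = (grp["end"] - grp["start"]).to_numpy()
        positions = np.concatenate([
            np.arange(s, e) for s, e in zip(grp["start"], grp["end"])
        ]) if len(grp) else np.empty(0, dtype=np.int64)
        values = np.repeat(grp["value"].to_numpy(), widths)
        order = np.argsort(positions, kind="stable")
        tracks[chrom] = SignalTrack(
            chrom=chrom, strand=strand,
            positions=positions[order], values=values[order],
            time_label=time_label,
        )
    return tracks


def write_bedgraph(
    tracks: Iterable[SignalTrack], path: str | os.PathLike
) -> None:
    """Write per-base tracks as 1-bp bedGraph intervals (zero values skipped)."""
    with open(path, "w") as fh:
        for tr in tracks:
            nz = tr.values != 0
            for pos, val in zip(tr.positions[nz], tr.values[nz]):
                val_str = f"{int(val)}" if float(val).is_integer() else f"{val:.6g}"
                fh.write(f"{tr.chrom}\t{pos}\t{pos + 1}\t{val_str}\n")


def read_bed6_tus(path: str | os.PathLike) -> list[TranscriptionUnit]:
    """Transcription units from a BED6 file (name column is the TU id)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        TranscriptionUnit(r.chrom, int(r.start), int(r.end), r.strand, r.name)
        for r in df.itertuples()
    ]


def write_regions_bed(
    regions: Iterable[GenomicRegion], path: str | os.PathLike
) -> None:
    """Regions as BED6; the name field carries ``parent|role``."""
    with open(path, "w") as fh:
        for r in regions:
            strand = r.strand if r.strand in "+-" else "."
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t{strand}\n"
            )


def read_regions_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    regions = []
    for r in df.itertuples():
        parent, _, role = r.name.rpartition("|")
        if role not in ROLES:
            raise ValueError(f"unrecognised role in BED name {r.name!r}")
        strand = "both" if r.strand == "." else r.strand
        regions.append(GenomicRegion(
            r.chrom, int(r.start), int(r.end), strand, role,
            parent_id=parent or None,
        ))
    return regions


def write_fasta(
    sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Whole-sequence FASTA load via pyfaidx (suitable for small genomes)."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def read_meres_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Centromere/telomere landmark table: chrom, centromere_pos, telomere_pos."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "centromere_pos", "telomere_pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"meres TSV needs columns {sorted(required)}")
    return df


def write_fits_tsv(fits: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["region_id", "class", "m", "tau", "beta", "theta", "adj_r2",
            "n_points_used", "passes_filter"]
    extra = [c for c in fits.columns if c not in cols]
    fits.loc[:, [c for c in cols if c in fits.columns] + extra].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_time_courses_tsv(
    courses: Mapping[str, "object"], path: str | os.PathLike,
    raw: Mapping[str, Mapping[float, float]] | None = None,
) -> None:
    """Per-region rectified repair fractions, one column per time point.

    When the pre-rectification fractions are supplied they are written as
    additional ``raw_t<min>`` columns.
    """
    rows = []
    for region_id, tc in courses.items():
        row: dict = {"region_id": region_id}
        for t, v in zip(tc.times, tc.values):
            row[f"t{int(t)}"] = v
        if raw and region_id in raw:
            for t, v in raw[region_id].items():
                if t > 0:
                    row[f"raw_t{int(t)}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
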