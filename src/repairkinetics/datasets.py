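"""Fully synthetic on-disk datasets for end-to-end runs.

Fabricates a coherent experiment directory: a random chromosome (FASTA), TU
annotations (BED6), centromere/telomere landmarks (TSV), per-time per-strand
damage tracks (bedGraph) whose lesions sit on actual dipyrimidine sites of
the sequence, XR-like region counts (TSV), a feature table (TSV) and the
ground-truth parameters (TSV) for recovery scoring.  Everything is derived
from one integer seed.

Half of the TUs are given fast, TCR-like transcribed-strand kinetics (small
tau, m near 1) and the rest—as well as all non-transcribed strands and
intergenic space—slow GGR-like kinetics, so downstream TCR classification
and segmentation have realistic structure to find.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rkio
from .segmentation import TranscriptionUnit, template_strand
from .signal import SignalTrack, dipyrimidine_positions
from .simulate import (
    RegionSpec, _simulate_region, generate_features, generate_genome,
    sample_damage_counts, sample_xr_counts, DEFAULT_SAMPLE_TIMES,
    DEFAULT_XR_TIMES,
)

__all__ = ["write_simulated_dataset", "load_dataset"]


def _draw_spec(rng: np.random.Generator, kind: str, region_id: str) -> RegionSpec:
    if kind == "tcr":  # fast, early repair on the transcribed strand
        return RegionSpec(region_id, m=float(rng.uniform(0.9, 1.4)),
                          tau=float(rng.uniform(25, 60)),
                          theta=float(rng.uniform(0.75, 0.95)))
    return RegionSpec(region_id, m=float(rng.uniform(1.5, 3.0)),  # GGR-like
                      tau=float(rng.uniform(60, 150)),
                      theta=float(rng.uniform(0.5, 0.8)))


def write_simulated_dataset(
    outdir: str | Path,
    n_tus: int = 20,
    n_cells: int = 300,
    damage_prob: float = 0.05,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
    xr_times: Sequence[float] = DEFAULT_XR_TIMES,
    xr_window: float = 10.0,
    poisson_noise: bool = False,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate and write a complete small experiment; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sequences, tus, meres = generate_genome(n_tus, rng)
    (chrom, seq), = sequences.items()

    tcr_flags = {tu.tu_id: (i % 2 == 0) for i, tu in enumerate(tus)}
    specs: dict[str, RegionSpec] = {}
    # strand-resolved simulation units: (id, strand, site positions, spec kind)
    units: list[tuple[str, str, np.ndarray, RegionSpec]] = []
    for tu in tus:
        sub = seq[tu.start:tu.end]
        for label, strand in (("TS", template_strand(tu.strand)),
                              ("NTS", tu.strand)):
            sites = dipyrimidine_positions(sub, strand) + tu.start
            kind = "tcr" if (label == "TS" and tcr_flags[tu.tu_id]) else "ggr"
            spec = _draw_spec(rng, kind, f"{tu.tu_id}|{label}")
            specs[spec.region_id] = spec
            units.append((spec.region_id, strand, sites, spec))
    # intergenic background on both strands, one slow process per gap
    bounds = [0] + [x for tu in tus for x in (tu.start, tu.end)] + [len(seq)]
    for gi in range(0, len(bounds) - 1, 2):
        lo, hi = bounds[gi], bounds[gi + 1]
        if hi - lo < 10:
            continue
        sub = seq[lo:hi]
        for strand in "+-":
            sites = dipyrimidine_positions(sub, strand) + lo
            spec = _draw_spec(rng, "ggr", f"gap_{gi // 2:03d}|{strand}")
            specs[spec.region_id] = spec
            units.append((spec.region_id, strand, sites, spec))

    per_strand_time: dict[tuple[str, float], tuple[list, list]] = {
        (s, t): ([], []) for s in "+-" for t in sample_times
    }
    xr_rows = []
    for region_id, strand, sites, spec in units:
        if len(sites) == 0:
            continue
        grid = _simulate_region(spec, n_cells, len(sites), damage_prob, rng)
        counts = sample_damage_counts(grid, sample_times, rng, poisson_noise)
        for t, row in zip(sample_times, counts):
            ps, vs = per_strand_time[(strand, t)]
            ps.append(sites)
            vs.append(row)
        xr = sample_xr_counts(grid, xr_times, xr_window, rng, poisson_noise)
        for t, v in zip(xr_times, xr):
            xr_rows.append({"region_id": region_id, "time": t, "count": v})

    paths: dict[str, Path] = {}
    for (strand, t), (ps, vs) in per_strand_time.items():
        pos = np.concatenate(ps)
        val = np.concatenate(vs)
        order = np.argsort(pos, kind="stable")
        track = SignalTrack(chrom, strand, pos[order], val[order], t)
        tag = "plus" if strand == "+" else "minus"
        p = outdir / f"cpd_t{int(t)}_{tag}.bedGraph"
        rkio.write_bedgraph([track], p)
        paths[f"cpd_t{int(t)}_{tag}"] = p

    paths["fasta"] = outdir / "genome.fa"
    rkio.write_fasta(sequences, paths["fasta"])
    paths["tus"] = outdir / "tus.bed"
    with open(paths["tus"], "w") as fh:
        for tu in tus:
            fh.write(f"{tu.chrom}\t{tu.start}\t{tu.end}\t{tu.tu_id}\t0\t{tu.strand}\n")
    paths["meres"] = outdir / "meres.tsv"
    meres.to_csv(paths["meres"], sep="\t", index=False)
    paths["xr"] = outdir / "xr_counts.tsv"
    pd.DataFrame(xr_rows).to_csv(paths["xr"], sep="\t", index=False)

    gt = pd.DataFrame(
        [{"region_id": rid, "m": s.m, "tau": s.tau, "theta": s.theta}
         for rid, s in specs.items()]
    )
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    gt.to_csv(paths["ground_truth"], sep="\t", index=False)

    ts_gt = gt[gt.region_id.str.endswith("|TS")].set_index("region_id")
    ts_gt["beta"] = 1.0 / ts_gt["tau"]
    features = generate_features(
        ts_gt,
        {"transcription_rate_like": ("beta", 1.0),
         "tu_length_like": ("tau", 1.0),
         "null_feature": (None, 1.0)},
        noise_sd=0.2, seed=rng,
    )
    features.insert(0, "tu_id", [rid.split("|")[0] for rid in features.index])
    paths["features"] = outdir / "features.tsv"
    features.to_csv(paths["features"], sep="\t", index=False)
    return paths


def load_dataset(
    directory: str | Path,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
) -> dict:
    """Read a dataset directory back into in-memory objects."""
    directory = Path(directory)
    tracks_by_time: dict[float, list[SignalTrack]] = {}
    for t in sample_times:
        tracks: list[SignalTrack] = []
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = directory / f"cpd_t{int(t)}_{tag}.bedGraph"
            if p.exists():
                tracks.extend(
                    rkio.read_bedgraph(p, strand=strand, time_label=t).values()
                )
        tracks_by_time[float(t)] = tracks
    sequences = rkio.read_fasta(directory / "genome.fa")
    tus = rkio.read_bed6_tus(directory / "tus.bed")
    out = {
        "tracks_by_time": tracks_by_time,
        "sequences": sequences,
        "tus": tus,
        "chrom_sizes": {c: len(s) for c, s in sequences.items()},
        "meres": rkio.read_meres_tsv(directory / "meres.tsv"),
        "ground_truth": pd.read_csv(directory / "ground_truth.tsv", sep="\t"),
    }
    xr_path = directory / "xr_counts.tsv"
    if xr_path.exists():
        out["xr_counts"] = pd.read_csv(xr_path, sep="\t")
    feat_path = directory / "features.tsv"
    if feat_path.exists():
        out["features"] = pd.read_csv(feat_path, sep="\t", index_col=0)
    return out
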