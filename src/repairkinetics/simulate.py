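"""Stochastic cells-x-positions simulator of population-scale CPD repair.

The generative picture: a UV-irradiated culture is a grid of independent
cells (rows) and dipyrimidine positions (columns).  Each position in each
cell carries at most one lesion (Bernoulli damage), each lesion is repair-
competent with probability theta, and a competent lesion's repair time is
drawn Weibull(shape m, scale tau) — the unique law whose CDF reproduces the
repaired fraction theta * (1 - exp[-(t/tau)^m]).  Summing unrepaired lesions
over cells at the sampled times yields CPD-seq-like damage tracks; counting
repair events inside a short window around a time point yields XR-seq-like
excision tracks (a snapshot of ongoing repair).

The module also fabricates the surrounding artefacts — random genome FASTA
with controllable pyrimidine content, TU annotations, centromere/telomere
tables, and feature tables correlated (or not) with the ground-truth
parameters — so the whole analysis stack is testable without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import KJMAParams, RepairTimeCourse
from .signal import SignalTrack, RegionCounts, build_time_course

__all__ = [
    "RegionSpec",
    "SimulationConfig",
    "PopulationGrid",
    "simulate_population",
    "iter_population",
    "sample_damage_counts",
    "sample_xr_counts",
    "generate_genome",
    "generate_features",
    "random_region_specs",
    "region_counts_from_grid",
    "simulate_time_courses",
]

DEFAULT_SAMPLE_TIMES = (0.0, 20.0, 60.0, 120.0)
DEFAULT_XR_TIMES = (5.0, 20.0, 60.0)


@dataclass(frozen=True)
class RegionSpec:
    """Ground truth for one simulated region."""

    region_id: str
    m: float
    tau: float
    theta: float

    def __post_init__(self) -> None:
        if self.m <= 0 or self.tau <= 0:
            raise ValueError("m and tau must be positive")
        if not (0 <= self.theta <= 1):
            raise ValueError("theta must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults reproduce the reference conditions: 2,000 cells, 200
    dipyrimidine positions per region, lesions at 5% of sites, CPD samples
    at 0/20/60/120 min and XR samples at 5/20/60 min with a 10-minute
    capture window, no sequencing noise.
    """

    regions: tuple[RegionSpec, ...]
    n_cells: int = 2000
    n_positions: int = 200
    damage_prob: float = 0.05
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    xr_times: tuple[float, ...] = DEFAULT_XR_TIMES
    xr_window: float = 10.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_positions < 1:
            raise ValueError("n_cells and n_positions must be >= 1")
        if 0.0 not in self.sample_times:
            raise ValueError("sample_times must include the 0-minute reference")
        if not (0 < self.damage_prob <= 1):
            raise ValueError("damage_prob must be in (0, 1]")
        if self.xr_window <= 0:
            raise ValueError("xr_window must be positive")


@dataclass
class PopulationGrid:
    """One region's lesion/repair state over the cell population.

    ``lesion`` is a boolean cells x positions matrix; ``repair_time`` holds
    the repair minute for competent lesions, +inf for lesions that never
    repair, and NaN where no lesion exists.
    """

    region_id: str
    lesion: np.ndarray
    repair_time: np.ndarray

    def __post_init__(self) -> None:
        if self.lesion.shape != self.repair_time.shape:
            raise ValueError("lesion and repair_time shapes differ")


def _simulate_region(
    spec: RegionSpec, n_cells: int, n_positions: int,
    damage_prob: float, rng: np.random.Generator,
) -> PopulationGrid:
    lesion = rng.random((n_cells, n_positions)) < damage_prob
    repair_time = np.full((n_cells, n_positions), np.nan)
    n_lesions = int(lesion.sum())
    competent = rng.random(n_lesions) < spec.theta
    times = np.full(n_lesions, np.inf)
    n_comp = int(competent.sum())
    if n_comp:
        times[competent] = spec.tau * rng.weibull(spec.m, size=n_comp)
    repair_time[lesion] = times
    return PopulationGrid(spec.region_id, lesion, repair_time)


def iter_population(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Iterator[PopulationGrid]:
    """Yield one region's grid at a time (constant memory over regions)."""
    rng = rng or np.random.default_rng(config.seed)
    for spec in config.regions:
        yield _simulate_region(
            spec, config.n_cells, config.n_positions, config.damage_prob, rng
        )


def simulate_population(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, PopulationGrid]:
    """Materialise every region's grid (memory scales with region count)."""
    return {g.region_id: g for g in iter_population(config, rng)}


def sample_damage_counts(
    grid: PopulationGrid,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
    rng: np.random.Generator | None = None,
    poisson_noise: bool = False,
) -> np.ndarray:
    """Remaining-lesion counts per position at each sampled time.

    Row t of the returned (n_times x n_positions) integer array counts the
    cells whose lesion at that position is still unrepaired at time t
    (repair time strictly greater than t, never-repaired lesions included).
    Optional Poisson resampling emulates sequencing-depth noise.
    """
    counts = np.empty((len(sample_times), grid.lesion.shape[1]), dtype=float)
    with np.errstate(invalid="ignore"):
        for i, t in enumerate(sample_times):
            unrepaired = grid.lesion & ~(grid.repair_time <= t)
            counts[i] = unrepaired.sum(axis=0)
    if poisson_noise:
        if rng is None:
            raise ValueError("poisson_noise requires an rng")
        counts = rng.poisson(counts).astype(float)
    return counts


def sample_xr_counts(
    grid: PopulationGrid,
    xr_times: Sequence[float] = DEFAULT_XR_TIMES,
    window: float = 10.0,
    rng: np.random.Generator | None = None,
    poisson_noise: bool = False,
) -> np.ndarray:
    """Excision-fragment counts per region: repair events near each time.

    The count at time t is the number of lesions (pooled over cells and
    positions) whose repair time falls in (t - window/2, t + window/2].  For
    small windows the expectation is proportional to the instantaneous
    repair rate times the number of lesions times the window length.
    """
    finite = grid.repair_time[np.isfinite(grid.repair_time)]
    counts = np.array([
        float(np.sum((finite > t - window / 2) & (finite <= t + window / 2)))
        for t in xr_times
    ])
    if poisson_noise:
        if rng is None:
            raise ValueError("poisson_noise requires an rng")
        counts = rng.poisson(counts).astype(float)
    return counts


def region_counts_from_grid(
    grid: PopulationGrid,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
    rng: np.random.Generator | None = None,
    poisson_noise: bool = False,
) -> RegionCounts:
    """Region-summed damage per sampled time, ready for the repair transform."""
    counts = sample_damage_counts(grid, sample_times, rng, poisson_noise)
    return RegionCounts(
        region_id=grid.region_id,
        sums={float(t): float(c.sum()) for t, c in zip(sample_times, counts)},
    )


def simulate_time_courses(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    with_xr: bool = False,
):
    """Run the simulator through the repair transform for every region.

    Returns ``(courses, xr)`` where ``courses`` maps region_id to a rectified
    :class:`RepairTimeCourse` and ``xr`` (when requested) maps region_id to
    {time: count}.  Regions are processed one at a time, so memory stays
    flat regardless of region count.
    """
    rng = rng or np.random.default_rng(config.seed)
    courses: dict[str, RepairTimeCourse] = {}
    xr: dict[str, dict[float, float]] = {}
    for grid in iter_population(config, rng):
        counts = region_counts_from_grid(
            grid, config.sample_times, rng, config.poisson_noise
        )
        courses[grid.region_id] = build_time_course(counts)
        if with_xr:
            vals = sample_xr_counts(
                grid, config.xr_times, config.xr_window, rng,
                config.poisson_noise,
            )
            xr[grid.region_id] = {
                float(t): float(v) for t, v in zip(config.xr_times, vals)
            }
    return (courses, xr) if with_xr else (courses, None)


def random_region_specs(
    n_regions: int,
    rng: np.random.Generator,
    m_range: tuple[float, float] = (0.8, 3.0),
    tau_range: tuple[float, float] = (30.0, 150.0),
    theta_range: tuple[float, float] = (0.5, 0.95),
    prefix: str = "region",
) -> tuple[RegionSpec, ...]:
    """Ground-truth triples drawn uniformly from the stated ranges."""
    return tuple(
        RegionSpec(
            region_id=f"{prefix}_{i:04d}",
            m=float(rng.uniform(*m_range)),
            tau=float(rng.uniform(*tau_range)),
            theta=float(rng.uniform(*theta_range)),
        )
        for i in range(n_regions)
    )


def ground_truth_frame(regions: Sequence[RegionSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"region_id": r.region_id, "m": r.m, "tau": r.tau,
          "theta": r.theta, "beta": 1.0 / r.tau} for r in regions]
    ).set_index("region_id")


# ---------------------------------------------------------------------------
# genome / annotation / feature fabrication


def generate_genome(
    n_tus: int,
    rng: np.random.Generator,
    tu_length_range: tuple[int, int] = (600, 3000),
    gap_length_range: tuple[int, int] = (200, 800),
    pyrimidine_fraction: float = 0.5,
    chrom: str = "chrSim",
):
    """A random chromosome with TUs, consistent coordinates and landmarks.

    Returns ``(sequences, tus, meres)``: a {chrom: sequence} dict, a list of
    (chrom, start, end, strand, tu_id) tuples, and a one-row DataFrame of
    centromere/telomere positions.  TU lengths span the stated range so the
    TU-length feature varies; base composition is i.i.d. with the requested
    pyrimidine (C+T) fraction, giving dipyrimidine density close to the
    squared pyrimidine fraction per dinucleotide.
    """
    from .segmentation import TranscriptionUnit

    py = pyrimidine_fraction
    probs = np.array([py / 2, py / 2, (1 - py) / 2, (1 - py) / 2])
    letters = np.array(list("CTAG"))
    tus = []
    cursor = int(rng.integers(*gap_length_range))
    for i in range(n_tus):
        length = int(rng.integers(tu_length_range[0], tu_length_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tus.append(TranscriptionUnit(chrom, cursor, cursor + length, strand,
                                     f"TU_{i:04d}"))
        cursor += length + int(rng.integers(*gap_length_range))
    chrom_len = cursor
    seq = "".join(rng.choice(letters, size=chrom_len, p=probs))
    meres = pd.DataFrame(
        {"chrom": [chrom], "centromere_pos": [chrom_len // 2],
         "telomere_pos": [0]}
    )
    return {chrom: seq}, tus, meres


def generate_features(
    ground_truth: pd.DataFrame,
    effect_map: Mapping[str, tuple[str | None, float]],
    noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-region features tied to (or independent of) the true parameters.

    ``effect_map`` maps a feature name to ``(parameter, coefficient)`` where
    parameter is one of the ground-truth columns (m, tau, theta, beta) or
    None for a pure-noise null feature.  A linked feature is the stated
    monotone (linear) function of the parameter plus Gaussian noise with SD
    ``noise_sd`` times the parameter's spread; e.g. a transcription-rate-like
    feature uses ('beta', +1): faster characteristic repair, higher rate.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = pd.DataFrame(index=ground_truth.index)
    for name, (param, coef) in effect_map.items():
        if param is None:
            out[name] = rng.normal(size=len(ground_truth))
        else:
            base = ground_truth[param].to_numpy(dtype=float)
            spread = base.std() or 1.0
            out[name] = coef * base + rng.normal(
                scale=noise_sd * spread * abs(coef), size=len(base)
            )
    return out
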