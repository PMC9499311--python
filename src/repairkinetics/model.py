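"""KJMA-form repair kinetics: the repair function, its derivative, and fitting.

The repaired fraction of lesions in a genomic region, measured over a
population of independent cells, is modelled as

    f(t) = theta * (1 - exp[-(t / tau)**m])

where ``m`` is the Avrami exponent (time dependence / anomalous-diffusion
shape), ``tau`` the characteristic repair time in minutes, and ``theta`` the
asymptotic fraction of cells that repair the lesion at all.  ``f(t) / theta``
is identically the Weibull(shape ``m``, scale ``tau``) CDF.

Fitting proceeds by a grid search over ``theta``: for each candidate the model
is linearized by a double logarithm,

    ln(-ln(1 - f(t)/theta)) = m * ln(t) - m * ln(tau),

so ordinary least squares on (ln t, double-log repair) yields ``m`` (slope)
and ``tau`` (from the intercept).  The candidate maximising the adjusted R²
of that regression wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KJMAParams",
    "RepairTimeCourse",
    "pool_time_courses",
    "InfeasibleThetaError",
    "UnfittableRegionError",
    "repair_fraction",
    "repair_rate",
    "linearize",
    "fit_given_theta",
    "fit",
    "filter_params",
    "fit_many",
    "DEFAULT_M_RANGE",
    "DEFAULT_TAU_RANGE",
]

DEFAULT_M_RANGE = (0.5, 5.0)
DEFAULT_TAU_RANGE = (20.0, 200.0)

#: adjusted-R² differences below this are treated as ties (smallest theta wins)
_R2_TIE_TOL = 1e-12


class InfeasibleThetaError(ValueError):
    """theta is not strictly above every observed repair fraction."""


class UnfittableRegionError(ValueError):
    """No theta on the grid yields a valid linearized regression."""


@dataclass(frozen=True)
class KJMAParams:
    """Fitted parameter triple of the repair function plus fit diagnostics.

    Parameters
    ----------
    m : float
        Avrami exponent, dimensionless, > 0.
    tau : float
        Characteristic repair time, minutes, > 0.
    theta : float
        Maximal repair fraction in (0, 1].
    adj_r2 : float
        Adjusted R² of the selected linearized regression (<= 1).
    n_points_used : int
        Number of time points that entered the regression.
    degenerate : bool
        True when the regression interpolated exactly two points (zero
        residual by construction).
    r2_original : float
        R² of the fitted curve against the repair fractions in the original
        (untransformed) space, reported for transparency.
    """

    m: float
    tau: float
    theta: float
    adj_r2: float = float("nan")
    n_points_used: int = 0
    degenerate: bool = False
    r2_original: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.m > 0):
            raise ValueError(f"m must be > 0, got {self.m}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not (0 < self.theta <= 1):
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if self.adj_r2 == self.adj_r2 and self.adj_r2 > 1 + 1e-9:
            raise ValueError(f"adjusted R² cannot exceed 1, got {self.adj_r2}")

    @property
    def beta(self) -> float:
        """Rate-like parameter 1/tau, per minute (beta * tau == 1 exactly)."""
        return 1.0 / self.tau


@dataclass(frozen=True)
class RepairTimeCourse:
    """Per-region repair fractions at the sampled post-irradiation times.

    Times must be sorted and positive; ties are allowed so that several
    strands' points can be pooled into one regression (the fit treats every
    (t, value) pair as an observation).
    """

    times: np.ndarray
    values: np.ndarray
    region_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1-D and equally long")
        if len(t) < 2:
            raise ValueError("a time course needs at least 2 points")
        if np.any(t <= 0) or np.any(np.diff(t) < 0):
            raise ValueError("times must be sorted and > 0")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("repair fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def pool_time_courses(
    courses: Sequence[RepairTimeCourse], region_id: str = ""
) -> RepairTimeCourse:
    """Pool several courses' (t, value) points into one regression input.

    Used for strand-merged regions where one parameter set must represent
    both strands: every point of every course enters the fit.
    """
    t = np.concatenate([c.times for c in courses])
    v = np.concatenate([c.values for c in courses])
    order = np.argsort(t, kind="stable")
    return RepairTimeCourse(times=t[order], values=v[order],
                            region_id=region_id)


def repair_fraction(params: KJMAParams, t) -> np.ndarray | float:
    """Repaired fraction f(t) = theta * (1 - exp[-(t/tau)^m]) at time t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = params.theta * -np.expm1(-((t_arr / params.tau) ** params.m))
    return out if t_arr.ndim else float(out)


def repair_rate(params: KJMAParams, t) -> np.ndarray | float:
    """Instantaneous repair rate df/dt, per minute.

    Equals ``m * theta * t**(m-1) / tau**m * exp[-(t/tau)**m]``.  At t = 0 the
    rate is theta/tau for m = 1 and 0 for m > 1; for m < 1 it diverges and a
    ValueError is raised.
    """
    m, tau, theta = params.m, params.tau, params.theta
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if np.any(t_arr == 0) and m < 1:
        raise ValueError("repair rate diverges at t = 0 for m < 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = m * theta * t_arr ** (m - 1.0) / tau**m * np.exp(-((t_arr / tau) ** m))
    # limits at t = 0: theta/tau for m == 1, 0 for m > 1
    if np.any(t_arr == 0):
        limit = theta / tau if m == 1 else 0.0
        rate = np.where(t_arr == 0, limit, rate)
    return rate if t_arr.ndim else float(rate)


def linearize(
    tc: RepairTimeCourse, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Double-log transform of a repair time course for a candidate theta.

    Returns (x, y) with x = ln t and y = ln(-ln(1 - value/theta)), one pair
    per retained point.  Points with value = 0 are dropped (their double log
    is undefined); at theta = 1, points with value = 1 are dropped likewise.

    Raises
    ------
    InfeasibleThetaError
        If theta <= the largest retained value (the transform requires
        value/theta < 1).
    UnfittableRegionError
        If fewer than 2 points survive.
    """
    if not (0 < theta <= 1):
        raise ValueError("theta must be in (0, 1]")
    t = tc.times
    v = tc.values
    keep = v > 0
    if theta == 1.0:
        keep &= v < 1.0
    t, v = t[keep], v[keep]
    if np.any(v >= theta):
        raise InfeasibleThetaError(
            f"theta={theta} not above max observed repair {v.max():.4f}"
        )
    if len(v) < 2:
        raise UnfittableRegionError(
            f"only {len(v)} usable point(s) after dropping zero-repair values"
        )
    x = np.log(t)
    y = np.log(-np.log1p(-v / theta))
    return x, y


def _adjusted_r2(r2: float, n: int) -> float:
    # one predictor (ln t); n == 2 interpolates exactly and is flagged upstream
    if n <= 2:
        return 1.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_given_theta(tc: RepairTimeCourse, theta: float):
    """OLS fit of (m, tau) in the linearized space for a fixed theta.

    Returns ``(m, tau, adj_r2, n_used, degenerate)`` or ``None`` when the fit
    is invalid (theta infeasible, fewer than 2 usable points, or non-positive
    slope), so that grid searches and batch runs can skip rather than abort.
    """
    try:
        x, y = linearize(tc, theta)
    except (InfeasibleThetaError, UnfittableRegionError):
        return None
    n = len(x)
    if np.all(x == x[0]):  # pooled duplicates only: slope undefined
        return None
    if n == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    if not (slope > 0) or not math.isfinite(slope):
        return None
    tau = math.exp(-intercept / slope)
    return slope, tau, _adjusted_r2(r2, n), n, n == 2


def _original_space_r2(tc: RepairTimeCourse, params: KJMAParams) -> float:
    pred = repair_fraction(params, tc.times)
    resid = tc.values - pred
    tot = tc.values - tc.values.mean()
    ss_tot = float(tot @ tot)
    if ss_tot == 0.0:
        return 1.0 if float(resid @ resid) < 1e-24 else float("-inf")
    return 1.0 - float(resid @ resid) / ss_tot


def theta_grid(theta_min: float, theta_step: float = 0.01) -> np.ndarray:
    """Candidate thetas {theta_min, theta_min + step, ..., 1.0} inclusive."""
    if not (0 < theta_min <= 1):
        raise ValueError("theta_min must be in (0, 1]")
    n = int(round((1.0 - theta_min) / theta_step))
    grid = theta_min + theta_step * np.arange(n + 1)
    grid = np.round(grid, 10)
    if grid[-1] < 1.0:
        grid = np.append(grid, 1.0)
    return np.minimum(grid, 1.0)


def fit(
    tc: RepairTimeCourse,
    theta_min: float = 0.4,
    theta_step: float = 0.01,
) -> KJMAParams:
    """Grid-search fit of (m, tau, theta) to a repair time course.

    Every theta on ``theta_grid(theta_min, theta_step)`` that is feasible is
    fitted by :func:`fit_given_theta`; the candidate with the highest adjusted
    R² is returned (ties within 1e-12 resolved to the smallest theta, so the
    result is deterministic).  ``theta_min`` conventionally defaults to 0.5
    for transcribed/TCR regions and 0.4 otherwise.

    Raises
    ------
    UnfittableRegionError
        If no candidate theta yields a valid regression.
    """
    best = None  # (adj_r2, theta, m, tau, n, degenerate)
    for theta in theta_grid(theta_min, theta_step):
        res = fit_given_theta(tc, float(theta))
        if res is None:
            continue
        m, tau, adj_r2, n, degen = res
        if best is None or adj_r2 > best[0] + _R2_TIE_TOL:
            best = (adj_r2, float(theta), m, tau, n, degen)
    if best is None:
        raise UnfittableRegionError(
            f"region {tc.region_id!r}: no feasible theta in the grid"
        )
    adj_r2, theta, m, tau, n, degen = best
    params = KJMAParams(
        m=m, tau=tau, theta=theta, adj_r2=min(adj_r2, 1.0),
        n_points_used=n, degenerate=degen,
    )
    return KJMAParams(
        m=params.m, tau=params.tau, theta=params.theta, adj_r2=params.adj_r2,
        n_points_used=n, degenerate=degen,
        r2_original=_original_space_r2(tc, params),
    )


def filter_params(
    params: KJMAParams,
    m_range: tuple[float, float] = DEFAULT_M_RANGE,
    tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
) -> bool:
    """True iff the fitted parameters lie in the physically reasonable range.

    Defaults restrict m to [0.5, 5] and tau to [20, 200] minutes; theta is
    already constrained by the fitting grid.
    """
    return (
        m_range[0] <= params.m <= m_range[1]
        and tau_range[0] <= params.tau <= tau_range[1]
    )


def fit_many(
    courses: Iterable[RepairTimeCourse],
    region_class: Mapping[str, str] | None = None,
    theta_min_tcr: float = 0.5,
    theta_min_other: float = 0.4,
    theta_step: float = 0.01,
    m_range: tuple[float, float] = DEFAULT_M_RANGE,
    tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
) -> pd.DataFrame:
    """Fit a batch of time courses into a tidy fit table.

    ``region_class`` maps region_id to a role label; classes containing "TS",
    "NTS" or "TCR" (other than "nonTCR") use ``theta_min_tcr``, everything
    else ``theta_min_other``.  Unfittable regions yield a row of NaNs with
    ``fitted = False`` instead of raising, so batch runs never abort.
    """
    rows = []
    region_class = region_class or {}
    for tc in courses:
        cls = region_class.get(tc.region_id, "")
        transcribed = ("TS" in cls or "TCR" in cls) and "non" not in cls.lower()
        theta_min = theta_min_tcr if transcribed else theta_min_other
        row = {"region_id": tc.region_id, "class": cls}
        try:
            p = fit(tc, theta_min=theta_min, theta_step=theta_step)
        except UnfittableRegionError:
            row.update(
                m=np.nan, tau=np.nan, beta=np.nan, theta=np.nan,
                adj_r2=np.nan, n_points_used=0, degenerate=False,
                passes_filter=False, fitted=False,
            )
        else:
            row.update(
                m=p.m, tau=p.tau, beta=p.beta, theta=p.theta,
                adj_r2=p.adj_r2, n_points_used=p.n_points_used,
                degenerate=p.degenerate,
                passes_filter=filter_params(p, m_range, tau_range),
                fitted=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
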