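"""Gompertz growth machinery for the melanoma.

The tumor is modelled as a flat disk of identical cells, so cell count and
caliper diameter interconvert through the mean cancer-cell diameter
(default 20 µm): ``count = (diameter / cell_diameter)**2``.

Growth follows the two-parameter Gompertz law in differential form

    dx/dt = x * (a - b * ln x),

whose carrying capacity is K = exp(a/b) and whose closed-form solution is
``x(t) = K * exp(ln(x0 / K) * exp(-b t))``.  The engine advances the law by
forward Euler, one 8-hour step at a time, and introduces the integer newborn
count w = x_{t+1} - x_t into the lattice (fractional parts carried in a
residual so no growth is lost to rounding).

Because no caliper data set is deposited, a synthetic fixture generator
emulates noisy diameter measurements of a Gompertz-growing tumor; the fitting
routine recovers (a, b) from such series by least squares on the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "GompertzParams",
    "GrowthMeasurement",
    "TumorState",
    "cells_from_diameter",
    "area_from_cells",
    "gompertz_closed_form",
    "fit_gompertz",
    "euler_newborns",
    "seed_initial_tumor",
    "generate_growth_fixture",
]

#: default mean melanoma cell diameter, µm
DEFAULT_CELL_DIAMETER_UM = 20.0


@dataclass(frozen=True)
class GompertzParams:
    """Growth-law unknowns, in per-timestep units."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"deceleration constant b must be >= 0; got {self.b}")

    @property
    def carrying_capacity(self) -> float:
        """K = exp(a/b); infinite in the pure-exponential limit b = 0."""
        if self.b == 0:
            return math.inf
        return math.exp(self.a / self.b)


@dataclass(frozen=True)
class GrowthMeasurement:
    """One caliper reading: mean of two perpendicular diameters, in mm."""

    time: float  # days post-injection
    diameter: float  # mm

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("diameter must be >= 0")


@dataclass
class TumorState:
    """Running cancer-cell count with fractional newborn carry-over."""

    x_t: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.x_t < 0:
            raise ValueError("cell count must be >= 0")


def cells_from_diameter(diameter_mm: float, cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM) -> int:
    """Cancer-cell count of a disk-shaped tumor of the given caliper diameter."""
    if cell_diameter_um <= 0:
        raise ValueError("cell_diameter must be > 0")
    if diameter_mm < 0:
        raise ValueError("diameter must be >= 0")
    return round((diameter_mm * 1000.0 / cell_diameter_um) ** 2)


def area_from_cells(x: float, cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM) -> float:
    """Tumor area in mm^2 occupied by ``x`` cells in the disk model."""
    if x < 0:
        raise ValueError("cell count must be >= 0")
    cd_mm = cell_diameter_um / 1000.0
    return float(x) * cd_mm * cd_mm


def gompertz_closed_form(t: np.ndarray | float, x0: float, a: float, b: float) -> np.ndarray | float:
    """Exact Gompertz trajectory x(t) from x(0) = x0, t in timesteps."""
    if b == 0:
        return x0 * np.exp(a * np.asarray(t, dtype=float))
    K = math.exp(a / b)
    return K * np.exp(math.log(x0 / K) * np.exp(-b * np.asarray(t, dtype=float)))


def fit_gompertz(
    series: Sequence[GrowthMeasurement],
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM,
    steps_per_day: float = 3.0,
    x0: float | None = None,
) -> Tuple[GompertzParams, float]:
    """Least-squares Gompertz fit to a caliper series.

    Diameters are converted to cell counts through the disk model and the
    closed-form log trajectory ``ln x(t) = ln K + (ln x0 - ln K) e^{-b t}``
    is fitted in log space (multiplicative measurement noise).  When the
    engrafted inoculum ``x0`` is known it anchors the curve at injection
    (t = 0), which substantially sharpens the (a, b) estimates; otherwise
    the first measurement anchors it.

    Because ln K enters linearly for fixed b, the fit is a profile least
    squares: a closed-form ln K inside a bounded one-dimensional search over
    b, which has no dependence on optimizer initialisation.

    Returns (a, b) in per-timestep units plus the log-space residual norm.

    Raises
    ------
    ValueError
        for degenerate series (< 3 points, non-increasing times, or fewer
        than two distinct positive counts).
    """
    if len(series) < 3:
        raise ValueError("Gompertz fit needs at least 3 measurements")
    times = np.array([m.time for m in series], dtype=float) * steps_per_day
    if not np.all(np.diff(times) > 0):
        raise ValueError("measurement times must be strictly increasing")
    counts = np.array(
        [cells_from_diameter(m.diameter, cell_diameter_um) for m in series], dtype=float
    )
    if np.any(counts <= 0):
        raise ValueError("all measurements must convert to positive cell counts")
    if len(np.unique(counts)) < 2:
        raise ValueError("degenerate series: all counts equal")

    if x0 is not None:
        t = times
        lx0 = math.log(float(x0))
        logy = np.log(counts)
    else:
        t = times - times[0]
        lx0 = float(np.log(counts[0]))
        logy = np.log(counts)

    def profile(b: float) -> Tuple[float, float]:
        """Closed-form ln K and SSE for a fixed deceleration constant."""
        decay = np.exp(-b * t)
        basis = 1.0 - decay
        resp = logy - lx0 * decay
        denom = float(basis @ basis)
        if denom < 1e-12:
            return lx0, float(((logy - lx0 - 1e-12) ** 2).sum())
        lk = float(basis @ resp) / denom
        r = resp - lk * basis
        return lk, float(r @ r)

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda b: profile(b)[1], bounds=(1e-5, 1.0), method="bounded")
    b_hat = float(res.x)
    lk, sse = profile(b_hat)
    # pure-exponential comparison (b -> 0 degenerate limit)
    A = np.vstack([t, np.ones_like(t)]).T if x0 is None else t[:, None]
    y_lin = logy - lx0
    coef, *_ = np.linalg.lstsq(A, y_lin, rcond=None)
    sse_lin = float(((y_lin - A @ coef) ** 2).sum())
    if sse_lin < sse:
        return GompertzParams(a=float(coef[0]), b=0.0), math.sqrt(sse_lin)
    return GompertzParams(a=b_hat * lk, b=b_hat), math.sqrt(sse)


def euler_newborns(state: TumorState, params: GompertzParams, dt: float = 1.0) -> int:
    """Expected newborn cancer cells over one forward-Euler step.

    Advances ``x_{t+1} = x_t + dt * x_t * (a - b ln x_t)`` and returns the
    integer newborn count w = x_{t+1} - x_t, carrying the fractional part in
    ``state.residual``.  At or above carrying capacity the update would be
    non-positive and w is clamped to 0 (the tumor does not shrink by growth;
    immune killing is handled elsewhere).  An extinct tumor stays extinct.
    """
    if state.x_t <= 0:
        return 0
    x = state.x_t
    w = dt * x * (params.a - params.b * math.log(x))
    if w <= 0:
        return 0
    w += state.residual
    n = int(w)
    state.residual = w - n
    state.x_t = x + n
    return n


def seed_initial_tumor(injected: int, death_fraction: float) -> int:
    """Engrafted cell count x0 after early post-injection death."""
    if not (0.0 <= death_fraction <= 1.0):
        raise ValueError("death_fraction must lie in [0, 1]")
    if injected < 0:
        raise ValueError("injected count must be >= 0")
    return round(injected * (1.0 - death_fraction))


def generate_growth_fixture(
    params: GompertzParams,
    x0: float,
    times_days: Sequence[float],
    noise_cv: float,
    rng: np.random.Generator,
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM,
    steps_per_day: float = 3.0,
) -> List[GrowthMeasurement]:
    """Synthetic caliper series of a Gompertz-growing disk tumor.

    Stands in for the undeposited in vivo measurements.  Exact closed-form
    cell counts are converted to diameters, and each recorded value emulates
    the measurement protocol — the mean of two perpendicular caliper
    readings, each carrying independent lognormal noise with per-reading
    coefficient of variation ``noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    out: List[GrowthMeasurement] = []
    cd_mm = cell_diameter_um / 1000.0
    for day in times_days:
        x = float(gompertz_closed_form(day * steps_per_day, x0, params.a, params.b))
        d = math.sqrt(x) * cd_mm
        if noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + noise_cv**2))
            readings = d * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=2)
            d = float(readings.mean())
        out.append(GrowthMeasurement(time=float(day), diameter=d))
    return out
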