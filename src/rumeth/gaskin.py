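"""In vitro gas-kinetics processing.

Raw bottle recordings — cumulative gas volumes on a 0.2 h grid plus sparse
headspace CH4 concentration samples — are normalized to standard pressure,
blank corrected, converted to per-interval CH4 production and fitted with a
two-pool Gompertz model

    V(t) = A1 * exp(-b1 * exp(-k1 * t)) + A2 * exp(-b2 * exp(-k2 * t))

with the convention that pool 1 is the faster pool (k1 >= k2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    GridMismatchError,
    InvalidGridError,
    InvalidParameterError,
    UnderdeterminedFitError,
)

logger = logging.getLogger(__name__)

#: Normal air pressure used to standardize recorded gas volumes (kPa).
STANDARD_PRESSURE_KPA = 101.3

#: Default headspace volume of a 250 mL serum bottle with 60 mL liquid phase.
DEFAULT_HEADSPACE_ML = 190.0

#: Default headspace sampling times (h).
PROTOCOL_SAMPLE_TIMES = (2.0, 4.0, 8.0, 24.0, 32.0, 48.0)

_GRID_TOL = 1e-9


def time_grid(horizon: float = 48.0, step: float = 0.2) -> np.ndarray:
    """Recording grid ``step, 2*step, ..., horizon``.

    Raises :class:`InvalidGridError` if the horizon is not a positive
    multiple of the step.
    """
    if step <= 0 or horizon <= 0:
        raise InvalidGridError(f"horizon and step must be positive, got {horizon}, {step}")
    n = horizon / step
    if abs(n - round(n)) > 1e-9:
        raise InvalidGridError(f"horizon {horizon} h is not a multiple of the {step} h step")
    return np.round(np.arange(1, int(round(n)) + 1) * step, 10)


def _validate_grid(t: np.ndarray) -> None:
    if t.ndim != 1 or t.size < 2:
        raise InvalidGridError("time grid needs at least two points")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise InvalidGridError("time grid must be strictly increasing")
    if np.ptp(steps) > 1e-6:
        raise InvalidGridError("time grid must have a constant step")


@dataclass
class GasCurve:
    """Cumulative gas volume (mL at standard pressure) for one bottle."""

    bottle_id: str
    time: np.ndarray
    volume: np.ndarray
    sample_mass: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.time.shape != self.volume.shape:
            raise InvalidParameterError("time and volume must have equal length")
        _validate_grid(self.time)
        if self.sample_mass <= 0:
            raise InvalidParameterError("sample_mass must be positive")

    @property
    def step(self) -> float:
        return float(self.time[1] - self.time[0])

    def increments(self) -> np.ndarray:
        """Per-interval gas production; the first interval starts at V(0)=0."""
        return np.diff(self.volume, prepend=0.0)


@dataclass
class HeadspaceSeries:
    """Headspace CH4 fractions (0-1) sampled at a few incubation times."""

    bottle_id: str
    time: np.ndarray
    ch4_fraction: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.ch4_fraction = np.asarray(self.ch4_fraction, dtype=float)
        if self.time.shape != self.ch4_fraction.shape:
            raise InvalidParameterError("time and ch4_fraction must have equal length")
        if np.any(self.time <= 0):
            raise InvalidParameterError("sample times must be positive")
        if np.any(self.ch4_fraction < 0) or np.any(self.ch4_fraction > 1):
            raise InvalidParameterError("CH4 fractions must lie in [0, 1]")


@dataclass
class LogConcModel:
    """CH4 fraction as ``a + b*ln(t)``, clipped to [0, 1] on evaluation."""

    a: float
    b: float

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise InvalidParameterError("log-time model is undefined at t <= 0")
        return np.clip(self.a + self.b * np.log(t), 0.0, 1.0)


@dataclass
class CH4Curve:
    """Estimated CH4 production per 0.2 h interval, expressed per g DM."""

    bottle_id: str
    time: np.ndarray
    interval: np.ndarray
    cumulative: np.ndarray
    meta: dict = field(default_factory=dict)


def two_pool_gompertz(t, a1, b1, k1, a2, b2, k2) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return a1 * np.exp(-b1 * np.exp(-k1 * t)) + a2 * np.exp(-b2 * np.exp(-k2 * t))


def two_pool_gompertz_rate(t, a1, b1, k1, a2, b2, k2) -> np.ndarray:
    """dV/dt of the two-pool Gompertz."""
    t = np.asarray(t, dtype=float)
    r1 = a1 * b1 * k1 * np.exp(-k1 * t) * np.exp(-b1 * np.exp(-k1 * t))
    r2 = a2 * b2 * k2 * np.exp(-k2 * t) * np.exp(-b2 * np.exp(-k2 * t))
    return r1 + r2


@dataclass
class GompertzFit:
    """Two-pool Gompertz parameters; pool 1 is the faster pool (k1 >= k2)."""

    a1: float
    b1: float
    k1: float
    a2: float
    b2: float
    k2: float
    rss: float = np.nan
    converged: bool = True
    n_obs: int = 0

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0:
            raise InvalidParameterError("pool asymptotes must be nonnegative")
        if self.b1 <= 0 or self.b2 <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise InvalidParameterError("shape and rate parameters must be positive")
        if self.k1 < self.k2:
            raise InvalidParameterError("pool 1 must be the faster pool (k1 >= k2)")

    @property
    def params(self) -> tuple:
        return (self.a1, self.b1, self.k1, self.a2, self.b2, self.k2)

    @property
    def asymptote(self) -> float:
        return self.a1 + self.a2

    def evaluate(self, t) -> np.ndarray:
        return two_pool_gompertz(t, *self.params)

    def rate(self, t) -> np.ndarray:
        return two_pool_gompertz_rate(t, *self.params)


def normalize_pressure(volume_ml, pressure_kpa: float) -> np.ndarray:
    """Scale a recorded volume to standard pressure (101.3 kPa)."""
    if pressure_kpa <= 0:
        raise InvalidParameterError(f"pressure must be positive, got {pressure_kpa}")
    return np.asarray(volume_ml, dtype=float) * pressure_kpa / STANDARD_PRESSURE_KPA


def blank_correct_gas(sample: GasCurve, blanks) -> GasCurve:
    """Subtract the pointwise mean of blank bottles from a sample curve.

    The net curve is kept nondecreasing by flooring each value at the running
    maximum of the preceding values (negatives at the start floor at 0);
    adjustments are logged.
    """
    blanks = list(blanks)
    if not blanks:
        raise InvalidParameterError("at least one blank curve required")
    for blank in blanks:
        if blank.time.shape != sample.time.shape or np.max(np.abs(blank.time - sample.time)) > 1e-9:
            raise GridMismatchError(
                f"blank {blank.bottle_id} grid does not match sample {sample.bottle_id}"
            )
    blank_mean = np.mean([b.volume for b in blanks], axis=0)
    net = sample.volume - blank_mean
    cleaned = np.maximum.accumulate(np.maximum(net, 0.0))
    n_adjusted = int(np.sum(cleaned - net > _GRID_TOL))
    if n_adjusted:
        logger.warning(
            "blank correction of %s floored %d point(s) to keep monotonicity",
            sample.bottle_id, n_adjusted,
        )
    meta = dict(sample.meta)
    meta["blank_corrected"] = True
    return GasCurve(sample.bottle_id, sample.time.copy(), cleaned,
                    sample_mass=sample.sample_mass, meta=meta)


def fit_log_conc(series: HeadspaceSeries) -> LogConcModel:
    """Least-squares fit of CH4 fraction on ln(incubation time)."""
    t = series.time
    if np.unique(t).size < 2:
        raise UnderdeterminedFitError(
            f"bottle {series.bottle_id}: need >=2 distinct sample times"
        )
    design = np.column_stack([np.ones_like(t), np.log(t)])
    coef, *_ = np.linalg.lstsq(design, series.ch4_fraction, rcond=None)
    return LogConcModel(a=float(coef[0]), b=float(coef[1]))


def estimate_ch4_curve(net_gas: GasCurve, conc: LogConcModel,
                       headspace_volume: float = DEFAULT_HEADSPACE_ML) -> CH4Curve:
    """Per-interval CH4 from net gas increments and the concentration model.

    For interval (t-step, t]:

        ch4 = dG(t) * c(t) + V_hs * (c(t) - c(t - step))

    where c is the evaluated (clipped) concentration. The concentration model
    cannot be evaluated at t=0, so the first interval carries no headspace
    term. Negative interval values are floored at 0 and logged. The result is
    expressed per g DM of the incubated sample.
    """
    if headspace_volume <= 0:
        raise InvalidParameterError("headspace volume must be positive")
    c = conc.evaluate(net_gas.time)
    dg = net_gas.increments()
    dc = np.diff(c, prepend=c[0])  # first interval: no headspace change
    interval = dg * c + headspace_volume * dc
    n_neg = int(np.sum(interval < -_GRID_TOL))
    if n_neg:
        logger.warning("bottle %s: floored %d negative CH4 interval(s) at 0",
                       net_gas.bottle_id, n_neg)
    interval = np.maximum(interval, 0.0) / net_gas.sample_mass
    meta = dict(net_gas.meta)
    return CH4Curve(net_gas.bottle_id, net_gas.time.copy(), interval,
                    np.cumsum(interval), meta=meta)


def _starts(t: np.ndarray, y: np.ndarray):
    """Multi-start heuristics: asymptote split 60/40 of the observed maximum,
    rate pairs spanning the plausible magnitudes, shape b = e (inflection
    near t = 1/k)."""
    vmax = max(float(np.max(y)), 1e-6)
    e = np.e
    for split in ((0.6, 0.4), (0.4, 0.6)):
        for k_pair in ((0.10, 0.03), (0.05, 0.02), (0.20, 0.05)):
            yield np.array([vmax * split[0], e, k_pair[0], vmax * split[1], e, k_pair[1]])


def fit_two_pool_gompertz(time, volume, max_nfev: int = 3000) -> GompertzFit:
    """Bounded nonlinear least squares of the two-pool Gompertz model.

    Accepts the cumulative curve as arrays. Runs every documented start and
    keeps the best solution; if no start converges the best-of-starts is
    returned with ``converged=False`` and a warning (a total failure raises
    :class:`FitFailureError`). If the two pools collapse onto the same
    kinetics (k and b equal to within 0.1% relative) they are merged into
    pool 1, which keeps the degenerate single-pool case identifiable.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(volume, dtype=float)
    if t.size != y.size:
        raise InvalidParameterError("time and volume must have equal length")
    if t.size < 6:
        raise UnderdeterminedFitError("need >=6 points to fit six parameters")
    if np.any(y < -_GRID_TOL):
        raise InvalidParameterError("cumulative curve must be nonnegative")

    lower = np.array([0.0, 1e-6, 1e-6, 0.0, 1e-6, 1e-6])
    upper = np.array([np.inf, 60.0, 5.0, np.inf, 60.0, 5.0])

    def residuals(p):
        return two_pool_gompertz(t, *p) - y

    best = None
    failures = []
    for x0 in _starts(t, y):
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper), method="trf",
                                ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("all Gompertz starts diverged",
                              diagnostics={"failures": failures})
    if not best.success:
        logger.warning("Gompertz fit did not report convergence; best-of-starts kept")

    a1, b1, k1, a2, b2, k2 = best.x
    # merge pools that collapsed onto identical kinetics
    if (abs(k1 - k2) <= 1e-3 * max(k1, k2)) and (abs(b1 - b2) <= 1e-3 * max(b1, b2)):
        a1, a2 = a1 + a2, 0.0
        b2 = b1
        k2 = min(k1, k2) * 0.5  # keep ordering valid; pool 2 is empty
        k1 = max(k1, k2)
    if k1 < k2:  # pool 1 is the faster pool
        a1, b1, k1, a2, b2, k2 = a2, b2, k2, a1, b1, k1
    return GompertzFit(a1=float(a1), b1=float(b1), k1=float(k1),
                       a2=float(a2), b2=float(b2), k2=float(k2),
                       rss=float(2 * best.cost), converged=bool(best.success),
                       n_obs=int(t.size))


def curve_summaries(fit: GompertzFit, at: float = 48.0) -> dict:
    """Asymptote, predicted value at ``at`` hours, and the pool-size-weighted
    composite fractional rate (A1*k1 + A2*k2) / (A1 + A2)."""
    total = fit.asymptote
    rate = (fit.a1 * fit.k1 + fit.a2 * fit.k2) / total if total > 0 else np.nan
    return {
        "asymptote": total,
        "value_at": float(fit.evaluate(at)),
        "at": at,
        "rate": rate,
    }


def ch4_to_gas_ratio(ch4_summary: dict, gas_summary: dict) -> float:
    """CH4:total-gas ratio at the shared summary time (typically 48 h)."""
    if gas_summary["value_at"] <= 0:
        raise InvalidParameterError("gas value at the summary time must be positive")
    return ch4_summary["value_at"] / gas_summary["value_at"]
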