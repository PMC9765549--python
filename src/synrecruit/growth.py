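"""Growth-rate estimation and cardinal-temperature model fitting.

A culture sampled through its exponential phase grows as dN/dt = mu * N, so
mu (day^-1) is the slope of an ordinary least-squares fit of ln N on time
over the exponential window.  The rate-versus-temperature response of each
strain is then summarised with the Cardinal Temperature Model with
Inflection (CTMI), a four-parameter curve

    mu_max(T) = 0                      for T <= Tmin or T >= Tmax
    mu_max(T) = mu_opt * phi(T)        for Tmin < T < Tmax

    phi(T) = (T - Tmax)(T - Tmin)^2 /
             ((Topt - Tmin) * ((Topt - Tmin)(T - Topt)
                               - (Topt - Tmax)(Topt + Tmin - 2T)))

where Tmin and Tmax are the minimal and maximal growth temperatures and Topt
the optimum at which mu_max = mu_opt.  phi(Topt) = 1 identically.  Fitting
minimises the residual sum of squares with bounded least squares from a
Latin-hypercube of starting points; confidence intervals come from a
nonparametric bootstrap over replicate rate measurements within temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .errors import (
    FitError,
    InsufficientDataError,
    UnfittableError,
    ValidationError,
)

logger = logging.getLogger(__name__)

TMIN_SEARCH_FLOOR = -20.0  # deg C; lower bound of the Tmin search range
MIN_CARDINAL_GAP = 0.5     # deg C; minimal Tmin<Topt<Tmax separation in fits


@dataclass
class GrowthCurve:
    """Cell-density time series of one culture replicate at one temperature."""

    strain: str
    temperature: float
    replicate: int
    times: np.ndarray       # days
    densities: np.ndarray   # cells / mL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.shape != self.densities.shape:
            raise ValidationError("times and densities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"{self.strain} @ {self.temperature}C rep {self.replicate}: "
                "sampling times must be strictly increasing"
            )
        if np.any(self.densities <= 0):
            raise ValidationError(
                f"{self.strain} @ {self.temperature}C rep {self.replicate}: "
                "cell densities must be positive"
            )


@dataclass(frozen=True)
class RateMeasurement:
    strain: str
    temperature: float
    mu: float               # day^-1, clamped at 0 for non-growing cultures
    stderr: float
    n_points: int
    window: tuple[float, float]
    clamped: bool = False


@dataclass
class CardinalParams:
    """CTMI parameters: cardinal temperatures (deg C) and optimal rate."""

    t_min: float
    t_opt: float
    t_max: float
    mu_opt: float
    rss: float = np.nan

    def validate(self) -> "CardinalParams":
        if not self.t_min < self.t_opt < self.t_max:
            raise ValidationError(
                f"cardinal temperatures must satisfy Tmin < Topt < Tmax, got "
                f"({self.t_min}, {self.t_opt}, {self.t_max})"
            )
        if self.mu_opt < 0:
            raise ValidationError("mu_opt must be non-negative")
        return self


# ---------------------------------------------------------------------------
# Exponential-phase rate estimation
# ---------------------------------------------------------------------------


def _window_candidates(n: int, min_points: int) -> Iterable[tuple[int, int]]:
    for start in range(n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            yield start, stop


def fit_exponential_rate(
    curve: GrowthCurve,
    window: Optional[tuple[float, float]] = None,
) -> RateMeasurement:
    """Estimate mu as the OLS slope of ln N(t) over the exponential window.

    With an explicit ``window=(t_start, t_end)`` the fit uses the samples
    inside it (inclusive).  Otherwise the window is chosen automatically:
    among contiguous windows of at least 4 points (at least 3 when the curve
    has only 3), the one with positive slope maximising R^2, ties going to
    the longest then earliest window.  A non-growing culture (no window with
    positive slope) is recorded as mu = 0.
    """
    t, logn = curve.times, np.log(curve.densities)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 3:
            raise InsufficientDataError(
                f"window {window} contains {int(mask.sum())} points; need >= 3"
            )
        res = stats.linregress(t[mask], logn[mask])
        mu, clamped = (res.slope, False) if res.slope > 0 else (0.0, True)
        if clamped:
            logger.info(
                "%s @ %.1fC rep %d: non-positive slope clamped to 0",
                curve.strain, curve.temperature, curve.replicate,
            )
        return RateMeasurement(
            curve.strain, curve.temperature, mu, res.stderr,
            int(mask.sum()), (float(t[mask][0]), float(t[mask][-1])), clamped,
        )

    n = len(t)
    if n < 3:
        raise InsufficientDataError(f"curve has {n} points; need >= 3")
    min_points = 4 if n >= 4 else 3
    best = None  # (r2, length, -start, result, (start, stop))
    for start, stop in _window_candidates(n, min_points):
        res = stats.linregress(t[start:stop], logn[start:stop])
        if res.slope <= 0:
            continue
        key = (res.rvalue**2, stop - start, -start)
        if best is None or key > best[0]:
            best = (key, res, (start, stop))
    if best is None:
        # flat or declining culture: report zero growth over the whole series
        res = stats.linregress(t, logn)
        logger.info(
            "%s @ %.1fC rep %d: no growing window, mu clamped to 0",
            curve.strain, curve.temperature, curve.replicate,
        )
        return RateMeasurement(
            curve.strain, curve.temperature, 0.0, res.stderr, n,
            (float(t[0]), float(t[-1])), True,
        )
    _, res, (start, stop) = best
    return RateMeasurement(
        curve.strain, curve.temperature, float(res.slope), float(res.stderr),
        stop - start, (float(t[start]), float(t[stop - 1])), False,
    )


# ---------------------------------------------------------------------------
# CTMI model
# ---------------------------------------------------------------------------


def ctmi_phi(T, t_min: float, t_opt: float, t_max: float):
    """Shape factor phi(T); equals 1 at T = Topt."""
    T = np.asarray(T, dtype=float)
    num = (T - t_max) * (T - t_min) ** 2
    den = (t_opt - t_min) * (
        (t_opt - t_min) * (T - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2.0 * T)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, 0.0)


def ctmi_mu(T, params: CardinalParams):
    """Piecewise CTMI growth rate; zero at and outside the cardinal bounds."""
    params.validate()
    T = np.asarray(T, dtype=float)
    phi = ctmi_phi(T, params.t_min, params.t_opt, params.t_max)
    mu = params.mu_opt * phi
    mu = np.where((T <= params.t_min) | (T >= params.t_max), 0.0, mu)
    out = np.maximum(mu, 0.0)
    return float(out) if out.ndim == 0 else out


def _prepare_rates(
    rates: Sequence[RateMeasurement], average_replicates: bool
) -> tuple[np.ndarray, np.ndarray]:
    temps = np.array([r.temperature for r in rates], dtype=float)
    mus = np.array([r.mu for r in rates], dtype=float)
    if average_replicates:
        uniq = np.unique(temps)
        mus = np.array([mus[temps == u].mean() for u in uniq])
        temps = uniq
    order = np.argsort(temps, kind="stable")
    return temps[order], mus[order]


def _fit_once(
    temps: np.ndarray, mus: np.ndarray, x0: np.ndarray, bounds
) -> Optional[tuple[CardinalParams, float]]:
    def residuals(x):
        t_min, d_opt, d_max, mu_opt = x
        p = CardinalParams(t_min, t_min + d_opt, t_min + d_opt + d_max, mu_opt)
        return ctmi_mu(temps, p) - mus

    try:
        sol = optimize.least_squares(
            residuals, x0, bounds=bounds, method="trf", xtol=1e-10, ftol=1e-12
        )
    except Exception:  # pragma: no cover - solver pathologies
        return None
    if not sol.success and not np.isfinite(sol.cost):
        return None
    t_min, d_opt, d_max, mu_opt = sol.x
    params = CardinalParams(
        float(t_min),
        float(t_min + d_opt),
        float(t_min + d_opt + d_max),
        float(mu_opt),
        rss=float(2.0 * sol.cost),
    )
    return params, params.rss


def fit_ctmi(
    rates: Sequence[RateMeasurement],
    n_starts: int = 20,
    seed: int = 0,
    average_replicates: bool = True,
) -> CardinalParams:
    """Least-squares CTMI fit to one strain's rate-vs-temperature data.

    The model is parameterised as (Tmin, Topt-Tmin, Tmax-Topt, mu_opt) so the
    ordering constraint Tmin < Topt < Tmax becomes simple positivity bounds.
    ``n_starts`` starting points are drawn from a Latin hypercube spanning
    Tmin in [-20, min T], Topt across the observed range, Tmax up to
    max T + 10, and mu_opt up to twice the maximal observed rate; the start
    reaching the lowest residual sum of squares wins (ties: first start).
    Replicate measurements at one temperature are averaged before fitting by
    default.
    """
    if len({r.strain for r in rates}) > 1:
        raise ValidationError("fit_ctmi expects rates from a single strain")
    temps, mus = _prepare_rates(rates, average_replicates)
    if len(temps) < 5:
        raise InsufficientDataError(
            f"need rates at >= 5 distinct temperatures, got {len(temps)}"
        )
    if not np.any(mus > 0):
        raise UnfittableError("all growth rates are zero; CTMI cannot be fitted")

    t_lo, t_hi = float(temps.min()), float(temps.max())
    mu_hi = float(mus.max())
    span = t_hi - t_lo + 10.0
    # x = (t_min, d_opt = Topt - Tmin, d_max = Tmax - Topt, mu_opt)
    lower = np.array([TMIN_SEARCH_FLOOR, MIN_CARDINAL_GAP, MIN_CARDINAL_GAP, 1e-9])
    upper = np.array([t_lo, t_hi - TMIN_SEARCH_FLOOR, span, 2.0 * mu_hi])
    bounds = (lower, upper)

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    unit = sampler.random(n_starts)
    # sample in interpretable coordinates, then convert to the delta space
    t_min0 = TMIN_SEARCH_FLOOR + unit[:, 0] * (t_lo - TMIN_SEARCH_FLOOR)
    t_opt0 = t_lo + unit[:, 1] * (t_hi - t_lo)
    t_max0 = t_opt0 + MIN_CARDINAL_GAP + unit[:, 2] * (t_hi + 10.0 - t_opt0)
    mu0 = 1e-6 + unit[:, 3] * (2.0 * mu_hi - 1e-6)

    best: Optional[tuple[CardinalParams, float]] = None
    for s in range(n_starts):
        x0 = np.array(
            [
                t_min0[s],
                max(t_opt0[s] - t_min0[s], MIN_CARDINAL_GAP),
                max(t_max0[s] - t_opt0[s], MIN_CARDINAL_GAP),
                mu0[s],
            ]
        )
        x0 = np.clip(x0, lower, upper)
        result = _fit_once(temps, mus, x0, bounds)
        if result is None:
            continue
        if best is None or result[1] < best[1] - 1e-15:
            best = result
    if best is None:
        raise FitError(
            f"CTMI optimization failed from all {n_starts} starting points"
        )
    return best[0]


def ctmi_confidence_intervals(
    rates: Sequence[RateMeasurement],
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    average_replicates: bool = True,
    fit: Optional[CardinalParams] = None,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap confidence intervals for Topt, Tmax and mu_opt.

    Replicate measurements are resampled with replacement within each
    temperature.  Because per-temperature replicate counts are small (three
    in a typical acclimation experiment), the deviation of each resampled
    mean from the observed mean is inflated by sqrt(n/(n-1)) — without this
    the bootstrap variance of a mean of n replicates is shrunk by a factor
    (n-1)/n, and the intervals undercover.  Each resample is refitted
    starting from the full-data estimate.  If more than half of the refits
    fail, a warning is logged and an empty dict returned (CI unavailable).
    """
    if n_bootstrap < 1:
        raise ValidationError("n_bootstrap must be >= 1")
    point = fit if fit is not None else fit_ctmi(
        rates, seed=seed, average_replicates=average_replicates
    )
    rng = np.random.default_rng(seed)
    by_temp: dict[float, list[float]] = {}
    for r in rates:
        by_temp.setdefault(r.temperature, []).append(r.mu)
    temps = np.array(sorted(by_temp), dtype=float)
    groups = [np.asarray(by_temp[t], dtype=float) for t in temps]
    means = np.array([g.mean() for g in groups])
    inflate = np.array(
        [np.sqrt(len(g) / (len(g) - 1)) if len(g) > 1 else 1.0 for g in groups]
    )

    x0 = np.array(
        [
            point.t_min,
            point.t_opt - point.t_min,
            point.t_max - point.t_opt,
            point.mu_opt,
        ]
    )
    t_lo, t_hi = float(temps.min()), float(temps.max())
    lower = np.array([TMIN_SEARCH_FLOOR, MIN_CARDINAL_GAP, MIN_CARDINAL_GAP, 1e-9])
    samples: list[tuple[float, float, float]] = []
    failures = 0
    for _ in range(n_bootstrap):
        mus = np.empty(len(groups))
        for gi, (g, m, c) in enumerate(zip(groups, means, inflate)):
            resampled_mean = g[rng.integers(0, len(g), size=len(g))].mean()
            mus[gi] = max(m + c * (resampled_mean - m), 0.0)
        if not np.any(mus > 0):
            failures += 1
            continue
        upper = np.array(
            [
                t_lo,
                t_hi - TMIN_SEARCH_FLOOR,
                t_hi - t_lo + 10.0,
                2.0 * max(float(mus.max()), point.mu_opt),
            ]
        )
        start = np.clip(x0, lower, upper)
        result = _fit_once(temps, mus, start, (lower, upper))
        if result is None:
            failures += 1
            continue
        p = result[0]
        samples.append((p.t_opt, p.t_max, p.mu_opt))
    if failures > 0.5 * n_bootstrap or not samples:
        logger.warning(
            "bootstrap CI unavailable: %d of %d refits failed", failures, n_bootstrap
        )
        return {}
    arr = np.array(samples)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        name: (float(np.percentile(arr[:, i], lo)), float(np.percentile(arr[:, i], hi)))
        for i, name in enumerate(("t_opt", "t_max", "mu_opt"))
    }


@dataclass
class StrainFitReport:
    """Per-strain summary combining observed and model thermal optima."""

    strain: str
    t_opt_measured: float   # temperature of the highest observed mean rate
    t_max_measured: float   # highest temperature with a positive mean rate
    params: CardinalParams
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def fit_strain(
    rates: Sequence[RateMeasurement],
    n_bootstrap: int = 1000,
    seed: int = 0,
    average_replicates: bool = True,
) -> StrainFitReport:
    """Full per-strain workflow: CTMI fit plus bootstrap intervals."""
    strain = rates[0].strain
    temps, mus = _prepare_rates(rates, average_replicates=True)
    t_opt_measured = float(temps[np.argmax(mus)])
    growing = temps[mus > 0]
    t_max_measured = float(growing.max()) if growing.size else np.nan
    params = fit_ctmi(
        rates, seed=seed, average_replicates=average_replicates
    )
    ci = (
        ctmi_confidence_intervals(
            rates,
            n_bootstrap=n_bootstrap,
            seed=seed,
            average_replicates=average_replicates,
            fit=params,
        )
        if n_bootstrap > 0
        else {}
    )
    return StrainFitReport(strain, t_opt_measured, t_max_measured, params, ci)
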