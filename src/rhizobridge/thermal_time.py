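"""Thermal-time phenology: chilling/forcing units, growing degree days, and T50.

Daily temperature records are converted into unitless thermal-time increments
(chilling units for cold exposure, forcing units for warm exposure, growing
degree days for overall heat accumulation) and summed from a stated start
date. Rooting phenology of cutting cohorts is summarized by T50 — the
estimated number of days until half the cohort shows its first adventitious
root — obtained from a two-parameter log-logistic fit to the cumulative
fraction rooted, and T50 is related to cumulative thermal time by ordinary
least squares.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DailyWeatherRecord",
    "ThermalSeries",
    "RootingCohort",
    "T50Estimate",
    "RegressionSummary",
    "chilling_units",
    "forcing_units",
    "growing_degree_days",
    "accumulate_thermal",
    "estimate_t50",
    "regress_t50",
    "read_weather_csv",
    "read_rooting_csv",
]

# Chilling-unit piecewise coefficients (triangular response centred near 3.5 °C)
_CU_LO, _CU_PEAK, _CU_HI = -3.4, 3.5, 10.4
_CU_UP_SLOPE, _CU_UP_ICEPT = 0.159, 0.506
_CU_DN_SLOPE, _CU_DN_ICEPT = -0.159, 1.621

# Forcing-unit logistic coefficients
_FU_RATE, _FU_SHIFT = 0.47, 6.49


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One day of weather: mean, max and min air temperature in °C."""

    date: _dt.date
    t_mean: float
    t_max: float
    t_min: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_mean):
            raise ValueError(f"t_mean must be finite, got {self.t_mean}")
        if self.t_min > self.t_max:
            raise ValueError(
                f"t_min ({self.t_min}) exceeds t_max ({self.t_max}) on {self.date}"
            )


@dataclass
class ThermalSeries:
    """Ordered daily weather records with cumulative thermal-time columns."""

    records: list[DailyWeatherRecord]

    def __post_init__(self) -> None:
        dates = [r.date for r in self.records]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("dates must be strictly increasing")

    @property
    def dates(self) -> list[_dt.date]:
        return [r.date for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        if not df.empty:
            df["cu"] = chilling_units(df["t_mean"].to_numpy())
            df["fu"] = forcing_units(df["t_mean"].to_numpy())
            df["gdd"] = growing_degree_days(
                df["t_max"].to_numpy(), df["t_min"].to_numpy()
            )
        return df


@dataclass
class RootingCohort:
    """Per-cutting first-rooting day indices for one collection cohort.

    ``root_day`` holds a 1-based day index (from the collection date) for each
    cutting that rooted before observation ended; cuttings never seen to root
    are censored and appear only in ``n_cuttings``.
    """

    cohort_id: str
    collection_date: _dt.date
    n_cuttings: int
    root_day: list[int] = field(default_factory=list)
    max_day: int | None = None

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.root_day):
            raise ValueError("root_day indices are 1-based and must be >= 1")
        if self.n_cuttings < len(self.root_day):
            raise ValueError("n_cuttings smaller than number of recorded rooting days")

    @property
    def observation_end(self) -> int:
        if self.max_day is not None:
            return int(self.max_day)
        if not self.root_day:
            raise ValueError("cohort has no rooted cuttings and no max_day")
        return int(max(self.root_day))

    def cumulative_fraction(self) -> tuple[np.ndarray, np.ndarray]:
        """Days 1..observation_end and the fraction rooted by each day."""
        end = self.observation_end
        days = np.arange(1, end + 1)
        rooted = np.asarray(self.root_day)
        frac = np.array([(rooted <= d).sum() for d in days]) / self.n_cuttings
        return days, frac


@dataclass
class T50Estimate:
    cohort_id: str
    t50: float
    std_error: float
    slope: float
    converged: bool
    residual_scale: float

    def __post_init__(self) -> None:
        if self.converged and not self.t50 > 0:
            raise ValueError("converged T50 estimate must be positive")


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    mse: float
    p_value: float
    n: int


def chilling_units(t_mean):
    """Daily chilling units (unitless) from mean temperature.

    Triangular piecewise response: zero at or below −3.4 °C and above
    10.4 °C, rising linearly to a peak near 3.5 °C and falling back to zero
    at 10.4 °C. The printed line segments are used exactly, including the
    slightly negative values they take at the cold edge of the window.
    """
    t = np.asarray(t_mean, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t_mean must be finite")
    out = np.zeros_like(t)
    up = (t > _CU_LO) & (t <= _CU_PEAK)
    down = (t > _CU_PEAK) & (t <= _CU_HI)
    out[up] = _CU_UP_SLOPE * t[up] + _CU_UP_ICEPT
    out[down] = _CU_DN_SLOPE * t[down] + _CU_DN_ICEPT
    return out if out.ndim else float(out)


def forcing_units(t_mean):
    """Daily forcing units: logistic in mean temperature, bounded in (0, 1).

    FU = 1 / (1 + exp(−0.47·T + 6.49)); midpoint ≈ 13.81 °C.
    """
    t = np.asarray(t_mean, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t_mean must be finite")
    out = 1.0 / (1.0 + np.exp(-_FU_RATE * t + _FU_SHIFT))
    return out if out.ndim else float(out)


def growing_degree_days(t_max, t_min):
    """Daily growing degree days: mean of max and min, floored at zero."""
    hi = np.asarray(t_max, dtype=float)
    lo = np.asarray(t_min, dtype=float)
    if np.any(lo > hi):
        raise ValueError("t_min exceeds t_max")
    out = np.maximum((hi + lo) / 2.0, 0.0)
    return out if out.ndim else float(out)


_METRICS = {
    "CU": lambda r: chilling_units(r.t_mean),
    "FU": lambda r: forcing_units(r.t_mean),
    "GDD": lambda r: growing_degree_days(r.t_max, r.t_min),
}


def accumulate_thermal(
    series: ThermalSeries,
    start_date: _dt.date,
    metric: str,
    end_date: _dt.date | None = None,
) -> pd.Series:
    """Running sum of a daily thermal metric from ``start_date`` inclusive.

    Raises if the start date falls outside the series or if any calendar day
    in the accumulation window is missing: silent gaps would corrupt the
    cumulative sums, so they are a hard error rather than interpolated.
    """
    metric = metric.upper()
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected CU, FU or GDD")
    dates = series.dates
    if not dates:
        if end_date is not None or start_date is not None:
            raise ValueError("start_date outside empty series")
    if start_date not in dates:
        raise ValueError(f"start_date {start_date} not present in weather series")
    window = [
        r
        for r in series.records
        if r.date >= start_date and (end_date is None or r.date <= end_date)
    ]
    for prev, cur in zip(window, window[1:]):
        if (cur.date - prev.date).days != 1:
            raise ValueError(
                f"gap in weather series between {prev.date} and {cur.date}"
            )
    daily = [float(np.asarray(_METRICS[metric](r))) for r in window]
    return pd.Series(
        np.cumsum(daily), index=pd.Index([r.date for r in window], name="date"),
        name=f"c{metric}",
    )


def _ll2(t, slope, t50):
    """Two-parameter log-logistic CDF: F(t) = 1/(1 + exp(b·(ln t − ln e)))."""
    z = np.clip(slope * (np.log(t) - np.log(t50)), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def estimate_t50(cohort: RootingCohort) -> T50Estimate:
    """Fit a two-parameter log-logistic to cumulative rooting and return T50.

    The cumulative fraction rooted by day d is fit with
    F(t) = 1/(1 + exp(b·(ln t − ln e))) where e is the day at which the
    fitted fraction reaches one half (T50) and b < 0 controls steepness.
    Points are weighted by the binomial standard error at the cohort size,
    and the standard error of T50 comes from the fit covariance
    (delta method). Daily records are interval data — a rooting day index d
    covers continuous emergence times rounded to day d — so the cumulative
    fraction observed by day d is evaluated at the interval edge d + ½
    (without this continuity correction T50 is biased half a day early).
    Non-convergence is reported through the ``converged`` flag rather than
    an exception; a cohort in which fewer than half the cuttings ever root
    has no identifiable T50 and raises.
    """
    days, frac = cohort.cumulative_fraction()
    if frac.size and frac[-1] < 0.5:
        raise ValueError("T50 not identifiable: fewer than 50% of cuttings rooted")
    if len(days) < 3:
        raise ValueError("need at least 3 observation days to fit T50")
    n = cohort.n_cuttings
    # Binomial weights; clip so fully-rooted days keep finite weight.
    p = np.clip(frac, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    sigma = np.sqrt(p * (1 - p) / n)
    t50_0 = float(days[np.searchsorted(frac, 0.5)])
    try:
        popt, pcov = optimize.curve_fit(
            _ll2,
            days.astype(float) + 0.5,
            frac,
            p0=[-5.0, max(t50_0, 1.0)],
            sigma=sigma,
            absolute_sigma=True,
            maxfev=10000,
        )
        slope, t50 = popt
        resid = frac - _ll2(days + 0.5, *popt)
        scale = float(np.sqrt(np.mean(resid**2)))
        # Delta-method SE of the median: the cumulative points are
        # correlated (same cuttings), so the curve-fit covariance is
        # anti-conservative; instead propagate the binomial variance of the
        # 50% crossing through the fitted density, Var(t50) =
        # [F(1−F)/n] / f(t50)² with F = ½ and f(t50) = |b|/(4·t50).
        se = 2.0 * abs(t50) / (abs(slope) * np.sqrt(n))
        ok = np.isfinite(se) and t50 > 0 and slope < 0
        return T50Estimate(
            cohort_id=cohort.cohort_id,
            t50=float(t50),
            std_error=float(se) if ok else float("nan"),
            slope=float(slope),
            converged=bool(ok),
            residual_scale=scale,
        )
    except RuntimeError:
        return T50Estimate(
            cohort_id=cohort.cohort_id,
            t50=float("nan"),
            std_error=float("nan"),
            slope=float("nan"),
            converged=False,
            residual_scale=float("nan"),
        )


def regress_t50(t50_values, thermal_values) -> RegressionSummary:
    """OLS of T50 on a cumulative thermal metric.

    Returns slope, intercept, R², mean squared residual and the two-sided
    p-value of the slope t-test.
    """
    y = np.asarray(t50_values, dtype=float)
    x = np.asarray(thermal_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("t50_values and thermal_values must be equal-length 1-D")
    if y.size < 3:
        raise ValueError("need at least 3 points for regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    mse = float(np.mean((y - fitted) ** 2))
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        mse=mse,
        p_value=float(res.pvalue),
        n=int(y.size),
    )


def read_weather_csv(path) -> ThermalSeries:
    """Read a weather CSV with columns date, t_mean, t_max, t_min."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "t_mean", "t_max", "t_min"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    records = [
        DailyWeatherRecord(
            date=row.date.date(),
            t_mean=float(row.t_mean),
            t_max=float(row.t_max),
            t_min=float(row.t_min),
        )
        for row in df.itertuples()
    ]
    return ThermalSeries(records)


def read_rooting_csv(path) -> list[RootingCohort]:
    """Read per-cutting rooting records: cohort_id, collection_date, cutting_id, root_day.

    An empty root_day marks a cutting censored at observation end.
    """
    df = pd.read_csv(path, parse_dates=["collection_date"])
    missing = {"cohort_id", "collection_date", "cutting_id", "root_day"} - set(df.columns)
    if missing:
        raise ValueError(f"rooting CSV missing columns: {sorted(missing)}")
    cohorts = []
    for cid, grp in df.groupby("cohort_id", sort=True):
        days = [int(d) for d in grp["root_day"].dropna()]
        cohorts.append(
            RootingCohort(
                cohort_id=str(cid),
                collection_date=grp["collection_date"].iloc[0].date(),
                n_cuttings=len(grp),
                root_day=days,
            )
        )
    return cohorts
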