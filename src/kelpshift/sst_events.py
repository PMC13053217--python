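"""Daily-SST extreme-event detection and trend statistics.

Event definitions are inclusive ("at or above"): a stress event is >= 14
consecutive days at or above 18 degC, a mortality (reproductive-failure)
event >= 7 consecutive days at or above 20 degC.  Missing calendar days
break runs.  Mann-Kendall, Sen's slope and the logistic event-frequency
trend are implemented from first principles; the smoothed warming rate
uses a GCV-penalized smoothing spline on annual means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "DailySSTSeries",
    "HeatEvent",
    "TrendResult",
    "SEASONS",
    "read_daily_series",
    "write_daily_series",
    "annual_means",
    "days_above",
    "detect_events",
    "events_to_frame",
    "annual_event_indicator",
    "mann_kendall",
    "sen_slope",
    "event_odds_trend",
    "trend_rate",
    "anomalies_and_correlation",
    "SeparationError",
]

STRESS_THRESHOLD = 18.0
STRESS_MIN_DAYS = 14
MORTALITY_THRESHOLD = 20.0
MORTALITY_MIN_DAYS = 7

#: month windows; winter (Dec-Feb) spans the year boundary and is assigned
#: to the January year
SEASONS = {
    "annual": tuple(range(1, 13)),
    "summer": (6, 7, 8),
    "winter": (12, 1, 2),
}


class SeparationError(RuntimeError):
    """Raised when a logistic fit is completely separated."""


@dataclass(frozen=True)
class DailySSTSeries:
    """Daily SST (and optional salinity) record.

    Dates must be unique and strictly increasing; gaps are allowed and are
    reported by :meth:`gap_years`.
    """

    dates: pd.DatetimeIndex
    sst: np.ndarray
    salinity: np.ndarray | None = None

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        sst = np.asarray(self.sst, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "sst", sst)
        if self.salinity is not None:
            sal = np.asarray(self.salinity, dtype=float)
            if sal.shape != sst.shape:
                raise ValueError("salinity length mismatch")
            object.__setattr__(self, "salinity", sal)
        if len(dates) == 0:
            raise ValueError("empty series")
        if dates.has_duplicates:
            raise ValueError("duplicate dates")
        if not dates.is_monotonic_increasing:
            raise ValueError("dates must be increasing")
        if sst.shape != (len(dates),):
            raise ValueError("sst length mismatch")

    def __len__(self) -> int:
        return len(self.dates)

    def as_series(self) -> pd.Series:
        return pd.Series(self.sst, index=self.dates, name="sst_c")

    def gap_years(self) -> list[int]:
        """Calendar years inside the record span with no observations."""
        have = set(self.dates.year)
        return [
            y
            for y in range(int(self.dates[0].year), int(self.dates[-1].year) + 1)
            if y not in have
        ]


@dataclass(frozen=True)
class HeatEvent:
    """A maximal run of consecutive days at or above a threshold."""

    start_date: pd.Timestamp
    end_date: pd.Timestamp
    length: int
    threshold: float
    kind: str

    def __post_init__(self) -> None:
        expected = (self.end_date - self.start_date).days + 1
        if self.length != expected:
            raise ValueError(
                f"length {self.length} != inclusive day count {expected}"
            )


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall / Sen trend summary for an annual series."""

    tau: float
    sen_slope: float
    p_value: float
    n: int
    s: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.tau <= 1.0:
            raise ValueError(f"tau {self.tau} outside [-1, 1]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_daily_series(path: str | Path) -> DailySSTSeries:
    """Read a daily CSV with columns date (ISO-8601), sst_c[, psu]."""
    df = pd.read_csv(path, parse_dates=["date"])
    for col in ("date", "sst_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("date")
    sal = df["psu"].to_numpy(float) if "psu" in df.columns else None
    return DailySSTSeries(
        dates=pd.DatetimeIndex(df["date"]),
        sst=df["sst_c"].to_numpy(float),
        salinity=sal,
    )


def write_daily_series(series: DailySSTSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"date": series.dates.strftime("%Y-%m-%d"), "sst_c": series.sst}
    )
    if series.salinity is not None:
        df["psu"] = series.salinity
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annual aggregation
# ---------------------------------------------------------------------------

def annual_means(
    series: DailySSTSeries, season: str = "annual", variable: str = "sst"
) -> pd.Series:
    """Per-year mean within a season window, indexed by calendar year.

    Winter (Dec-Feb) means are assigned to the year of the January.
    Years without data inside the window are absent (not zero).
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; choose from {sorted(SEASONS)}")
    months = SEASONS[season]
    values = series.sst if variable == "sst" else series.salinity
    if values is None:
        raise ValueError(f"series has no {variable!r} values")
    month = series.dates.month
    year = series.dates.year.to_numpy().copy()
    if season == "winter":
        year[month == 12] += 1  # December joins the following January
    mask = np.isin(month, months)
    s = pd.Series(values[mask], index=year[mask])
    out = s.groupby(level=0).mean()
    out.index.name = "year"
    return out


def days_above(
    series: DailySSTSeries,
    threshold: float,
    season: str = "summer",
) -> pd.Series:
    """Per-year count of days with SST >= threshold inside the season
    window.  Years with no data in the window are NaN, not zero."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    months = SEASONS[season]
    mask = np.isin(series.dates.month, months)
    year = series.dates.year.to_numpy()
    hot = (series.sst >= threshold) & mask
    counts = pd.Series(hot[mask].astype(int), index=year[mask]).groupby(level=0).sum()
    years = pd.RangeIndex(int(series.dates[0].year), int(series.dates[-1].year) + 1)
    out = counts.reindex(years).astype(float)
    out.index.name = "year"
    return out


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_events(
    series: DailySSTSeries,
    threshold: float,
    min_days: int,
    kind: str = "stress",
) -> list[HeatEvent]:
    """Maximal runs of consecutive calendar days with SST >= threshold and
    run length >= min_days.  A missing day breaks a run."""
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    hot = series.sst >= threshold
    events: list[HeatEvent] = []
    run_start: int | None = None
    for i in range(len(series)):
        contiguous = (
            i > 0 and (series.dates[i] - series.dates[i - 1]).days == 1
        )
        if hot[i]:
            if run_start is None or not contiguous:
                if run_start is not None:
                    _close_run(events, series, run_start, i - 1, threshold, min_days, kind)
                run_start = i
        else:
            if run_start is not None:
                _close_run(events, series, run_start, i - 1, threshold, min_days, kind)
                run_start = None
    if run_start is not None:
        _close_run(events, series, run_start, len(series) - 1, threshold, min_days, kind)
    return events


def _close_run(events, series, i0, i1, threshold, min_days, kind) -> None:
    length = i1 - i0 + 1
    if length >= min_days:
        events.append(
            HeatEvent(
                start_date=series.dates[i0],
                end_date=series.dates[i1],
                length=length,
                threshold=threshold,
                kind=kind,
            )
        )


def events_to_frame(events: Sequence[HeatEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_date": e.start_date.strftime("%Y-%m-%d"),
                "end_date": e.end_date.strftime("%Y-%m-%d"),
                "length": e.length,
                "threshold": e.threshold,
                "kind": e.kind,
            }
            for e in events
        ],
        columns=["start_date", "end_date", "length", "threshold", "kind"],
    )


def annual_event_indicator(
    series: DailySSTSeries, events: Sequence[HeatEvent]
) -> pd.Series:
    """0/1 per observed year: did any event start in that year?  Years with
    no observations at all are NaN."""
    years = pd.RangeIndex(int(series.dates[0].year), int(series.dates[-1].year) + 1)
    observed = set(series.dates.year)
    flag = pd.Series(
        [0.0 if y in observed else np.nan for y in years], index=years
    )
    for e in events:
        y = int(e.start_date.year)
        if y in flag.index:
            flag.loc[y] = 1.0
    flag.index.name = "year"
    return flag


# ---------------------------------------------------------------------------
# Trend statistics
# ---------------------------------------------------------------------------

def _prepare_annual(values, years):
    v = np.asarray(values, dtype=float)
    if years is None:
        t = np.arange(v.size, dtype=float)
    else:
        t = np.asarray(years, dtype=float)
    ok = np.isfinite(v) & np.isfinite(t)
    return v[ok], t[ok]


def mann_kendall(values: Sequence[float], years: Sequence[float] | None = None) -> TrendResult:
    """Mann-Kendall trend test with tie-corrected variance and tau-b.

    S sums the signs of all pairwise differences taken in time order; the
    two-sided p-value uses the normal approximation with continuity
    correction.  Missing (NaN) years are dropped.
    """
    v, t = _prepare_annual(values, years)
    n = v.size
    if n < 4:
        raise ValueError(f"need >= 4 non-missing years, got {n}")
    order = np.argsort(t, kind="stable")
    v = v[order]
    t = t[order]
    diff = np.sign(v[None, :] - v[:, None])
    iu = np.triu_indices(n, k=1)
    s = int(diff[iu].sum())

    def tie_groups(x):
        _, counts = np.unique(x, return_counts=True)
        return counts[counts > 1]

    tv = tie_groups(v)
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(tv * (tv - 1) * (2 * tv + 5))
    ) / 18.0
    d0 = n * (n - 1) / 2.0
    ties_v = np.sum(tv * (tv - 1) / 2.0)
    tt = tie_groups(t)
    ties_t = np.sum(tt * (tt - 1) / 2.0)
    denom = np.sqrt((d0 - ties_v) * (d0 - ties_t))
    tau = s / denom if denom > 0 else 0.0
    if var_s <= 0 or s == 0:
        z = 0.0
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)
    p = 1.0 if s == 0 else float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(
        tau=float(tau),
        sen_slope=sen_slope(v, t),
        p_value=min(p, 1.0),
        n=n,
        s=s,
        extra={"var_s": float(var_s), "z": float(z)},
    )


def sen_slope(values: Sequence[float], years: Sequence[float] | None = None) -> float:
    """Sen's estimator: median of all pairwise slopes (v_j-v_i)/(t_j-t_i)."""
    v, t = _prepare_annual(values, years)
    if v.size < 2:
        raise ValueError("need >= 2 non-missing years")
    slopes = []
    for i in range(v.size):
        for j in range(i + 1, v.size):
            dt = t[j] - t[i]
            if dt != 0:
                slopes.append((v[j] - v[i]) / dt)
    if not slopes:
        raise ValueError("no distinct years")
    return float(np.median(slopes))


def event_odds_trend(
    indicator: Sequence[float],
    years: Sequence[float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> dict:
    """Logistic regression of an annual 0/1 event indicator on calendar
    year, by iteratively reweighted least squares.

    Returns the yearly odds ratio exp(slope), the percent change per year
    (exp(slope)-1)*100, and a Wald confidence interval.  NaN years are
    dropped.  Complete separation is detected and raised.
    """
    y, t = _prepare_annual(indicator, years)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("indicator must be 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    t0 = t.mean()
    x = np.column_stack([np.ones_like(t), t - t0])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            raise SeparationError("degenerate weights in IRLS")
        xtwx = x.T @ (w[:, None] * x)
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise SeparationError("IRLS did not converge (possible separation)")
    if abs(beta[1]) > 30:
        raise SeparationError("slope diverged: complete separation")
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(x.T @ (w[:, None] * x))
    se = float(np.sqrt(cov[1, 1]))
    z = stats.norm.ppf(0.975)
    slope = float(beta[1])
    return {
        "slope": slope,
        "se": se,
        "odds_ratio": float(np.exp(slope)),
        "percent_per_year": float((np.exp(slope) - 1.0) * 100.0),
        "or_ci": (float(np.exp(slope - z * se)), float(np.exp(slope + z * se))),
        "p_value": float(2.0 * stats.norm.sf(abs(slope / se))),
        "n": int(y.size),
    }


def trend_rate(
    values: Sequence[float],
    years: Sequence[float],
    period: tuple[int, int] | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    ci: float = 0.95,
) -> dict:
    """Average warming rate from a penalized smoothing spline of annual
    means on year (smoothing parameter by generalized cross-validation).

    The rate is the mean of the fitted first derivative evaluated at each
    year of *period*, times 10 (units per decade); the total change is the
    rate times the period length in decades.  The CI comes from a residual
    bootstrap (refit on resampled residuals).
    """
    v, t = _prepare_annual(values, years)
    if v.size < 10:
        raise ValueError(f"need >= 10 non-missing years, got {v.size}")
    order = np.argsort(t)
    v, t = v[order], t[order]
    if period is None:
        period = (int(t[0]), int(t[-1]))
    y0, y1 = period
    if y0 < t[0] or y1 > t[-1] or y1 <= y0:
        raise ValueError(f"period {period} outside data range [{t[0]}, {t[-1]}]")

    grid = np.arange(y0, y1 + 1, dtype=float)

    def mean_deriv(vals: np.ndarray) -> float:
        spl = make_smoothing_spline(t, vals)  # lam chosen by GCV
        return float(spl.derivative()(grid).mean())

    d = mean_deriv(v)
    rate = d * 10.0
    total = d * (y1 - y0)

    lo = hi = rate
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        spl = make_smoothing_spline(t, v)
        fitted = spl(t)
        resid = v - fitted
        boots = np.empty(n_boot)
        for b in range(n_boot):
            vb = fitted + rng.choice(resid, size=resid.size, replace=True)
            boots[b] = mean_deriv(vb) * 10.0
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return {
        "rate_per_decade": rate,
        "total_change": total,
        "ci": (float(lo), float(hi)),
        "period": (int(y0), int(y1)),
        "n": int(v.size),
    }


def anomalies_and_correlation(
    series_a: pd.Series,
    series_b: pd.Series,
    baseline_years: tuple[int, int] = (1971, 2000),
) -> dict:
    """Anomalize two annual series against a common baseline period and
    correlate them (Pearson) over their overlapping years."""
    b0, b1 = baseline_years

    def anomalize(s: pd.Series) -> pd.Series:
        s = s.dropna()
        base = s[(s.index >= b0) & (s.index <= b1)]
        if base.empty:
            raise ValueError(
                f"no data inside baseline years [{b0}, {b1}]"
            )
        return s - base.mean()

    aa = anomalize(series_a)
    ab = anomalize(series_b)
    common = aa.index.intersection(ab.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping years; need >= 3")
    r, p = stats.pearsonr(aa.loc[common], ab.loc[common])
    return {
        "anomalies_a": aa,
        "anomalies_b": ab,
        "r": float(r),
        "p_value": float(p),
        "n": int(len(common)),
    }
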