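"""Trend fitting, growth rates, forecasting, carrying capacity, correlations.

Annual production (or value, consumption, ratio) series are fitted with
linear, polynomial or exponential least-squares models after centering years
at the window start (uncentered powers of calendar years are badly
conditioned).  The module also provides year-over-year growth-rate series,
windowed mean growth (arithmetic or CAGR), the long-run-mean "carrying
capacity" of a capture-fishery series, element-wise ratio series
(e.g. fishery/aquaculture), and Pearson correlation utilities for
user-supplied covariate tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ProductionPanel, aggregate


@dataclass
class AnnualSeries:
    """An annual numeric series (tonnes, US$, kg/person, or a ratio)."""

    years: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise ValueError("years and values must have equal length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")

    def __len__(self) -> int:
        return int(self.years.size)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=self.label)

    @classmethod
    def from_pandas(cls, s: pd.Series, label: str | None = None) -> "AnnualSeries":
        s = s.sort_index()
        return cls(s.index.to_numpy(), s.to_numpy(),
                   label=label if label is not None else (s.name or ""))


def series_from_panel(
    panel: ProductionPanel,
    selector: str = "total",
    measure: str = "quantity",
) -> AnnualSeries:
    """Annual totals from a panel.

    ``selector`` is ``"total"``, ``"species:<name>"`` or ``"country:<name>"``.
    """
    if selector == "total":
        table = aggregate(panel, ["year"], measure=measure)
        col = table.columns[-1]
        return AnnualSeries(table["year"].to_numpy(), table[col].to_numpy(),
                            label=f"total {measure}")
    try:
        axis, name = selector.split(":", 1)
    except ValueError:
        raise ValueError(f"bad selector {selector!r}") from None
    if axis not in ("species", "country"):
        raise ValueError(f"bad selector axis {axis!r}")
    table = aggregate(panel, ["year", axis], measure=measure)
    sub = table[table[axis] == name]
    if sub.empty:
        raise KeyError(f"{axis} {name!r} not present in panel")
    col = sub.columns[-1]
    return AnnualSeries(sub["year"].to_numpy(), sub[col].to_numpy(),
                        label=f"{name} {measure}")


@dataclass
class TrendModel:
    """A fitted trend.

    ``coefficients`` are highest power first for polynomial kinds (numpy
    convention); for the exponential kind they are ``(a, b)`` of
    ``y = exp(b) · exp(a · (year − x_origin))``, i.e. ``a`` is the
    continuous growth rate per year.
    """

    kind: str                      # "linear", "polynomial", "exponential"
    degree: int
    coefficients: np.ndarray
    r2: float
    pearson_r: float
    x_origin: int
    fit_window: tuple[int, int]

    def predict(self, years) -> np.ndarray:
        scalar = np.isscalar(years)
        t = np.asarray(years, dtype=float) - self.x_origin
        if self.kind == "exponential":
            a, b = self.coefficients
            out = np.exp(b + a * t)
        else:
            out = np.polyval(self.coefficients, t)
        return float(out) if scalar else out


def fit_trend(
    series: AnnualSeries,
    kind: str = "polynomial",
    degree: int = 2,
    window: tuple[int, int] | None = None,
) -> TrendModel:
    """Least-squares trend fit after centering years at the window start.

    ``kind="linear"`` is a degree-1 polynomial; ``"exponential"`` fits a
    straight line to log values (all values must be positive), so its slope
    coefficient is the continuous annual growth rate.  R² and the Pearson r
    of fitted vs observed are computed on the original scale.
    """
    if kind == "linear":
        kind, degree = "polynomial", 1
    if kind not in ("polynomial", "exponential"):
        raise ValueError(f"unknown trend kind {kind!r}")
    if degree < 1:
        raise ValueError("degree must be >= 1")

    years, values = series.years, series.values
    if window is not None:
        mask = (years >= window[0]) & (years <= window[1])
        years, values = years[mask], values[mask]
    if years.size == 0:
        raise ValueError("fit window contains no data")
    x_origin = int(years[0])
    x = years.astype(float) - x_origin

    if kind == "exponential":
        if np.any(values <= 0):
            raise ValueError("exponential fit requires strictly positive values")
        if years.size < 3:
            raise ValueError("need at least 3 points for an exponential fit")
        a, b = np.polyfit(x, np.log(values), 1)
        coeffs = np.array([a, b])
        fitted = np.exp(b + a * x)
        degree = 1
    else:
        if years.size < degree + 2:
            raise ValueError(f"need at least {degree + 2} points for degree {degree}")
        coeffs = np.polyfit(x, values, degree)
        fitted = np.polyval(coeffs, x)

    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    if np.std(fitted) == 0 or np.std(values) == 0:
        pr = 1.0 if ss_res == 0 else 0.0
    else:
        pr = float(np.corrcoef(fitted, values)[0, 1])
    return TrendModel(
        kind=kind, degree=int(degree), coefficients=coeffs, r2=r2,
        pearson_r=pr, x_origin=x_origin,
        fit_window=(int(years[0]), int(years[-1])),
    )


def forecast(model: TrendModel, year: int) -> float:
    """Evaluate the fitted trend at a calendar year (no clamping).

    Warns when extrapolating beyond the fit window.
    """
    lo, hi = model.fit_window
    if year < lo or year > hi:
        warnings.warn(
            f"forecast at {year} extrapolates beyond fit window {lo}-{hi}",
            stacklevel=2,
        )
    return float(model.predict(year))


def growth_rate_series(series: AnnualSeries) -> AnnualSeries:
    """Year-over-year percent change; years after a zero are skipped."""
    if len(series) < 2:
        raise ValueError("need at least 2 years")
    s = series.to_pandas()
    prev = s.shift(1)
    rates = (100.0 * (s - prev) / prev)[prev != 0].dropna()
    return AnnualSeries(rates.index.to_numpy(), rates.to_numpy(),
                        label=f"{series.label} growth rate (%)")


def mean_growth_rate(
    series: AnnualSeries,
    window: int = 10,
    method: str = "arithmetic",
) -> float:
    """Average annual growth over the trailing window, percent.

    ``arithmetic`` averages the year-over-year percent changes;
    ``cagr`` is 100 × ((v_end / v_start)^(1/span) − 1) where span is the
    elapsed years between the first and last observation in the window.
    """
    if method not in ("arithmetic", "cagr"):
        raise ValueError(f"unknown method {method!r}")
    s = series.to_pandas()
    last = int(s.index.max())
    win = s[s.index > last - window]
    if len(win) < 2:
        raise ValueError("window must contain at least 2 years of data")
    if method == "arithmetic":
        rates = growth_rate_series(AnnualSeries.from_pandas(win))
        if len(rates) == 0:
            raise ValueError("no valid year-over-year rate in window")
        return float(rates.values.mean())
    v0, v1 = win.iloc[0], win.iloc[-1]
    if v0 <= 0:
        raise ValueError("CAGR requires a positive start value")
    span = int(win.index[-1] - win.index[0])  # elapsed years, robust to gaps
    return float(100.0 * ((v1 / v0) ** (1.0 / span) - 1.0))


def carrying_capacity(series: AnnualSeries, window: tuple[int, int]) -> float:
    """Long-run mean of the series over a closed year window.

    Used on capture-fishery landings: with wild extraction flat for decades,
    its long-run mean is read as the basin's ceiling of wild production.
    """
    lo, hi = window
    mask = (series.years >= lo) & (series.years <= hi)
    if not mask.any():
        raise ValueError(f"window {lo}-{hi} does not overlap the series")
    return float(series.values[mask].mean())


def ratio_series(numerator: AnnualSeries, denominator: AnnualSeries) -> AnnualSeries:
    """Element-wise ratio on the year intersection; zero denominators skipped."""
    num, den = numerator.to_pandas(), denominator.to_pandas()
    common = num.index.intersection(den.index)
    if common.empty:
        raise ValueError("series share no years")
    num, den = num.loc[common], den.loc[common]
    keep = den != 0
    if not keep.all():
        warnings.warn(
            f"skipping {(~keep).sum()} year(s) with zero denominator",
            stacklevel=2,
        )
    ratio = (num[keep] / den[keep]).sort_index()
    return AnnualSeries(ratio.index.to_numpy(), ratio.to_numpy(),
                        label=f"{numerator.label}/{denominator.label}")


def pearson(x: AnnualSeries, y: AnnualSeries) -> float:
    """Product-moment correlation of two series on their year intersection."""
    xs, ys = x.to_pandas(), y.to_pandas()
    common = xs.index.intersection(ys.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned points")
    a, b = xs.loc[common].to_numpy(), ys.loc[common].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(a, b).statistic)


def correlation_matrix(
    table: pd.DataFrame,
    exclude: list[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of an entities × indicators table.

    ``exclude`` drops rows (e.g. one outlier country) before correlating.
    Indicator pairs with fewer than ``min_pairs`` complete observations are
    NaN (flagged undefined).  The result is symmetric with a unit diagonal.
    """
    if exclude:
        table = table.drop(index=[e for e in exclude if e in table.index])
    corr = table.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr
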