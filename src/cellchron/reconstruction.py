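"""Proxy-climate regression, split calibration-verification, reconstruction.

The reconstruction model regresses the seasonal climate variable directly
on the chronology index (ordinary least squares), so the fitted intercept
and slope map index values to climate units.  Skill on withheld years is
measured by the reduction of error (RE, benchmark: calibration-period
mean), the coefficient of efficiency (CE, benchmark: verification-period
mean) and the Durbin-Watson statistic of the verification residuals; RE and
CE above zero indicate skill, and RE >= CE always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chronology import Chronology
from .tables import ClimateMatrix


class ReconstructionError(ValueError):
    pass


def season_months(season: tuple[int, int]) -> list[tuple[int, int]]:
    """Expand (start, end) into (year_offset, month) pairs.

    Months are contiguous; a season with start > end crosses the calendar
    boundary and is assigned to the ending year, so its first months carry
    year_offset -1 (previous year).
    """
    start, end = season
    if not (1 <= start <= 12 and 1 <= end <= 12):
        raise ReconstructionError(f"season months must lie in 1-12, got {season}")
    length = (end - start) % 12 + 1
    out = []
    for i in range(length):
        m = (start - 1 + i) % 12 + 1
        offset = -1 if (start > end and m >= start) else 0
        out.append((offset, m))
    return out


def seasonal_aggregate(
    climate: ClimateMatrix,
    season: tuple[int, int],
    variable: str = "ppt",
    aggregation: str | None = None,
) -> pd.Series:
    """Annual seasonal aggregate of one climate variable.

    Precipitation is summed, temperature averaged (override with
    ``aggregation``).  Cross-boundary seasons (e.g. October-March) are
    labelled by the ending year; the first labelled year is the one for
    which every season month is covered.
    """
    if aggregation is None:
        aggregation = "sum" if variable == "ppt" else "mean"
    if aggregation not in ("sum", "mean"):
        raise ReconstructionError(f"unknown aggregation {aggregation!r}")
    months = season_months(season)
    wide = climate.monthly(variable)
    pieces = []
    for offset, m in months:
        col = wide[m]
        if offset == -1:
            col = col.copy()
            col.index = col.index + 1  # contributes to the following (ending) year
        pieces.append(col)
    mat = pd.concat(pieces, axis=1, keys=range(len(pieces))).dropna()
    agg = mat.sum(axis=1) if aggregation == "sum" else mat.mean(axis=1)
    agg.index.name = "year"
    return agg


@dataclass
class ReconstructionModel:
    """OLS model: climate = intercept + slope * chronology index."""

    intercept: float
    slope: float
    r_squared: float
    calibration_period: tuple[int, int]
    season: tuple[int, int]
    variable: str = "ppt"
    aggregation: str = "sum"

    def predict(self, index_values: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(index_values, dtype=float)


@dataclass
class SkillStats:
    re: float
    ce: float
    dw: float
    n_verification: int


@dataclass
class ReconstructedSeries:
    years: np.ndarray
    values: np.ndarray = field(repr=False)
    observed: pd.Series | None = None
    model: ReconstructionModel | None = None

    def __len__(self) -> int:
        return len(self.years)


def _align(chronology: Chronology, seasonal: pd.Series,
           years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    chron = pd.Series(chronology.values, index=chronology.years)
    missing = [int(y) for y in years if y not in chron.index or y not in seasonal.index]
    if missing:
        raise ReconstructionError(f"year {missing[0]} outside chronology/climate overlap")
    return chron.loc[years].to_numpy(), seasonal.loc[years].to_numpy()


def fit_linear_model(
    chronology: Chronology,
    seasonal: pd.Series,
    calibration_years: tuple[int, int],
    season: tuple[int, int] = (3, 8),
    variable: str = "ppt",
    aggregation: str = "sum",
) -> ReconstructionModel:
    """OLS fit of the seasonal climate series on the chronology index."""
    years = np.arange(calibration_years[0], calibration_years[1] + 1)
    if len(years) < 10:
        raise ReconstructionError("need at least 10 calibration years")
    x, y = _align(chronology, seasonal, years)
    if np.std(x) == 0:
        raise ReconstructionError("chronology has zero variance over calibration years")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return ReconstructionModel(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=float(fit.rsquared),
        calibration_period=calibration_years,
        season=season,
        variable=variable,
        aggregation=aggregation,
    )


def durbin_watson(residuals: np.ndarray) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2 on year-ordered residuals."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ReconstructionError("Durbin-Watson needs at least 2 residuals")
    denom = np.sum(e * e)
    if denom == 0:
        return 2.0  # perfect fit: no residual autocorrelation to measure
    return float(np.sum(np.diff(e) ** 2) / denom)


def verify(
    model: ReconstructionModel,
    chronology: Chronology,
    seasonal: pd.Series,
    verification_years: tuple[int, int],
) -> SkillStats:
    """Skill of the model's predictions on withheld verification years.

    RE  = 1 - SSE / sum (O - mean_cal)^2   (benchmark: calibration mean)
    CE  = 1 - SSE / sum (O - mean_ver)^2   (benchmark: verification mean)
    DW on the verification residuals in year order.
    """
    v0, v1 = verification_years
    c0, c1 = model.calibration_period
    if not (v1 < c0 or v0 > c1):
        raise ReconstructionError("verification years overlap the calibration period")
    years = np.arange(v0, v1 + 1)
    if len(years) < 3:
        raise ReconstructionError("need at least 3 verification years")
    x, obs = _align(chronology, seasonal, years)
    cal_years = np.arange(c0, c1 + 1)
    _, obs_cal = _align(chronology, seasonal, cal_years)
    pred = model.predict(x)
    sse = np.sum((obs - pred) ** 2)
    re = 1.0 - sse / np.sum((obs - obs_cal.mean()) ** 2)
    ce = 1.0 - sse / np.sum((obs - obs.mean()) ** 2)
    return SkillStats(re=float(re), ce=float(ce),
                      dw=durbin_watson(obs - pred), n_verification=len(years))


@dataclass
class CalibrationVerificationResult:
    """Table of the split calibration-verification exercise.

    ``forward`` calibrates on the first half and verifies on the second,
    ``reverse`` the opposite; ``full_model`` is fitted on the whole period.
    """

    forward: SkillStats
    reverse: SkillStats
    full_model: ReconstructionModel
    split: tuple[tuple[int, int], tuple[int, int]]


def split_calibration_verification(
    chronology: Chronology,
    seasonal: pd.Series,
    split: tuple[tuple[int, int], tuple[int, int]] = ((1950, 1981), (1982, 2013)),
    season: tuple[int, int] = (3, 8),
    variable: str = "ppt",
    aggregation: str = "sum",
) -> CalibrationVerificationResult:
    (a0, a1), (b0, b1) = split
    if not (a1 < b0 or b1 < a0):
        raise ReconstructionError("split halves overlap")
    model_a = fit_linear_model(chronology, seasonal, (a0, a1), season, variable, aggregation)
    model_b = fit_linear_model(chronology, seasonal, (b0, b1), season, variable, aggregation)
    forward = verify(model_a, chronology, seasonal, (b0, b1))
    reverse = verify(model_b, chronology, seasonal, (a0, a1))
    full = fit_linear_model(
        chronology, seasonal, (min(a0, b0), max(a1, b1)), season, variable, aggregation
    )
    return CalibrationVerificationResult(
        forward=forward, reverse=reverse, full_model=full, split=split
    )


def reconstruct(model: ReconstructionModel, chronology: Chronology,
                seasonal: pd.Series | None = None) -> ReconstructedSeries:
    """Apply the fitted model to every chronology year."""
    values = model.predict(chronology.values)
    observed = None
    if seasonal is not None:
        observed = seasonal.reindex(chronology.years)
    return ReconstructedSeries(
        years=chronology.years.copy(), values=values, observed=observed, model=model
    )
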