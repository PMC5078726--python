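"""Smoothing-spline detrending and ratio indices.

Each measurement series is standardized by fitting a cubic smoothing spline
whose amplitude (frequency) response equals a chosen fraction at a chosen
wavelength — the conventional "f % frequency response at p years" spline —
and dividing the measurements by the fitted curve.  With the defaults the
spline passes 50% of the amplitude of a 50-year cycle, removing age trends
and slower non-climatic variability while retaining inter-annual variation.

The stiffness (roughness penalty) lambda follows from the filter-response
identity of the discrete smoothing spline: a penalized smoother with
second-difference penalty attenuates frequency f by 1 / (1 + lambda * (2
sin(pi f))^4), so requiring response r at wavelength p gives

    lambda = ((1 - r) / r) / (2 sin(pi / p))^4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .series import MeasurementSeries


class DetrendError(ValueError):
    pass


def spline_lambda(frequency_response: float, wavelength_years: float) -> float:
    """Roughness penalty giving the requested amplitude response.

    ``frequency_response`` is the fraction of amplitude passed at period
    ``wavelength_years`` (0.5 = 50%).
    """
    if not 0 < frequency_response < 1:
        raise DetrendError("frequency_response must be in (0, 1)")
    if wavelength_years <= 2:
        raise DetrendError("wavelength_years must exceed 2 (Nyquist)")
    r = frequency_response
    return (1 - r) / r / (2 * np.sin(np.pi / wavelength_years)) ** 4


@dataclass
class DetrendCurve:
    """Fitted smooth growth curve aligned year-wise to its series."""

    series_id: str
    first_year: int
    fitted: np.ndarray = field(repr=False)
    frequency_response: float = 0.5
    wavelength_years: float = 50.0

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.fitted))


@dataclass
class IndexSeries:
    """Dimensionless ratio indices w_t / y_t for one series."""

    series_id: str
    tree_id: str
    first_year: int
    indices: np.ndarray = field(repr=False)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.indices) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.indices)


def fit_detrending_spline(
    series: MeasurementSeries,
    frequency_response: float = 0.5,
    wavelength_years: float = 50.0,
    min_length: int = 10,
) -> DetrendCurve:
    """Fit the cubic smoothing spline used for standardization.

    Natural boundary conditions, no padding; end segments of the curve are
    therefore less constrained than the interior (a known end-effect of
    spline detrending).
    """
    n = len(series)
    if n < min_length:
        raise DetrendError(
            f"series {series.series_id} has {n} years < floor {min_length}; "
            "use a shorter wavelength or a straight-line fit"
        )
    lam = spline_lambda(frequency_response, wavelength_years)
    t = np.arange(n, dtype=float)
    fitted = make_smoothing_spline(t, series.values, lam=lam)(t)
    return DetrendCurve(
        series_id=series.series_id,
        first_year=series.first_year,
        fitted=np.asarray(fitted, dtype=float),
        frequency_response=frequency_response,
        wavelength_years=wavelength_years,
    )


def compute_indices(series: MeasurementSeries, curve: DetrendCurve) -> IndexSeries:
    """Ratio indices index_t = w_t / y_t.

    Raises if the fitted curve is non-positive anywhere: a non-positive
    expected growth makes the ratio meaningless, and silently truncating
    would bias the chronology.
    """
    if curve.series_id != series.series_id or curve.first_year != series.first_year:
        raise DetrendError("curve was not fitted to this series")
    if len(curve.fitted) != len(series):
        raise DetrendError("curve and series lengths differ")
    bad = np.flatnonzero(curve.fitted <= 0)
    if bad.size:
        raise DetrendError(
            f"series {series.series_id}: fitted curve <= 0 in year "
            f"{series.first_year + int(bad[0])}"
        )
    return IndexSeries(
        series_id=series.series_id,
        tree_id=series.tree_id,
        first_year=series.first_year,
        indices=series.values / curve.fitted,
    )


def detrend(
    series: MeasurementSeries,
    frequency_response: float = 0.5,
    wavelength_years: float = 50.0,
) -> IndexSeries:
    """Convenience: fit the spline and return ratio indices in one step."""
    return compute_indices(
        series, fit_detrending_spline(series, frequency_response, wavelength_years)
    )
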