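"""Crossdating quality check: leave-one-out master correlations.

A quality-assurance report, never a data transformation.  Each series is
high-pass filtered (ratio to its own detrending spline) and correlated with
the mean of all other filtered series over the maximum common overlap, both
overall and in fixed-length segments; segments correlating below a threshold
are flagged as potential dating errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detrend import detrend
from .series import MeasurementSeries


class CrossdatingError(ValueError):
    pass


@dataclass
class SegmentFlag:
    series_id: str
    segment_start: int
    segment_end: int
    correlation: float
    n_overlap: int
    flagged: bool


@dataclass
class CrossdatingReport:
    series_correlations: dict[str, float]
    series_overlaps: dict[str, int]
    segments: list[SegmentFlag] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    segment_length: int = 30
    threshold: float = 0.32

    @property
    def flagged_segments(self) -> list[SegmentFlag]:
        return [s for s in self.segments if s.flagged]


def crossdating_correlations(
    series: Sequence[MeasurementSeries],
    segment_length: int = 30,
    threshold: float = 0.32,
    min_overlap: int = 20,
) -> CrossdatingReport:
    """Correlate each detrended series against its leave-one-out master.

    Series whose overlap with the master falls below ``min_overlap`` are
    skipped and recorded, not failed.
    """
    if len(series) < 2:
        raise CrossdatingError("crossdating check needs at least two series")
    detrended = [detrend(s) for s in series]
    first = min(d.first_year for d in detrended)
    last = max(d.last_year for d in detrended)
    span = last - first + 1
    mat = np.full((len(detrended), span), np.nan)
    for i, d in enumerate(detrended):
        mat[i, d.first_year - first : d.first_year - first + len(d)] = d.indices

    report = CrossdatingReport(
        series_correlations={}, series_overlaps={},
        segment_length=segment_length, threshold=threshold,
    )
    for i, d in enumerate(detrended):
        others = np.delete(mat, i, axis=0)
        have = np.any(~np.isnan(others), axis=0)
        master = np.full(span, np.nan)
        master[have] = np.nanmean(others[:, have], axis=0)
        both = ~np.isnan(mat[i]) & ~np.isnan(master)
        n = int(both.sum())
        if n < min_overlap:
            report.skipped.append(d.series_id)
            continue
        x, m = mat[i, both], master[both]
        r = float(np.corrcoef(x, m)[0, 1])
        report.series_correlations[d.series_id] = r
        report.series_overlaps[d.series_id] = n
        years = np.arange(first, last + 1)[both]
        for seg_start in range(int(years[0]), int(years[-1]) - segment_length + 2,
                               segment_length // 2 or 1):
            in_seg = (years >= seg_start) & (years < seg_start + segment_length)
            if in_seg.sum() < segment_length:
                continue
            seg_r = float(np.corrcoef(x[in_seg], m[in_seg])[0, 1])
            report.segments.append(
                SegmentFlag(
                    series_id=d.series_id,
                    segment_start=seg_start,
                    segment_end=seg_start + segment_length - 1,
                    correlation=seg_r,
                    n_overlap=int(in_seg.sum()),
                    flagged=seg_r < threshold,
                )
            )
    return report
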