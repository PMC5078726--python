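"""Core measurement containers for crossdated annual tree-ring series.

A :class:`MeasurementSeries` holds one crossdated annual time series of a
single ring parameter — either ring width or one of the annualized tracheid
(wood-anatomical) parameters — tied to a specific tree and core.  Anatomical
values are per-ring aggregates (one value per calendar year), mirroring the
output of cell-measurement software after averaging all tracheids of a ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Registry of supported ring parameters and their measurement units.
#:
#: ring_width — total annual radial increment;
#: LA   — mean tracheid lumen area;
#: LA30 — mean lumen area of the 30% largest tracheids;
#: LD   — lumen radial diameter;
#: LW   — lumen tangential width;
#: DWT  — double (radial) cell-wall thickness;
#: CD   — cell radial diameter, defined as LD + DWT.
PARAMETERS: dict[str, str] = {
    "ring_width": "mm",
    "LA": "um2",
    "LA30": "um2",
    "LD": "um",
    "LW": "um",
    "DWT": "um",
    "CD": "um",
}


class SeriesError(ValueError):
    """Raised for structurally invalid measurement series."""


@dataclass
class MeasurementSeries:
    """One crossdated annual series of a ring parameter.

    Parameters
    ----------
    series_id, tree_id, core_id
        Identifiers; ``series_id`` must be unique within a collection.
    parameter
        Key into :data:`PARAMETERS`.
    first_year
        Calendar year of the first ring.
    values
        Positive measurements, one per consecutive year (no gaps: the
        sampled material has no missing rings).
    """

    series_id: str
    tree_id: str
    core_id: str
    parameter: str
    first_year: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise SeriesError(
                f"unknown parameter {self.parameter!r}; "
                f"allowed: {sorted(PARAMETERS)}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise SeriesError(f"series {self.series_id}: values must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise SeriesError(f"series {self.series_id}: values must be finite and > 0")

    @property
    def unit(self) -> str:
        return PARAMETERS[self.parameter]

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        """Consecutive calendar years covered by the series."""
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.values)


def derive_cd(ld: MeasurementSeries, dwt: MeasurementSeries) -> MeasurementSeries:
    """Derive the cell radial diameter series CD = LD + DWT year-wise.

    Both inputs must come from the same core and cover identical years.
    """
    if ld.parameter != "LD" or dwt.parameter != "DWT":
        raise SeriesError("derive_cd expects an LD series and a DWT series")
    if (ld.tree_id, ld.core_id) != (dwt.tree_id, dwt.core_id):
        raise SeriesError("LD and DWT series must come from the same core")
    if ld.first_year != dwt.first_year or len(ld) != len(dwt):
        raise SeriesError(
            f"LD ({ld.first_year}-{ld.last_year}) and DWT "
            f"({dwt.first_year}-{dwt.last_year}) cover different years"
        )
    return MeasurementSeries(
        series_id=ld.series_id.rsplit("_", 1)[0] + "_CD"
        if "_" in ld.series_id
        else ld.series_id + "CD",
        tree_id=ld.tree_id,
        core_id=ld.core_id,
        parameter="CD",
        first_year=ld.first_year,
        values=ld.values + dwt.values,
    )
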