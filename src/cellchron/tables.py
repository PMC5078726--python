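"""Delimited-text tables: monthly climate and annualized cell measurements.

Climate tables are long format — one row per (year, month) with total
precipitation (mm) and mean/max/min temperature (°C) — emulating a monthly
extraction from a gridded climate product.  Cell tables carry one row per
(series, year, parameter) of annualized tracheid measurements.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .series import PARAMETERS, MeasurementSeries

CLIMATE_COLUMNS = ["year", "month", "ppt", "tmean", "tmax", "tmin"]
CLIMATE_VARIABLES = ["ppt", "tmean", "tmax", "tmin"]


class TableFormatError(ValueError):
    """Raised for malformed climate or cell tables."""


class ClimateMatrix:
    """Validated monthly climate table.

    Wraps a DataFrame with columns ``year, month, ppt, tmean, tmax, tmin``,
    one row per (year, month), all twelve months present for every covered
    year, and ``tmin <= tmean <= tmax`` row-wise.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"climate table missing columns: {missing}")
        df = df[CLIMATE_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["month"] = df["month"].astype(int)
        if ((df["month"] < 1) | (df["month"] > 12)).any():
            bad = df.loc[(df["month"] < 1) | (df["month"] > 12)].iloc[0]
            raise TableFormatError(f"month outside 1-12 at year {bad['year']}")
        dup = df.duplicated(["year", "month"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise TableFormatError(
                f"duplicate (year, month) = ({bad['year']}, {bad['month']})"
            )
        df = df.sort_values(["year", "month"]).reset_index(drop=True)
        counts = df.groupby("year")["month"].agg(["count", "sum"])
        incomplete = counts[(counts["count"] != 12) | (counts["sum"] != 78)]
        if len(incomplete):
            year = int(incomplete.index[0])
            present = set(df.loc[df["year"] == year, "month"])
            gap = sorted(set(range(1, 13)) - present)
            raise TableFormatError(f"year {year} incomplete: missing months {gap}")
        if (df["tmin"] > df["tmax"]).any() or (df["tmean"] > df["tmax"]).any() or (
            df["tmean"] < df["tmin"]
        ).any():
            bad = df.loc[(df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])].iloc[0]
            raise TableFormatError(
                f"temperature ordering violated at ({int(bad['year'])}, {int(bad['month'])})"
            )
        if (df["ppt"] < 0).any():
            raise TableFormatError("negative precipitation")
        self.df = df

    @property
    def first_year(self) -> int:
        return int(self.df["year"].iloc[0])

    @property
    def last_year(self) -> int:
        return int(self.df["year"].iloc[-1])

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def monthly(self, variable: str) -> pd.DataFrame:
        """Pivot one variable into a (year x month) table."""
        if variable not in CLIMATE_VARIABLES:
            raise TableFormatError(f"unknown climate variable {variable!r}")
        return self.df.pivot(index="year", columns="month", values=variable)

    def value(self, year: int, month: int, variable: str) -> float:
        sel = self.df[(self.df["year"] == year) & (self.df["month"] == month)]
        if sel.empty:
            raise TableFormatError(f"no climate row for ({year}, {month})")
        return float(sel[variable].iloc[0])

    def __len__(self) -> int:
        return len(self.df)


def read_climate_table(path: str | Path, delimiter: str | None = None) -> ClimateMatrix:
    """Read and validate a long-format monthly climate table."""
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    return ClimateMatrix(df)


def write_climate_table(climate: ClimateMatrix, path: str | Path, delimiter: str = ",") -> None:
    climate.df.to_csv(path, sep=delimiter, index=False)


CELL_COLUMNS = ["series_id", "tree_id", "core_id", "year", "parameter", "value"]


def read_cell_table(path: str | Path, delimiter: str | None = None) -> list[MeasurementSeries]:
    """Read annualized cell-measurement rows into one series per (id, parameter).

    Expected columns: ``series_id, tree_id, year, parameter, value`` (an
    optional ``core_id`` column defaults to the series id).  Row order is
    irrelevant; a gap in years within a series is an error because the
    sampled material has no missing rings.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    required = ["series_id", "tree_id", "year", "parameter", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"cell table missing columns: {missing}")
    if "core_id" not in df.columns:
        df["core_id"] = df["series_id"]
    unknown = sorted(set(df["parameter"]) - set(PARAMETERS))
    if unknown:
        raise TableFormatError(
            f"unknown parameter(s) {unknown}; allowed: {sorted(PARAMETERS)}"
        )
    out: list[MeasurementSeries] = []
    for (sid, param), grp in df.groupby(["series_id", "parameter"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if np.unique(years).size != years.size:
            raise TableFormatError(f"duplicate year in series {sid}/{param}")
        gaps = np.flatnonzero(np.diff(years) != 1)
        if gaps.size:
            raise TableFormatError(
                f"series {sid}/{param}: gap after year {years[gaps[0]]}"
            )
        out.append(
            MeasurementSeries(
                series_id=str(sid),
                tree_id=str(grp["tree_id"].iloc[0]),
                core_id=str(grp["core_id"].iloc[0]),
                parameter=str(param),
                first_year=int(years[0]),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return out


def write_cell_table(
    series: Iterable[MeasurementSeries], path: str | Path, delimiter: str = ","
) -> None:
    rows = []
    for s in series:
        for year, value in zip(s.years, s.values):
            rows.append((s.series_id, s.tree_id, s.core_id, int(year), s.parameter, value))
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, sep=delimiter, index=False)
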