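"""Tucson/RWL decadal ring-width format.

The decadal ("Tucson") layout stores one series per block of lines: an
8-character series id, the decade's starting year, then up to ten 6-character
integer fields, one per year.  Two dialects are in circulation and both are
supported: values in units of 0.01 mm terminated by ``999``, and values in
units of 0.001 mm terminated by ``-9999``.  The terminator is metadata, never
a measurement.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .series import MeasurementSeries

_TERMINATORS = {999: 0.01, -9999: 0.001}


class RWLFormatError(ValueError):
    """Raised for malformed Tucson/RWL content."""


def read_rwl(path: str | Path) -> list[MeasurementSeries]:
    """Read a decadal Tucson/RWL file into ring-width series (mm).

    The measurement precision of each series is inferred from its
    terminator value: ``999`` means the stored integers are hundredths of a
    millimetre, ``-9999`` thousandths.
    """
    # A value of 999 can be genuine data in the 0.001-mm dialect, so the
    # terminator is identified positionally: the last stored value of each
    # series block must be 999 or -9999.
    raw: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        sid = line[:8].strip()
        tokens = line[8:].split()
        if not sid or len(tokens) < 2:
            raise RWLFormatError(f"line {lineno}: expected series id, year and values")
        try:
            year = int(tokens[0])
            fields = [int(t) for t in tokens[1:]]
        except ValueError as exc:
            raise RWLFormatError(f"line {lineno}: non-numeric field ({exc})") from None
        if sid not in raw:
            raw[sid] = []
            order.append(sid)
        elif raw[sid] and raw[sid][-1][1] == -9999:
            raise RWLFormatError(
                f"line {lineno}: series {sid} continues after its terminator"
            )
        raw[sid].extend((year + off, v) for off, v in enumerate(fields))

    out: list[MeasurementSeries] = []
    for sid in order:
        stream = raw[sid]
        if stream[-1][1] not in _TERMINATORS:
            raise RWLFormatError(f"series {sid}: missing terminator (999 or -9999)")
        scale = _TERMINATORS[stream[-1][1]]
        data = stream[:-1]
        if not data:
            raise RWLFormatError(f"series {sid}: no data before terminator")
        seen: dict[int, int] = {}
        for yr, v in data:
            if yr in seen:
                raise RWLFormatError(f"duplicate value for series {sid}, year {yr}")
            seen[yr] = v
        years = sorted(seen)
        if years != list(range(years[0], years[-1] + 1)):
            missing = next(y for y in range(years[0], years[-1] + 1) if y not in seen)
            raise RWLFormatError(f"series {sid}: missing year {missing} inside the series")
        values = np.array([seen[y] for y in years], dtype=float) * scale
        out.append(
            MeasurementSeries(
                series_id=sid,
                tree_id=sid,
                core_id=sid,
                parameter="ring_width",
                first_year=years[0],
                values=values,
            )
        )
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def write_rwl(
    series: Iterable[MeasurementSeries],
    path: str | Path,
    precision: float = 0.001,
) -> None:
    """Write ring-width series in decadal Tucson layout.

    ``precision`` is the storage unit in mm (0.001 or 0.01); it selects the
    matching terminator.  Values are rounded half-up to the storage unit.
    """
    if precision not in (0.001, 0.01):
        raise RWLFormatError("precision must be 0.001 or 0.01 mm")
    terminator = -9999 if precision == 0.001 else 999
    lines: list[str] = []
    for s in series:
        if len(s.series_id) > 8:
            raise RWLFormatError(f"series id {s.series_id!r} exceeds 8 characters")
        stored: Sequence[int] = [_round_half_up(v / precision) for v in s.values]
        stream = list(zip(s.years, stored)) + [(s.last_year + 1, terminator)]
        i = 0
        while i < len(stream):
            year = stream[i][0]
            row_end = (year // 10) * 10 + 10  # first year of the next decade
            row = [v for y, v in stream[i:] if y < row_end][: row_end - year]
            lines.append(f"{s.series_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in row))
            i += len(row)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
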