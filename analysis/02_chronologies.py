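"""Standardize all series and build the eight site chronologies.

Each series is detrended with a cubic smoothing spline (50% frequency
response at 50 years) and the annual median of the ratio indices forms the
chronology wherever at least five samples overlap.  Writes one
chronology_<param>.csv per parameter plus the summary-statistics table
(ar1, SD, Gini, RBAR_eff, EPS, SNR) to results/.
"""

from pathlib import Path

import pandas as pd

import cellchron as cc
from cellchron.pipeline import group_series

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    series = cc.read_rwl(DATA / "ringwidth.rwl") + cc.read_cell_table(DATA / "cells.csv")
    # RWL carries no tree metadata: recover tree ids from the Txx[A|B] naming
    for s in series:
        if s.parameter == "ring_width":
            s.tree_id, s.core_id = s.series_id[:-1], s.series_id[-1]

    report = cc.crossdating_correlations(
        [s for s in series if s.parameter == "ring_width"]
    )
    print(f"crossdating check: {len(report.flagged_segments)} flagged segments "
          f"of {len(report.segments)} (threshold {report.threshold})")

    rows = []
    for name, grp in group_series(series).items():
        indices = [cc.detrend(s) for s in grp]
        chron = cc.build_chronology(indices, min_depth=5)
        stats = cc.summarize_chronology(chron, indices)
        pd.DataFrame({
            "year": chron.years, "index": chron.values, "depth": chron.sample_depth,
        }).to_csv(ROOT / f"chronology_{name}.csv", index=False)
        rows.append({
            "parameter": name, "span": f"{chron.first_year}-{chron.last_year}",
            "years": len(chron), "ar1": round(stats.ar1, 3),
            "stdev": round(stats.stdev, 3), "gini": round(stats.gini, 3),
            "rbar_eff": round(stats.rbar_eff, 3), "eps": round(stats.eps, 3),
            "snr": round(stats.snr, 3),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    table.to_csv(ROOT / "stats.csv")
    print(table)
    weak = table[table["snr"] < 1.0].index.tolist()
    print(f"noise-dominated (SNR < 1), excluded from climate calibration: {weak}")


if __name__ == "__main__":
    main()
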