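"""Median-index chronologies and empirical signal-strength statistics.

The site chronology value for year t is the median of all dimensionless
ratio indices available that year, reported only where the sample depth n_t
reaches a minimum (default 5 series).  Signal strength is summarized by the
effective mean inter-series correlation (RBAR_eff), the expressed population
signal (EPS), the signal-to-noise ratio (SNR = EPS / (1 - EPS)), the Gini
coefficient (an all-lag sensitivity measure), the first-order
autocorrelation, and the standard deviation of the chronology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detrend import IndexSeries


class ChronologyError(ValueError):
    pass


@dataclass
class Chronology:
    """Standardized annual index chronology with per-year sample depth."""

    years: np.ndarray
    values: np.ndarray = field(repr=False)
    sample_depth: np.ndarray = field(repr=False)
    min_depth: int = 5

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def __len__(self) -> int:
        return len(self.years)


def build_chronology(
    indices: Sequence[IndexSeries],
    min_depth: int = 5,
    aggregator: str = "median",
) -> Chronology:
    """Aggregate index series into a site chronology.

    Only years where at least ``min_depth`` series overlap are reported; the
    even-count median is the midpoint of the two central values.
    """
    if aggregator not in ("median", "mean"):
        raise ChronologyError(f"unknown aggregator {aggregator!r}")
    if not indices:
        raise ChronologyError("no index series supplied")
    first = min(s.first_year for s in indices)
    last = max(s.last_year for s in indices)
    span = last - first + 1
    mat = np.full((len(indices), span), np.nan)
    for i, s in enumerate(indices):
        mat[i, s.first_year - first : s.first_year - first + len(s)] = s.indices
    depth = np.sum(~np.isnan(mat), axis=0)
    keep = depth >= min_depth
    if not keep.any():
        raise ChronologyError(
            f"no year reaches sample depth {min_depth} (max depth {depth.max()})"
        )
    agg = np.nanmedian if aggregator == "median" else np.nanmean
    values = agg(mat[:, keep], axis=0)
    years = np.arange(first, last + 1)[keep]
    return Chronology(years=years, values=values, sample_depth=depth[keep], min_depth=min_depth)


def _overlap(a: IndexSeries, b: IndexSeries) -> tuple[np.ndarray, np.ndarray]:
    lo = max(a.first_year, b.first_year)
    hi = min(a.last_year, b.last_year)
    if hi < lo:
        return np.empty(0), np.empty(0)
    return (
        a.indices[lo - a.first_year : hi - a.first_year + 1],
        b.indices[lo - b.first_year : hi - b.first_year + 1],
    )


@dataclass
class RbarResult:
    rbar_within: float
    rbar_between: float
    rbar_eff: float
    mean_cores_per_tree: float
    n_pairs_within: int
    n_pairs_between: int
    n_pairs_skipped: int


def rbar_eff(
    indices: Sequence[IndexSeries],
    tree_of: Mapping[str, str] | None = None,
    min_overlap: int = 30,
) -> RbarResult:
    """Effective mean inter-series correlation over maximum pairwise overlaps.

    Each pairwise Pearson correlation uses that pair's full common overlap;
    pairs overlapping fewer than ``min_overlap`` years are skipped (and
    counted).  With c̄ mean cores per tree the effective RBAR is

        rbar_eff = rbar_between / (rbar_within + (1 - rbar_within) / c̄),

    which collapses to the plain between-tree mean when c̄ = 1.
    """
    if len(indices) < 2:
        raise ChronologyError("rbar_eff needs at least two series")
    if tree_of is None:
        tree_of = {s.series_id: s.tree_id for s in indices}
    missing = [s.series_id for s in indices if s.series_id not in tree_of]
    if missing:
        raise ChronologyError(f"tree mapping missing series {missing}")
    within, between = [], []
    skipped = 0
    for a, b in itertools.combinations(indices, 2):
        xa, xb = _overlap(a, b)
        if len(xa) < min_overlap:
            skipped += 1
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        (within if tree_of[a.series_id] == tree_of[b.series_id] else between).append(r)
    if not between:
        raise ChronologyError(
            f"no between-tree pair with overlap >= {min_overlap} years"
        )
    trees: dict[str, int] = {}
    for s in indices:
        trees[tree_of[s.series_id]] = trees.get(tree_of[s.series_id], 0) + 1
    cbar = float(np.mean(list(trees.values())))
    r_bt = float(np.mean(between))
    r_wt = float(np.mean(within)) if within else 1.0  # one core/tree: no within pairs
    eff = r_bt / (r_wt + (1.0 - r_wt) / cbar) if within else r_bt
    return RbarResult(
        rbar_within=r_wt if within else float("nan"),
        rbar_between=r_bt,
        rbar_eff=eff,
        mean_cores_per_tree=cbar,
        n_pairs_within=len(within),
        n_pairs_between=len(between),
        n_pairs_skipped=skipped,
    )


def eps_snr(rbar: float, n_trees_effective: float) -> tuple[float, float]:
    """Expressed population signal and signal-to-noise ratio.

    For n effectively independent trees with mean inter-tree correlation r̄:
    SNR = n r̄ / (1 - r̄) and EPS = SNR / (1 + SNR).
    """
    if not -1 < rbar < 1:
        raise ChronologyError(f"rbar must lie in (-1, 1), got {rbar}")
    if n_trees_effective <= 0:
        raise ChronologyError("n_trees_effective must be positive")
    snr = n_trees_effective * rbar / (1.0 - rbar)
    eps = snr / (1.0 + snr)
    return eps, snr


def snr_from_eps(eps: float) -> float:
    """Invert EPS = SNR / (1 + SNR): SNR = EPS / (1 - EPS)."""
    if not 0 <= eps < 1:
        raise ChronologyError(f"eps must lie in [0, 1), got {eps}")
    return eps / (1.0 - eps)


def gini(values: np.ndarray) -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 mean).

    An all-lag measure of series sensitivity: 0 for a constant series,
    approaching 1 as variability concentrates.  Scale-invariant.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ChronologyError("gini needs a 1-d vector of length >= 2")
    if np.any(x < 0):
        raise ChronologyError("gini requires non-negative values")
    mean = x.mean()
    if mean <= 0:
        raise ChronologyError("gini requires a positive mean")
    # O(n log n) via the sorted-rank identity, equivalent to the pairwise sum
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(np.sum((2 * ranks - n - 1) * xs) / (n * n * mean))


def ar1(values: np.ndarray) -> float:
    """Sample lag-1 autocorrelation (mean-centred cross-product estimator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ChronologyError("ar1 needs at least 3 values")
    d = x - x.mean()
    denom = np.sum(d * d)
    if denom == 0:
        raise ChronologyError("ar1 undefined for a zero-variance series")
    return float(np.sum(d[1:] * d[:-1]) / denom)


@dataclass
class SignalStrengthStats:
    """One chronology's row of summary statistics."""

    ar1: float
    stdev: float
    gini: float
    rbar_eff: float
    eps: float
    snr: float
    n_series: int
    n_trees: int
    mean_cores_per_tree: float
    n_trees_effective: float
    partial: bool = False


def effective_n_trees(
    chronology: Chronology,
    indices: Sequence[IndexSeries],
    tree_of: Mapping[str, str],
    convention: str = "mean-trees",
) -> float:
    """Sample size n used in EPS/SNR.

    ``mean-trees`` (default): mean number of distinct trees present per
    chronology year; ``max-trees``: total number of trees; ``cores``: total
    number of series.  EPS is defined on tree-level signal, so counting
    trees rather than cores is the default.
    """
    if convention == "cores":
        return float(len(indices))
    trees = {tree_of[s.series_id] for s in indices}
    if convention == "max-trees":
        return float(len(trees))
    if convention != "mean-trees":
        raise ChronologyError(f"unknown EPS n convention {convention!r}")
    per_year = np.zeros(len(chronology.years))
    for i, year in enumerate(chronology.years):
        present = {
            tree_of[s.series_id]
            for s in indices
            if s.first_year <= year <= s.last_year
        }
        per_year[i] = len(present)
    return float(per_year.mean())


def summarize_chronology(
    chronology: Chronology,
    indices: Sequence[IndexSeries],
    tree_of: Mapping[str, str] | None = None,
    min_overlap: int = 30,
    eps_n: str = "mean-trees",
) -> SignalStrengthStats:
    """Assemble the full signal-strength battery for one chronology.

    With a single series, RBAR/EPS/SNR are undefined; the record is returned
    with those entries NaN and flagged ``partial``.
    """
    if tree_of is None:
        tree_of = {s.series_id: s.tree_id for s in indices}
    a1 = ar1(chronology.values)
    sd = float(np.std(chronology.values, ddof=1))
    g = gini(chronology.values)
    trees = {tree_of[s.series_id] for s in indices}
    try:
        rb = rbar_eff(indices, tree_of, min_overlap=min_overlap)
    except ChronologyError:
        return SignalStrengthStats(
            ar1=a1, stdev=sd, gini=g,
            rbar_eff=float("nan"), eps=float("nan"), snr=float("nan"),
            n_series=len(indices), n_trees=len(trees),
            mean_cores_per_tree=len(indices) / max(len(trees), 1),
            n_trees_effective=float("nan"), partial=True,
        )
    n_eff = effective_n_trees(chronology, indices, tree_of, convention=eps_n)
    eps, snr = eps_snr(rb.rbar_eff, n_eff)
    return SignalStrengthStats(
        ar1=a1, stdev=sd, gini=g,
        rbar_eff=rb.rbar_eff, eps=eps, snr=snr,
        n_series=len(indices), n_trees=len(trees),
        mean_cores_per_tree=rb.mean_cores_per_tree,
        n_trees_effective=n_eff,
    )
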