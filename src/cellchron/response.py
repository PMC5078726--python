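"""Monthly and seasonal climate signals in a chronology.

Three analyses over the water-year window (previous October through current
September):

* static response functions — the chronology is regressed on principal
  components of the standardized monthly climate predictors, coefficients
  are mapped back to (variable, month) space, and significance comes from
  resampling years with replacement (percentile confidence intervals);
* moving response functions — the same machinery over a sliding window to
  judge temporal stability of the signal;
* seasonal correlation scans — for season lengths of 3-6 months and every
  ending month in the window, the correlation of the chronology with the
  seasonal aggregate of a primary variable, plus the partial correlation
  with a secondary variable controlling for the primary.  Significance is
  judged against AR(1)-matched surrogate chronologies so that the test
  respects the chronology's own persistence.

Month labels follow the dendroclimatological convention: lowercase for
previous-year months ("oct"), uppercase for current-year months ("MAR").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronology import Chronology, ar1
from .tables import ClimateMatrix

_MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec"]


class ResponseError(ValueError):
    pass


def month_label(offset: int) -> str:
    """Label for a water-year month offset (0 = previous October).

    Offsets may run negative (months before previous October) for seasonal
    scans; previous-year months are lowercase, current-year uppercase.
    """
    month = (9 + offset) % 12 + 1
    prev = (9 + offset) < 12
    name = _MONTH_ABBR[month - 1]
    return name if prev else name.upper()


def _offset_matrix(
    climate: ClimateMatrix, years: np.ndarray, variable: str,
    offsets: range,
) -> np.ndarray:
    """Matrix (len(years) x len(offsets)) of monthly values.

    Offset o maps chronology year y to calendar month (9 + o) % 12 + 1 of
    year y - 1 + (9 + o) // 12.
    """
    wide = climate.monthly(variable)
    out = np.empty((len(years), len(offsets)))
    for j, o in enumerate(offsets):
        month = (9 + o) % 12 + 1
        yshift = (9 + o) // 12 - 1
        col = wide[month]
        want = years + yshift
        missing = [int(y) for y in want if y not in col.index]
        if missing:
            raise ResponseError(
                f"climate coverage gap: need ({missing[0]}, {month}) "
                f"for {variable}"
            )
        out[:, j] = col.loc[want].to_numpy()
    return out


def monthly_design_matrix(
    climate: ClimateMatrix,
    years: np.ndarray,
    variables: tuple[str, ...] = ("ppt", "tmean"),
) -> pd.DataFrame:
    """Water-year design matrix: 12 monthly columns per climate variable.

    Row y holds the months previous-October(y-1) through current-September(y).
    Columns are a MultiIndex of (variable, month label).
    """
    years = np.asarray(years, dtype=int)
    if np.any(np.diff(years) <= 0):
        raise ResponseError("years must be strictly increasing")
    blocks, columns = [], []
    for var in variables:
        blocks.append(_offset_matrix(climate, years, var, range(12)))
        columns.extend((var, month_label(o)) for o in range(12))
    return pd.DataFrame(
        np.hstack(blocks),
        index=pd.Index(years, name="year"),
        columns=pd.MultiIndex.from_tuples(columns, names=["variable", "month"]),
    )


def _standardize(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (mat - mu) / sd


def _pc_regression(x: np.ndarray, y: np.ndarray, pc_rule: str) -> np.ndarray:
    """Back-transformed response coefficients for standardized x, y.

    Principal components of the predictor correlation matrix are retained
    by the eigenvalue-product rule (keep the first m while the running
    product of eigenvalues exceeds 1) or the Kaiser rule (eigenvalue > 1);
    the chronology is regressed on the retained scores and the coefficient
    vector is rotated back through the loadings.
    """
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    if pc_rule == "pvp":
        prod = np.cumprod(eig)
        m = int(np.sum(prod >= 1.0 - 1e-9))
    elif pc_rule == "kaiser":
        m = int(np.sum(eig > 1.0))
    else:
        raise ResponseError(f"unknown pc_rule {pc_rule!r}")
    if m < 1:
        raise ResponseError("no principal component retained (leading eigenvalue <= 1)")
    scores = x @ vt[:m].T
    b, *_ = np.linalg.lstsq(scores, y, rcond=None)
    return vt[:m].T @ b


@dataclass
class ResponseFunctionResult:
    """Monthly response coefficients with bootstrap confidence intervals."""

    table: pd.DataFrame          # rows (variable, month): coefficient, median, ci, flag
    n_boot: int
    n_pcs: int
    seed: int | None
    years: tuple[int, int]

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]


def response_function(
    chronology: Chronology,
    design: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    pc_rule: str = "pvp",
    ci: float = 0.95,
) -> ResponseFunctionResult:
    """Bootstrapped principal-component response function.

    Predictors and chronology are standardized over the analysis years; the
    full estimation (standardization, PCA, retention, regression) is
    repeated on every bootstrap draw of years with replacement, and a month
    is significant iff its percentile interval excludes zero.
    """
    if n_boot < 100:
        raise ResponseError("n_boot must be >= 100")
    chron = pd.Series(chronology.values, index=chronology.years)
    years = design.index.intersection(chron.index)
    if len(years) < 30:
        raise ResponseError(f"only {len(years)} overlapping years; need >= 30")
    x_raw = design.loc[years].to_numpy(dtype=float)
    y_raw = chron.loc[years].to_numpy(dtype=float)
    if np.linalg.matrix_rank(x_raw - x_raw.mean(axis=0)) < min(x_raw.shape) and (
        x_raw.shape[1] < x_raw.shape[0]
    ):
        raise ResponseError("design matrix is rank deficient")
    x = _standardize(x_raw)
    y = _standardize(y_raw[:, None])[:, 0]
    coef = _pc_regression(x, y, pc_rule)
    n = len(years)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    n_pcs = int(np.sum(np.cumprod(eig) >= 1.0 - 1e-9)) if pc_rule == "pvp" else int(np.sum(eig > 1.0))

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, x.shape[1]))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb = _standardize(x_raw[idx])
        yb = y_raw[idx]
        ysd = yb.std(ddof=1)
        yb = (yb - yb.mean()) / (ysd if ysd > 0 else 1.0)
        boots[i] = _pc_regression(xb, yb, pc_rule)
    alpha = 1.0 - ci
    lo = np.percentile(boots, 100 * alpha / 2, axis=0)
    hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
    med = np.median(boots, axis=0)
    table = pd.DataFrame(
        {
            "coefficient": coef,
            "boot_median": med,
            "ci_lower": lo,
            "ci_upper": hi,
            "significant": (lo > 0) | (hi < 0),
        },
        index=design.columns,
    )
    return ResponseFunctionResult(
        table=table, n_boot=n_boot, n_pcs=n_pcs, seed=seed,
        years=(int(years[0]), int(years[-1])),
    )


@dataclass
class MovingResponseResult:
    """Response coefficients over sliding windows, labelled by start year."""

    tables: dict[int, pd.DataFrame]
    window: int
    step: int
    n_boot: int
    seed: int | None

    def grid(self, column: str = "coefficient") -> pd.DataFrame:
        """(window start year) x (variable, month) matrix of one column."""
        return pd.DataFrame({start: t[column] for start, t in self.tables.items()}).T


def moving_response(
    chronology: Chronology,
    design: pd.DataFrame,
    window: int = 30,
    step: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
    pc_rule: str = "pvp",
) -> MovingResponseResult:
    """Static response function applied to each sliding window of years.

    Each window reuses the same seed, so a window equal to the full span
    reproduces the static result exactly.
    """
    chron = pd.Series(chronology.values, index=chronology.years)
    years = design.index.intersection(chron.index)
    if len(years) < window:
        raise ResponseError(f"span {len(years)} shorter than window {window}")
    tables: dict[int, pd.DataFrame] = {}
    for i in range(0, len(years) - window + 1, step):
        wyears = years[i : i + window]
        sub_design = design.loc[wyears]
        sub_chron = Chronology(
            years=np.asarray(wyears),
            values=chron.loc[wyears].to_numpy(),
            sample_depth=np.zeros(window, dtype=int),
            min_depth=0,
        )
        res = response_function(
            sub_chron, sub_design, n_boot=n_boot, seed=seed, pc_rule=pc_rule
        )
        tables[int(wyears[0])] = res.table
    return MovingResponseResult(
        tables=tables, window=window, step=step, n_boot=n_boot, seed=seed
    )


@dataclass
class SeasonalCorrelationResult:
    """Grid of seasonal correlations and secondary partial correlations."""

    table: pd.DataFrame     # rows (length, ending label)
    primary: str
    secondary: str
    n_surrogates: int
    seed: int | None

    def best(self) -> pd.Series:
        """Cell with the largest primary correlation."""
        return self.table.loc[self.table["r_primary"].idxmax()]


def partial_correlation(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """Correlation of x and y after removing the control variable.

    Computed from the pairwise correlations:
    r_xy.c = (r_xy - r_xc r_yc) / sqrt((1 - r_xc^2)(1 - r_yc^2)).
    """
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xc = np.corrcoef(x, control)[0, 1]
    r_yc = np.corrcoef(y, control)[0, 1]
    denom_sq = (1 - r_xc**2) * (1 - r_yc**2)
    if denom_sq < 1e-14:  # an argument is collinear with the control
        return 0.0
    return float(np.clip((r_xy - r_xc * r_yc) / np.sqrt(denom_sq), -1.0, 1.0))


def _ar1_surrogates(values: np.ndarray, n_surrogates: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Surrogate series matching the sample lag-1 autocorrelation and variance."""
    phi = float(np.clip(ar1(values), -0.99, 0.99))
    n = len(values)
    sd = values.std(ddof=1)
    out = np.empty((n_surrogates, n))
    out[:, 0] = rng.normal(size=n_surrogates)
    innov = rng.normal(0.0, np.sqrt(1 - phi**2), size=(n_surrogates, n))
    for t in range(1, n):
        out[:, t] = phi * out[:, t - 1] + innov[:, t]
    return out * sd


def seasonal_partial_correlations(
    chronology: Chronology,
    climate: ClimateMatrix,
    primary: str = "ppt",
    secondary: str = "tmean",
    lengths: tuple[int, ...] = (3, 4, 5, 6),
    years: tuple[int, int] | None = None,
    n_surrogates: int = 1000,
    seed: int | None = None,
    method: str = "surrogate",
    alpha: float = 0.05,
) -> SeasonalCorrelationResult:
    """Seasonal correlation scan over the water-year window.

    For every season length L and every ending month from previous October
    to current September, the primary statistic is the correlation between
    the chronology and the seasonal aggregate of the primary variable (sum
    for precipitation, mean for temperature); the secondary statistic is
    the partial correlation with the secondary variable's aggregate,
    controlling for the primary.  Surrogate significance (default) draws
    AR(1)-matched chronology surrogates; ``method="t"`` uses the usual
    t-distribution test instead.
    """
    for L in lengths:
        if not 1 <= L <= 12:
            raise ResponseError(f"season length {L} outside 1-12")
    if method == "surrogate" and n_surrogates < 100:
        raise ResponseError("n_surrogates must be >= 100")
    chron = pd.Series(chronology.values, index=chronology.years)
    if years is not None:
        sel = np.arange(years[0], years[1] + 1)
        missing = [int(y) for y in sel if y not in chron.index]
        if missing:
            raise ResponseError(f"chronology does not cover year {missing[0]}")
        chron = chron.loc[sel]
    yrs = chron.index.to_numpy()
    max_back = max(lengths) - 1
    offsets = range(-max_back, 12)
    prim_mat = _offset_matrix(climate, yrs, primary, offsets)
    sec_mat = _offset_matrix(climate, yrs, secondary, offsets)
    agg_primary = "sum" if primary == "ppt" else "mean"
    agg_secondary = "sum" if secondary == "ppt" else "mean"

    y = chron.to_numpy()
    yc = y - y.mean()
    n = len(y)

    rng = np.random.default_rng(seed)
    if method == "surrogate":
        surr = _ar1_surrogates(y, n_surrogates, rng)
        surr_c = surr - surr.mean(axis=1, keepdims=True)
        surr_n = surr_c / np.linalg.norm(surr_c, axis=1, keepdims=True)
    elif method != "t":
        raise ResponseError(f"unknown significance method {method!r}")

    rows = []
    for L in lengths:
        for end in range(12):
            cols = slice(end - L + 1 + max_back, end + 1 + max_back)
            g = prim_mat[:, cols].sum(axis=1) if agg_primary == "sum" else prim_mat[:, cols].mean(axis=1)
            h = sec_mat[:, cols].sum(axis=1) if agg_secondary == "sum" else sec_mat[:, cols].mean(axis=1)
            r_prim = float(np.corrcoef(y, g)[0, 1])
            r_part = partial_correlation(y, h, g)
            if method == "surrogate":
                gc = g - g.mean()
                gn = gc / np.linalg.norm(gc)
                surr_r = surr_n @ gn
                lo, hi = np.percentile(surr_r, [100 * alpha / 2, 100 * (1 - alpha / 2)])
                sig_prim = bool(r_prim < lo or r_prim > hi)
                hc = h - h.mean()
                r_sg = surr_r
                r_sh = surr_n @ (hc / np.linalg.norm(hc))
                r_gh = float(np.corrcoef(g, h)[0, 1])
                denom = np.sqrt(np.clip((1 - r_sg**2) * (1 - r_gh**2), 1e-12, None))
                surr_part = (r_sh - r_sg * r_gh) / denom
                plo, phi_ = np.percentile(surr_part, [100 * alpha / 2, 100 * (1 - alpha / 2)])
                sig_part = bool(r_part < plo or r_part > phi_)
            else:
                from scipy import stats

                t_prim = r_prim * np.sqrt((n - 2) / max(1 - r_prim**2, 1e-12))
                sig_prim = bool(2 * stats.t.sf(abs(t_prim), n - 2) < alpha)
                t_part = r_part * np.sqrt((n - 3) / max(1 - r_part**2, 1e-12))
                sig_part = bool(2 * stats.t.sf(abs(t_part), n - 3) < alpha)
            start_off = end - L + 1
            rows.append(
                {
                    "length": L,
                    "ending": month_label(end),
                    "start": month_label(start_off),
                    "ending_month": (9 + end) % 12 + 1,
                    "ending_prev_year": (9 + end) < 12,
                    "r_primary": r_prim,
                    "sig_primary": sig_prim,
                    "r_partial_secondary": r_part,
                    "sig_secondary": sig_part,
                }
            )
    table = pd.DataFrame(rows).set_index(["length", "ending"])
    return SeasonalCorrelationResult(
        table=table, primary=primary, secondary=secondary,
        n_surrogates=n_surrogates if method == "surrogate" else 0, seed=seed,
    )
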