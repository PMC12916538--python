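"""Per-cell monotonic trend detection on annual habitat-suitability series.

The Mann-Kendall test compares every value of a time series with every
earlier value and accumulates the signs of the differences into the
statistic ``S``; under the no-trend null, ``S`` is asymptotically normal
with a variance that is corrected for tied values.  Sen's slope — the
median of all pairwise slopes — gives a robust trend magnitude in HSI
units per year.  Years enter as integer offsets 0..T-1.

The normal approximation (with the +/-1 continuity correction) is standard
for annual series of the length used here (T >= 10); no exact small-n table
is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import Grid, RasterLayer


@dataclass
class TrendMap:
    """Per-cell Sen slope and Mann-Kendall significance for one species.

    ``s_statistic`` and ``n_effective`` are flat per-cell integer arrays;
    cells with fewer than 3 usable years are flagged missing in both the
    slope and p-value layers.
    """

    species_id: str
    grid: Grid
    slope: RasterLayer
    p_value: RasterLayer
    s_statistic: np.ndarray
    n_effective: np.ndarray

    def kept_cells(self) -> np.ndarray:
        """Cell ids with a defined (non-missing) trend."""
        return np.flatnonzero(~self.p_value.is_missing())


def mann_kendall_matrix(X: np.ndarray):
    """Column-wise Mann-Kendall test on an (n_times, n_series) matrix.

    Returns ``(S, var_S, z, p)`` arrays of length ``n_series``.  The tie
    correction subtracts sum(t(t-1)(2t+5)) over groups of t tied values;
    all-tied columns get var_S = 0 and p = 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 time points")

    S = np.zeros(m)
    # e[i] = number of series values equal to x_i (including itself);
    # tie term = 18 * (#tied pairs) + 12 * (#tied triples)
    eq_count = np.ones((n, m))
    for i in range(n - 1):
        d = X[i + 1:] - X[i]
        S += np.sign(d).sum(axis=0)
        eq = d == 0
        eq_count[i] += eq.sum(axis=0)
        eq_count[i + 1:] += eq
    tied_pairs = (eq_count - 1).sum(axis=0) / 2.0
    tied_triples = ((eq_count - 1) * (eq_count - 2) / 2.0).sum(axis=0) / 3.0
    tie_term = 18.0 * tied_pairs + 12.0 * tied_triples

    var_S = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    var_S = np.maximum(var_S, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(S > 0, S - 1, np.where(S < 0, S + 1, 0.0)) / np.sqrt(var_S)
    z = np.where(var_S == 0, 0.0, z)
    p = np.where(var_S == 0, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return S, var_S, z, p


def mann_kendall(series) -> tuple:
    """Mann-Kendall test for a single series: ``(S, var_S, z, p)``."""
    S, v, z, p = mann_kendall_matrix(np.asarray(series, dtype=float)[:, None])
    return float(S[0]), float(v[0]), float(z[0]), float(p[0])


def sen_slope_matrix(X: np.ndarray, times=None) -> np.ndarray:
    """Column-wise Sen slope: median of (x_j - x_i)/(t_j - t_i) over i < j."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if n < 2:
        raise ValueError("Sen slope needs at least 2 time points")
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    slopes = np.empty((n * (n - 1) // 2, m))
    k = 0
    for i in range(n - 1):
        cnt = n - 1 - i
        slopes[k:k + cnt] = (X[i + 1:] - X[i]) / (t[i + 1:, None] - t[i])
        k += cnt
    return np.median(slopes, axis=0)


def sen_slope(series, times=None) -> float:
    return float(sen_slope_matrix(np.asarray(series, dtype=float)[:, None], times)[0])


def trend_map(hsi) -> TrendMap:
    """Cellwise Mann-Kendall + Sen slope over an annual HSI stack.

    ``hsi`` is an :class:`~hstrend.maxent.HsiSeries`.  Cells missing in
    some years are evaluated on their non-missing years (with the years'
    integer offsets as abscissae); cells with fewer than 3 usable years are
    flagged missing.
    """
    grid = hsi.grid
    years = list(hsi.years)
    if len(years) < 3:
        raise ValueError("trend analysis needs at least 3 annual layers")
    nodata = hsi.hsi[years[0]].nodata
    M = np.stack([hsi.hsi[y].values for y in years])  # (T, n_cells)
    missing = M == nodata
    n_eff = (~missing).sum(axis=0)

    slope = np.full(grid.n_cells, nodata)
    p_val = np.full(grid.n_cells, nodata)
    s_stat = np.zeros(grid.n_cells, dtype=int)

    complete = np.flatnonzero(n_eff == len(years))
    if complete.size:
        S, _, _, p = mann_kendall_matrix(M[:, complete])
        slope[complete] = sen_slope_matrix(M[:, complete])
        p_val[complete] = p
        s_stat[complete] = S.astype(int)

    partial = np.flatnonzero((n_eff >= 3) & (n_eff < len(years)))
    offsets = np.arange(len(years), dtype=float)
    for c in partial:
        keep = ~missing[:, c]
        s, _, _, p = mann_kendall(M[keep, c])
        slope[c] = sen_slope(M[keep, c], times=offsets[keep])
        p_val[c] = p
        s_stat[c] = int(s)

    return TrendMap(
        species_id=hsi.species_id,
        grid=grid,
        slope=RasterLayer(grid, slope, nodata=nodata),
        p_value=RasterLayer(grid, p_val, nodata=nodata),
        s_statistic=s_stat,
        n_effective=n_eff,
    )
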