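"""Annual aggregation and collinearity screening of candidate predictors.

Screening follows the usual two-stage recipe: iteratively drop the
predictor with the largest variance inflation factor (VIF = 1/(1-R^2) of
its regression on the others) until all VIFs fall below the threshold,
then break remaining high-correlation pairs (|Pearson r| above threshold)
by dropping the pair member with the higher mean absolute correlation to
everything still retained.  Both steps are deterministic: ties are broken
by candidate-list order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, RasterLayer, PredictorStack


@dataclass
class CollinearityReport:
    retained: list
    dropped: list = field(default_factory=list)  # (name, reason, statistic)
    vif: dict = field(default_factory=dict)
    pearson: np.ndarray | None = None  # among retained, candidate order

    @property
    def dropped_names(self) -> list:
        return [d[0] for d in self.dropped]


def annual_mean(sub_annual) -> RasterLayer:
    """Cellwise mean of sub-annual layers, ignoring nodata.

    A cell is nodata in the output only if it is nodata in every input.
    """
    if not sub_annual:
        raise ValueError("annual_mean needs at least one layer")
    grid = sub_annual[0].grid
    nodata = sub_annual[0].nodata
    for lyr in sub_annual[1:]:
        if not lyr.grid.same_geometry(grid):
            raise ValueError("annual_mean: layers on different grids")
    M = np.stack([lyr.values for lyr in sub_annual])
    miss = np.stack([lyr.is_missing() for lyr in sub_annual])
    cnt = (~miss).sum(axis=0)
    total = np.where(miss, 0.0, M).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, total / np.maximum(cnt, 1), nodata)
    out_mask = grid.valid_mask.ravel() & (cnt > 0)
    out_grid = Grid(grid.n_rows, grid.n_cols, grid.origin_x, grid.origin_y,
                    grid.cell_size, out_mask.reshape(grid.n_rows, grid.n_cols))
    return RasterLayer(out_grid, mean, nodata=nodata)


def block_mean_resample(fine: RasterLayer, coarse_grid: Grid) -> RasterLayer:
    """Aggregate a fine raster to a coarser aligned grid by block means.

    The coarse cell size must be an integer multiple of the fine cell size
    and the two origins must coincide; each coarse cell is the
    nodata-ignoring mean of the fine cells it covers.
    """
    fg = fine.grid
    ratio = coarse_grid.cell_size / fg.cell_size
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError("coarse cell size must be an integer multiple of fine")
    if not (np.isclose(fg.origin_x, coarse_grid.origin_x)
            and np.isclose(fg.origin_y, coarse_grid.origin_y)):
        raise ValueError("block_mean_resample: origins not aligned")
    if fg.n_rows != coarse_grid.n_rows * k or fg.n_cols != coarse_grid.n_cols * k:
        raise ValueError("fine grid does not tile the coarse grid")
    V = fine.as_2d()
    miss = fine.is_missing().reshape(fg.n_rows, fg.n_cols)
    blocks = V.reshape(coarse_grid.n_rows, k, coarse_grid.n_cols, k)
    bmiss = miss.reshape(coarse_grid.n_rows, k, coarse_grid.n_cols, k)
    cnt = (~bmiss).sum(axis=(1, 3))
    total = np.where(bmiss, 0.0, blocks).sum(axis=(1, 3))
    mean = np.where(cnt > 0, total / np.maximum(cnt, 1), fine.nodata)
    mask = coarse_grid.valid_mask & (cnt > 0)
    out_grid = Grid(coarse_grid.n_rows, coarse_grid.n_cols, coarse_grid.origin_x,
                    coarse_grid.origin_y, coarse_grid.cell_size, mask)
    return RasterLayer(out_grid, mean.ravel(), nodata=fine.nodata)


def vif_scores(X: np.ndarray) -> np.ndarray:
    """VIF of each column of X: 1/(1-R^2) of its regression on the rest
    (with intercept).  A single column has VIF 1; a perfectly predictable
    column gets +inf.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p == 1:
        return np.ones(1)
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        A = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _pooled_matrix(stack: PredictorStack, pooling: str) -> np.ndarray:
    arr = stack.array()  # (T, P, C)
    if pooling == "pooled":
        T, P, C = arr.shape
        return arr.transpose(0, 2, 1).reshape(T * C, P)
    if pooling == "cell-mean":
        return arr.mean(axis=0).T  # (C, P)
    raise ValueError(f"unknown pooling {pooling!r}")


def screen_collinearity(stack: PredictorStack, vif_threshold: float = 4.0,
                        r_threshold: float = 0.75,
                        pooling: str = "pooled") -> CollinearityReport:
    """Screen predictors for multicollinearity over pooled cell-year samples.

    ``pooling='pooled'`` stacks all years' valid-cell values (the default);
    ``'cell-mean'`` uses the per-cell multi-year mean instead.
    """
    names = list(stack.predictor_names)
    if len(names) < 2:
        raise ValueError("screening needs at least 2 predictors")
    X = _pooled_matrix(stack, pooling)

    dropped = []
    keep = list(range(len(names)))

    # degenerate predictors: too few samples or no variance
    for j in list(keep):
        col = X[:, j]
        if col.size < 2 or np.std(col) == 0:
            dropped.append((names[j], "degenerate", float("nan")))
            keep.remove(j)

    # stage 1: greedy max-VIF elimination
    while len(keep) >= 2:
        v = vif_scores(X[:, keep])
        worst = int(np.argmax(v))  # argmax returns first max -> list-order tie-break
        if v[worst] < vif_threshold:
            break
        dropped.append((names[keep[worst]], "vif", float(v[worst])))
        keep.pop(worst)

    # stage 2: break remaining high-|r| pairs
    while len(keep) >= 2:
        R = np.corrcoef(X[:, keep], rowvar=False)
        A = np.abs(R)
        np.fill_diagonal(A, 0.0)
        i, j = np.unravel_index(np.argmax(A), A.shape)
        if A[i, j] < r_threshold:
            break
        mean_i, mean_j = A[i].mean(), A[j].mean()
        # drop the member more correlated with everything else;
        # on a tie keep the earlier-listed candidate
        loser = j if mean_j >= mean_i else i
        dropped.append((names[keep[loser]], "pearson", float(R[i, j])))
        keep.pop(loser)

    retained = [names[j] for j in keep]
    vif = {}
    if keep:
        v = vif_scores(X[:, keep])
        vif = {names[j]: float(vv) for j, vv in zip(keep, v)}
    pearson = np.corrcoef(X[:, keep], rowvar=False) if len(keep) >= 2 else None
    return CollinearityReport(retained=retained, dropped=dropped, vif=vif,
                              pearson=pearson)
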