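"""Masking, aggregation and group comparison of habitat-suitability trends.

Trend maps are masked in two steps — keep only cells with a statistically
significant monotonic trend (p < alpha, strict), then only cells inside
the species' distribution range — and summarized as the proportions of
significant cells with negative and positive Sen slopes.  The negative
proportion is the vulnerability metric: the share of a species' trending
habitat that is deteriorating.  Group-level figures pool significant
pixels across the group's species (a cell counts once per species
covering it); a mean-of-species variant is provided for robustness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .grid import Grid, RasterLayer, OccurrenceSet
from .trends import TrendMap

logger = logging.getLogger("hstrend")


@dataclass
class SpeciesRange:
    species_id: str
    cells: set

    def __post_init__(self):
        self.cells = set(int(c) for c in self.cells)


@dataclass
class VulnerabilitySummary:
    """Vulnerability statistics for one species or one group."""

    unit_id: str
    n_cells_range: int
    n_cells_significant: int
    n_neg: int
    n_pos: int
    n_zero: int
    prop_neg: float | None
    prop_pos: float | None
    mean_slope: float | None
    sd_slope: float | None

    def __post_init__(self):
        assert self.n_neg + self.n_pos + self.n_zero == self.n_cells_significant


def species_range(sp: OccurrenceSet, grid: Grid, method: str = "convex-hull",
                  buffer_cells: int = 2) -> SpeciesRange:
    """Approximate a species' distribution range on the grid.

    ``convex-hull`` (default): all valid cells whose centroids lie in the
    convex hull of the occurrence centroids; degenerate (collinear)
    occurrence sets fall back to the buffer method with a warning.
    ``buffer``: cells within Chebyshev distance ``buffer_cells`` (in cell
    units) of an occurrence.  ``occupied-cells``: the occurrences only.
    """
    occ = sp.sorted_cells()
    if method == "occupied-cells":
        return SpeciesRange(sp.species_id, set(occ.tolist()))
    if method == "buffer":
        return _buffer_range(sp, grid, buffer_cells)
    if method != "convex-hull":
        raise ValueError(f"unknown range method {method!r}")
    x, y = grid.cell_centroid_xy(occ)
    pts = np.column_stack([x, y])
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        logger.warning("%s: degenerate occurrence geometry, falling back to "
                       "buffer range", sp.species_id)
        return _buffer_range(sp, grid, buffer_cells)
    vid = grid.valid_cell_ids()
    cx, cy = grid.cell_centroid_xy(vid)
    P = np.column_stack([cx, cy])
    # half-space test: A p + b <= 0 for all hull facets (tolerance keeps
    # boundary centroids, hence all occurrences, inside)
    A, b = hull.equations[:, :-1], hull.equations[:, -1]
    inside = (P @ A.T + b <= 1e-9).all(axis=1)
    cells = set(vid[inside].tolist()) | set(occ.tolist())
    return SpeciesRange(sp.species_id, cells)


def _buffer_range(sp: OccurrenceSet, grid: Grid, buffer_cells: int) -> SpeciesRange:
    occ = sp.sorted_cells()
    orow, ocol = grid.cell_to_rowcol(occ)
    vid = grid.valid_cell_ids()
    vrow, vcol = grid.cell_to_rowcol(vid)
    cheb = np.maximum(np.abs(vrow[:, None] - orow[None, :]),
                      np.abs(vcol[:, None] - ocol[None, :])).min(axis=1)
    return SpeciesRange(sp.species_id, set(vid[cheb <= buffer_cells].tolist()))


def mask_trends(tm: TrendMap, rng: SpeciesRange, alpha: float = 0.05) -> TrendMap:
    """Keep cells with p < alpha (strict) that lie inside the range."""
    grid = tm.grid
    nodata = tm.p_value.nodata
    in_range = np.zeros(grid.n_cells, dtype=bool)
    in_range[np.fromiter(rng.cells, dtype=int, count=len(rng.cells))] = True
    defined = ~tm.p_value.is_missing()
    keep = defined & in_range & (tm.p_value.values < alpha)
    slope = np.where(keep, tm.slope.values, nodata)
    p = np.where(keep, tm.p_value.values, nodata)
    return TrendMap(tm.species_id, grid,
                    RasterLayer(grid, slope, nodata=nodata),
                    RasterLayer(grid, p, nodata=nodata),
                    np.where(keep, tm.s_statistic, 0),
                    np.where(keep, tm.n_effective, 0))


def species_summary(masked: TrendMap, rng: SpeciesRange) -> VulnerabilitySummary:
    """Count negative/positive/zero significant cells and slope moments.

    An exactly zero slope on a significant cell counts as ``n_zero`` and
    is excluded from both proportions; proportions are undefined (None)
    when no cell is significant.
    """
    kept = masked.kept_cells()
    slopes = masked.slope.values[kept]
    n_sig = kept.size
    n_neg = int((slopes < 0).sum())
    n_pos = int((slopes > 0).sum())
    n_zero = n_sig - n_neg - n_pos
    return VulnerabilitySummary(
        unit_id=masked.species_id,
        n_cells_range=len(rng.cells),
        n_cells_significant=n_sig,
        n_neg=n_neg, n_pos=n_pos, n_zero=n_zero,
        prop_neg=n_neg / n_sig if n_sig else None,
        prop_pos=n_pos / n_sig if n_sig else None,
        mean_slope=float(slopes.mean()) if n_sig else None,
        sd_slope=float(slopes.std(ddof=1)) if n_sig > 1 else None,
    )


def group_aggregate(members, unit_id: str = "group", mode: str = "pooled"):
    """Aggregate species-level results into one group summary plus rasters.

    ``members`` is a list of (summary, masked TrendMap, SpeciesRange).
    ``pooled`` (default) sums significant-pixel counts over species before
    taking proportions — a cell contributes once per species covering it;
    ``mean-of-species`` averages per-species proportions unweighted.
    The returned rasters are the cellwise mean and (sample) SD of the
    species' masked slopes, over the species whose map keeps each cell.

    Returns ``(VulnerabilitySummary, mean_slope_layer, sd_slope_layer)``.
    """
    if not members:
        raise ValueError("group_aggregate needs at least one species")
    grid = members[0][1].grid
    nodata = members[0][1].slope.nodata

    n_range = sum(s.n_cells_range for s, _, _ in members)
    n_sig = sum(s.n_cells_significant for s, _, _ in members)
    n_neg = sum(s.n_neg for s, _, _ in members)
    n_pos = sum(s.n_pos for s, _, _ in members)
    n_zero = sum(s.n_zero for s, _, _ in members)

    slope_stack = np.stack([tm.slope.values for _, tm, _ in members])
    kept_stack = np.stack([~tm.slope.is_missing() for _, tm, _ in members])
    cnt = kept_stack.sum(axis=0)
    with np.errstate(invalid="ignore"):
        tot = np.where(kept_stack, slope_stack, 0.0).sum(axis=0)
        mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), nodata)
        sq = np.where(kept_stack, (slope_stack - np.where(cnt > 0, mean, 0.0)) ** 2,
                      0.0).sum(axis=0)
        sd = np.where(cnt > 1, np.sqrt(sq / np.maximum(cnt - 1, 1)), nodata)

    mask = (cnt > 0).reshape(grid.n_rows, grid.n_cols) & grid.valid_mask
    out_grid = Grid(grid.n_rows, grid.n_cols, grid.origin_x, grid.origin_y,
                    grid.cell_size, mask)
    mean_layer = RasterLayer(out_grid, mean, nodata=nodata)
    sd_mask = (cnt > 1).reshape(grid.n_rows, grid.n_cols) & grid.valid_mask
    sd_layer = RasterLayer(
        Grid(grid.n_rows, grid.n_cols, grid.origin_x, grid.origin_y,
             grid.cell_size, sd_mask), sd, nodata=nodata)

    if mode == "pooled":
        prop_neg = n_neg / n_sig if n_sig else None
        prop_pos = n_pos / n_sig if n_sig else None
    elif mode == "mean-of-species":
        props = [(s.prop_neg, s.prop_pos) for s, _, _ in members
                 if s.prop_neg is not None]
        prop_neg = float(np.mean([p for p, _ in props])) if props else None
        prop_pos = float(np.mean([q for _, q in props])) if props else None
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")

    all_kept = slope_stack[kept_stack]
    summary = VulnerabilitySummary(
        unit_id=unit_id,
        n_cells_range=n_range,
        n_cells_significant=n_sig,
        n_neg=n_neg, n_pos=n_pos, n_zero=n_zero,
        prop_neg=prop_neg, prop_pos=prop_pos,
        mean_slope=float(all_kept.mean()) if all_kept.size else None,
        sd_slope=float(all_kept.std(ddof=1)) if all_kept.size > 1 else None,
    )
    return summary, mean_layer, sd_layer


def compare_groups(prop_neg_by_species: dict, grouping: dict):
    """One-way ANOVA + Tukey HSD on per-species negative-trend proportions.

    ``grouping`` maps species_id -> group label.  Species with undefined
    proportions are dropped.  Returns ``(F, p, tukey)`` where tukey is a
    list of ((group_a, group_b), mean_difference, p_adjusted); F and p are
    NaN when the within-group variance is zero everywhere.
    """
    values, labels = [], []
    for sp, prop in prop_neg_by_species.items():
        if prop is None or sp not in grouping:
            continue
        values.append(float(prop))
        labels.append(grouping[sp])
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least 2 groups")
    arrays = [np.array([v for v, l in zip(values, labels) if l == g])
              for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("compare_groups needs >= 2 species per group")
    if all(a.std() == 0 for a in arrays):
        logger.warning("compare_groups: zero within-group variance, F undefined")
        return float("nan"), float("nan"), []
    F, p = stats.f_oneway(*arrays)
    tuk = pairwise_tukeyhsd(np.asarray(values), np.asarray(labels))
    pairs = list(combinations(tuk.groupsunique, 2))
    tukey = [
        ((str(a), str(b)), float(diff), float(padj))
        for (a, b), diff, padj in zip(pairs, tuk.meandiffs, tuk.pvalues)
    ]
    return float(F), float(p), tukey


def conservation_tables(members_by_species: dict, statuses: dict,
                        mode: str = "pooled"):
    """Group summaries per IUCN status code, for one assessment level.

    ``members_by_species`` maps species_id -> (summary, masked, range);
    ``statuses`` maps species_id -> IUCN code.  Returns a dict code ->
    VulnerabilitySummary covering the codes present.
    """
    from .grid import IUCN_CODES
    by_code = {}
    for sp, code in statuses.items():
        if code not in IUCN_CODES:
            raise ValueError(f"unknown IUCN code {code!r} for species {sp}")
        by_code.setdefault(code, []).append(members_by_species[sp])
    out = {}
    for code in sorted(by_code):
        summary, _, _ = group_aggregate(by_code[code], unit_id=code, mode=mode)
        out[code] = summary
    return out
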