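import numpy as np
import pytest

from hstrend import (Grid, RasterLayer, OccurrenceSet, TrendMap,
                     species_range, mask_trends, species_summary,
                     group_aggregate, compare_groups, conservation_tables)


def make_trend_map(grid, slopes, pvals, species_id="sp"):
    return TrendMap(species_id, grid,
                    RasterLayer(grid, np.asarray(slopes, dtype=float)),
                    RasterLayer(grid, np.asarray(pvals, dtype=float)),
                    np.zeros(grid.n_cells, dtype=int),
                    np.full(grid.n_cells, 23))


@pytest.fixture
def grid10():
    return Grid(10, 10, origin_y=10.0)


def point_in_polygon(px, py, poly):
    """Ray-casting point-in-polygon (closed polygon, counterclockwise)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


class TestSpeciesRange:
    def test_rectangle_hull_encloses_interior(self, grid10):
        corners = {grid10.rowcol_to_cell(r, c)
                   for r, c in [(1, 1), (1, 7), (6, 1), (6, 7)]}
        sp = OccurrenceSet("sp", corners)
        rng = species_range(sp, grid10, method="convex-hull")
        expect = {grid10.rowcol_to_cell(r, c)
                  for r in range(1, 7) for c in range(1, 8)}
        assert rng.cells == expect

    def test_occupied_cells_method(self, grid10):
        cells = {3, 17, 42}
        rng = species_range(OccurrenceSet("sp", cells),
                            grid10, method="occupied-cells")
        assert rng.cells == cells

    def test_buffer_method_chebyshev(self, grid10):
        centre = grid10.rowcol_to_cell(5, 5)
        rng = species_range(OccurrenceSet("sp", {centre}), grid10,
                            method="buffer", buffer_cells=1)
        expect = {grid10.rowcol_to_cell(r, c)
                  for r in (4, 5, 6) for c in (4, 5, 6)}
        assert rng.cells == expect

    def test_hull_matches_point_in_polygon_oracle(self, grid10, rng):
        occ = set(rng.choice(100, size=12, replace=False).tolist())
        sp = OccurrenceSet("sp", occ)
        out = species_range(sp, grid10, method="convex-hull")
        from scipy.spatial import ConvexHull
        x, y = grid10.cell_centroid_xy(np.array(sorted(occ)))
        hull = ConvexHull(np.column_stack([x, y]))
        poly = [(x[i], y[i]) for i in hull.vertices]
        for cell in range(100):
            cx, cy = grid10.cell_centroid_xy(cell)
            oracle = point_in_polygon(cx, cy, poly)
            if cell in occ:
                assert cell in out.cells  # occurrences always in range
            elif oracle:
                assert cell in out.cells

    def test_collinear_occurrences_fall_back_to_buffer(self, grid10, caplog):
        cells = {grid10.rowcol_to_cell(4, c) for c in range(2, 8)}
        with caplog.at_level("WARNING", logger="hstrend"):
            out = species_range(OccurrenceSet("sp", cells), grid10,
                                method="convex-hull", buffer_cells=1)
        assert "degenerate" in caplog.text
        assert cells < out.cells  # buffer extends beyond the line


class TestMasking:
    def test_boundary_alpha_is_strict(self, grid10):
        p = np.full(100, 0.5)
        p[0], p[1], p[2] = 0.05, 0.049999, 0.051
        tm = make_trend_map(grid10, np.ones(100), p)
        from hstrend import SpeciesRange
        masked = mask_trends(tm, SpeciesRange("sp", set(range(100))), alpha=0.05)
        kept = set(masked.kept_cells().tolist())
        assert 1 in kept and 0 not in kept and 2 not in kept

    def test_empty_range_masks_everything(self, grid10):
        tm = make_trend_map(grid10, np.ones(100), np.zeros(100))
        from hstrend import SpeciesRange
        rng = SpeciesRange("sp", set())
        masked = mask_trends(tm, rng, alpha=0.05)
        assert masked.kept_cells().size == 0
        summ = species_summary(masked, rng)
        assert summ.n_cells_significant == 0 and summ.prop_neg is None

    def test_kept_set_equals_brute_force(self, grid10, rng):
        p = rng.random(100)
        slopes = rng.normal(size=100)
        cells = set(rng.choice(100, size=40, replace=False).tolist())
        tm = make_trend_map(grid10, slopes, p)
        from hstrend import SpeciesRange
        masked = mask_trends(tm, SpeciesRange("sp", cells), alpha=0.05)
        expect = {c for c in cells if p[c] < 0.05}
        assert set(masked.kept_cells().tolist()) == expect

    def test_masking_monotone_in_alpha_and_range(self, grid10, rng):
        p = rng.random(100)
        tm = make_trend_map(grid10, rng.normal(size=100), p)
        from hstrend import SpeciesRange
        big = SpeciesRange("sp", set(range(100)))
        small = SpeciesRange("sp", set(range(50)))
        n = lambda m: m.kept_cells().size
        assert n(mask_trends(tm, big, 0.2)) >= n(mask_trends(tm, big, 0.05))
        assert n(mask_trends(tm, big, 0.05)) >= n(mask_trends(tm, small, 0.05))


class TestSummaries:
    def _masked(self, grid10, slopes_by_cell):
        slopes = np.zeros(100)
        p = np.ones(100)
        for c, s in slopes_by_cell.items():
            slopes[c] = s
            p[c] = 0.01
        tm = make_trend_map(grid10, slopes, p)
        from hstrend import SpeciesRange
        rng = SpeciesRange("sp", set(slopes_by_cell))
        return mask_trends(tm, rng, 0.05), rng

    def test_proportions(self, grid10):
        masked, rng = self._masked(grid10, {0: -0.1, 1: -0.2, 2: 0.3})
        s = species_summary(masked, rng)
        assert s.n_neg == 2 and s.n_pos == 1 and s.n_zero == 0
        assert s.prop_neg == pytest.approx(2 / 3)
        assert s.prop_neg + s.prop_pos == pytest.approx(1.0)

    def test_all_negative(self, grid10):
        masked, rng = self._masked(grid10, {i: -0.1 * (i + 1) for i in range(5)})
        assert species_summary(masked, rng).prop_neg == 1.0

    def test_exact_zero_slope_counted_separately(self, grid10):
        masked, rng = self._masked(grid10, {0: -0.1, 1: 0.0, 2: 0.1})
        s = species_summary(masked, rng)
        assert s.n_zero == 1
        assert s.prop_neg == pytest.approx(1 / 3)

    def test_accounting_identity_enforced(self, grid10, rng):
        slopes = dict(enumerate(rng.normal(size=30)))
        masked, r = self._masked(grid10, slopes)
        s = species_summary(masked, r)
        assert s.n_neg + s.n_pos + s.n_zero == s.n_cells_significant


class TestGroupAggregation:
    def test_single_species_group_equals_species(self, grid10):
        helper = TestSummaries()
        masked, rng = helper._masked(grid10, {0: -0.1, 1: 0.2, 2: -0.3})
        s = species_summary(masked, rng)
        g, mean_l, sd_l = group_aggregate([(s, masked, rng)], unit_id="g")
        assert g.prop_neg == s.prop_neg
        assert g.n_cells_significant == s.n_cells_significant
        np.testing.assert_allclose(mean_l.values[0], masked.slope.values[0])

    def test_opposite_species_balance(self, grid10):
        helper = TestSummaries()
        m1, r1 = helper._masked(grid10, {0: -0.1, 1: -0.2})
        m2, r2 = helper._masked(grid10, {2: 0.1, 3: 0.2})
        members = [(species_summary(m1, r1), m1, r1),
                   (species_summary(m2, r2), m2, r2)]
        pooled, _, _ = group_aggregate(members, mode="pooled")
        mos, _, _ = group_aggregate(members, mode="mean-of-species")
        assert pooled.prop_neg == pytest.approx(0.5)
        assert mos.prop_neg == pytest.approx(0.5)

    def test_pooled_counts_equal_concatenation(self, grid10, rng):
        helper = TestSummaries()
        members = []
        all_slopes = []
        for k in range(3):
            cells = rng.choice(100, size=10, replace=False)
            d = {int(c): float(s) for c, s in
                 zip(cells, rng.normal(size=10))}
            m, r = helper._masked(grid10, d)
            members.append((species_summary(m, r), m, r))
            all_slopes += list(d.values())
        g, _, _ = group_aggregate(members)
        assert g.n_cells_significant == 30
        assert g.n_neg == sum(1 for s in all_slopes if s < 0)
        assert g.mean_slope == pytest.approx(np.mean(all_slopes))

    def test_group_raster_is_cellwise_mean_sd(self, grid10):
        helper = TestSummaries()
        m1, r1 = helper._masked(grid10, {0: -0.2, 1: 0.4})
        m2, r2 = helper._masked(grid10, {0: 0.6})
        members = [(species_summary(m1, r1), m1, r1),
                   (species_summary(m2, r2), m2, r2)]
        _, mean_l, sd_l = group_aggregate(members)
        assert mean_l.values[0] == pytest.approx(0.2)       # (-0.2+0.6)/2
        assert mean_l.values[1] == pytest.approx(0.4)       # single species
        assert sd_l.values[0] == pytest.approx(np.std([-0.2, 0.6], ddof=1))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_aggregate([])


class TestGroupComparison:
    def test_identical_groups_give_zero_f(self):
        props = {f"s{i}": v for i, v in enumerate([0.1, 0.2, 0.3] * 2)}
        grouping = {f"s{i}": "AB"[i // 3] for i in range(6)}
        F, p, tukey = compare_groups(props, grouping)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert all(padj > 0.9 for _, _, padj in tukey)

    def test_separated_groups_highly_significant(self, rng):
        eps = rng.normal(0, 1e-4, size=6)
        props = {f"s{i}": (0.0 if i < 3 else 1.0) + eps[i] for i in range(6)}
        grouping = {f"s{i}": "AB"[i // 3] for i in range(6)}
        F, p, tukey = compare_groups(props, grouping)
        assert p < 1e-6
        assert tukey[0][2] < 1e-4

    def test_f_matches_brute_force_mean_squares(self, rng):
        vals = rng.random(12)
        props = {f"s{i}": vals[i] for i in range(12)}
        grouping = {f"s{i}": "ABC"[i % 3] for i in range(12)}
        F, p, _ = compare_groups(props, grouping)
        groups = [[vals[i] for i in range(12) if i % 3 == g] for g in range(3)]
        grand = np.mean(vals)
        msb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups) / 2
        msw = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups) / 9
        assert F == pytest.approx(msb / msw)

    def test_degenerate_variance_reported_missing(self):
        props = {f"s{i}": 0.5 for i in range(6)}
        grouping = {f"s{i}": "AB"[i // 3] for i in range(6)}
        F, p, tukey = compare_groups(props, grouping)
        assert np.isnan(F) and np.isnan(p)


class TestConservationTables:
    def _member(self, grid10, cells):
        helper = TestSummaries()
        m, r = helper._masked(grid10, cells)
        return (species_summary(m, r), m, r)

    def test_single_status_single_row(self, grid10):
        members = {f"s{i}": self._member(grid10, {i: -0.1}) for i in range(3)}
        out = conservation_tables(members, {f"s{i}": "LC" for i in range(3)})
        assert list(out) == ["LC"]

    def test_species_appears_under_each_assessment(self, grid10):
        members = {"s0": self._member(grid10, {0: -0.1})}
        regional = conservation_tables(members, {"s0": "NE"})
        european = conservation_tables(members, {"s0": "LC"})
        assert "NE" in regional and "LC" in european

    def test_row_count_matches_distinct_codes(self, grid10):
        members = {f"s{i}": self._member(grid10, {i: 0.1}) for i in range(4)}
        codes = {"s0": "LC", "s1": "LC", "s2": "VU", "s3": "EN"}
        assert len(conservation_tables(members, codes)) == 3

    def test_unknown_code_is_hard_error(self, grid10):
        members = {"s0": self._member(grid10, {0: -0.1})}
        with pytest.raises(ValueError, match="ZZ"):
            conservation_tables(members, {"s0": "ZZ"})
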