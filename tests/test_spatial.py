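"""Gridding: construction, occupancy rules, layers, and brute-force oracles."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from taxroi import spatial
from taxroi.errors import GeometryError
from taxroi.spatial import (
    GridSpec,
    LayerKind,
    OccupancyRule,
    RangeMap,
    build_grid,
    cells_occupied,
    island_subgrid_analysis,
    mean_score_map,
    richness_map,
    sqrt_transform,
    sum_score_map,
)

KM = 1_000.0


def brute_force_layers(scores, ranges, grid):
    """Independent triple loop (species x cell x intersection test)."""
    richness = np.zeros((grid.n_rows, grid.n_cols))
    total = np.zeros_like(richness)
    count = np.zeros_like(richness)
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            cell = box(
                grid.origin[0] + j * grid.cell_size,
                grid.origin[1] + i * grid.cell_size,
                grid.origin[0] + (j + 1) * grid.cell_size,
                grid.origin[1] + (i + 1) * grid.cell_size,
            )
            for r in ranges:
                if r.geometry.intersection(cell).area > 0:
                    richness[i, j] += 1
                    if r.species_id in scores:
                        total[i, j] += scores[r.species_id]
                        count[i, j] += 1
    mean = np.where(count > 0, total / np.where(count > 0, count, 1), np.nan)
    return richness, mean


class TestBuildGrid:
    def test_exact_division(self):
        g = build_grid((0, 0, 100 * KM, 75 * KM), 25 * KM)
        assert (g.n_rows, g.n_cols) == (3, 4)
        assert g.n_cells == 12

    def test_ceiling_padding(self):
        g = build_grid((0, 0, 60 * KM, 60 * KM), 25 * KM)
        assert (g.n_rows, g.n_cols) == (3, 3)

    def test_origin_snaps_to_cell_size_multiple(self):
        g = build_grid((10 * KM, 30 * KM, 80 * KM, 80 * KM), 25 * KM)
        assert g.origin == (0.0, 25 * KM)
        # still covers the extent fully
        assert g.origin[0] + g.n_cols * g.cell_size >= 80 * KM
        assert g.origin[1] + g.n_rows * g.cell_size >= 80 * KM

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 10 * KM, 10 * KM), 0)
        with pytest.raises(ValueError):
            build_grid((0, 0, 0, 10 * KM), 25 * KM)

    def test_geographic_crs_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            build_grid((0, 0, 10, 10), 0.25, crs="EPSG:4326")


class TestCellsOccupied:
    grid = GridSpec(crs=spatial.DEFAULT_CRS, cell_size=25 * KM,
                    origin=(0.0, 0.0), n_rows=3, n_cols=3)

    def test_polygon_inside_one_cell(self):
        r = RangeMap("a", box(30 * KM, 30 * KM, 40 * KM, 40 * KM))
        assert cells_occupied(r, self.grid) == {(1, 1)}

    def test_polygon_straddling_shared_edge_claims_both_cells(self):
        r = RangeMap("a", box(20 * KM, 5 * KM, 30 * KM, 10 * KM))
        assert cells_occupied(r, self.grid) == {(0, 0), (0, 1)}

    def test_boundary_touch_with_zero_area_is_excluded(self):
        # polygon exactly abuts the x = 25 km cell edge
        r = RangeMap("a", box(5 * KM, 5 * KM, 25 * KM, 10 * KM))
        assert cells_occupied(r, self.grid) == {(0, 0)}

    def test_centroid_rule_needs_cell_center_inside_polygon(self):
        corner_sliver = RangeMap("a", box(26 * KM, 26 * KM, 30 * KM, 30 * KM))
        assert cells_occupied(corner_sliver, self.grid,
                              OccupancyRule.ANY_INTERSECTION) == {(1, 1)}
        assert cells_occupied(corner_sliver, self.grid,
                              OccupancyRule.CENTROID) == set()
        covering = RangeMap("a", box(26 * KM, 26 * KM, 49 * KM, 49 * KM))
        assert cells_occupied(covering, self.grid,
                              OccupancyRule.CENTROID) == {(1, 1)}

    def test_refining_the_grid_never_drops_occupied_coverage(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x, y = rng.uniform(5 * KM, 60 * KM, size=2)
            r = RangeMap("a", Point(x, y).buffer(rng.uniform(2 * KM, 15 * KM)))
            coarse = build_grid((0, 0, 75 * KM, 75 * KM), 25 * KM)
            fine = build_grid((0, 0, 75 * KM, 75 * KM), 12.5 * KM)
            assert len(cells_occupied(r, fine)) >= len(cells_occupied(r, coarse))


class TestLayers:
    grid = GridSpec(crs=spatial.DEFAULT_CRS, cell_size=25 * KM,
                    origin=(0.0, 0.0), n_rows=2, n_cols=2)

    def test_identical_ranges_double_richness(self):
        geom = box(5 * KM, 5 * KM, 30 * KM, 10 * KM)
        layer = richness_map([RangeMap("a", geom), RangeMap("b", geom)], self.grid)
        assert layer.values[0, 0] == 2 and layer.values[0, 1] == 2
        assert layer.values.sum() == 4

    def test_no_ranges_gives_all_zero_richness(self):
        layer = richness_map([], self.grid)
        assert (layer.values == 0).all()

    def test_duplicate_species_id_rejected(self):
        geom = box(1, 1, 2, 2)
        with pytest.raises(ValueError, match="duplicate"):
            richness_map([RangeMap("a", geom), RangeMap("a", geom)], self.grid)

    def test_richness_total_equals_sum_of_per_species_cell_counts(self):
        rng = np.random.default_rng(11)
        ranges = [
            RangeMap(f"sp{k}", Point(rng.uniform(0, 50 * KM),
                                     rng.uniform(0, 50 * KM)).buffer(8 * KM))
            for k in range(12)
        ]
        layer = richness_map(ranges, self.grid)
        assert layer.values.sum() == sum(
            len(cells_occupied(r, self.grid)) for r in ranges
        )

    def test_weighted_mean_of_cooccurring_scores(self):
        ranges = [
            RangeMap(f"sp{k}", Point(3 * KM + 2 * KM * k, 5 * KM).buffer(KM))
            for k in range(6)
        ]
        scores = {"sp0": 1.0, "sp1": 1.0, "sp2": 1.0, "sp3": 1.0,
                  "sp4": 3.0, "sp5": 4.0}
        mean = mean_score_map(scores, ranges, self.grid)
        assert mean.values[0, 0] == pytest.approx(11 / 6)
        assert np.isnan(mean.values[1, 1])

    def test_constant_scores_give_constant_mean(self):
        ranges = [RangeMap(f"sp{k}", Point(5 * KM * (k + 1), 5 * KM).buffer(KM))
                  for k in range(3)]
        mean = mean_score_map({f"sp{k}": 2.5 for k in range(3)}, ranges, self.grid)
        finite = mean.values[np.isfinite(mean.values)]
        assert (finite == 2.5).all()

    def test_binary_scores_mean_is_the_proportion_flagged(self):
        ranges = [RangeMap(f"sp{k}", Point(10 * KM, 10 * KM).buffer(KM))
                  for k in range(4)]
        scores = {"sp0": 1.0, "sp1": 0.0, "sp2": 0.0, "sp3": 1.0}
        mean = mean_score_map(scores, ranges, self.grid)
        assert mean.values[0, 0] == pytest.approx(0.5)

    def test_scored_species_without_a_range_is_an_error(self):
        with pytest.raises(ValueError, match="ghost"):
            mean_score_map({"ghost": 1.0}, [], self.grid)

    def test_mean_lies_within_the_range_of_present_scores(self):
        rng = np.random.default_rng(3)
        ranges = [
            RangeMap(f"sp{k}", Point(rng.uniform(0, 50 * KM),
                                     rng.uniform(0, 50 * KM)).buffer(10 * KM))
            for k in range(10)
        ]
        scores = {f"sp{k}": float(rng.uniform(0, 4)) for k in range(10)}
        mean = mean_score_map(scores, ranges, self.grid)
        finite = mean.values[np.isfinite(mean.values)]
        assert (finite >= min(scores.values()) - 1e-12).all()
        assert (finite <= max(scores.values()) + 1e-12).all()


class TestSqrtTransform:
    def _raster(self, values):
        vals = np.asarray(values, dtype=float)
        grid = GridSpec(crs=spatial.DEFAULT_CRS, cell_size=KM, origin=(0, 0),
                        n_rows=vals.shape[0], n_cols=vals.shape[1])
        return spatial.ScoreRaster(grid=grid, values=vals, kind=LayerKind.MEAN)

    def test_fixed_points_value_and_nodata_preservation(self):
        out = sqrt_transform(self._raster([[0.0, 1.0], [11 / 6, np.nan]]))
        assert out.values[0, 0] == 0.0 and out.values[0, 1] == 1.0
        assert out.values[1, 0] == pytest.approx(math.sqrt(11 / 6))
        assert round(out.values[1, 0], 4) == 1.3540
        assert np.isnan(out.values[1, 1])
        assert out.kind is LayerKind.SQRT_MEAN

    def test_ordering_preserved_and_all_ones_is_a_fixed_point(self):
        r = self._raster([[0.3, 2.7], [1.4, 0.9]])
        out = sqrt_transform(r)
        assert (np.argsort(out.values, axis=None)
                == np.argsort(r.values, axis=None)).all()
        ones = self._raster([[1.0, 1.0]])
        assert (sqrt_transform(sqrt_transform(ones)).values == ones.values).all()

    def test_negative_cell_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sqrt_transform(self._raster([[-0.1]]))


def _random_blobs(n, rng, extent):
    xmin, ymin, xmax, ymax = extent
    blobs = []
    for k in range(n):
        p = Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        blobs.append(RangeMap(f"sp{k:03d}", p.buffer(rng.uniform(0.5 * KM, 40 * KM))))
    return blobs


def test_layers_match_brute_force_oracle_on_small_grids():
    rng = np.random.default_rng(20)
    for trial in range(3):
        grid = build_grid((0, 0, 200 * KM, 150 * KM), 12.5 * KM)  # 12 x 16 cells
        assert grid.n_rows <= 20 and grid.n_cols <= 20
        ranges = _random_blobs(40, rng, (-20 * KM, -20 * KM, 220 * KM, 170 * KM))
        scores = {r.species_id: float(rng.uniform(0, 4)) for r in ranges[:30]}
        exp_rich, exp_mean = brute_force_layers(scores, ranges, grid)
        got_rich = richness_map(ranges, grid)
        got_mean = mean_score_map(scores, ranges, grid)
        np.testing.assert_array_equal(got_rich.values, exp_rich)
        np.testing.assert_allclose(got_mean.values, exp_mean, equal_nan=True)


def test_sum_layer_is_mean_times_count():
    rng = np.random.default_rng(5)
    grid = build_grid((0, 0, 100 * KM, 100 * KM), 25 * KM)
    ranges = _random_blobs(15, rng, (0, 0, 100 * KM, 100 * KM))
    scores = {r.species_id: float(rng.uniform(0, 4)) for r in ranges}
    total = sum_score_map(scores, ranges, grid).values
    mean = mean_score_map(scores, ranges, grid).values
    rich = richness_map(ranges, grid).values
    np.testing.assert_allclose(np.where(rich > 0, total, np.nan),
                               mean * rich, equal_nan=True)


class TestIslandSubgrids:
    def test_singleton_island_species(self):
        extent = (0.0, 0.0, 10 * KM, 10 * KM)
        ranges = [RangeMap("islander", Point(5 * KM, 5 * KM).buffer(2 * KM))]
        out = island_subgrid_analysis(ranges, {"islander": 2.25}, {"isle": extent})
        prods = out["isle"]
        assert prods["richness"].grid.cell_size == KM
        occupied = prods["richness"].values > 0
        assert occupied.any()
        assert (prods["mean"].values[occupied] == 2.25).all()
        assert prods["sqrt_mean"].values[occupied] == pytest.approx(1.5)

    def test_empty_island_is_all_nodata_means(self):
        out = island_subgrid_analysis([], {}, {"bare": (0, 0, 5 * KM, 5 * KM)})
        assert np.isnan(out["bare"]["mean"].values).all()
        assert (out["bare"]["richness"].values == 0).all()

    def test_matches_mainland_ops_on_clipped_inputs(self):
        rng = np.random.default_rng(9)
        extent = (0.0, 0.0, 20 * KM, 20 * KM)
        ranges = _random_blobs(8, rng, (-5 * KM, -5 * KM, 25 * KM, 25 * KM))
        scores = {r.species_id: float(rng.uniform(0, 4)) for r in ranges}
        out = island_subgrid_analysis(ranges, scores, {"isle": extent})
        clipped = spatial.clip_ranges(ranges, extent)
        grid = build_grid(extent, cell_size=KM)
        local_scores = {r.species_id: scores[r.species_id] for r in clipped}
        np.testing.assert_array_equal(
            out["isle"]["richness"].values, richness_map(clipped, grid).values
        )
        np.testing.assert_allclose(
            out["isle"]["mean"].values,
            mean_score_map(local_scores, clipped, grid).values,
            equal_nan=True,
        )

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            island_subgrid_analysis([], {}, {"bad": (0, 0, 0, 5 * KM)})


class TestGeometryAndIo:
    def test_empty_geometry_rejected(self):
        with pytest.raises(GeometryError):
            RangeMap("a", box(0, 0, 1, 1).intersection(box(5, 5, 6, 6)))

    def test_invalid_bowtie_polygon_is_repaired(self):
        from shapely.geometry import Polygon

        bowtie = Polygon([(0, 0), (2 * KM, 2 * KM), (2 * KM, 0), (0, 2 * KM)])
        r = RangeMap("a", bowtie)
        assert r.geometry.is_valid and r.geometry.area > 0

    def test_geojson_round_trip(self, tmp_path):
        ranges = [RangeMap("Gehyra alpha", Point(5 * KM, 5 * KM).buffer(2 * KM))]
        path = tmp_path / "ranges.geojson"
        spatial.write_ranges_geojson(ranges, path)
        back = spatial.read_ranges_geojson(path)
        assert back[0].species_id == "Gehyra alpha"
        assert back[0].geometry.area == pytest.approx(ranges[0].geometry.area)

    def test_ascii_grid_round_trips_values(self, tmp_path):
        grid = build_grid((0, 0, 50 * KM, 50 * KM), 25 * KM)
        vals = np.array([[1.0, np.nan], [0.25, 3.5]])
        raster = spatial.ScoreRaster(grid=grid, values=vals, kind=LayerKind.MEAN)
        path = tmp_path / "layer.asc"
        spatial.write_raster_ascii(raster, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "ncols 2" and lines[1] == "nrows 2"
        data = np.loadtxt(lines[6:])
        np.testing.assert_allclose(data, [[0.25, 3.5], [1.0, -9999.0]])

    def test_long_format_frame_has_one_row_per_cell(self):
        grid = build_grid((0, 0, 50 * KM, 75 * KM), 25 * KM)
        raster = richness_map([], grid)
        frame = spatial.raster_to_frame(raster)
        assert len(frame) == grid.n_cells
        assert set(frame.columns) == {"row", "col", "cell_x", "cell_y", "layer", "value"}
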