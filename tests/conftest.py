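import numpy as np
import pytest
import shapely

from gridpopval import PopulationGrid, ReservoirPolygon


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def uniform_grid():
    """10x10 grid of 100 m cells, 1 person per cell, origin at (0, 0)."""
    return PopulationGrid(np.ones((10, 10)), cell_size=100.0)


def random_grid(rng, n_rows, n_cols, cell_size=100.0, scale=10.0):
    return PopulationGrid(
        rng.uniform(0, scale, size=(n_rows, n_cols)), cell_size=cell_size
    )


def random_convex_polygon(rng, bounds, pid="poly"):
    """Random convex polygon inside (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = bounds
    while True:
        pts = np.c_[
            rng.uniform(xmin, xmax, 8), rng.uniform(ymin, ymax, 8)
        ]
        hull = shapely.MultiPoint(pts).convex_hull
        if isinstance(hull, shapely.Polygon) and hull.area > 0:
            ring = np.asarray(hull.exterior.coords)[:-1]
            return ReservoirPolygon(pid, ring)


def brute_force_zonal(grid, polygon, refine_factor):
    """Independent oracle: materialise the refined grid and test every
    centroid for polygon coverage, with no windowing or indexing tricks."""
    from gridpopval import refine_grid

    fine = refine_grid(grid, refine_factor)
    geom = polygon.to_shapely()
    total = 0.0
    xs = fine.origin_x + (np.arange(fine.n_cols) + 0.5) * fine.cell_size
    ys = fine.origin_y + (np.arange(fine.n_rows) + 0.5) * fine.cell_size
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.covers(geom, shapely.points(xx.ravel(), yy.ravel()))
    return float(fine.counts.ravel()[inside].sum())
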