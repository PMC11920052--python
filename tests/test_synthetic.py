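import numpy as np
import pytest
import shapely

from gridpopval import (
    DatasetSpec,
    SyntheticWorldConfig,
    derive_gridded_dataset,
    generate_scenario,
    generate_true_field,
    polygon_area_km2,
    sample_reservoirs,
    shrink_polygon,
    zonal_population,
)
from gridpopval.errors import PackingError
from gridpopval.synthetic import generate_icold_table

from conftest import random_convex_polygon


def small_config(**kw):
    defaults = dict(
        seed=7, extent_m=20_000, true_cell_size_m=500, n_clusters=10,
        cluster_intensity=500, cluster_spread_m=800,
        background_density_per_km2=5.0, n_reservoirs=5,
        area_range_km2=(1.2, 6.0), completion_year_range=(1985, 2015),
        shrink_mean=0.188, shrink_sd=0.0, report_noise_sd=0.0,
        dataset_specs=[DatasetSpec("a", beta=1.0)],
        reference_years=(1975, 1980, 1985, 1990, 1995, 2000, 2005, 2010),
    )
    defaults.update(kw)
    return SyntheticWorldConfig(**defaults)


def test_uniform_background_field():
    cfg = small_config(
        n_clusters=0, background_density_per_km2=10.0,
        extent_m=10_000, true_cell_size_m=100,
    )
    field = generate_true_field(cfg)
    assert field.counts.shape == (100, 100)
    np.testing.assert_allclose(field.counts, 0.1)
    assert field.total == pytest.approx(1000.0)


def test_field_deterministic_given_seed():
    cfg = small_config()
    a = generate_true_field(cfg)
    b = generate_true_field(cfg)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = generate_true_field(small_config(seed=8))
    assert not np.array_equal(a.counts, c.counts)


def test_cluster_mass_matches_intensity_over_seeds():
    totals = []
    for seed in range(20):
        cfg = small_config(
            seed=seed, n_clusters=5, cluster_intensity=1000,
            background_density_per_km2=0.0,
        )
        totals.append(generate_true_field(cfg).total)
    assert np.mean(totals) == pytest.approx(5000.0, rel=0.05)


def test_degenerate_area_range_gives_exact_area():
    cfg = small_config(n_reservoirs=1, area_range_km2=(4.0, 4.0))
    [(poly, year)] = sample_reservoirs(cfg)
    assert polygon_area_km2(poly) == pytest.approx(4.0, rel=0.01)
    assert 1985 <= year <= 2015


def test_reservoirs_disjoint_inside_extent_with_correct_areas():
    cfg = small_config(n_reservoirs=10, extent_m=40_000)
    sampled = sample_reservoirs(cfg)
    assert len(sampled) == 10
    geoms = [p.to_shapely() for p, _ in sampled]
    for g in geoms:
        minx, miny, maxx, maxy = g.bounds
        assert 0 <= minx and 0 <= miny and maxx <= 40_000 and maxy <= 40_000
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            assert geoms[i].intersection(geoms[j]).area == 0.0
    lo, hi = cfg.area_range_km2
    for p, _ in sampled:
        assert lo * 0.99 <= polygon_area_km2(p) <= hi * 1.01
    years = [y for _, y in sampled]
    assert all(1985 <= y <= 2015 for y in years)


def test_infeasible_packing_raises():
    with pytest.raises(PackingError):
        sample_reservoirs(
            small_config(n_reservoirs=30, area_range_km2=(25.0, 25.0), extent_m=20_000)
        )


def test_sampling_deterministic():
    cfg = small_config(n_reservoirs=4)
    a = sample_reservoirs(cfg)
    b = sample_reservoirs(cfg)
    for (pa, ya), (pb, yb) in zip(a, b):
        np.testing.assert_array_equal(pa.ring, pb.ring)
        assert ya == yb


@pytest.mark.parametrize("s, dim_scale", [(0.0, 1.0), (0.75, 0.5)])
def test_shrink_scales_linear_dimensions(rng, s, dim_scale):
    poly = random_convex_polygon(rng, (0, 0, 5000, 5000))
    shrunk = shrink_polygon(poly, s)
    width = np.ptp(poly.ring[:, 0])
    assert np.ptp(shrunk.ring[:, 0]) == pytest.approx(width * dim_scale, rel=1e-9)


def test_shrink_area_ratio_and_centroid_property(rng):
    for s in (0.1, 0.188, 0.5, 0.9):
        poly = random_convex_polygon(rng, (0, 0, 5000, 5000))
        shrunk = shrink_polygon(poly, s)
        assert polygon_area_km2(shrunk) / polygon_area_km2(poly) == pytest.approx(
            1 - s, rel=1e-9
        )
        c0 = poly.to_shapely().centroid
        c1 = shrunk.to_shapely().centroid
        assert c0.distance(c1) < 1e-6


def test_shrink_paper_magnitude_on_unit_square():
    unit = shapely.Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
    from gridpopval import ReservoirPolygon

    poly = ReservoirPolygon("u", np.asarray(unit.exterior.coords)[:-1])
    assert polygon_area_km2(shrink_polygon(poly, 0.188)) == pytest.approx(0.812, abs=1e-9)


def test_derive_identity():
    field = generate_true_field(small_config())
    spec = DatasetSpec("x", beta=1.0, realloc_fraction=0.0)
    out = derive_gridded_dataset(field, spec)
    np.testing.assert_allclose(out.counts, field.counts)
    assert out.dataset_name == "x"


@pytest.mark.parametrize("beta", [0.5, 0.47, 2.0])
def test_derive_total_scales_linearly_in_beta(beta):
    field = generate_true_field(small_config())
    spec = DatasetSpec(
        "x", beta=beta, realloc_fraction=0.3, realloc_radius_m=1500, out_cell_size_m=1000
    )
    out = derive_gridded_dataset(field, spec)
    assert out.total == pytest.approx(beta * field.total, rel=1e-6)
    assert out.cell_size == 1000


def test_derive_reallocation_moves_mass_but_conserves():
    field = generate_true_field(small_config(n_clusters=3, background_density_per_km2=0.0))
    spec = DatasetSpec("x", beta=1.0, realloc_fraction=0.5, realloc_radius_m=2000)
    out = derive_gridded_dataset(field, spec)
    assert out.total == pytest.approx(field.total, rel=1e-6)
    assert not np.allclose(out.counts, field.counts)  # mass actually moved
    assert out.counts.max() < field.counts.max() + 1e-9  # smoothing lowers peaks


def test_icold_table_noiseless_equals_true_zonal():
    cfg = small_config(n_reservoirs=3)
    field = generate_true_field(cfg)
    sampled = sample_reservoirs(cfg, field)
    records = generate_icold_table(field, sampled, cfg, refine_factor=10)
    for (poly, year), rec in zip(sampled, records):
        assert rec.id == poly.id
        assert rec.resettled_persons == pytest.approx(
            zonal_population(field, poly, 10), rel=1e-12
        )
        assert rec.reported_area_km2 == pytest.approx(polygon_area_km2(poly))
        assert rec.completion_year == year
        assert not rec.excluded_transboundary and not rec.excluded_preexisting


def test_icold_table_empty_region_reports_zero():
    cfg = small_config(n_reservoirs=1, n_clusters=0, background_density_per_km2=0.0)
    field = generate_true_field(cfg)
    sampled = sample_reservoirs(cfg, field)
    [rec] = generate_icold_table(field, sampled, cfg)
    assert rec.resettled_persons == 0.0


def test_report_noise_is_unbiased_in_log_space():
    cfg = small_config(
        n_reservoirs=200, extent_m=200_000, true_cell_size_m=1000,
        area_range_km2=(1.5, 10.0), report_noise_sd=0.2,
        background_density_per_km2=10.0, n_clusters=0,
    )
    field = generate_true_field(cfg)
    sampled = sample_reservoirs(cfg, field)
    noiseless_cfg = small_config(**{**cfg.__dict__, "report_noise_sd": 0.0,
                                    "dataset_specs": cfg.dataset_specs})
    noisy = generate_icold_table(field, sampled, cfg, refine_factor=4)
    clean = generate_icold_table(field, sampled, noiseless_cfg, refine_factor=4)
    logs = [
        np.log(n.resettled_persons / c.resettled_persons)
        for n, c in zip(noisy, clean)
        if c.resettled_persons > 0
    ]
    assert abs(np.mean(logs)) < 0.05


def test_scenario_round_trips_through_disk(tmp_path):
    from gridpopval import read_population_raster, read_reservoir_polygons, read_reservoir_table

    cfg = small_config(n_reservoirs=3, reference_years=(1995, 2000))
    scenario = generate_scenario(cfg, out_dir=tmp_path)
    truth = read_population_raster(tmp_path / "truth.tif")
    np.testing.assert_allclose(truth.counts, scenario.truth.counts, rtol=1e-9)
    grid = read_population_raster(tmp_path / "a_2000.tif")
    assert grid.reference_year == 2000 and grid.dataset_name == "a"
    polys = read_reservoir_polygons(tmp_path / "polygons.geojson")
    assert {p.id for p in polys} == set(scenario.polygons)
    records = read_reservoir_table(tmp_path / "records.csv")
    assert len(records) == 3
    manifest = (tmp_path / "manifest.json").read_text()
    assert '"beta"' in manifest and '"seed": 7' in manifest


def test_scenario_polygons_are_shrunk_versions_of_truth():
    cfg = small_config(n_reservoirs=4, shrink_mean=0.188, shrink_sd=0.0)
    scenario = generate_scenario(cfg)
    for pid, shrunk in scenario.polygons.items():
        ratio = polygon_area_km2(shrunk) / polygon_area_km2(scenario.true_polygons[pid])
        assert ratio == pytest.approx(1 - 0.188, rel=1e-9)
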