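"""Synthetic world with known ground truth for end-to-end validation.

The generator emulates the structure of the real validation problem without
any external data: a clustered "true" population field (settlement clusters
on a sparse rural background), convex reservoir footprints whose published
polygons systematically under-represent the true surface area, an
ICOLD-like attribute table whose resettlement figures equal the true
population inside the *true* footprint (optionally with multiplicative
lognormal reporting noise), and derived gridded population datasets that
are beta-scaled, spatially reallocated, re-gridded copies of the truth.

Every output is a pure function of (config, seed): independent random
streams are spawned per stage so regenerating one artefact never perturbs
another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .core_io import (
    PopulationGrid,
    ReservoirPolygon,
    ReservoirRecord,
    aggregate_grid,
    polygon_area_km2,
    write_population_raster,
    write_reservoir_polygons,
    write_reservoir_table,
)
from .errors import PackingError
from .extraction import zonal_population

# country roster for round-robin attribute assignment (ISO3, income level)
DEFAULT_ROSTER: tuple[tuple[str, str], ...] = (
    ("CHN", "upper-middle"),
    ("IND", "lower-middle"),
    ("BRA", "upper-middle"),
    ("ETH", "low"),
    ("TUR", "upper-middle"),
    ("VNM", "lower-middle"),
    ("USA", "high"),
    ("NGA", "lower-middle"),
    ("COD", "low"),
    ("MEX", "upper-middle"),
)


@dataclass
class DatasetSpec:
    """Recipe for one derived gridded dataset.

    beta is the multiplicative total-population bias; realloc_fraction of
    every cell's mass is spread uniformly over a disk of realloc_radius_m
    (edge-truncated, renormalised so mass is conserved) before aggregation
    to out_cell_size_m.
    """

    name: str
    beta: float
    realloc_fraction: float = 0.0
    realloc_radius_m: float = 0.0
    out_cell_size_m: float | None = None  # None: keep the truth resolution

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not (0 <= self.realloc_fraction <= 1):
            raise ValueError("realloc_fraction must lie in [0, 1]")


def _default_dataset_specs() -> list[DatasetSpec]:
    # betas mirror the bias magnitudes of the five real products
    return [
        DatasetSpec("worldpop", beta=0.47, realloc_fraction=0.3, realloc_radius_m=2000, out_cell_size_m=1000),
        DatasetSpec("gwp", beta=0.35, realloc_fraction=0.3, realloc_radius_m=4000, out_cell_size_m=2000),
        DatasetSpec("grump", beta=0.33, realloc_fraction=0.3, realloc_radius_m=4000, out_cell_size_m=2000),
        DatasetSpec("landscan", beta=0.32, realloc_fraction=0.3, realloc_radius_m=2000, out_cell_size_m=1000),
        DatasetSpec("ghs_pop", beta=0.16, realloc_fraction=0.3, realloc_radius_m=2000, out_cell_size_m=1000),
    ]


@dataclass
class SyntheticWorldConfig:
    seed: int = 0
    extent_m: float = 400_000.0
    true_cell_size_m: float = 1_000.0
    n_clusters: int = 400
    cluster_intensity: float = 2_000.0
    cluster_spread_m: float = 2_000.0
    background_density_per_km2: float = 10.0
    n_reservoirs: int = 307
    area_range_km2: tuple[float, float] = (1.5, 400.0)
    completion_year_range: tuple[int, int] = (1985, 2015)
    shrink_mean: float = 0.188
    shrink_sd: float = 0.05
    report_noise_sd: float = 0.0
    dataset_specs: list[DatasetSpec] = field(default_factory=_default_dataset_specs)
    reference_years: tuple[int, ...] = (1975, 1980, 1985, 1990, 1995, 2000, 2005, 2010)
    country_roster: tuple[tuple[str, str], ...] = DEFAULT_ROSTER

    def __post_init__(self) -> None:
        n = self.extent_m / self.true_cell_size_m
        if abs(n - round(n)) > 1e-9:
            raise ValueError("extent_m must be divisible by true_cell_size_m")
        if not (0 <= self.shrink_mean < 1):
            raise ValueError("shrink_mean must lie in [0, 1)")
        lo, hi = self.area_range_km2
        if not (0 < lo <= hi < self.extent_m**2 / 1e6):
            raise ValueError("area_range_km2 must lie within (0, extent area)")
        for spec in self.dataset_specs:
            if spec.out_cell_size_m is not None:
                f = spec.out_cell_size_m / self.true_cell_size_m
                if abs(f - round(f)) > 1e-9 or f < 1:
                    raise ValueError(
                        f"dataset {spec.name!r}: out_cell_size_m must be an integer "
                        "multiple of true_cell_size_m"
                    )
                g = self.extent_m / spec.out_cell_size_m
                if abs(g - round(g)) > 1e-9:
                    raise ValueError(
                        f"dataset {spec.name!r}: extent_m must be divisible by "
                        f"out_cell_size_m ({spec.out_cell_size_m})"
                    )


def _rng(config: SyntheticWorldConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_true_field(config: SyntheticWorldConfig) -> PopulationGrid:
    """The ground-truth population field: uniform rural background plus
    Gaussian settlement clusters.

    Each cluster holds a Poisson(cluster_intensity) number of persons
    scattered around a uniformly placed centre with isotropic Gaussian
    dispersion cluster_spread_m; points are clamped to the extent so no
    mass is lost at the edges.
    """
    rng = _rng(config, 0)
    n = int(round(config.extent_m / config.true_cell_size_m))
    cell_area_km2 = (config.true_cell_size_m / 1e3) ** 2
    counts = np.full((n, n), config.background_density_per_km2 * cell_area_km2)
    if config.n_clusters > 0:
        centers = rng.uniform(0, config.extent_m, size=(config.n_clusters, 2))
        sizes = rng.poisson(config.cluster_intensity, size=config.n_clusters)
        total_pts = int(sizes.sum())
        if total_pts:
            reps = np.repeat(np.arange(config.n_clusters), sizes)
            pts = centers[reps] + rng.normal(0, config.cluster_spread_m, size=(total_pts, 2))
            eps = 1e-6 * config.true_cell_size_m
            pts = np.clip(pts, 0, config.extent_m - eps)
            hist, _, _ = np.histogram2d(
                pts[:, 1], pts[:, 0], bins=n, range=[[0, config.extent_m]] * 2
            )
            counts += hist
    return PopulationGrid(
        counts=counts,
        cell_size=config.true_cell_size_m,
        reference_year=None,
        dataset_name="truth",
    )


def _random_convex_polygon(
    rng: np.random.Generator, area_km2: float, center: np.ndarray
) -> np.ndarray:
    """A random convex ring of exact planar area, centred at ``center``."""
    while True:
        m = int(rng.integers(6, 13))
        ang = np.sort(rng.uniform(0, 2 * np.pi, m))
        rad = 1.0 + 0.4 * rng.uniform(-1, 1, m)
        pts = np.c_[np.cos(ang) * rad, np.sin(ang) * rad]
        hull = shapely.MultiPoint(pts).convex_hull
        if isinstance(hull, shapely.Polygon) and hull.area > 0:
            break
    ring = np.asarray(hull.exterior.coords)[:-1]
    ring -= ring.mean(axis=0)
    scale = np.sqrt(area_km2 * 1e6 / shapely.Polygon(ring).area)
    return ring * scale + center


def sample_reservoirs(
    config: SyntheticWorldConfig, field: PopulationGrid | None = None
) -> list[tuple[ReservoirPolygon, int]]:
    """Place non-overlapping convex reservoir footprints inside the extent.

    Areas are log-uniform in ``area_range_km2`` (small reservoirs dominate,
    with a long tail of large ones); completion years are uniform integers.
    Placement is by rejection sampling, largest first, with a bounded
    attempt budget per polygon.
    """
    rng = _rng(config, 1)
    lo, hi = config.area_range_km2
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_reservoirs))
    if areas.sum() > 0.25 * config.extent_m**2 / 1e6:
        raise PackingError(
            f"requested total area {areas.sum():.0f} km2 exceeds 25% of the extent"
        )
    y_lo, y_hi = config.completion_year_range
    years = rng.integers(y_lo, y_hi + 1, config.n_reservoirs)
    order = np.argsort(-areas)  # place the hardest (largest) first
    placed: list[tuple[int, shapely.Polygon, np.ndarray]] = []
    max_attempts = 10_000
    for idx in order:
        area = float(areas[idx])
        for _ in range(max_attempts):
            ring = _random_convex_polygon(
                rng, area, rng.uniform(0, config.extent_m, size=2)
            )
            if ring[:, 0].min() < 0 or ring[:, 1].min() < 0:
                continue
            if ring[:, 0].max() > config.extent_m or ring[:, 1].max() > config.extent_m:
                continue
            geom = shapely.Polygon(ring)
            bounds = geom.bounds
            clash = False
            for _, other, ob in placed:
                if (
                    bounds[0] <= ob[2] and ob[0] <= bounds[2]
                    and bounds[1] <= ob[3] and ob[1] <= bounds[3]
                    and geom.intersects(other)
                ):
                    clash = True
                    break
            if not clash:
                placed.append((int(idx), geom, np.asarray(bounds)))
                break
        else:
            raise PackingError(
                f"could not place reservoir of {area:.1f} km2 after "
                f"{max_attempts} attempts"
            )
    width = len(str(config.n_reservoirs))
    out: list[tuple[ReservoirPolygon, int]] = []
    for idx, geom, _ in sorted(placed, key=lambda t: t[0]):
        ring = np.asarray(geom.exterior.coords)[:-1]
        out.append(
            (
                ReservoirPolygon(id=f"res_{idx + 1:0{width}d}", ring=ring),
                int(years[idx]),
            )
        )
    return out


def shrink_polygon(polygon: ReservoirPolygon, s: float) -> ReservoirPolygon:
    """Contract a footprint toward its centroid so its area drops by the
    fraction ``s`` exactly (linear dimensions scale by sqrt(1-s))."""
    if not (0 <= s < 1):
        raise ValueError(f"shrink fraction must lie in [0, 1), got {s}")
    centroid = np.asarray(polygon.to_shapely().centroid.coords[0])
    ring = centroid + (polygon.ring - centroid) * np.sqrt(1.0 - s)
    return ReservoirPolygon(id=polygon.id, ring=ring)


def derive_gridded_dataset(
    field: PopulationGrid, spec: DatasetSpec, seed: int = 0
) -> PopulationGrid:
    """A biased gridded dataset derived from the truth.

    The truth is scaled by beta; realloc_fraction of every cell's mass is
    spread uniformly over a disk of realloc_radius_m (kernel truncated at
    the extent edge and renormalised per source cell, so the total is
    exactly beta times the truth); the result is aggregated to
    out_cell_size_m. The derivation is deterministic; ``seed`` is accepted
    for interface symmetry with the stochastic generators.
    """
    counts = field.counts * spec.beta
    radius_cells = spec.realloc_radius_m / field.cell_size
    if spec.realloc_fraction > 0 and radius_cells >= 1:
        from scipy import ndimage

        r = int(np.floor(radius_cells))
        offs = np.arange(-r, r + 1)
        dy, dx = np.meshgrid(offs, offs, indexing="ij")
        kernel = (dy**2 + dx**2 <= radius_cells**2).astype(float)
        kernel /= kernel.sum()
        # per-source in-bounds kernel mass; dividing by it before the
        # convolution makes edge truncation mass-conserving
        inbounds = ndimage.convolve(np.ones_like(counts), kernel, mode="constant")
        moved = counts * spec.realloc_fraction
        counts = (counts - moved) + ndimage.convolve(moved / inbounds, kernel, mode="constant")
    grid = PopulationGrid(
        counts=counts,
        cell_size=field.cell_size,
        origin_x=field.origin_x,
        origin_y=field.origin_y,
        reference_year=field.reference_year,
        dataset_name=spec.name,
    )
    if spec.out_cell_size_m is not None:
        factor = int(round(spec.out_cell_size_m / field.cell_size))
        if factor > 1:
            grid = aggregate_grid(grid, factor)
    return grid


def generate_icold_table(
    field: PopulationGrid,
    true_polygons: list[tuple[ReservoirPolygon, int]],
    config: SyntheticWorldConfig,
    refine_factor: int = 10,
) -> list[ReservoirRecord]:
    """ICOLD-like attribute rows from the true footprints.

    Resettlement equals the true zonal population of the *true* (pre-shrink)
    polygon, times a lognormal noise factor exp(N(0, report_noise_sd²))
    (exactly 1 when the noise sd is 0, emulating accurate on-the-ground
    surveys). Reported area is the true polygon area; country and income
    level rotate through the roster.
    """
    rng = _rng(config, 2)
    records: list[ReservoirRecord] = []
    roster = config.country_roster
    for k, (poly, year) in enumerate(true_polygons):
        pop = zonal_population(field, poly, refine_factor)
        noise = 1.0
        if config.report_noise_sd > 0:
            noise = float(np.exp(rng.normal(0.0, config.report_noise_sd)))
        country, income = roster[k % len(roster)]
        records.append(
            ReservoirRecord(
                id=poly.id,
                country=country,
                income_level=income,
                completion_year=year,
                reported_area_km2=polygon_area_km2(poly),
                resettled_persons=pop * noise,
            )
        )
    return records


@dataclass
class SyntheticScenario:
    """In-memory bundle of one generated world."""

    config: SyntheticWorldConfig
    truth: PopulationGrid
    grids: dict[tuple[str, int], PopulationGrid]
    polygons: dict[str, ReservoirPolygon]  # the shrunken footprints the pipeline sees
    true_polygons: dict[str, ReservoirPolygon]
    records: list[ReservoirRecord]
    manifest: dict


def generate_scenario(
    config: SyntheticWorldConfig, out_dir: str | Path | None = None
) -> SyntheticScenario:
    """Generate a full scenario; optionally write all artefacts to disk.

    The on-disk layout is ``truth.tif``, one ``<dataset>_<year>.tif`` per
    dataset and reference year, ``polygons.geojson`` (the shrunken
    footprints), ``records.csv``, and ``manifest.json`` recording the seed,
    config and per-dataset beta for later recovery scoring. The population
    field is static, so a dataset's grids differ across years only in their
    metadata vintage.
    """
    truth = generate_true_field(config)
    sampled = sample_reservoirs(config, truth)
    records = generate_icold_table(truth, sampled, config)

    rng = _rng(config, 3)
    shrinks = np.clip(
        rng.normal(config.shrink_mean, config.shrink_sd, len(sampled)), 0.0, 0.95
    )
    shrunk = {
        poly.id: shrink_polygon(poly, float(s))
        for (poly, _), s in zip(sampled, shrinks)
    }

    grids: dict[tuple[str, int], PopulationGrid] = {}
    for spec in config.dataset_specs:
        derived = derive_gridded_dataset(truth, spec, seed=config.seed)
        for year in config.reference_years:
            grids[(spec.name, year)] = dataclasses.replace(
                derived, counts=derived.counts, reference_year=int(year)
            )

    manifest = {
        "seed": config.seed,
        "extent_m": config.extent_m,
        "true_cell_size_m": config.true_cell_size_m,
        "n_reservoirs": config.n_reservoirs,
        "shrink_mean": config.shrink_mean,
        "shrink_sd": config.shrink_sd,
        "report_noise_sd": config.report_noise_sd,
        "reference_years": list(config.reference_years),
        "datasets": {spec.name: {"beta": spec.beta} for spec in config.dataset_specs},
        "total_true_population": truth.total,
    }

    scenario = SyntheticScenario(
        config=config,
        truth=truth,
        grids=grids,
        polygons=shrunk,
        true_polygons={poly.id: poly for poly, _ in sampled},
        records=records,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_population_raster(truth, out / "truth.tif")
        for (name, year), grid in grids.items():
            write_population_raster(grid, out / f"{name}_{year}.tif")
        write_reservoir_polygons(list(shrunk.values()), out / "polygons.geojson")
        write_reservoir_table(records, out / "records.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return scenario
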