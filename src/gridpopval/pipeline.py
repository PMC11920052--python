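"""End-to-end orchestration: ingest, filter, extract, score, report.

``run_validation`` wires the whole pipeline on on-disk inputs (rasters
directory + polygons GeoJSON + attribute CSV): it filters the reservoir
records, resolves each dam's reference year, extracts the zonal populations
from the matching dataset grids, applies the area-bias adjustment, and
writes pairs, stratified metrics, audit logs and a JSON summary.
``run_simulate`` materialises a synthetic scenario; ``run_report``
recomputes all metrics from a pairs CSV alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import read_population_raster, read_reservoir_polygons, read_reservoir_table, unmatched_record_ids
from .errors import GridValidationError, NoPairsError
from .extraction import AreaBiasEstimate, estimate_mean_area_bias, predict_all
from .metrics import (
    country_mean_bias,
    evaluate,
    evaluate_group,
    frame_to_pairs,
    group_results_frame,
    pairs_to_frame,
)
from .selection import FilterCriteria, filter_reservoirs, write_audit_log
from .synthetic import SyntheticWorldConfig, generate_scenario
from .temporal import ReferenceYearPolicy

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    rasters_dir: str
    polygons_path: str
    records_path: str
    output_dir: str
    criteria: FilterCriteria = dc_field(default_factory=FilterCriteria)
    policy: ReferenceYearPolicy = dc_field(default_factory=ReferenceYearPolicy)
    refine_factor: int = 10
    bias_source: str = "fixed"  # "fixed" or "estimated"
    fixed_b: float = 0.188
    year_range: tuple[int, int] | None = None
    datasets: tuple[str, ...] | None = None  # None: every non-truth raster
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_source not in ("fixed", "estimated"):
            raise ValueError("bias_source must be 'fixed' or 'estimated'")
        if not (self.fixed_b < 1):
            raise ValueError("fixed_b must be < 1")


def _load_grids(config: RunConfig) -> dict:
    grids = {}
    for path in sorted(Path(config.rasters_dir).glob("*.tif")):
        grid = read_population_raster(path)
        if grid.dataset_name == "truth":
            continue
        if config.datasets is not None and grid.dataset_name not in config.datasets:
            continue
        if grid.reference_year is None:
            raise GridValidationError(f"{path}: raster carries no reference_year tag")
        grids[(grid.dataset_name, grid.reference_year)] = grid
    return grids


def run_validation(config: RunConfig) -> dict:
    """Execute the full validation and write the report bundle.

    Returns a dict with the pairs frame, per-dataset summary and file paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    grids = _load_grids(config)
    if not grids:
        raise GridValidationError(f"no dataset rasters found in {config.rasters_dir}")
    polygons = read_reservoir_polygons(config.polygons_path)
    records = read_reservoir_table(config.records_path)

    unmatched = unmatched_record_ids(records, polygons)
    kept_ids, audit = filter_reservoirs(records, config.criteria)
    write_audit_log(audit, out / "filter_audit.csv")
    kept_records = [r for r in records if r.id in set(kept_ids) and r.id not in set(unmatched)]

    if config.bias_source == "fixed":
        estimate = AreaBiasEstimate(b=config.fixed_b)
    else:
        estimate = estimate_mean_area_bias(
            kept_records, polygons, max_ratio=config.criteria.max_area_ratio
        )

    pairs, skipped = predict_all(
        grids,
        polygons,
        kept_records,
        policy=config.policy,
        estimate=estimate,
        refine_factor=config.refine_factor,
    )
    pd.DataFrame(skipped, columns=["id", "dataset_name", "reason"]).to_csv(
        out / "skip_log.csv", index=False
    )
    if unmatched:
        pd.DataFrame({"id": unmatched, "reason": "no matching polygon"}).to_csv(
            out / "unmatched_records.csv", index=False
        )
    if not pairs:
        raise NoPairsError("validation produced no pairs")

    pairs_df = pairs_to_frame(pairs).sort_values(["dataset_name", "id"], kind="stable")
    # %.17g round-trips doubles exactly, so re-reporting from pairs.csv
    # reproduces every metric bit-for-bit
    pairs_df.to_csv(out / "pairs.csv", index=False, float_format="%.17g")

    # score the sorted pairs so a later re-report from pairs.csv is
    # bit-identical (float summation order matters at the last ulp)
    summary = _summarise(frame_to_pairs(pairs_df), out, year_range=config.year_range)
    summary["area_bias"] = {
        "b": estimate.b,
        "adjustment_factor": estimate.adjustment_factor,
        "n_pairs_used": estimate.n_pairs_used,
        "n_outliers_removed": estimate.n_outliers_removed,
        "source": config.bias_source,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    _write_run_log(config, estimate, len(pairs), out / "run_log.txt")
    return {"pairs": pairs_df, "summary": summary, "output_dir": str(out)}


def _summarise(pairs, out: Path, year_range=None) -> dict:
    by_dataset = evaluate_group(pairs, ["dataset_name"])
    group_results_frame(by_dataset, ["dataset_name"]).to_csv(
        out / "metrics_by_dataset.csv", index=False
    )
    for keys, fname in (
        (["dataset_name", "reference_year"], "metrics_by_dataset_year.csv"),
        (["dataset_name", "income_level"], "metrics_by_dataset_income.csv"),
        (["dataset_name", "country"], "metrics_by_dataset_country.csv"),
    ):
        try:
            res = evaluate_group(pairs, keys, year_range=year_range if "income" in fname else None)
        except NoPairsError:
            continue
        group_results_frame(res, keys).to_csv(out / fname, index=False)

    by_ds_country = evaluate_group(pairs, ["dataset_name", "country"])
    cmb = country_mean_bias(by_ds_country)
    pd.DataFrame(
        {"country": list(cmb), "mean_bias_percent": list(cmb.values())}
    ).to_csv(out / "country_mean_bias.csv", index=False)

    overall = evaluate(pairs)
    return {
        "overall": {"bias_percent": overall.bias_percent, "smape": overall.smape, "n": overall.n},
        "per_dataset": {
            key[0]: {"bias_percent": r.bias_percent, "smape": r.smape, "n": r.n}
            for key, r in by_dataset.items()
        },
    }


def _write_run_log(config: RunConfig, estimate: AreaBiasEstimate, n_pairs: int, path: Path) -> None:
    lines = [
        f"gridpopval {__version__}",
        f"rasters_dir = {config.rasters_dir}",
        f"polygons = {config.polygons_path}",
        f"records = {config.records_path}",
        f"refine_factor = {config.refine_factor}",
        f"bias_source = {config.bias_source} (b = {estimate.b:.6f}, "
        f"factor = {estimate.adjustment_factor:.6f})",
        f"reference-year mode = {config.policy.mode}, valid years = "
        f"{config.policy.valid_reference_years}",
        f"filters: min_area_km2 = {config.criteria.min_area_km2}, "
        f"min_completion_year = {config.criteria.min_completion_year}, "
        f"max_density_per_km2 = {config.criteria.max_density_per_km2}, "
        f"exclude_countries = {list(config.criteria.exclude_countries)}",
        f"seed = {config.seed}",
        f"pairs evaluated = {n_pairs}",
    ]
    path.write_text("\n".join(lines) + "\n")


def run_simulate(config: SyntheticWorldConfig, out_dir: str) -> dict:
    """Generate and write a synthetic scenario; returns its manifest."""
    scenario = generate_scenario(config, out_dir=out_dir)
    return scenario.manifest


def run_report(
    pairs_csv: str,
    out_dir: str,
    exclude_countries: tuple[str, ...] = (),
    year_range: tuple[int, int] | None = None,
) -> dict:
    """Recompute all metrics from a pairs CSV alone (no rasters needed)."""
    df = pd.read_csv(pairs_csv, float_precision="round_trip")
    if df.empty:
        raise NoPairsError(f"no pairs in {pairs_csv}")
    if exclude_countries:
        excluded = {c.upper() for c in exclude_countries}
        df = df[~df["country"].str.upper().isin(excluded)]
    if df.empty:
        raise NoPairsError("no pairs left after country exclusion")
    pairs = frame_to_pairs(df)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = _summarise(pairs, out, year_range=year_range)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
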