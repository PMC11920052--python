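"""Accuracy metrics for validation pairs: bias percentage and sMAPE.

Bias percentage is a ratio of sums,

    Bias = (sum P_predicted - sum P_reported) / sum P_reported * 100%,

in [-100%, +inf): 0% means no systematic error, negative values systematic
underestimation. Because it is a ratio of sums, per-group biases pooled by
summing numerators and denominators reproduce the global bias exactly.

sMAPE is the mean over pairs of |reported - predicted| / (|reported| +
|predicted|), in [0, 1]: 0 is a perfect prediction, 1 an average estimation
error of 100% (e.g. every prediction zero against positive reports). A pair
with both values zero contributes 0 (perfect agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoPairsError
from .extraction import ValidationPair

GROUP_KEYS = ("dataset_name", "reference_year", "income_level", "country")


@dataclass
class AccuracyResult:
    bias_percent: float
    smape: float
    n: int


def pairs_to_frame(pairs: list[ValidationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in pairs],
            "dataset_name": [p.dataset_name for p in pairs],
            "reference_year": [p.reference_year for p in pairs],
            "country": [p.country for p in pairs],
            "income_level": [p.income_level for p in pairs],
            "P_reported": [p.P_reported for p in pairs],
            "P_polygon": [p.P_polygon for p in pairs],
            "P_predicted": [p.P_predicted for p in pairs],
        }
    )


def frame_to_pairs(df: pd.DataFrame) -> list[ValidationPair]:
    return [
        ValidationPair(
            id=str(row.id),
            dataset_name=str(row.dataset_name),
            reference_year=int(row.reference_year),
            country=str(row.country),
            income_level=str(row.income_level),
            P_reported=float(row.P_reported),
            P_polygon=float(getattr(row, "P_polygon", row.P_predicted)),
            P_predicted=float(row.P_predicted),
        )
        for row in df.itertuples(index=False)
    ]


def bias_percentage(pairs: list[ValidationPair]) -> float:
    """Systematic over-/underestimation in percent (ratio of sums)."""
    if not pairs:
        raise NoPairsError("bias percentage needs at least one pair")
    reported = sum(p.P_reported for p in pairs)
    predicted = sum(p.P_predicted for p in pairs)
    if reported <= 0:
        raise NoPairsError("bias percentage undefined: sum of reported populations is 0")
    return (predicted - reported) / reported * 100.0


def smape(pairs: list[ValidationPair]) -> float:
    """Symmetric mean absolute percentage error in [0, 1]."""
    if not pairs:
        raise NoPairsError("sMAPE needs at least one pair")
    terms = []
    for p in pairs:
        denom = abs(p.P_reported) + abs(p.P_predicted)
        terms.append(0.0 if denom == 0 else abs(p.P_reported - p.P_predicted) / denom)
    return float(np.mean(terms))


def evaluate(pairs: list[ValidationPair]) -> AccuracyResult:
    return AccuracyResult(
        bias_percent=bias_percentage(pairs), smape=smape(pairs), n=len(pairs)
    )


def evaluate_group(
    pairs: list[ValidationPair],
    group_keys: tuple[str, ...] | list[str],
    year_range: tuple[int, int] | None = None,
) -> dict[tuple, AccuracyResult]:
    """Both metrics per stratum, keyed by the tuple of group-key values.

    ``group_keys`` is a subset of dataset_name / reference_year /
    income_level / country. ``year_range`` (inclusive) restricts the pairs
    first — used e.g. to limit an income-level analysis to recent map
    vintages so time effects do not confound the comparison.
    """
    if not pairs:
        raise NoPairsError("evaluate_group needs at least one pair")
    keys = list(group_keys)
    unknown = set(keys) - set(GROUP_KEYS)
    if unknown:
        raise ValueError(f"unknown group keys {sorted(unknown)}; allowed: {GROUP_KEYS}")
    if year_range is not None:
        lo, hi = year_range
        pairs = [p for p in pairs if lo <= p.reference_year <= hi]
        if not pairs:
            raise NoPairsError(f"no pairs with reference year in {lo}-{hi}")
    df = pairs_to_frame(pairs)
    out: dict[tuple, AccuracyResult] = {}
    for key, sub in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = evaluate(frame_to_pairs(sub))
    return out


def country_mean_bias(
    results: dict[tuple[str, str], AccuracyResult]
) -> dict[str, float]:
    """Unweighted mean bias over datasets per country.

    ``results`` is keyed (dataset_name, country); countries missing a
    dataset are averaged over the datasets they do have, never zero-filled.
    """
    sums: dict[str, list[float]] = {}
    for (_, country), res in results.items():
        sums.setdefault(country, []).append(res.bias_percent)
    return {c: float(np.mean(v)) for c, v in sorted(sums.items())}


def group_results_frame(results: dict[tuple, AccuracyResult], key_names: list[str]) -> pd.DataFrame:
    """Long-format table of grouped results (one row per stratum)."""
    rows = []
    for key, res in sorted(results.items(), key=lambda kv: tuple(map(str, kv[0]))):
        row = dict(zip(key_names, key))
        row.update(bias_percent=res.bias_percent, smape=res.smape, n=res.n)
        rows.append(row)
    return pd.DataFrame(rows)
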