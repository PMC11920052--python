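"""Reservoir inclusion filters and the area-validation outlier filter.

The inclusion filter mirrors the study-design criteria for a usable
validation area: a resettlement figure must exist, the reported reservoir
surface must exceed 1 km², the dam must have been completed in 1980 or
later, the implied population density (resettled persons over reported
area) must stay below the 1500 people/km² urban-delineation threshold, and
manually flagged transboundary or pre-existing reservoirs are excluded.
Every rejection is audited with the full list of violated criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import ReservoirRecord


@dataclass
class FilterCriteria:
    min_area_km2: float = 1.0
    min_completion_year: int = 1980
    max_density_per_km2: float = 1500.0
    max_area_ratio: float = 5.0
    require_resettlement: bool = True
    exclude_countries: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_area_km2 <= 0 or self.max_density_per_km2 <= 0 or self.max_area_ratio <= 0:
            raise ValueError("all thresholds must be > 0")
        self.exclude_countries = tuple(c.upper() for c in self.exclude_countries)


@dataclass
class AuditEntry:
    id: str
    kept: bool
    reasons: list[str] = field(default_factory=list)


def filter_reservoirs(
    records: list[ReservoirRecord], criteria: FilterCriteria | None = None
) -> tuple[list[str], list[AuditEntry]]:
    """Apply the inclusion criteria; return kept ids and a full audit log.

    A record is kept iff every criterion holds; a rejected record's audit
    entry lists each violated criterion. Area and density thresholds use
    strict inequalities, computed from the reported (attribute-table)
    values — the only quantities available before any geometry work.
    """
    criteria = criteria or FilterCriteria()
    kept: list[str] = []
    audit: list[AuditEntry] = []
    for rec in records:
        reasons: list[str] = []
        if criteria.require_resettlement and rec.resettled_persons is None:
            reasons.append("no resettlement data")
        if not (rec.reported_area_km2 > criteria.min_area_km2):
            reasons.append(
                f"reported area {rec.reported_area_km2:g} km2 <= {criteria.min_area_km2:g} km2"
            )
        if rec.completion_year < criteria.min_completion_year:
            reasons.append(
                f"completion year {rec.completion_year} < {criteria.min_completion_year}"
            )
        if rec.resettled_persons is not None:
            density = rec.resettled_persons / rec.reported_area_km2
            if not (density < criteria.max_density_per_km2):
                reasons.append(
                    f"density {density:g} >= {criteria.max_density_per_km2:g} per km2"
                )
        if rec.excluded_transboundary:
            reasons.append("flagged transboundary")
        if rec.excluded_preexisting:
            reasons.append("flagged pre-existing reservoir")
        if rec.country.upper() in criteria.exclude_countries:
            reasons.append(f"country {rec.country} excluded")
        entry = AuditEntry(id=rec.id, kept=not reasons, reasons=reasons)
        audit.append(entry)
        if entry.kept:
            kept.append(rec.id)
    return kept, audit


def area_outlier_pair_mask(
    pairs: list[tuple[float, float]], max_ratio: float = 5.0
) -> tuple[list[bool], int, int]:
    """Per-pair keep mask for (reported_area, polygon_area) comparisons.

    Returns ``(mask, n_small_reported, n_ratio_outliers)``. A pair is
    dropped when the reported area is <= 1 km² or when the two areas
    disagree by more than ``max_ratio`` in either direction (the ratio test
    is symmetric).
    """
    mask: list[bool] = []
    n_small = 0
    n_outliers = 0
    for reported, polygon in pairs:
        if reported <= 0 or polygon <= 0:
            raise ValueError(f"areas must be > 0, got ({reported}, {polygon})")
        if reported <= 1.0:
            mask.append(False)
            n_small += 1
            continue
        ratio = max(reported / polygon, polygon / reported)
        if ratio > max_ratio:
            mask.append(False)
            n_outliers += 1
        else:
            mask.append(True)
    return mask, n_small, n_outliers


def area_outlier_filter(
    pairs: list[tuple[float, float]], max_ratio: float = 5.0
) -> list[tuple[float, float]]:
    """Keep the (reported_area, polygon_area) pairs that pass the symmetric
    ratio test and have reported area above 1 km²."""
    mask, _, _ = area_outlier_pair_mask(pairs, max_ratio)
    return [p for p, keep in zip(pairs, mask) if keep]


def write_audit_log(audit: list[AuditEntry], path) -> None:
    pd.DataFrame(
        {
            "id": [a.id for a in audit],
            "kept": [a.kept for a in audit],
            "reasons": ["; ".join(a.reasons) for a in audit],
        }
    ).to_csv(path, index=False)
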