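"""Mapping dam completion years to population-map reference years.

The completion year of a dam describes the situation *after* the reservoir
has filled and people have been relocated. Large-dam construction takes close
to a decade on average and resettlement is gradual over the construction
period, so the population map that represents the pre-resettlement situation
is found by rounding the completion year down to the *second* closest 5-year
map vintage:

    Y_reference = Y_completion - (5 + Y_completion mod 5)

which yields a temporal offset of 5-9 years. The ``late`` mode shifts one
more interval back (offset 10-14 years) for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ReferenceYearError


@dataclass
class ReferenceYearPolicy:
    mode: str = "standard"  # "standard" (5-9 y offset) or "late" (10-14 y)
    interval_years: int = 5
    valid_reference_years: tuple[int, int] = (1975, 2010)

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "late"):
            raise ValueError(f"mode must be 'standard' or 'late', got {self.mode!r}")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be > 0")


def select_reference_year(completion_year: int, policy: ReferenceYearPolicy | None = None) -> int:
    """Reference year for a dam completed in ``completion_year``.

    Raises :class:`ReferenceYearError` when the result falls outside the
    policy's valid reference-year range.
    """
    policy = policy or ReferenceYearPolicy()
    k = policy.interval_years
    offset = k + (int(completion_year) % k)
    if policy.mode == "late":
        offset += k
    year = int(completion_year) - offset
    lo, hi = policy.valid_reference_years
    if not (lo <= year <= hi):
        raise ReferenceYearError(
            f"reference year {year} for completion year {completion_year} lies "
            f"outside the valid range {lo}-{hi}",
            year,
        )
    return year
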