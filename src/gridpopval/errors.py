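"""Named exceptions raised across the validation pipeline."""


class GridPopValError(Exception):
    """Base class for all package errors."""


class GridValidationError(GridPopValError):
    """A population grid violates an invariant (negative/non-finite counts,
    non-square cells, bad shape)."""


class PolygonError(GridPopValError):
    """A reservoir polygon is degenerate, self-intersecting, or unparsable."""


class TableError(GridPopValError):
    """An attribute table row violates the schema (duplicate id, unknown
    income label, bad numeric field)."""


class ReferenceYearError(GridPopValError):
    """The temporal-offset rule produced a year outside the valid
    population-map reference-year range."""

    def __init__(self, message: str, year: int):
        super().__init__(message)
        self.year = year


class PackingError(GridPopValError):
    """Reservoir placement failed: the rejection sampler exhausted its
    attempt budget or the requested areas cannot fit the extent."""


class NoPairsError(GridPopValError):
    """A metrics computation received an empty set of validation pairs."""
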