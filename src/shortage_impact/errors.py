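"""Exception hierarchy for shortage-registry processing.

All package-specific failures derive from :class:`ShortageDataError`, so
callers (and the CLI) can distinguish validation problems (exit code 1)
from genuine bugs (exit code 2).
"""

from __future__ import annotations


class ShortageDataError(Exception):
    """Base class for all validation and data-contract failures."""


class SchemaError(ShortageDataError):
    """A registry file is missing a mandatory column or is unreadable."""


class RowValidationError(ShortageDataError):
    """One or more registry rows violate a field invariant.

    Parameters
    ----------
    rows : list of (int, str)
        ``(row_index, message)`` pairs; row indices are zero-based data
        rows (the header does not count).
    """

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = list(rows)
        lines = [f"row {i}: {msg}" for i, msg in self.rows]
        super().__init__(
            f"{len(self.rows)} invalid row(s):\n" + "\n".join(lines)
        )


class ThresholdError(ShortageDataError):
    """Cohort-relative cost thresholds cannot be computed."""


class RatingError(ShortageDataError):
    """An element cannot be rated from the available record attributes."""


class AggregationError(ShortageDataError):
    """An element rating required for aggregation is missing or invalid."""
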