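"""Exception hierarchy.

Everything derives from :class:`SzjitterError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal invalid inputs or parameters.
"""


class SzjitterError(Exception):
    """Base class for all szjitter errors."""


class FormatError(SzjitterError, ValueError):
    """Unknown or malformed file format."""


class SamplingError(SzjitterError, ValueError):
    """Non-uniform or inconsistent sample timing."""


class ParseError(SzjitterError, ValueError):
    """Malformed tabular row; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class ParameterError(SzjitterError, ValueError):
    """Invalid parameter value or combination."""


class EstimationError(SzjitterError, ValueError):
    """Background/baseline estimation impossible (e.g. everything excluded)."""


class InsufficientSpikesError(SzjitterError, ValueError):
    """A spike train has too few spikes for the requested statistic."""


class AlignmentError(SzjitterError, ValueError):
    """No paired intervals (or no common timebase) at the requested alignment."""


class DataError(SzjitterError, ValueError):
    """Non-finite or otherwise unusable input data."""


class BaselineError(SzjitterError, ValueError):
    """Invalid fluorescence baseline (non-positive F0)."""


class UndefinedEventError(SzjitterError, ValueError):
    """A requested event-locked quantity is undefined (no post-event peak)."""


class GenerationError(SzjitterError, RuntimeError):
    """Synthetic generation failed (e.g. timing-noise rejection exhausted)."""


class PlacementError(SzjitterError, ValueError):
    """Synthetic seizure placement conflict (overlapping events)."""
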